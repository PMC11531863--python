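"""Genomic data model and readers/writers for BED, FASTA, UCSC chain and minimal VCF.

Coordinates are 0-based half-open everywhere internally (the BED/chain native
convention); VCF's 1-based POS is converted on read. Genome sequences are
uppercased and restricted to the alphabet {A, C, G, T, N}: any other symbol is
masked to N at load so downstream one-hot encoding has a single unknown symbol.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

VALID_STRANDS = ("+", "-", ".")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome.

    ``strand`` is '+', '-' or '.' (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Window:
    """Unvalidated interval used for context windows that may extend past
    chromosome bounds; ``fetch_sequence`` N-pads the out-of-range part."""

    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus a stable identifier and optional score."""

    interval: GenomicInterval
    id: str
    score: Optional[float] = None


@dataclass
class Genome:
    """In-memory genome: chromosome name -> sequence over {A,C,G,T,N}."""

    species: str
    sequences: dict[str, str]

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class ChainAlignment:
    """One UCSC chain: a block-structured pairwise coordinate map.

    Target (t_*) coordinates refer to the source genome and are always on the
    + strand. Query (q_*) coordinates refer to the destination genome; when
    ``q_strand`` is '-', q_start/q_end are given on the reversed query sequence
    per the UCSC convention. ``blocks`` is an ordered list of
    (aligned_size, gap_after_in_target, gap_after_in_query); the last block has
    zero gaps.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: list[tuple[int, int, int]]
    chain_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.q_strand not in ("+", "-"):
            raise ValueError(f"invalid query strand {self.q_strand!r}")
        if not self.blocks:
            raise ValueError("chain must contain at least one block")
        t_span = sum(size + dt for size, dt, _ in self.blocks)
        q_span = sum(size + dq for size, _, dq in self.blocks)
        ident = self.chain_id if self.chain_id is not None else "<unnamed>"
        if any(size <= 0 or dt < 0 or dq < 0 for size, dt, dq in self.blocks):
            raise ValueError(f"chain {ident}: block sizes must be positive, gaps >= 0")
        if self.blocks[-1][1] != 0 or self.blocks[-1][2] != 0:
            raise ValueError(f"chain {ident}: last block must have zero gaps")
        if t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {ident}: target block sum {t_span} != span "
                f"{self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {ident}: query block sum {q_span} != span "
                f"{self.q_end - self.q_start}"
            )


@dataclass(frozen=True)
class SNPRecord:
    """Single-nucleotide variant. ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if allele not in ("A", "C", "G", "T"):
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3+ file into a list of peaks.

    Coordinates are preserved verbatim (BED is already 0-based half-open).
    Comment (#), track and browser lines and blank lines are skipped. The 4th
    column, when present, becomes the peak id; otherwise ids are generated.
    """
    peaks: list[Peak] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            pid = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"peak_{len(peaks) + 1}"
            if pid in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate peak id {pid!r}")
            seen_ids.add(pid)
            score = None
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            peaks.append(Peak(GenomicInterval(chrom, start, end, strand), pid, score))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6 (score '.' when absent)."""
    with open(path, "w") as fh:
        for peak in peaks:
            iv = peak.interval
            score = "." if peak.score is None else format(peak.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peak.id}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species: Optional[str] = None) -> Genome:
    """Read a FASTA file into a Genome.

    Sequences are uppercased; non-ACGTN symbols are masked to N. Duplicate
    record names are an error. ``species`` defaults to the file stem.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate chromosome name {record.id!r}")
        seq = str(record.seq).upper()
        sequences[record.id] = _NON_ACGTN.sub("N", seq)
    return Genome(species=species or path.stem, sequences=sequences)


def write_fasta(genome: Genome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome: Genome, interval: GenomicInterval | Window) -> str:
    """Extract the sequence of an interval; N-pad outside chromosome bounds.

    Strand '-' returns the reverse complement of the forward-strand slice, so
    context windows at chromosome edges are total (padding contract).
    """
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r} in genome {genome.species}")
    chrom_seq = genome.sequences[interval.chrom]
    size = len(chrom_seq)
    # pads cover the parts of [start, end) outside [0, size); a window wholly
    # outside the chromosome yields all N of the requested length
    left_pad = max(0, min(interval.end, 0) - interval.start)
    right_pad = max(0, interval.end - max(interval.start, size))
    core = chrom_seq[max(0, interval.start) : min(size, interval.end)]
    seq = "N" * left_pad + core + "N" * right_pad
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

def read_chain(path: str | Path) -> list[ChainAlignment]:
    """Parse a UCSC chain file; block-sum invariants are verified on load."""
    chains: list[ChainAlignment] = []
    header: Optional[list[str]] = None
    blocks: list[tuple[int, int, int]] = []

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, *rest) = header
        if t_strand != "+":
            raise ValueError(f"chain {rest[0] if rest else '?'}: target strand must be +")
        chains.append(
            ChainAlignment(
                score=float(score),
                t_name=t_name, t_size=int(t_size), t_start=int(t_start), t_end=int(t_end),
                q_name=q_name, q_size=int(q_size), q_strand=q_strand,
                q_start=int(q_start), q_end=int(q_end),
                blocks=blocks, chain_id=rest[0] if rest else None,
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                finish()
                header = line.split()
                if len(header) < 12:
                    raise ValueError(f"{path}: malformed chain header: {line!r}")
                blocks = []
            else:
                parts = line.split()
                if header is None:
                    raise ValueError(f"{path}: alignment line outside a chain: {line!r}")
                if len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ValueError(f"{path}: malformed block line: {line!r}")
    finish()
    return chains


def write_chain(chains: Iterable[ChainAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, ch in enumerate(chains, start=1):
            cid = ch.chain_id if ch.chain_id is not None else str(i)
            fh.write(
                f"chain {ch.score:g} {ch.t_name} {ch.t_size} + {ch.t_start} {ch.t_end} "
                f"{ch.q_name} {ch.q_size} {ch.q_strand} {ch.q_start} {ch.q_end} {cid}\n"
            )
            for size, dt, dq in ch.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{ch.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

def read_vcf_minimal(path: str | Path) -> list[SNPRecord]:
    """Read CHROM/POS/ID/REF/ALT from a VCF-like text file.

    Only single-nucleotide ref/alt records are retained; multi-allelic records
    are split into one record per alt; indels and non-ACGT alleles are skipped
    (a count is logged).
    """
    records: list[SNPRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            chrom, pos_s, vid, ref, alts = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric POS {pos_s!r}") from exc
            ref = ref.upper()
            for alt in alts.upper().split(","):
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                    n_skipped += 1
                    continue
                records.append(
                    SNPRecord(chrom, pos, ref, alt, id=None if vid in (".", "") else vid)
                )
    if n_skipped:
        logger.info("read_vcf_minimal: skipped %d indel/non-SNV allele(s)", n_skipped)
    return records


def write_vcf_minimal(records: Iterable[SNPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            vid = rec.id if rec.id else "."
            fh.write(f"{rec.chrom}\t{rec.pos}\t{vid}\t{rec.ref}\t{rec.alt}\t.\t.\t.\n")
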