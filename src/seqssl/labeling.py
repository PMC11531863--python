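"""Genome binning, peak-overlap labeling and training-example extraction.

The labeled genome is tiled into non-overlapping 200 b bins. A bin is positive
when more than half of its bases are covered by the union of peaks (strict
inequality: exactly 50% is negative). Two sequence dialects are supported:
``bin_only_200`` (the 200 b bin itself) and ``context_1kb`` (a 1 kb window
centered on the bin, N-padded at chromosome edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_io import Genome, GenomicInterval, Peak, Window, fetch_sequence

DIALECTS = {"bin_only_200": 200, "context_1kb": 1000}


@dataclass(frozen=True)
class BinLabel:
    interval: GenomicInterval
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class SequenceExample:
    """The unit of training: a fixed-length sequence plus label and provenance.

    ``source_chrom`` is the labeled-genome chromosome the example derives from
    (pseudo-labeled examples inherit it from their source peak), used for
    leakage-free chromosome holdout. ``weight`` is the per-example loss weight
    (confidence weight for noisy-student pseudo-positives).
    """

    sequence: str
    label: int
    weight: float = 1.0
    species: str = ""
    origin: str = "labeled"  # "labeled" | "pseudo"
    source_chrom: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.origin not in ("labeled", "pseudo"):
            raise ValueError(f"invalid origin {self.origin!r}")


@dataclass
class LabeledDataset:
    examples: list[SequenceExample]
    dialect: str
    balanced: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        lengths = {len(e.sequence) for e in self.examples}
        if len(lengths) > 1:
            raise ValueError(f"mixed sequence lengths in dataset: {sorted(lengths)}")
        if self.balanced:
            n_pos = sum(e.label for e in self.examples)
            if 2 * n_pos != len(self.examples):
                raise ValueError("balanced flag set but classes are not 1:1")

    def __len__(self) -> int:
        return len(self.examples)

    @property
    def input_length(self) -> int:
        return DIALECTS[self.dialect]


def bin_genome(sizes: dict[str, int], bin_size: int = 200) -> list[GenomicInterval]:
    """Tile each chromosome into non-overlapping bins; a trailing partial bin
    (length < bin_size) is dropped."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[GenomicInterval] = []
    for chrom in sizes:
        n = sizes[chrom] // bin_size
        bins.extend(
            GenomicInterval(chrom, i * bin_size, (i + 1) * bin_size) for i in range(n)
        )
    return bins


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def label_bins(
    bins: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    min_frac: float = 0.5,
) -> list[BinLabel]:
    """Label each bin 1 iff the union of peaks covers strictly more than
    ``min_frac`` of its bases.

    Coverage is computed against the union of peaks so labels are invariant to
    peak fragmentation (two abutting peaks each covering 60 b of a bin yield
    120 b of coverage).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for peak in peaks:
        iv = peak.interval
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    union = {chrom: _union_intervals(ivs) for chrom, ivs in by_chrom.items()}
    starts = {c: np.array([s for s, _ in u]) for c, u in union.items()}
    ends = {c: np.array([e for _, e in u]) for c, u in union.items()}

    labels: list[BinLabel] = []
    for b in bins:
        cov = 0
        if b.chrom in union:
            s_arr, e_arr = starts[b.chrom], ends[b.chrom]
            lo = int(np.searchsorted(e_arr, b.start, side="right"))
            hi = int(np.searchsorted(s_arr, b.end, side="left"))
            for i in range(lo, hi):
                cov += max(0, min(b.end, int(e_arr[i])) - max(b.start, int(s_arr[i])))
        frac = cov / len(b)
        labels.append(BinLabel(b, int(frac > min_frac)))
    return labels


def extract_examples(
    bin_labels: Sequence[BinLabel],
    genome: Genome,
    dialect: str,
) -> list[SequenceExample]:
    """Extract fixed-length sequences for labeled bins.

    ``bin_only_200``: the 200 b bin itself. ``context_1kb``: a 1 kb window with
    the bin midpoint at its center (the bin extended by 400 b each side),
    N-padded at chromosome edges.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    length = DIALECTS[dialect]
    examples: list[SequenceExample] = []
    for bl in bin_labels:
        iv = bl.interval
        if dialect == "bin_only_200":
            seq = fetch_sequence(genome, iv)
        else:
            pad = (length - len(iv)) // 2
            seq = fetch_sequence(genome, Window(iv.chrom, iv.start - pad, iv.end + pad))
        examples.append(
            SequenceExample(
                sequence=seq,
                label=bl.label,
                weight=1.0,
                species=genome.species,
                origin="labeled",
                source_chrom=iv.chrom,
                source_id=f"{iv.chrom}:{iv.start}-{iv.end}",
            )
        )
    return examples


def balance_dataset(
    positives: Sequence[SequenceExample],
    negative_pool: Sequence[SequenceExample],
    seed: int,
    dialect: Optional[str] = None,
) -> LabeledDataset:
    """All positives plus an equal number of negatives sampled uniformly
    without replacement (deterministic given ``seed``)."""
    n = len(positives)
    if len(negative_pool) < n:
        raise ValueError(
            f"negative pool ({len(negative_pool)}) smaller than positives ({n})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negative_pool), size=n, replace=False)
    chosen = [negative_pool[int(i)] for i in idx]
    examples = list(positives) + chosen
    if dialect is None:
        length = len(examples[0].sequence) if examples else 200
        dialect = "bin_only_200" if length == 200 else "context_1kb"
    return LabeledDataset(examples=examples, dialect=dialect, balanced=True)


def write_examples_tsv(examples: Sequence[SequenceExample], path) -> None:
    """Sequence table writer (TSV: sequence, label, weight, species, origin,
    source_chrom, source_id)."""
    with open(path, "w") as fh:
        fh.write("sequence\tlabel\tweight\tspecies\torigin\tsource_chrom\tsource_id\n")
        for e in examples:
            fh.write(
                f"{e.sequence}\t{e.label}\t{e.weight:g}\t{e.species}\t{e.origin}"
                f"\t{e.source_chrom}\t{e.source_id}\n"
            )


def read_examples_tsv(path) -> list[SequenceExample]:
    examples: list[SequenceExample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            examples.append(
                SequenceExample(
                    sequence=row["sequence"],
                    label=int(row["label"]),
                    weight=float(row.get("weight", 1.0)),
                    species=row.get("species", ""),
                    origin=row.get("origin", "labeled"),
                    source_chrom=row.get("source_chrom", ""),
                    source_id=row.get("source_id", ""),
                )
            )
    return examples
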