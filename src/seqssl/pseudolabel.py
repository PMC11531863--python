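"""Cross-species pseudo-labeling: project peaks through chain maps and apply
merge/discard rules.

A peak lifted to another genome may split into several segments (insertions and
deletions in the alignment break the image). Segments separated by gaps smaller
than ``merge_gap`` (default 20 b) are merged into a single homologous peak;
peaks whose images remain split by >= merge_gap, map to several chromosomes or
strands, or do not map at all, yield no homologous peak. Each homologous peak
becomes one pseudo-labeled positive training sequence (a fixed-length window
centered on its midpoint, reverse-complemented for minus-strand homologs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import ChainAlignment, Genome, GenomicInterval, Peak, Window, fetch_sequence
from .labeling import LabeledDataset, SequenceExample, balance_dataset


@dataclass(frozen=True)
class HomologousPeak:
    """The single merged locus a peak maps to on an unlabeled genome."""

    source_peak_id: str
    species: str
    interval: GenomicInterval
    n_merged_loci: int
    q_strand: str

    def __post_init__(self) -> None:
        if self.n_merged_loci < 1:
            raise ValueError("n_merged_loci must be >= 1")
        if self.q_strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.q_strand!r}")


@dataclass
class PseudoLabelReport:
    """Per-species accounting of the remapping outcome.

    Invariant: n_mapped + n_discarded_split + n_discarded_unmapped
    = n_source_peaks.
    """

    species: str
    n_source_peaks: int = 0
    n_mapped: int = 0
    n_merged: int = 0
    n_discarded_split: int = 0
    n_discarded_unmapped: int = 0
    n_dropped_high_n: int = 0

    def validate(self) -> None:
        if (self.n_mapped + self.n_discarded_split + self.n_discarded_unmapped
                != self.n_source_peaks):
            raise AssertionError("pseudo-label report counts do not partition the peaks")


def _map_through_chain(
    interval: GenomicInterval, chain: ChainAlignment
) -> list[GenomicInterval]:
    """Project a target-genome interval through one chain's aligned blocks.

    Returns forward-strand query intervals carrying the chain's query strand
    (UCSC convention: minus-strand block coordinates live on the reversed
    query; forward_start = q_size - reversed_end). Gaps split the image.
    """
    if interval.chrom != chain.t_name:
        return []
    out: list[GenomicInterval] = []
    t_pos, q_pos = chain.t_start, chain.q_start
    for size, dt, dq in chain.blocks:
        t0, t1 = t_pos, t_pos + size
        lo, hi = max(interval.start, t0), min(interval.end, t1)
        if hi > lo:
            qs = q_pos + (lo - t0)
            qe = q_pos + (hi - t0)
            if chain.q_strand == "-":
                fs, fe = chain.q_size - qe, chain.q_size - qs
            else:
                fs, fe = qs, qe
            out.append(GenomicInterval(chain.q_name, fs, fe, chain.q_strand))
        t_pos = t1 + dt
        q_pos += size + dq
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def map_interval(
    interval: GenomicInterval, chains: Sequence[ChainAlignment]
) -> list[GenomicInterval]:
    """Project an interval through every chain; pooled segments sorted by
    query position. Unmapped intervals yield an empty list."""
    segments: list[GenomicInterval] = []
    for chain in chains:
        segments.extend(_map_through_chain(interval, chain))
    segments.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return segments


def merge_segments(
    segments: Sequence[GenomicInterval], merge_gap: int = 20
) -> list[GenomicInterval]:
    """Iteratively merge same-chromosome, same-strand segments whose gap is
    strictly smaller than ``merge_gap``; overlapping segments always merge.

    The gap between [s1,e1) and [s2,e2) with s2 >= e1 is s2 - e1 (so a gap of
    19 merges and a gap of 20 does not). Returns the merged loci sorted by
    position; segments on different chromosomes or strands are never merged.
    """
    if merge_gap <= 0:
        raise ValueError("merge_gap must be positive")
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for seg in segments:
        groups.setdefault((seg.chrom, seg.strand), []).append(seg)
    merged: list[GenomicInterval] = []
    for (chrom, strand), segs in groups.items():
        segs.sort(key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = segs[0].start, segs[0].end
        for seg in segs[1:]:
            if seg.start - cur_e < merge_gap:
                cur_e = max(cur_e, seg.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
                cur_s, cur_e = seg.start, seg.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e, strand))
    merged.sort(key=lambda iv: (iv.chrom, iv.start))
    return merged


def remap_peak(
    peak: Peak,
    chains: Sequence[ChainAlignment],
    species: str = "",
    merge_gap: int = 20,
) -> Optional[HomologousPeak]:
    """Remap one peak to the query genome, applying the merge/discard rules.

    When several chains cover the peak, the highest-score chain is tried
    first; lower-score chains are consulted only if it yields no segments
    (mirrors liftOver's best-chain behavior). Returns None when the peak is
    unmapped, its image stays split by >= merge_gap, or the surviving segments
    lie on different chromosomes or strands.
    """
    segments: list[GenomicInterval] = []
    for chain in sorted(chains, key=lambda c: -c.score):
        segments = _map_through_chain(peak.interval, chain)
        if segments:
            break
    if not segments:
        return None
    if len({(s.chrom, s.strand) for s in segments}) > 1:
        return None
    merged = merge_segments(segments, merge_gap=merge_gap)
    if len(merged) != 1:
        return None
    locus = merged[0]
    return HomologousPeak(
        source_peak_id=peak.id,
        species=species,
        interval=locus,
        n_merged_loci=len(segments),
        q_strand=locus.strand if locus.strand in ("+", "-") else "+",
    )


def pseudolabel_species(
    peaks: Sequence[Peak],
    species_genome: Genome,
    chains: Sequence[ChainAlignment],
    example_length: int,
    merge_gap: int = 20,
    max_n_frac: float = 0.5,
) -> tuple[list[SequenceExample], list[HomologousPeak], PseudoLabelReport]:
    """Emit one pseudo-labeled positive example per peak with a homologous peak.

    The example is a window of ``example_length`` centered on the homologous
    peak midpoint (floor of (start+end)/2), fetched on the homologous strand
    (reverse complement when the peak lifted to the minus strand). Windows with
    more than ``max_n_frac`` N content are dropped and counted. Examples keep
    the source peak's labeled-genome chromosome for holdout splitting.
    """
    peaks_by_id = {p.id: p for p in peaks}
    report = PseudoLabelReport(species=species_genome.species, n_source_peaks=len(peaks))
    examples: list[SequenceExample] = []
    homologs: list[HomologousPeak] = []
    half = example_length // 2
    for peak in peaks:
        segments: list[GenomicInterval] = []
        for chain in sorted(chains, key=lambda c: -c.score):
            segments = _map_through_chain(peak.interval, chain)
            if segments:
                break
        if not segments:
            report.n_discarded_unmapped += 1
            continue
        hp = remap_peak(peak, chains, species=species_genome.species, merge_gap=merge_gap)
        if hp is None:
            report.n_discarded_split += 1
            continue
        report.n_mapped += 1
        if hp.n_merged_loci > 1:
            report.n_merged += 1
        homologs.append(hp)
        mid = hp.interval.midpoint
        window = Window(hp.interval.chrom, mid - half, mid - half + example_length,
                        hp.q_strand)
        seq = fetch_sequence(species_genome, window)
        if seq.count("N") > max_n_frac * len(seq):
            report.n_dropped_high_n += 1
            continue
        source_peak = peaks_by_id[hp.source_peak_id]
        examples.append(
            SequenceExample(
                sequence=seq,
                label=1,
                weight=1.0,
                species=species_genome.species,
                origin="pseudo",
                source_chrom=source_peak.interval.chrom,
                source_id=f"{species_genome.species}:{peak.id}",
            )
        )
    report.validate()
    return examples, homologs, report


def assemble_pretraining_set(
    pseudo_positives: Sequence[SequenceExample],
    labeled_negative_pool: Sequence[SequenceExample],
    seed: int,
    dialect: Optional[str] = None,
) -> LabeledDataset:
    """Pooled pseudo-positives plus an equal count of labeled-genome negatives.

    With zero pseudo-positives returns an empty (degenerate) dataset; training
    then falls back to plain supervised learning.
    """
    if not pseudo_positives:
        import warnings

        warnings.warn("no pseudo-positive examples: pretraining set is empty")
        return LabeledDataset(examples=[], dialect=dialect or "bin_only_200",
                              balanced=True)
    return balance_dataset(pseudo_positives, labeled_negative_pool, seed=seed,
                           dialect=dialect)
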