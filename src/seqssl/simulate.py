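"""Synthetic multi-species genome simulator with ground truth for every
pipeline contract.

An ancestral "labeled" genome is drawn as i.i.d. uniform background with
motif-driven peaks planted at non-overlapping positions (each peak carries at
least one instance sampled from a position weight matrix). Descendant genomes
are produced independently (star phylogeny) by per-base substitutions and
geometric-length insertions/deletions; the exact edit history is emitted as
UCSC chain alignments (ancestor = target, descendant = query), so liftover has
real work — substitutions shift nothing, indels shift coordinates and split
mappings — without any aligner in the loop. SNPs are planted half inside motif
instances (with a known position-weight log-odds delta) and half in background
(delta 0), giving ground truth for variant effect scoring.

Functional conservation is modeled as sequence conservation of the planted
motif: a pseudo-label is correct by construction whenever the motif survives,
and a deletion that removes more than half of a peak marks its homolog lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core_io import (ChainAlignment, Genome, GenomicInterval, Peak, SNPRecord,
                      write_bed, write_chain, write_fasta, write_vcf_minimal)

_BASES = np.array(list("ACGT"))


def default_pwm(width: int = 12, dominant: float = 0.85,
                seed: int = 12345) -> np.ndarray:
    """A fixed informative PWM: one dominant base per position (probability
    ``dominant``), the rest uniform. Width 12 sits in the typical TF range."""
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=width)
    pwm = np.full((width, 4), (1.0 - dominant) / 3.0)
    pwm[np.arange(width), consensus] = dominant
    return pwm


@dataclass(frozen=True)
class SimConfig:
    """The stated synthetic world.

    The default preset — a 1 Mb genome over 4 chromosomes, 300 peaks with
    widths in the 150-450 b range (median ~300 b, matching real peak-size
    medians of roughly 170-440 b), 10 descendant species at substitution rate
    0.03/base and indel rate 0.002/base (geometric mean length 5) — trains a
    shallow CNN in minutes on one CPU.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 4
    n_peaks: int = 300
    peak_width_min: int = 150
    peak_width_max: int = 450
    motif_width: int = 12
    planting_prob: float = 1.0
    n_species: int = 10
    sub_rate: float = 0.03
    indel_rate: float = 0.002
    indel_geom_p: float = 0.2  # geometric length parameter; mean length 1/p = 5
    n_snps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.indel_rate, self.planting_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates/probabilities must be in [0, 1]")
        if not 0 < self.indel_geom_p <= 1:
            raise ValueError("indel_geom_p must be in (0, 1]")
        if self.genome_length < self.n_peaks * self.peak_width_max * 2:
            raise ValueError("genome too short for the requested peaks")

    def pwm(self) -> np.ndarray:
        return default_pwm(self.motif_width)


@dataclass(frozen=True)
class MotifSite:
    """A planted motif instance on the labeled genome."""

    chrom: str
    start: int
    peak_id: str


@dataclass
class SpeciesSim:
    genome: Genome
    chains: list[ChainAlignment]
    # peak id -> homologous interval on this species, or None when lost
    true_homologs: dict[str, Optional[GenomicInterval]]


@dataclass(frozen=True)
class SimulatedSNP:
    record: SNPRecord
    true_effect_sign: int  # -1 motif-disrupting, 0 background
    motif_score_delta: float  # log2 PWM odds of alt vs ref (0 for background)


@dataclass
class SyntheticGenomeSet:
    config: SimConfig
    labeled_genome: Genome
    labeled_peaks: list[Peak]
    motif_sites: list[MotifSite]
    species: list[SpeciesSim]
    snps: list[SimulatedSNP] = field(default_factory=list)


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_labeled_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Genome, list[Peak], list[MotifSite]]:
    """Background genome with planted, non-overlapping motif-bearing peaks."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pwm = config.pwm()
    names = _chrom_names(config.n_chromosomes)
    chrom_len = config.genome_length // config.n_chromosomes
    arrays = {name: rng.integers(0, 4, size=chrom_len, dtype=np.int8) for name in names}

    peaks: list[Peak] = []
    sites: list[MotifSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in names}
    attempts = 0
    while len(peaks) < config.n_peaks:
        attempts += 1
        if attempts > 50 * max(config.n_peaks, 1):
            raise RuntimeError("could not place non-overlapping peaks; genome too dense")
        width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
        chrom = names[int(rng.integers(len(names)))]
        if chrom_len <= width:
            continue
        start = int(rng.integers(0, chrom_len - width))
        if any(start < e and s < start + width for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + width))
        pid = f"peak_{len(peaks) + 1}"
        peaks.append(Peak(GenomicInterval(chrom, start, start + width), pid))
        if rng.random() < config.planting_prob:
            if config.motif_width > width:
                raise ValueError("motif wider than the peak; cannot plant")
            offset = int(rng.integers(0, width - config.motif_width + 1))
            instance = np.array(
                [rng.choice(4, p=pwm[j]) for j in range(config.motif_width)],
                dtype=np.int8,
            )
            arrays[chrom][start + offset : start + offset + config.motif_width] = instance
            sites.append(MotifSite(chrom, start + offset, pid))
    sequences = {name: "".join(_BASES[arr]) for name, arr in arrays.items()}
    peaks.sort(key=lambda p: (p.interval.chrom, p.interval.start))
    return Genome("labeled", sequences), peaks, sites


def _evolve_chrom(
    parent_codes: np.ndarray, sub_rate: float, indel_rate: float,
    indel_geom_p: float, rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int]], np.ndarray]:
    """Evolve one chromosome; returns (child codes, alignment ops, pos_map).

    ops is a list of ('M', n) / ('D', n) / ('I', n) items in parent order;
    pos_map[i] is the child coordinate of parent base i, or -1 if deleted.
    """
    L = len(parent_codes)
    mutated = parent_codes.copy()
    if sub_rate > 0:
        sub_mask = rng.random(L) < sub_rate
        shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
        mutated[sub_mask] = (mutated[sub_mask] + shifts) % 4

    events: list[tuple[int, str, int]] = []  # (parent pos, kind, length)
    if indel_rate > 0:
        ev_mask = rng.random(L) < indel_rate
        positions = np.flatnonzero(ev_mask)
        kinds = rng.random(len(positions)) < 0.5
        lengths = rng.geometric(indel_geom_p, size=len(positions))
        for pos, is_del, length in zip(positions, kinds, lengths):
            events.append((int(pos), "D" if is_del else "I", int(length)))

    child_parts: list[np.ndarray] = []
    ops: list[tuple[str, int]] = []
    pos_map = np.full(L, -1, dtype=np.int64)
    cur = 0          # parent cursor
    child_len = 0    # child cursor

    def emit_match(upto: int) -> None:
        nonlocal cur, child_len
        if upto > cur:
            n = upto - cur
            child_parts.append(mutated[cur:upto])
            pos_map[cur:upto] = np.arange(child_len, child_len + n)
            ops.append(("M", n))
            cur = upto
            child_len += n

    for pos, kind, length in events:
        if pos < cur:
            continue  # swallowed by a previous deletion
        emit_match(pos)
        if kind == "D":
            d = min(length, L - pos)
            if d > 0:
                ops.append(("D", d))
                cur += d
        else:
            ins = rng.integers(0, 4, size=length, dtype=np.int8)
            child_parts.append(ins)
            ops.append(("I", length))
            child_len += length
    emit_match(L)
    child = np.concatenate(child_parts) if child_parts else np.empty(0, dtype=np.int8)
    return child, ops, pos_map


def _ops_to_chain(ops: list[tuple[str, int]], chrom: str, t_size: int,
                  q_size: int, chain_id: str) -> Optional[ChainAlignment]:
    """Convert an alignment op list into a chain (gaps merged, leading and
    trailing gaps folded into the chain spans)."""
    # merge runs: aligned blocks separated by (dt, dq) gap pairs
    t_pos = q_pos = 0
    t_start = q_start = None
    blocks: list[list[int]] = []  # [size, dt, dq]
    for kind, n in ops:
        if kind == "M":
            if t_start is None:
                t_start, q_start = t_pos, q_pos
            blocks.append([n, 0, 0])
            t_pos += n
            q_pos += n
        elif kind == "D":
            if blocks:
                blocks[-1][1] += n
            t_pos += n
        else:  # I
            if blocks:
                blocks[-1][2] += n
            q_pos += n
    if not blocks:
        return None
    # trailing gaps were accumulated on the last block; fold them off
    last = blocks[-1]
    t_end = t_start + sum(b[0] + b[1] for b in blocks) - last[1]
    q_end = q_start + sum(b[0] + b[2] for b in blocks) - last[2]
    last[1] = last[2] = 0
    aligned = sum(b[0] for b in blocks)
    return ChainAlignment(
        score=float(aligned), t_name=chrom, t_size=t_size,
        t_start=int(t_start), t_end=int(t_end),
        q_name=chrom, q_size=q_size, q_strand="+",
        q_start=int(q_start), q_end=int(q_end),
        blocks=[tuple(b) for b in blocks], chain_id=chain_id,
    )


def evolve_genome(
    parent: Genome, sub_rate: float, indel_rate: float,
    indel_geom_p: float = 0.2, seed: int = 0, species: str = "descendant",
) -> tuple[Genome, list[ChainAlignment], dict[str, np.ndarray]]:
    """Evolve a descendant genome and emit exact parent->child chains.

    Zero rates yield an identical child and one identity chain per chromosome.
    Also returns, per chromosome, the parent-to-child position map (-1 marks a
    deleted base) — the edit-history ground truth used for true homologs.
    """
    rng = np.random.default_rng(seed)
    code = {b: i for i, b in enumerate("ACGT")}
    sequences: dict[str, str] = {}
    chains: list[ChainAlignment] = []
    pos_maps: dict[str, np.ndarray] = {}
    for i, (chrom, seq) in enumerate(parent.sequences.items()):
        parent_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int8)
        for b, c in code.items():
            lut[ord(b)] = c
        parent_codes = lut[parent_codes]
        child, ops, pos_map = _evolve_chrom(parent_codes, sub_rate, indel_rate,
                                            indel_geom_p, rng)
        sequences[chrom] = "".join(_BASES[child])
        pos_maps[chrom] = pos_map
        chain = _ops_to_chain(ops, chrom, t_size=len(seq), q_size=len(child),
                              chain_id=f"{species}.{i + 1}")
        if chain is not None:
            chains.append(chain)
    return Genome(species, sequences), chains, pos_maps


def _true_homolog(peak: Peak, pos_map: np.ndarray) -> Optional[GenomicInterval]:
    """Homologous interval from the edit history; lost when a deletion removed
    more than half of the peak's bases."""
    mapped = pos_map[peak.interval.start : peak.interval.end]
    surviving = mapped[mapped >= 0]
    if len(surviving) <= len(mapped) / 2:
        return None
    return GenomicInterval(peak.interval.chrom, int(surviving.min()),
                           int(surviving.max()) + 1)


def simulate_species_set(config: SimConfig) -> SyntheticGenomeSet:
    """Full synthetic world: labeled genome, descendant species with chains and
    edit-history homolog truth, and planted SNPs."""
    rng = np.random.default_rng(config.seed)
    labeled, peaks, sites = simulate_labeled_genome(config, rng)
    species: list[SpeciesSim] = []
    for k in range(config.n_species):
        sp_seed = int(np.random.SeedSequence([config.seed, k + 1]).generate_state(1)[0]
                      % (2**31))
        name = f"species_{k + 1}"
        genome, chains, pos_maps = evolve_genome(
            labeled, config.sub_rate, config.indel_rate, config.indel_geom_p,
            seed=sp_seed, species=name,
        )
        homologs = {
            p.id: _true_homolog(p, pos_maps[p.interval.chrom]) for p in peaks
        }
        species.append(SpeciesSim(genome, chains, homologs))
    gset = SyntheticGenomeSet(config, labeled, peaks, sites, species)
    gset.snps = simulate_snps(gset, config.n_snps,
                              seed=int(np.random.SeedSequence([config.seed, 777])
                                       .generate_state(1)[0] % (2**31)))
    return gset


def simulate_snps(genome_set: SyntheticGenomeSet, n_snps: int,
                  seed: int = 0) -> list[SimulatedSNP]:
    """Plant SNPs: half inside motif instances (alt = the least likely base at
    that PWM column, log2-odds delta recorded), half in background (delta 0).
    The reference allele always matches the genome."""
    rng = np.random.default_rng(seed)
    config = genome_set.config
    pwm = config.pwm()
    genome = genome_set.labeled_genome
    sites = genome_set.motif_sites
    if not sites:
        raise ValueError("no planted motif instances to place SNPs in")
    peak_spans: dict[str, list[tuple[int, int]]] = {}
    for p in genome_set.labeled_peaks:
        peak_spans.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end))

    snps: list[SimulatedSNP] = []
    n_motif = n_snps // 2
    base_idx = {b: i for i, b in enumerate("ACGT")}
    used: set[tuple[str, int]] = set()
    while sum(1 for s in snps if s.true_effect_sign != 0) < n_motif:
        site = sites[int(rng.integers(len(sites)))]
        offset = int(rng.integers(config.motif_width))
        pos0 = site.start + offset
        if (site.chrom, pos0) in used:
            continue
        used.add((site.chrom, pos0))
        ref = genome.sequences[site.chrom][pos0]
        probs = pwm[offset]
        alt_i = int(np.argmin(probs + (np.arange(4) == base_idx[ref]) * 10))
        alt = "ACGT"[alt_i]
        delta = float(np.log2(probs[alt_i] / probs[base_idx[ref]]))
        snps.append(SimulatedSNP(
            SNPRecord(site.chrom, pos0 + 1, ref, alt, id=f"snp_m{len(snps) + 1}"),
            true_effect_sign=int(np.sign(delta)), motif_score_delta=delta,
        ))
    sizes = genome.sizes
    chroms = list(sizes)
    while len(snps) < n_snps:
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos0 = int(rng.integers(sizes[chrom]))
        if (chrom, pos0) in used:
            continue
        if any(s <= pos0 < e for s, e in peak_spans.get(chrom, [])):
            continue
        used.add((chrom, pos0))
        ref = genome.sequences[chrom][pos0]
        if ref == "N":
            continue
        alt = "ACGT"[(base_idx[ref] + int(rng.integers(1, 4))) % 4]
        snps.append(SimulatedSNP(
            SNPRecord(chrom, pos0 + 1, ref, alt, id=f"snp_b{len(snps) + 1}"),
            true_effect_sign=0, motif_score_delta=0.0,
        ))
    return snps


def write_genome_set(genome_set: SyntheticGenomeSet, out_dir: str | Path) -> None:
    """Write the fixture to disk: labeled.fa, labeled_peaks.bed, per-species
    FASTA + chain, snps.vcf and a truth table (TSV). Byte-identical given the
    same (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome_set.labeled_genome, out / "labeled.fa")
    write_bed(genome_set.labeled_peaks, out / "labeled_peaks.bed")
    for sp in genome_set.species:
        write_fasta(sp.genome, out / f"{sp.genome.species}.fa")
        write_chain(sp.chains, out / f"{sp.genome.species}.chain")
    write_vcf_minimal([s.record for s in genome_set.snps], out / "snps.vcf")
    with open(out / "snp_truth.tsv", "w") as fh:
        fh.write("id\tchrom\tpos\tref\talt\ttrue_effect_sign\tmotif_score_delta\n")
        for s in genome_set.snps:
            r = s.record
            fh.write(f"{r.id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}"
                     f"\t{s.true_effect_sign}\t{s.motif_score_delta:.4f}\n")
    with open(out / "homolog_truth.tsv", "w") as fh:
        fh.write("species\tpeak_id\tchrom\tstart\tend\n")
        for sp in genome_set.species:
            for pid, iv in sp.true_homologs.items():
                if iv is None:
                    fh.write(f"{sp.genome.species}\t{pid}\t.\t.\t.\n")
                else:
                    fh.write(f"{sp.genome.species}\t{pid}\t{iv.chrom}"
                             f"\t{iv.start}\t{iv.end}\n")
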