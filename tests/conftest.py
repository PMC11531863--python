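import numpy as np
import pytest

from seqssl.core_io import ChainAlignment, Genome, GenomicInterval, Peak
from seqssl.simulate import SimConfig, simulate_species_set


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(42)
    seqs = {
        "chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)]),
        "chr2": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)]),
    }
    return Genome("toy", seqs)


def identity_chain(chrom: str, size: int, score: float = 1000.0) -> ChainAlignment:
    """One block covering the whole chromosome, no gaps."""
    return ChainAlignment(
        score=score, t_name=chrom, t_size=size, t_start=0, t_end=size,
        q_name=chrom, q_size=size, q_strand="+", q_start=0, q_end=size,
        blocks=[(size, 0, 0)], chain_id="id",
    )


def make_chain(t_name, t_size, t_start, blocks, q_name, q_size, q_strand,
               q_start, score=1000.0, chain_id="c1"):
    """Chain from explicit blocks [(size, dt, dq), ...] with derived ends."""
    t_end = t_start + sum(s + dt for s, dt, _ in blocks)
    q_end = q_start + sum(s + dq for s, _, dq in blocks)
    return ChainAlignment(score=score, t_name=t_name, t_size=t_size,
                          t_start=t_start, t_end=t_end, q_name=q_name,
                          q_size=q_size, q_strand=q_strand, q_start=q_start,
                          q_end=q_end, blocks=blocks, chain_id=chain_id)


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic multi-species world, shared across tests."""
    cfg = SimConfig(genome_length=240_000, n_chromosomes=4, n_peaks=80,
                    n_species=5, n_snps=80, seed=11)
    return simulate_species_set(cfg)
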