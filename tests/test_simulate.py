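import numpy as np
import pytest

from seqssl.core_io import read_chain, write_chain
from seqssl.pseudolabel import pseudolabel_species, remap_peak
from seqssl.simulate import (SimConfig, default_pwm, evolve_genome,
                             simulate_labeled_genome, simulate_snps,
                             simulate_species_set)

SMALL = SimConfig(genome_length=120_000, n_chromosomes=2, n_peaks=40,
                  n_species=2, n_snps=40, seed=3)


def pwm_scan_best(seq, pwm):
    """Independent best log-probability PWM hit over a sequence."""
    idx = {b: i for i, b in enumerate("ACGT")}
    logp = np.log(pwm)
    w = pwm.shape[0]
    codes = np.array([idx.get(b, -1) for b in seq])
    best = -np.inf
    for s in range(len(seq) - w + 1):
        window = codes[s : s + w]
        if (window < 0).any():
            continue
        best = max(best, float(logp[np.arange(w), window].sum()))
    return best


class TestLabeledGenome:
    def test_peaks_disjoint_and_motif_planted(self):
        genome, peaks, sites = simulate_labeled_genome(SMALL)
        by_chrom = {}
        for p in peaks:
            by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start
        pwm = SMALL.pwm()
        # background 90th percentile of best hit on random 300-mers
        rng = np.random.default_rng(0)
        bg = [pwm_scan_best("".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]), pwm)
              for _ in range(50)]
        threshold = np.quantile(bg, 0.9)
        planted = {s.peak_id for s in sites}
        hits = 0
        for p in peaks:
            if p.id not in planted:
                continue
            seq = genome.sequences[p.interval.chrom][p.interval.start:p.interval.end]
            if pwm_scan_best(seq, pwm) > threshold:
                hits += 1
        # instances are sampled from the PWM, so a few draws land in the
        # background score tail; the bulk must still scan as strong hits
        assert hits / len(planted) >= 0.85

    def test_no_peaks_gives_background_only(self):
        cfg = SimConfig(genome_length=50_000, n_chromosomes=1, n_peaks=0,
                        n_species=1, seed=1)
        genome, peaks, sites = simulate_labeled_genome(cfg)
        assert peaks == [] and sites == []
        assert len(genome.sequences["chr1"]) == 50_000

    def test_motif_wider_than_peak_rejected(self):
        cfg = SimConfig(genome_length=200_000, n_chromosomes=1, n_peaks=5,
                        peak_width_min=10, peak_width_max=11, motif_width=12,
                        seed=1)
        with pytest.raises(ValueError, match="motif"):
            simulate_labeled_genome(cfg)


class TestEvolveGenome:
    def test_zero_rates_identity(self):
        genome, _, _ = simulate_labeled_genome(SMALL)
        child, chains, pos_maps = evolve_genome(genome, 0.0, 0.0, seed=1)
        assert child.sequences == genome.sequences
        for ch in chains:
            assert ch.blocks == [(ch.t_end - ch.t_start, 0, 0)]
            assert ch.t_start == 0 and ch.t_end == ch.t_size
        for chrom, pm in pos_maps.items():
            np.testing.assert_array_equal(pm, np.arange(len(genome.sequences[chrom])))

    def test_substitution_rate_binomial_check(self):
        genome, _, _ = simulate_labeled_genome(
            SimConfig(genome_length=100_000, n_chromosomes=1, n_peaks=0, seed=2))
        rate = 0.05
        child, _, _ = evolve_genome(genome, rate, 0.0, seed=3)
        a = np.frombuffer(genome.sequences["chr1"].encode(), dtype=np.uint8)
        b = np.frombuffer(child.sequences["chr1"].encode(), dtype=np.uint8)
        mismatch = (a != b).mean()
        sigma = np.sqrt(rate * (1 - rate) / len(a))
        assert abs(mismatch - rate) < 3 * sigma

    def test_indels_shift_coordinates_and_chains_validate(self, tmp_path):
        genome, _, _ = simulate_labeled_genome(SMALL)
        child, chains, pos_maps = evolve_genome(genome, 0.01, 0.005, seed=4)
        assert any(len(ch.blocks) > 1 for ch in chains)
        # writer -> reader round trip revalidates every block-sum invariant
        path = tmp_path / "evo.chain"
        write_chain(chains, path)
        assert read_chain(path) == chains

    def test_deletion_yields_target_gap(self):
        from seqssl.core_io import Genome

        rng = np.random.default_rng(0)
        parent = Genome("p", {"c": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])})
        # high deletion pressure guarantees target gaps (dt > 0) in the chain
        child, chains, _ = evolve_genome(parent, 0.0, 0.02, indel_geom_p=0.1, seed=5)
        (ch,) = chains
        assert any(dt > 0 for _, dt, _ in ch.blocks[:-1])


class TestSpeciesSet:
    def test_truth_agrees_with_chain_remapping(self, small_world):
        """Edit-history homolog truth and chain-based remapping agree on >= 95%
        of recovered peaks within +/- 10 b (indel rounding tolerance)."""
        agree = total = 0
        for sp in small_world.species:
            for peak in small_world.labeled_peaks:
                hp = remap_peak(peak, sp.chains, species=sp.genome.species)
                truth = sp.true_homologs[peak.id]
                if hp is None or truth is None:
                    continue
                total += 1
                if (abs(hp.interval.start - truth.start) <= 10
                        and abs(hp.interval.end - truth.end) <= 10):
                    agree += 1
        assert total > 0
        assert agree / total >= 0.95

    def test_low_rate_recovery_band(self, small_world):
        """At the default low divergence most (peak, species) pairs recover,
        echoing the ~80% conservation regime."""
        recovered = 0
        n_pairs = len(small_world.species) * len(small_world.labeled_peaks)
        for sp in small_world.species:
            _, homologs, report = pseudolabel_species(
                small_world.labeled_peaks, sp.genome, sp.chains, 200)
            recovered += report.n_mapped
            report.validate()
        assert recovered / n_pairs >= 0.8

    def test_recovery_drops_monotonically_with_indel_rate(self):
        fracs = []
        for rate in (0.0005, 0.005, 0.03):
            cfg = SimConfig(genome_length=100_000, n_chromosomes=2, n_peaks=30,
                            n_species=1, indel_rate=rate, seed=9)
            gs = simulate_species_set(cfg)
            sp = gs.species[0]
            n_ok = sum(
                remap_peak(p, sp.chains) is not None for p in gs.labeled_peaks)
            fracs.append(n_ok / len(gs.labeled_peaks))
        assert fracs[0] >= fracs[1] >= fracs[2]
        assert fracs[0] > fracs[2]


class TestSimulatedSNPs:
    def test_motif_snps_disrupt_and_background_is_neutral(self, small_world):
        motif = [s for s in small_world.snps if s.true_effect_sign != 0]
        background = [s for s in small_world.snps if s.true_effect_sign == 0]
        assert motif and background
        # disruptive alt = least likely base at an informative column
        assert all(s.motif_score_delta < 0 for s in motif)
        assert all(s.motif_score_delta == 0 for s in background)

    def test_ref_allele_always_matches_genome(self, small_world):
        g = small_world.labeled_genome
        for s in small_world.snps:
            assert g.sequences[s.record.chrom][s.record.pos0] == s.record.ref

    def test_most_informative_position_gives_strongest_delta(self):
        pwm = default_pwm()
        consensus = pwm.argmax(axis=1)
        # consensus base vs least likely alternative at a dominant column
        delta = np.log2(pwm[0].min() / pwm[0, consensus[0]])
        assert delta < -3  # 0.05 vs 0.85 is a > 4-octave drop
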