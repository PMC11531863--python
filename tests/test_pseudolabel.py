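import numpy as np
import pytest

from seqssl.core_io import Genome, GenomicInterval, Peak, reverse_complement
from seqssl.labeling import SequenceExample
from seqssl.pseudolabel import (assemble_pretraining_set, map_interval,
                                merge_segments, pseudolabel_species, remap_peak)

from conftest import identity_chain, make_chain


def seg(chrom, s, e, strand="+"):
    return GenomicInterval(chrom, s, e, strand)


class TestMapInterval:
    def test_identity_chain_maps_to_itself(self):
        ch = identity_chain("chr1", 10_000)
        iv = seg("chr1", 1000, 1200)
        assert map_interval(iv, [ch]) == [seg("chr1", 1000, 1200, "+")]

    def test_query_gap_splits_image(self):
        # 30 b insertion in the query inside the interval -> two segments
        ch = make_chain("chr1", 10_000, 0, [(500, 0, 30), (500, 0, 0)],
                        "chrQ", 10_030, "+", 0)
        segs = map_interval(seg("chr1", 400, 600), [ch])
        assert segs == [seg("chrQ", 400, 500, "+"), seg("chrQ", 530, 630, "+")]

    def test_target_gap_drops_deleted_bases(self):
        # 50 b deleted from the query: those target bases project to nothing
        ch = make_chain("chr1", 10_000, 0, [(500, 50, 0), (450, 0, 0)],
                        "chrQ", 950, "+", 0)
        segs = map_interval(seg("chr1", 480, 560), [ch])
        assert segs == [seg("chrQ", 480, 500, "+"), seg("chrQ", 500, 510, "+")]

    def test_outside_every_chain_is_empty(self):
        ch = make_chain("chr1", 10_000, 0, [(500, 0, 0)], "chrQ", 500, "+", 0)
        assert map_interval(seg("chr1", 600, 700), [ch]) == []
        assert map_interval(seg("chr2", 0, 100), [ch]) == []

    def test_minus_strand_coordinates_converted(self):
        # block covers target [100, 200) -> reversed-query [0, 100);
        # forward coords are [q_size - 100, q_size - 0) = [400, 500)
        ch = make_chain("chr1", 1000, 100, [(100, 0, 0)], "chrQ", 500, "-", 0)
        (s,) = map_interval(seg("chr1", 100, 200), [ch])
        assert s == seg("chrQ", 400, 500, "-")
        # sub-interval at the start of the target maps to the END forward
        (s,) = map_interval(seg("chr1", 100, 110), [ch])
        assert s == seg("chrQ", 490, 500, "-")

    def test_projection_monotone_within_block(self):
        plus = make_chain("chr1", 1000, 0, [(800, 0, 0)], "chrQ", 900, "+", 50)
        minus = make_chain("chr1", 1000, 0, [(800, 0, 0)], "chrQ", 900, "-", 50)
        a = map_interval(seg("chr1", 100, 101), [plus])[0].start
        b = map_interval(seg("chr1", 500, 501), [plus])[0].start
        assert a < b
        a = map_interval(seg("chr1", 100, 101), [minus])[0].start
        b = map_interval(seg("chr1", 500, 501), [minus])[0].start
        assert a > b


def closure_merge_oracle(segments, gap=20):
    """Exhaustive pairwise closure: merge any two same-chrom/strand segments
    whose gap is < ``gap`` until a fixed point."""
    items = [(s.chrom, s.strand, s.start, s.end) for s in segments]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                ci, si, a0, a1 = items[i]
                cj, sj, b0, b1 = items[j]
                if ci != cj or si != sj:
                    continue
                g = max(a0, b0) - min(a1, b1)
                if g < gap:
                    items[i] = (ci, si, min(a0, b0), max(a1, b1))
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


class TestMergeSegments:
    def test_gap_threshold_rules(self):
        a, b = seg("c", 1000, 1100), seg("c", 1110, 1190)
        assert merge_segments([a, b]) == [seg("c", 1000, 1190)]  # gap 10 merges
        c = seg("c", 1125, 1190)
        assert merge_segments([a, c]) == [a, c]  # gap 25 stays split
        # boundary: gap 19 merges, gap 20 does not
        assert len(merge_segments([a, seg("c", 1119, 1150)])) == 1
        assert len(merge_segments([a, seg("c", 1120, 1150)])) == 2

    def test_three_segments_iterative_closure(self):
        segs = [seg("c", 0, 50), seg("c", 55, 90), seg("c", 95, 130)]
        assert merge_segments(segs) == [seg("c", 0, 130)]

    def test_overlapping_segments_merge_unconditionally(self):
        assert merge_segments([seg("c", 0, 60), seg("c", 40, 100)]) == [seg("c", 0, 100)]

    def test_cross_chrom_and_strand_never_merge(self):
        segs = [seg("c1", 0, 50), seg("c2", 55, 90)]
        assert len(merge_segments(segs)) == 2
        segs = [seg("c", 0, 50, "+"), seg("c", 55, 90, "-")]
        assert len(merge_segments(segs)) == 2

    def test_matches_exhaustive_closure_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            segs = []
            for _ in range(int(rng.integers(1, 8))):
                s = int(rng.integers(0, 500))
                segs.append(seg("c", s, s + int(rng.integers(1, 80))))
            got = merge_segments(segs)
            assert [(g.chrom, g.strand, g.start, g.end) for g in got] == \
                closure_merge_oracle(segs)


class TestRemapPeak:
    def test_clean_and_split_and_unmapped(self):
        # one query insertion of 10 b -> two segments, gap 10 -> merged
        near = make_chain("chr1", 10_000, 1000, [(100, 0, 10), (80, 0, 0)],
                          "chrQ", 10_010, "+", 1000)
        hp = remap_peak(Peak(seg("chr1", 1000, 1180), "p"), [near], species="sp")
        assert hp is not None
        assert (hp.interval.start, hp.interval.end) == (1000, 1190)
        assert hp.n_merged_loci == 2

        far = make_chain("chr1", 10_000, 1000, [(100, 0, 25), (65, 0, 0)],
                         "chrQ", 10_025, "+", 1000)
        assert remap_peak(Peak(seg("chr1", 1000, 1165), "p"), [far]) is None
        assert remap_peak(Peak(seg("chr1", 5000, 5100), "p"), [far]) is None

    def test_identity_fixed_point(self):
        ch = identity_chain("chr1", 10_000)
        p = Peak(seg("chr1", 123, 456), "p")
        hp = remap_peak(p, [ch])
        assert hp.interval == seg("chr1", 123, 456, "+")
        assert hp.n_merged_loci == 1

    def test_best_chain_tried_first(self):
        good = make_chain("chr1", 10_000, 0, [(10_000, 0, 0)],
                          "chrQ", 10_000, "+", 0, score=5000)
        shifted = make_chain("chr1", 10_000, 0, [(10_000, 0, 0)],
                             "chrR", 20_000, "+", 5000, score=100)
        hp = remap_peak(Peak(seg("chr1", 100, 200), "p"), [shifted, good])
        assert hp.interval.chrom == "chrQ"
        # lower-score chain consulted only when the best yields nothing
        partial = make_chain("chr1", 10_000, 9000, [(500, 0, 0)],
                             "chrQ", 500, "+", 0, score=5000)
        hp = remap_peak(Peak(seg("chr1", 100, 200), "p"), [partial, shifted])
        assert hp.interval.chrom == "chrR"


class TestPseudolabelSpecies:
    @staticmethod
    def _genome(n=12_000, seed=0, species="sp"):
        rng = np.random.default_rng(seed)
        return Genome(species, {"chrQ": "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])})

    def test_window_centering_and_report(self):
        g = self._genome()
        ch = make_chain("chr1", 10_000, 1000, [(100, 0, 10), (80, 0, 0)],
                        "chrQ", 12_000, "+", 1000)
        peaks = [Peak(seg("chr1", 1000, 1180), "p1"),
                 Peak(seg("chr1", 5000, 5100), "p2")]
        examples, homologs, report = pseudolabel_species(peaks, g, [ch], 200)
        assert len(examples) == 1 and len(homologs) == 1
        # homolog [1000,1190): midpoint 1095 -> window [995, 1195)
        assert examples[0].sequence == g.sequences["chrQ"][995:1195]
        assert examples[0].label == 1 and examples[0].origin == "pseudo"
        assert examples[0].source_chrom == "chr1"
        assert report.n_source_peaks == 2 and report.n_mapped == 1
        assert report.n_discarded_unmapped == 1
        report.validate()

    def test_minus_strand_emits_reverse_complement(self):
        g = self._genome()
        ch = make_chain("chr1", 10_000, 1000, [(200, 0, 0)],
                        "chrQ", 12_000, "-", 1000)
        (ex,), (hp,), _ = pseudolabel_species([Peak(seg("chr1", 1000, 1200), "p")],
                                              g, [ch], 200)
        assert hp.q_strand == "-"
        fs, fe = hp.interval.start, hp.interval.end
        mid = (fs + fe) // 2
        fwd = g.sequences["chrQ"][mid - 100: mid + 100]
        assert ex.sequence == reverse_complement(fwd)

    def test_self_map_reproduces_labeled_positives(self, toy_genome):
        chains = [identity_chain(c, n) for c, n in toy_genome.sizes.items()]
        peaks = [Peak(seg("chr1", 100, 300), "a"), Peak(seg("chr2", 500, 900), "b")]
        examples, homologs, report = pseudolabel_species(peaks, toy_genome, chains, 200)
        assert report.n_mapped == 2
        for p, hp in zip(peaks, homologs):
            assert hp.interval.start == p.interval.start
            assert hp.interval.end == p.interval.end
        mid = peaks[0].interval.midpoint
        assert examples[0].sequence == toy_genome.sequences["chr1"][mid - 100: mid + 100]


class TestAssemblePretrainingSet:
    def test_pooled_counts(self):
        pos = [SequenceExample("A" * 200, 1, origin="pseudo", species=f"s{k}")
               for k in range(3) for _ in range(40)]
        pool = [SequenceExample("C" * 200, 0) for _ in range(500)]
        ds = assemble_pretraining_set(pos, pool, seed=0)
        assert len(ds) == 240 and ds.balanced

    def test_empty_pseudo_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            ds = assemble_pretraining_set([], [SequenceExample("C" * 200, 0)], seed=0)
        assert len(ds) == 0

    def test_deterministic(self):
        pos = [SequenceExample("A" * 200, 1, origin="pseudo") for _ in range(10)]
        pool = [SequenceExample("C" * 200, 0, source_id=str(i)) for i in range(100)]
        a = assemble_pretraining_set(pos, pool, seed=4)
        b = assemble_pretraining_set(pos, pool, seed=4)
        assert [e.source_id for e in a.examples] == [e.source_id for e in b.examples]
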