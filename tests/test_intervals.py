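"""Interval arithmetic: Jaccard, method intersection, replica filtering,
merging, splitting and annotation, checked against per-base oracles."""
import numpy as np
import pytest

from rbpgroup.intervals import (
    AnnotationModel,
    GenomicInterval,
    MergedSite,
    Peak,
    PeakSet,
    annotate_site,
    filter_replicas,
    intersect_methods,
    jaccard_similarity,
    merge_sites,
    split_long_sites,
)

from conftest import make_peakset
from oracles import base_mask, blocks_from_mask, jaccard_from_masks, split_bins


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=10),
            dict(chrom="chr1", start=-1, end=10),
            dict(chrom="chr1", start=10, end=10),
            dict(chrom="chr1", start=10, end=5),
            dict(chrom="chr1", start=0, end=10, strand="x"),
        ],
    )
    def test_invalid_intervals_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_strand_blind_overlap_with_dot(self):
        a = GenomicInterval("chr1", 0, 50, "+")
        b = GenomicInterval("chr1", 40, 90, ".")
        c = GenomicInterval("chr1", 40, 90, "-")
        assert a.overlaps(b) and b.overlaps(a)
        assert not a.overlaps(c)


class TestJaccard:
    def test_identity_is_one(self):
        a = make_peakset([(0, 100)])
        assert jaccard_similarity(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert jaccard_similarity(make_peakset([(0, 100)]), make_peakset([(200, 300)])) == 0.0

    def test_half_overlap(self):
        # union 150 bases, intersection 50
        a, b = make_peakset([(0, 100)]), make_peakset([(50, 150)])
        assert jaccard_similarity(a, b) == pytest.approx(50 / 150)

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            jaccard_similarity(make_peakset([]), make_peakset([]))

    def test_matches_perbase_oracle_and_symmetry(self, rng):
        for _ in range(50):
            length = 2000
            iv_a = _random_intervals(rng, length, 12)
            iv_b = _random_intervals(rng, length, 12)
            a, b = make_peakset(iv_a), make_peakset(iv_b)
            expected = jaccard_from_masks(base_mask(iv_a, length), base_mask(iv_b, length))
            assert jaccard_similarity(a, b) == pytest.approx(expected, abs=1e-12)
            assert jaccard_similarity(a, b) == jaccard_similarity(b, a)


def _random_intervals(rng, length, n):
    starts = rng.integers(0, length - 60, n)
    return [(int(s), int(s + rng.integers(5, 60))) for s in starts]


class TestIntersectMethods:
    def test_no_overlap_gives_empty(self):
        out = intersect_methods(make_peakset([(0, 50)]), make_peakset([(100, 150)], method="paralyzer"))
        assert len(out) == 0

    def test_identical_sets_unchanged(self):
        p = make_peakset([(0, 50), (100, 150)], counts=[5, 9])
        out = intersect_methods(p, make_peakset([(0, 50), (100, 150)], method="paralyzer"))
        assert [(q.interval.start, q.interval.end, q.read_count) for q in out.peaks] == [
            (0, 50, 5), (100, 150, 9)
        ]

    def test_keeps_primary_coordinates(self):
        primary = make_peakset([(0, 50), (100, 150)])
        other = make_peakset([(40, 60)], method="paralyzer")
        out = intersect_methods(primary, other)
        assert [(q.interval.start, q.interval.end) for q in out.peaks] == [(0, 50)]

    def test_mismatched_rbp_raises(self):
        with pytest.raises(ValueError):
            intersect_methods(make_peakset([(0, 10)], rbp="A"), make_peakset([(0, 10)], rbp="B"))


class TestFilterReplicas:
    def test_identical_replicas_all_kept(self):
        r1 = make_peakset([(0, 40), (100, 140)], replicate="rep1")
        r2 = make_peakset([(0, 40), (100, 140)], replicate="rep2")
        out = filter_replicas([r1, r2])
        assert [(p.interval.start, p.interval.end) for p in out.peaks] == [(0, 40), (100, 140)]

    def test_peak_in_single_replica_dropped(self):
        r1 = make_peakset([(0, 40), (200, 240)], replicate="rep1")
        r2 = make_peakset([(0, 40)], replicate="rep2")
        out = filter_replicas([r1, r2])
        assert [(p.interval.start, p.interval.end) for p in out.peaks] == [(0, 40)]

    def test_low_count_partner_does_not_confirm(self):
        # overlap exists but the confirming replica has only 3 reads (< 4)
        r1 = make_peakset([(0, 40)], counts=[10], replicate="rep1")
        r2 = make_peakset([(10, 50)], counts=[3], replicate="rep2")
        assert len(filter_replicas([r1, r2])) == 0

    def test_min_reads_is_inclusive_threshold(self):
        r1 = make_peakset([(0, 40)], counts=[4], replicate="rep1")
        r2 = make_peakset([(10, 50)], counts=[4], replicate="rep2")
        assert len(filter_replicas([r1, r2])) == 1

    def test_single_replicate_falls_back_to_read_filter(self):
        r1 = make_peakset([(0, 40), (50, 90)], counts=[3, 7])
        out = filter_replicas([r1])
        assert [(p.interval.start, p.interval.end) for p in out.peaks] == [(50, 90)]

    def test_order_invariant(self, rng):
        reps = []
        for k in range(3):
            ivs = _random_intervals(rng, 3000, 15)
            # de-duplicate coordinates within a replicate
            ivs = sorted(set(ivs))
            reps.append(
                make_peakset(ivs, replicate=f"rep{k}", counts=list(rng.integers(0, 12, len(ivs))))
            )
        ref = filter_replicas(reps)
        perm = filter_replicas([reps[2], reps[0], reps[1]])
        assert [(p.interval.start, p.interval.end) for p in ref.peaks] == [
            (p.interval.start, p.interval.end) for p in perm.peaks
        ]

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            filter_replicas([])


class TestMergeSites:
    def test_single_peak_single_site(self):
        sites = merge_sites([make_peakset([(5, 45)], rbp="R1")])
        assert len(sites) == 1
        assert sites[0].source_rbps == {"R1"}

    def test_overlapping_rbps_coalesce(self):
        sites = merge_sites(
            [make_peakset([(0, 60)], rbp="R1"), make_peakset([(40, 90)], rbp="R2")]
        )
        assert len(sites) == 1
        iv = sites[0].interval
        assert (iv.start, iv.end) == (0, 90)
        assert sites[0].source_rbps == {"R1", "R2"}

    def test_disjoint_stay_separate(self):
        sites = merge_sites(
            [make_peakset([(0, 60)], rbp="R1"), make_peakset([(70, 90)], rbp="R2")]
        )
        assert len(sites) == 2

    def test_bookended_intervals_merge(self):
        sites = merge_sites(
            [make_peakset([(0, 60)], rbp="R1"), make_peakset([(60, 90)], rbp="R2")]
        )
        assert len(sites) == 1

    def test_matches_perbase_union_oracle(self, rng):
        length = 4000
        sets = []
        all_ivs = []
        for r in range(4):
            ivs = sorted(set(_random_intervals(rng, length, 20)))
            all_ivs.extend(ivs)
            sets.append(make_peakset(ivs, rbp=f"R{r}"))
        sites = merge_sites(sets)
        expected = blocks_from_mask(base_mask(all_ivs, length))
        got = [(s.interval.start, s.interval.end) for s in sites]
        assert got == expected
        # pairwise disjoint and non-bookended
        for (s1, e1), (s2, e2) in zip(got, got[1:]):
            assert e1 < s2


class TestSplitLongSites:
    def _site(self, start, end):
        return MergedSite(GenomicInterval("chr1", start, end, "+"), frozenset({"R"}))

    def test_boundary_length_unchanged(self):
        out = split_long_sites([self._site(0, 100)])
        assert [(s.interval.start, s.interval.end) for s in out] == [(0, 100)]
        assert out[0].parent_id is None

    def test_exact_multiple(self):
        out = split_long_sites([self._site(0, 250)])
        assert [(s.interval.start, s.interval.end) for s in out] == [
            (0, 100), (50, 150), (100, 200), (150, 250)
        ]

    def test_end_anchored_remainder(self):
        out = split_long_sites([self._site(0, 230)])
        assert [(s.interval.start, s.interval.end) for s in out] == [
            (0, 100), (50, 150), (100, 200), (130, 230)
        ]
        assert all(s.parent_id for s in out)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            split_long_sites([self._site(0, 300)], bin_len=50, step=50)

    def test_split_properties_random(self, rng):
        for _ in range(30):
            start = int(rng.integers(0, 500))
            end = start + int(rng.integers(101, 900))
            out = split_long_sites([self._site(start, end)])
            got = [(s.interval.start, s.interval.end) for s in out]
            assert got == split_bins(start, end, 100, 50)
            # full parent coverage, exact bin length, consecutive overlap
            mask = base_mask(got, end + 1)
            assert mask[start:end].all()
            assert all(e - s == 100 for s, e in got)
            for (s1, e1), (s2, e2) in zip(got, got[1:]):
                assert e1 - s2 >= 50


class TestAnnotation:
    @pytest.fixture
    def model(self):
        m = AnnotationModel()
        m.add_feature("CDS", GenomicInterval("chr1", 100, 200, "+"), "G1")
        m.add_feature("intron", GenomicInterval("chr1", 150, 400, "+"), "G2")
        m.add_feature("3'-UTR", GenomicInterval("chr1", 300, 380, "+"), "G2")
        m.add_feature("canonical ncRNA", GenomicInterval("chr1", 500, 560, "+"), "MIR1")
        return m

    def _site(self, start, end, strand="+"):
        return MergedSite(GenomicInterval("chr1", start, end, strand), frozenset())

    def test_cds_beats_intron(self, model):
        assert annotate_site(self._site(140, 180), model) == "CDS"

    def test_ncrna_beats_utr(self, model):
        m = AnnotationModel()
        m.add_feature("3'-UTR", GenomicInterval("chr1", 0, 100, "+"), "G")
        m.add_feature("canonical ncRNA", GenomicInterval("chr1", 50, 80, "+"), "MIR")
        assert annotate_site(self._site(60, 70), m) == "canonical ncRNA"

    def test_utr_beats_intron(self, model):
        assert annotate_site(self._site(320, 360), model) == "3'-UTR"

    def test_intron_only(self, model):
        assert annotate_site(self._site(210, 260), model) == "intron"

    def test_intergenic_when_nothing_overlaps(self, model):
        assert annotate_site(self._site(1000, 1050), model) == "intergenic"

    def test_mirna_is_canonical_ncrna(self, model):
        assert annotate_site(self._site(510, 530), model) == "canonical ncRNA"

    def test_strand_aware(self, model):
        assert annotate_site(self._site(140, 180, strand="-"), model) == "intergenic"

    def test_priority_deterministic_against_reference(self, rng):
        # randomized multi-overlap fixtures against an explicit priority scan
        classes = list(AnnotationModel.FEATURE_CLASSES)
        site = self._site(100, 120)
        for _ in range(30):
            m = AnnotationModel()
            placed = []
            for cls in classes:
                if rng.random() < 0.6:
                    s = int(rng.integers(0, 180))
                    m.add_feature(cls, GenomicInterval("chr1", s, s + 60, "+"), "G")
                    placed.append((cls, s, s + 60))
            overlapping = [c for c, s, e in placed if s < 120 and e > 100]
            expected = next((c for c in classes if c in overlapping), "intergenic")
            assert annotate_site(site, m) == expected
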