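"""Enrichment statistics: Fisher, permutation support, motifs, half-life, PSI."""
import math

import numpy as np
import pytest

from rbpgroup.enrichment import (
    AssociationNetwork,
    ContingencyTable2x2,
    fisher_exact,
    halflife_enrichment,
    known_motif_fraction,
    motif_enrichment_group_vs_rbp,
    permutation_group_support,
    splicing_enrichment,
)
from rbpgroup.intervals import GenomicInterval, MergedSite

from oracles import fisher_pvalues_by_margins, sort_percentile_classes


def _site(start, end, chrom="chr1", strand="+"):
    return MergedSite(GenomicInterval(chrom, start, end, strand), frozenset({"R"}))


class TestFisherExact:
    def test_balanced_table_no_association(self):
        res = fisher_exact(ContingencyTable2x2(5, 5, 5, 5), "two-sided")
        assert res.odds_ratio == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_separation_equals_enumeration(self):
        res = fisher_exact(ContingencyTable2x2(10, 0, 0, 10), "greater")
        assert res.p_value == pytest.approx(1 / math.comb(20, 10))
        assert res.odds_ratio == math.inf

    def test_matches_enumeration_on_random_margins(self, rng):
        for _ in range(40):
            r1, r2 = int(rng.integers(1, 20)), int(rng.integers(1, 20))
            c1 = int(rng.integers(0, r1 + r2 + 1))
            oracle = fisher_pvalues_by_margins(r1, r2, c1)
            a = int(rng.choice(list(oracle)))
            table = ContingencyTable2x2(a, r1 - a, c1 - a, r2 - (c1 - a))
            for alt in ("greater", "less", "two-sided"):
                assert fisher_exact(table, alt).p_value == pytest.approx(
                    oracle[a][alt], rel=1e-9
                )

    def test_zero_products_give_nan_odds(self):
        assert math.isnan(fisher_exact(ContingencyTable2x2(0, 0, 0, 5)).odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(1, -1, 2, 3)

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable2x2(1, 1, 1, 1), "sideways")


class TestPermutationSupport:
    def _network(self, edges):
        return AssociationNetwork({(a, b, "physical") for a, b in edges})

    def test_zero_internal_edges_gives_p_one(self):
        universe = [f"R{i}" for i in range(10)]
        net = self._network([("R5", "R6"), ("R7", "R8")])
        p = permutation_group_support(["R0", "R1", "R2"], universe, net, n_perm=200, seed=1)
        assert p["physical"] == 1.0

    def test_fully_connected_group_in_empty_network(self):
        universe = [f"R{i}" for i in range(30)]
        group = ["R0", "R1", "R2", "R3"]
        net = self._network([(a, b) for i, a in enumerate(group) for b in group[i + 1:]])
        p = permutation_group_support(group, universe, net, n_perm=500, seed=3)
        assert p["physical"] == pytest.approx(1 / 501)

    def test_seeded_determinism(self):
        universe = [f"R{i}" for i in range(12)]
        net = self._network([("R0", "R1"), ("R2", "R3"), ("R8", "R9")])
        args = (["R0", "R1", "R2"], universe, net)
        assert permutation_group_support(*args, n_perm=300, seed=7) == \
            permutation_group_support(*args, n_perm=300, seed=7)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_group_support(["R0"], ["R0", "R1"], self._network([]), 10, 0)

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            permutation_group_support(["R0", "Z9"], ["R0", "R1"], self._network([]), 10, 0)

    def test_network_rejects_self_edges(self):
        with pytest.raises(ValueError):
            AssociationNetwork({("A", "A", "physical")})


class TestKnownMotifs:
    def test_exact_motif_counts_once_per_sequence(self):
        count, frac = known_motif_fraction(["AAUAAA", "CCCCCC"], "AAUAAA")
        assert (count, frac) == (1, 0.5)

    def test_internal_hit_found(self):
        count, _ = known_motif_fraction(["AUGUAC"], "UGUA")
        assert count == 1

    def test_iupac_degenerate_letter_expands(self):
        count, frac = known_motif_fraction(["AGUA", "UGUA", "CGUA"], "WGUA")
        assert count == 2

    def test_u_and_t_equivalent(self):
        assert known_motif_fraction(["ATGTAC"], "UGUA")[0] == 1
        assert known_motif_fraction(["AUGUAC"], "TGTA")[0] == 1

    def test_duplicates_counted_separately(self):
        assert known_motif_fraction(["UGUA", "UGUA"], "UGUA") == (2, 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            known_motif_fraction([], "UGUA")
        with pytest.raises(ValueError):
            known_motif_fraction(["ACGU"], "UGX")


class TestMotifEnrichment:
    def test_delegates_to_fisher_greater(self):
        res = motif_enrichment_group_vs_rbp(30, 100, 3, 100)
        direct = fisher_exact(ContingencyTable2x2(30, 70, 3, 97), "greater")
        assert res.p_value == direct.p_value
        assert res.table == direct.table

    def test_equal_fractions_odds_one(self):
        assert motif_enrichment_group_vs_rbp(10, 50, 10, 50).odds_ratio == 1.0

    def test_depletion_direction_has_large_p(self):
        assert motif_enrichment_group_vs_rbp(2, 100, 30, 100).p_value > 0.5

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            motif_enrichment_group_vs_rbp(5, 3, 1, 10)


class TestHalflifeEnrichment:
    def _table(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return {f"G{i}": float(v) for i, v in enumerate(rng.lognormal(4, 0.6, n))}

    def test_identical_fractions_log2_zero(self):
        hl = self._table()
        hits = {g: True for g in hl}  # every gene bound
        res = halflife_enrichment(hits, hl)
        assert res.log2_ratio == pytest.approx(0.0)

    def test_fourfold_fraction_gap_is_two(self):
        hl = {f"S{i}": 10.0 + i * 0.01 for i in range(20)}
        hl.update({f"M{i}": 100.0 + i for i in range(60)})
        hl.update({f"L{i}": 500.0 + i * 0.01 for i in range(20)})
        short = sorted(g for g in hl if g.startswith("S"))[:19]
        long_ = sorted(g for g in hl if g.startswith("L"))[1:]
        hits = {g: False for g in hl}
        for g in short[:8]:  # 8/19 short bound
            hits[g] = True
        # choose long hits for an exact 4x fraction ratio: 2/19 vs 8/19
        for g in long_[:2]:
            hits[g] = True
        res = halflife_enrichment(hits, hl)
        assert res.log2_ratio == pytest.approx(2.0)

    def test_classes_match_sort_oracle(self, rng):
        for _ in range(10):
            hl = {f"G{i}": float(v) for i, v in enumerate(rng.lognormal(4, 1, 80))}
            short, long_ = sort_percentile_classes(hl, 0.20, 0.80)
            hits = {g: rng.random() < 0.5 for g in hl}
            res = halflife_enrichment(hits, hl)
            assert res.table.a + res.table.b == len(short)
            assert res.table.c + res.table.d == len(long_)
            assert res.table.a == sum(hits[g] for g in short)
            assert res.table.c == sum(hits[g] for g in long_)


class TestSplicingEnrichment:
    def _exons(self):
        # 10 AS exons and 10 constitutive exons along one chromosome
        out = []
        for k in range(10):
            out.append((GenomicInterval("chr1", 10_000 * k + 5000, 10_000 * k + 5100, "+"), 0.05))
        for k in range(10, 20):
            out.append((GenomicInterval("chr1", 10_000 * k + 5000, 10_000 * k + 5100, "+"), 0.95))
        return out

    def test_window_boundary_half_open(self):
        exon = [(GenomicInterval("chr1", 10_000, 10_100, "+"), 0.05),
                (GenomicInterval("chr1", 50_000, 50_100, "+"), 0.95)]
        hit_site = _site(10_000 - 2000 - 1999, 10_000 - 1999)  # ends 1999 bp upstream
        miss_site = _site(10_000 - 2000 - 2001, 10_000 - 2001)
        assert splicing_enrichment([hit_site], exon).table.a == 1
        assert splicing_enrichment([miss_site], exon).table.a == 0

    def test_intermediate_psi_excluded(self):
        exons = self._exons() + [(GenomicInterval("chr1", 500_000, 500_100, "+"), 0.5)]
        res = splicing_enrichment([_site(0, 50)], exons)
        assert res.table.a + res.table.b == 10
        assert res.table.c + res.table.d == 10

    def test_no_sites_gives_nan_ratio(self):
        with pytest.warns(UserWarning):
            res = splicing_enrichment([_site(900_000, 900_050)], self._exons())
        assert math.isnan(res.log2_ratio)

    def test_enrichment_direction(self):
        sites = [_site(10_000 * k + 5200, 10_000 * k + 5250) for k in range(8)]
        res = splicing_enrichment(sites, self._exons())
        assert res.log2_ratio > 1.5
        assert res.p_value < 0.01

    def test_invalid_psi_rejected(self):
        with pytest.raises(ValueError):
            splicing_enrichment([_site(0, 10)], [(GenomicInterval("chr1", 0, 100, "+"), 1.2)])
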