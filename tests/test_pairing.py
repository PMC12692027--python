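"""Pair enumeration (proximity and same-TAD), DE filtering, stable pairs."""

import random

import pandas as pd
import pytest

from tadlink.consensus import TadSet
from tadlink.intervals import GenomicInterval, IntervalSet
from tadlink.pairing import (
    EPPair,
    filter_differential,
    pairs_by_proximity,
    pairs_by_tad,
    stable_pairs,
)


def iset(items):
    """items: list of (chrom, start, end, id)."""
    return IntervalSet([GenomicInterval(c, s, e, id=i) for c, s, e, i in items]).normalize()


def de_table(rows):
    """rows: list of (feature_id, log2fc, fdr)."""
    return pd.DataFrame(rows, columns=["feature_id", "log2fc", "fdr"])


class TestPairsByProximity:
    def test_inclusive_boundary_at_exactly_max_distance(self):
        proms = iset([("chr1", 50, 150, "p")])  # midpoint 100
        enhs = iset([("chr1", 500050, 500150, "e")])  # midpoint 500100
        pairs = pairs_by_proximity(proms, enhs, max_distance=500_000)
        assert [p.key for p in pairs] == [("p", "e")]
        assert pairs[0].distance == 500_000

    def test_beyond_boundary_excluded(self):
        proms = iset([("chr1", 50, 150, "p")])
        enhs = iset([("chr1", 600050, 600150, "e")])
        assert pairs_by_proximity(proms, enhs) == []

    def test_different_chromosomes_never_pair(self):
        proms = iset([("chr1", 0, 100, "p")])
        enhs = iset([("chr2", 0, 100, "e")])
        assert pairs_by_proximity(proms, enhs) == []

    def test_matches_exhaustive_double_loop(self):
        rand = random.Random(47)
        for _ in range(30):
            proms = iset(
                [("chr1", s, s + 100, f"p{k}") for k, s in enumerate(
                    rand.sample(range(0, 2_000_000, 200), rand.randrange(1, 8))
                )]
            )
            enhs = iset(
                [("chr1", s, s + 400, f"e{k}") for k, s in enumerate(
                    rand.sample(range(100, 2_000_000, 250), rand.randrange(1, 8))
                )]
            )
            max_d = rand.choice([10_000, 300_000, 500_000])
            got = {p.key for p in pairs_by_proximity(proms, enhs, max_distance=max_d)}
            expected = {
                (p.id, e.id)
                for p in proms
                for e in enhs
                if abs(p.midpoint2 - e.midpoint2) <= 2 * max_d
            }
            assert got == expected

    def test_all_close_features_give_full_product(self):
        proms = iset([("chr1", 100 * k, 100 * k + 50, f"p{k}") for k in range(4)])
        enhs = iset([("chr1", 100 * k + 50, 100 * k + 90, f"e{k}") for k in range(5)])
        assert len(pairs_by_proximity(proms, enhs, max_distance=1000)) == 20


class TestPairsByTad:
    def setup_method(self):
        self.tads = TadSet(iset([("chr1", 0, 1000, None), ("chr1", 1000, 2000, None)]))

    def test_full_product_within_tad(self):
        proms = iset([("chr1", 10, 110, "p1"), ("chr1", 200, 300, "p2")])
        enhs = iset([("chr1", 400, 800, "e1"), ("chr1", 500, 900, "e2"), ("chr1", 100, 500, "e3")])
        pairs = pairs_by_tad(proms, enhs, self.tads)
        assert len(pairs) == 6
        assert all(p.tad_id == "TAD_chr1_1" for p in pairs)

    def test_cross_tad_features_never_pair(self):
        proms = iset([("chr1", 10, 110, "p1")])
        enhs = iset([("chr1", 1200, 1600, "e1")])
        assert pairs_by_tad(proms, enhs, self.tads) == []

    def test_feature_outside_all_tads_generates_no_pairs(self):
        proms = iset([("chr1", 10, 110, "p1")])
        enhs = iset([("chr1", 2500, 2900, "e1")])  # beyond both TADs
        assert pairs_by_tad(proms, enhs, self.tads) == []

    def test_count_identity_sum_of_per_tad_products(self):
        rand = random.Random(53)
        tads = TadSet(iset([("chr1", 2000 * k, 2000 * (k + 1), None) for k in range(5)]))
        for _ in range(20):
            proms, enhs = [], []
            per_tad = {}
            for k in range(5):
                np_, ne = rand.randrange(0, 4), rand.randrange(0, 4)
                per_tad[f"TAD_chr1_{k+1}"] = (np_, ne)
                base = 2000 * k
                proms += [("chr1", base + 10 + 120 * j, base + 100 + 120 * j, f"p{k}_{j}") for j in range(np_)]
                enhs += [("chr1", base + 600 + 450 * j, base + 1000 + 450 * j, f"e{k}_{j}") for j in range(ne)]
            pairs = pairs_by_tad(iset(proms), iset(enhs), tads)
            assert len(pairs) == sum(a * b for a, b in per_tad.values())

    def test_tad_pairs_subset_of_proximity_when_tads_short(self):
        rand = random.Random(59)
        tads = TadSet(iset([("chr1", 400_000 * k, 400_000 * (k + 1), None) for k in range(4)]))
        proms, enhs = [], []
        for k in range(4):
            base = 400_000 * k
            proms += [("chr1", base + rand.randrange(0, 390_000), 0, f"p{k}_{j}") for j in range(2)]
            enhs += [("chr1", base + rand.randrange(0, 390_000), 0, f"e{k}_{j}") for j in range(2)]
        proms = [(c, s, s + 100, i) for c, s, _, i in proms]
        enhs = [(c, s, s + 400, i) for c, s, _, i in enhs]
        tad_keys = {p.key for p in pairs_by_tad(iset(proms), iset(enhs), tads)}
        prox_keys = {p.key for p in pairs_by_proximity(iset(proms), iset(enhs), max_distance=500_000)}
        assert tad_keys <= prox_keys


class TestFilterDifferential:
    def setup_method(self):
        self.pairs = [EPPair("p1", "e1", tad_id="TAD_chr1_1", distance=100.0)]

    def test_kept_pair_gets_pattern_promoter_sign_first(self):
        kept = filter_differential(
            self.pairs,
            de_table([("p1", -1.2, 0.01)]),
            de_table([("e1", 0.8, 0.02)]),
        )
        assert len(kept) == 1
        assert kept[0].pattern == "-+"
        assert kept[0].prom_log2fc == pytest.approx(-1.2)

    def test_fdr_exactly_at_threshold_dropped(self):
        kept = filter_differential(
            self.pairs, de_table([("p1", -1.2, 0.01)]), de_table([("e1", 0.8, 0.05)])
        )
        assert kept == []

    def test_member_missing_from_de_table_dropped(self):
        kept = filter_differential(
            self.pairs, de_table([("other", 1.0, 0.01)]), de_table([("e1", 0.8, 0.02)])
        )
        assert kept == []

    def test_duplicate_feature_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            filter_differential(
                self.pairs,
                de_table([("p1", 1.0, 0.01), ("p1", 2.0, 0.02)]),
                de_table([("e1", 0.8, 0.02)]),
            )

    def test_significant_zero_log2fc_contradictory(self):
        with pytest.raises(ValueError, match="sign"):
            filter_differential(
                self.pairs, de_table([("p1", 0.0, 0.001)]), de_table([("e1", 0.8, 0.02)])
            )

    def test_monotone_in_threshold_and_never_invents(self):
        rand = random.Random(61)
        pairs = [EPPair(f"p{i}", f"e{j}") for i in range(5) for j in range(5)]
        de_p = de_table([(f"p{i}", rand.uniform(-2, 2) or 0.1, rand.random()) for i in range(5)])
        de_e = de_table([(f"e{j}", rand.uniform(-2, 2) or 0.1, rand.random()) for j in range(5)])
        kept_lo = {p.key for p in filter_differential(pairs, de_p, de_e, fdr_threshold=0.2)}
        kept_hi = {p.key for p in filter_differential(pairs, de_p, de_e, fdr_threshold=0.8)}
        all_keys = {p.key for p in pairs}
        assert kept_lo <= kept_hi <= all_keys


class TestStablePairs:
    def test_intersection_across_tissues(self):
        mk = lambda *keys: [EPPair(p, e, pattern="++") for p, e in keys]
        per_tissue = {
            "brain": mk(("p1", "e1"), ("p2", "e2")),
            "liver": mk(("p1", "e1"), ("p3", "e3")),
            "heart": mk(("p1", "e1"), ("p2", "e2")),
        }
        stable = stable_pairs(per_tissue)
        assert [key for key, _ in stable] == [("p1", "e1")]
        assert stable[0][1] == {"brain": "++", "liver": "++", "heart": "++"}

    def test_pair_missing_in_one_tissue_excluded(self):
        per_tissue = {
            "a": [EPPair("p1", "e1"), EPPair("p2", "e2")],
            "b": [EPPair("p1", "e1")],
        }
        assert [k for k, _ in stable_pairs(per_tissue)] == [("p1", "e1")]

    def test_identical_lists_give_identity(self):
        plist = [EPPair("p1", "e1"), EPPair("p2", "e2")]
        stable = stable_pairs({"a": plist, "b": list(plist)})
        assert [k for k, _ in stable] == [("p1", "e1"), ("p2", "e2")]

    def test_order_invariance_of_intersection(self):
        rand = random.Random(67)
        universe = [(f"p{i}", f"e{i}") for i in range(20)]
        tissues = {
            t: [EPPair(p, e) for p, e in rand.sample(universe, 12)] for t in "abcd"
        }
        ref = {k for k, _ in stable_pairs(tissues)}
        shuffled = dict(reversed(list(tissues.items())))
        assert {k for k, _ in stable_pairs(shuffled)} == ref

    def test_fewer_than_two_tissues_rejected(self):
        with pytest.raises(ValueError):
            stable_pairs({})
        with pytest.raises(ValueError):
            stable_pairs({"only": [EPPair("p", "e")]})
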