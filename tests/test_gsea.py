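import itertools
import math

import numpy as np
import pandas as pd
import pytest

from xtissue.enrichment import enrichment_t_test
from xtissue.errors import InputError
from xtissue.gsea import (
    RankedList,
    cross_species_matrix,
    enrichment_score,
    gsea_preranked,
    rank_by_neglog_p,
    rank_by_specificity,
)


def running_sum_oracle(ids, scores, gene_set, weight=1.0):
    """Stepwise pure-python running-sum evaluation (the independent oracle)."""
    hits = [g in gene_set for g in ids]
    H = sum(hits)
    L = len(ids)
    nr = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    rs, v = [], 0.0
    for g, s, h in zip(ids, scores, hits):
        if h:
            v += (abs(s) ** weight / nr) if nr > 0 else 1.0 / H
        else:
            v -= 1.0 / (L - H)
        rs.append(v)
    pos = max(rs)
    neg = min(rs)
    es = neg if abs(neg) >= pos else pos
    return es, rs


class TestRankedList:
    def test_sorted_descending_with_id_tiebreak(self):
        rl = RankedList(ids=("b", "a", "c"), scores=(1.0, 1.0, 5.0))
        assert rl.ids == ("c", "a", "b")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError):
            RankedList(ids=("a", "a"), scores=(1.0, 2.0))

    def test_nonfinite_rejected(self):
        with pytest.raises(InputError):
            RankedList(ids=("a", "b"), scores=(1.0, float("inf")))


class TestRankByNeglogP:
    def make_test(self, cluster, p=None, exclusive=False):
        if exclusive:
            return enrichment_t_test(10.0, (0.0, 0.0, 0.0), cluster=cluster)
        t = enrichment_t_test(10.0, (1.0, 2.0, 3.0), cluster=cluster)
        object.__setattr__(t, "p", p)
        return t

    def test_scores_and_order(self):
        tests = [
            self.make_test("a", 0.05),
            self.make_test("b", 0.001),
            self.make_test("c", 0.01),
        ]
        rl = rank_by_neglog_p(tests)
        assert rl.ids == ("b", "c", "a")
        assert rl.scores == pytest.approx((3.0, 2.0, -math.log10(0.05)))

    def test_tied_p_ordered_by_id(self):
        tests = [self.make_test("zz", 0.01), self.make_test("aa", 0.01)]
        rl = rank_by_neglog_p(tests)
        assert rl.ids == ("aa", "zz")

    def test_exclusive_ranks_first(self):
        tests = [self.make_test("a", 0.001), self.make_test("x", exclusive=True)]
        rl = rank_by_neglog_p(tests)
        assert rl.ids[0] == "x"
        assert rl.scores[0] == pytest.approx(4.0)  # max finite (3) + 1

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rank_by_neglog_p([])


class TestRankBySpecificity:
    def test_flat_gene_scores_zero(self):
        m = pd.DataFrame({"a": [5.0, 7.0], "b": [5.0, 7.0], "c": [5.0, 7.0]},
                         index=["g1", "g2"])
        rl = rank_by_specificity(m, "a")
        assert rl.scores == pytest.approx((0.0, 0.0))

    def test_log_ratio_with_pseudocount(self):
        m = pd.DataFrame({"a": [80.0], "b": [10.0], "c": [10.0]}, index=["g1"])
        rl = rank_by_specificity(m, "a", pseudocount=1.0)
        assert rl.scores[0] == pytest.approx(math.log2(81 / 11), rel=1e-12)
        assert rl.scores[0] == pytest.approx(2.880, abs=1e-3)

    def test_global_scaling_preserves_order(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.lognormal(2, 1, (30, 3)), columns=list("abc"),
                         index=[f"g{i}" for i in range(30)])
        r1 = rank_by_specificity(m, "a")
        r2 = rank_by_specificity(m * 7.0, "a", pseudocount=7.0)
        assert r1.ids == r2.ids


class TestEnrichmentScore:
    ranked = RankedList(ids=("g1", "g2", "g3", "g4", "g5"),
                        scores=(5.0, 4.0, 3.0, 2.0, 1.0))

    def test_hand_derived_running_sum(self):
        es, rs, le = enrichment_score(self.ranked, {"g1", "g3"})
        assert np.allclose(rs, [0.625, 0.625 - 1 / 3, 2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert es == pytest.approx(2 / 3, abs=1e-12)
        assert le == {"g1", "g3"}

    def test_full_set_scores_one(self):
        es, _, _ = enrichment_score(self.ranked, set(self.ranked.ids))
        assert es == pytest.approx(1.0)

    def test_top_gene_scores_one(self):
        es, _, le = enrichment_score(self.ranked, {"g1"})
        assert es == pytest.approx(1.0)
        assert le == {"g1"}

    def test_empty_intersection_rejected(self):
        with pytest.raises(InputError):
            enrichment_score(self.ranked, {"nope"})

    def test_bounded_by_one(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = rng.integers(3, 30)
            ids = tuple(f"g{i}" for i in range(n))
            scores = tuple(np.sort(rng.normal(0, 2, n))[::-1])
            rl = RankedList(ids=ids, scores=scores)
            gset = set(rng.choice(ids, size=rng.integers(1, n), replace=False))
            es, _, _ = enrichment_score(rl, gset)
            assert abs(es) <= 1.0 + 1e-12

    def test_matches_oracle_exhaustively_small(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 8):
            scores = tuple(np.sort(rng.uniform(0.5, 9.5, n))[::-1])
            ids = tuple(f"g{i}" for i in range(n))
            rl = RankedList(ids=ids, scores=scores)
            for r in (1, 2, 3):
                for combo in itertools.combinations(ids, r):
                    es, rs, _ = enrichment_score(rl, set(combo))
                    es_o, rs_o = running_sum_oracle(ids, scores, set(combo))
                    assert es == pytest.approx(es_o, abs=1e-12)
                    assert np.allclose(rs, rs_o, atol=1e-12)

    def test_reversal_negates_es(self):
        ids = ("a", "b", "c", "d", "e", "f")
        scores = (6.0, 4.0, 2.0, -1.0, -3.0, -5.0)
        rl = RankedList(ids=ids, scores=scores)
        flipped = RankedList(ids=ids, scores=tuple(-s for s in scores))
        for gset in ({"a", "c"}, {"f"}, {"b", "e"}):
            es1, _, _ = enrichment_score(rl, gset)
            es2, _, _ = enrichment_score(flipped, gset)
            assert es2 == pytest.approx(-es1, abs=1e-12)

    def test_leading_edge_negative_side(self):
        # set concentrated at the bottom -> negative ES, leading edge at/after min
        es, rs, le = enrichment_score(self.ranked, {"g4", "g5"})
        assert es < 0
        assert le <= {"g4", "g5"} and le


def exact_null_es(ids, scores, set_size, weight=1.0):
    """All placements of a set of given size -> exact null ES population."""
    out = []
    for combo in itertools.combinations(ids, set_size):
        es, _ = running_sum_oracle(ids, scores, set(combo), weight)
        out.append(es)
    return np.array(out)


class TestGseaPreranked:
    def ranked(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(1.0, 2.0, n))[::-1]
        return RankedList(ids=tuple(f"g{i:03d}" for i in range(n)),
                          scores=tuple(scores))

    def test_deterministic_given_seed(self):
        rl = self.ranked()
        sets = {"s1": {f"g{i:03d}" for i in range(8)},
                "s2": {f"g{i:03d}" for i in range(20, 40)}}
        r1 = gsea_preranked(rl, sets, n_perm=100, seed=11)
        r2 = gsea_preranked(rl, sets, n_perm=100, seed=11)
        for a, b in zip(r1, r2):
            assert (a.nes, a.nominal_p, a.fdr_q) == (b.nes, b.nominal_p, b.fdr_q)

    def test_planted_top_set_is_significant(self):
        rng = np.random.default_rng(5)
        n = 1000
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        ids = tuple(f"g{i:04d}" for i in range(n))
        rl = RankedList(ids=ids, scores=tuple(scores))
        planted = set(ids[:20])
        res = gsea_preranked(rl, {"planted": planted}, n_perm=1000, seed=1)[0]
        assert res.es > 0
        assert res.nominal_p <= 0.005

    def test_nes_sign_matches_es_sign(self):
        rl = self.ranked()
        sets = {"top": {f"g{i:03d}" for i in range(10)},
                "bottom": {f"g{i:03d}" for i in range(50, 60)}}
        for r in gsea_preranked(rl, sets, n_perm=300, seed=3):
            if r.es != 0:
                assert np.sign(r.nes) == np.sign(r.es)
            assert 0.0 <= r.fdr_q <= 1.0
            assert 0.0 < r.nominal_p <= 1.0

    def test_size_filter(self):
        rl = self.ranked()
        with pytest.raises(InputError):
            gsea_preranked(rl, {"tiny": {"g000"}}, n_perm=10, min_size=5)

    def test_nominal_p_matches_exhaustive_permutation(self):
        """Sampled permutation p agrees with full enumeration on a tiny list."""
        ids = tuple(f"g{i}" for i in range(10))
        scores = (9.0, 7.5, 6.0, 5.0, 4.0, 3.0, 2.5, 2.0, 1.5, 1.0)
        rl = RankedList(ids=ids, scores=scores)
        gset = {"g0", "g2"}
        res = gsea_preranked(rl, {"s": gset}, n_perm=4000, seed=9, min_size=1)[0]
        null = exact_null_es(ids, scores, 2)
        same_sign = null[null >= 0] if res.es >= 0 else null[null < 0]
        exact_frac = np.mean(np.abs(same_sign) >= abs(res.es) - 1e-12)
        se = math.sqrt(exact_frac * (1 - exact_frac) / 2000)
        # sampled p carries add-one smoothing of at most 1/(m+1)
        assert abs(res.nominal_p - exact_frac) < 4 * se + 2 / 2000

    def test_null_values_come_from_exact_population(self):
        """Vectorized permutation ES values all lie in the enumerable set."""
        from xtissue.gsea import _null_es

        ids = tuple(f"g{i}" for i in range(7))
        scores = (8.0, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0)
        abs_w = np.abs(np.array(scores))
        null = _null_es(abs_w, 2, 500, np.random.default_rng(0))
        population = np.unique(np.round(exact_null_es(ids, scores, 2), 12))
        for v in np.round(null, 12):
            assert np.min(np.abs(population - v)) < 1e-9


class TestCrossSpeciesMatrix:
    def test_identical_targets_give_equal_cells(self):
        rng = np.random.default_rng(8)
        n = 200
        col = rng.lognormal(2, 1, n)
        m = pd.DataFrame({"t1": col, "t2": col, "t3": col},
                         index=[f"g{i:03d}" for i in range(n)])
        # perturb so specificity scores are not all zero but columns identical
        query = {"q": set(m.index[:20])}
        nm = cross_species_matrix(query, m, n_perm=200, seed=2)
        row = nm.nes.loc["q"]
        assert row.notna().all()
        assert row.max() - row.min() < 0.5  # equal within permutation noise

    def test_disjoint_query_not_assessable(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.lognormal(2, 1, (50, 2)), columns=["t1", "t2"],
                         index=[f"g{i}" for i in range(50)])
        nm = cross_species_matrix({"q": {"zz1", "zz2"}}, m, n_perm=50, seed=1)
        assert nm.nes.loc["q"].isna().all()

    def test_significance_marks(self):
        nm_p = pd.DataFrame({"t": [0.0005, 0.01, 0.5]}, index=["a", "b", "c"])
        from xtissue.gsea import NESMatrix

        nm = NESMatrix(nes=nm_p * 0, fdr=nm_p, nominal_p=nm_p)
        marks = nm.significance()
        assert list(marks["t"]) == ["**", "*", ""]
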