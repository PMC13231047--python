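import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comorbhub.containers import ExpressionMatrix
from comorbhub.enrichment import (
    _enrichment_score,
    compare_infiltration,
    correlate_genes_cells,
    gsea,
    gsea_collection,
    ora,
    shared_terms,
    ssgsea,
)


def _genes(n, prefix="g"):
    return [f"{prefix}{i:03d}" for i in range(n)]


class TestORA:
    def test_perfect_overlap_exact_probability(self):
        universe = set(_genes(20))
        term = _genes(5)
        res = ora(set(term), {"t": term}, universe)
        assert res.loc["t", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        universe = set(_genes(30))
        res = ora(set(_genes(5)), {"t": _genes(30)[20:24]}, universe)
        assert res.loc["t", "p"] == pytest.approx(1.0)

    def test_query_equal_universe_degenerate(self):
        universe = set(_genes(15))
        res = ora(universe, {"t": _genes(15)[:6]}, universe)
        assert res.loc["t", "k"] == res.loc["t", "K"]
        assert res.loc["t", "p"] == pytest.approx(1.0)

    def test_out_of_universe_genes_dropped_with_warning(self):
        universe = set(_genes(10))
        with pytest.warns(UserWarning, match="outside"):
            res = ora(set(_genes(10)) | {"alien"}, {"t": _genes(10)[:3]}, universe)
        assert res.loc["t", "n"] == 10

    def test_empty_query_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                ora({"alien"}, {"t": _genes(5)}, set(_genes(5)))

    def test_matches_exact_combinatorial_sum(self):
        """Upper-tail p equals the exact sum of hypergeometric pmf terms
        computed from integer combinatorials."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            kmax = min(K, n)
            k = int(rng.integers(0, kmax + 1))
            if n - k > N - K:
                continue
            universe = _genes(N)
            term = universe[:K]
            query = set(universe[:k]) | set(universe[N - (n - k):] if n > k else [])
            res = ora(query, {"t": term}, set(universe))
            exact = sum(
                math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, kmax + 1)
            ) / math.comb(N, n)
            assert res.loc["t", "p"] == pytest.approx(exact, abs=1e-12)


class TestSharedTerms:
    def test_overlapping_top_lists(self):
        a = pd.DataFrame(index=[f"t{i}" for i in range(30)])
        b = pd.DataFrame(index=["t2", "t5", "t40", "t50"] + [f"u{i}" for i in range(20)])
        assert shared_terms(a, b, top_n=20) == ["t2", "t5"]

    def test_disjoint_lists_empty(self):
        a = pd.DataFrame(index=["a1", "a2"])
        b = pd.DataFrame(index=["b1", "b2"])
        assert shared_terms(a, b) == []


class TestGSEA:
    def test_running_sum_matches_hand_loop(self):
        """ES on a 10-gene example equals an explicitly accumulated
        weighted KS running sum."""
        scores = pd.Series(
            [5.0, 4.0, 3.5, 3.0, 2.0, 1.5, 1.0, 0.5, 0.4, 0.1],
            index=list("abcdefghij"),
        )
        gene_set = {"a", "c", "g"}
        res = gsea(scores, gene_set, n_perm=10, rng=0)
        # independent accumulation
        denom = sum(abs(scores[g]) for g in gene_set)
        running, best = 0.0, 0.0
        for g in scores.index:  # already sorted descending
            if g in gene_set:
                running += abs(scores[g]) / denom
            else:
                running -= 1.0 / 7
            if abs(running) > abs(best):
                best = running
        assert res.es == pytest.approx(best, abs=1e-12)

    def test_top_block_set_is_extreme(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(
            np.sort(rng.uniform(0.1, 5.0, 200))[::-1], index=_genes(200)
        )
        top = set(scores.index[:20])
        res = gsea(scores, top, n_perm=200, rng=2)
        assert res.es > 0.9
        assert res.p <= 1 / 201

    def test_weight_zero_is_classic_ks(self):
        scores = pd.Series([3.0, 2.0, 1.0, 0.5], index=list("abcd"))
        res = gsea(scores, {"a", "b", "d"}, n_perm=10, weight=0.0, rng=0)
        # unweighted: hits step 1/3, misses step 1/1
        assert res.es == pytest.approx(2 / 3)

    def test_small_overlap_rejected(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.raises(ValueError):
            gsea(scores, {"a", "zz"}, n_perm=10, rng=0)

    def test_null_pvalues_roughly_uniform(self):
        """Random gene sets give a uniform permutation p over repeats."""
        rng = np.random.default_rng(3)
        scores = pd.Series(rng.standard_normal(200), index=_genes(200))
        pvals = []
        for rep in range(200):
            gene_set = set(rng.choice(scores.index, size=15, replace=False))
            res = gsea(scores, gene_set, n_perm=99, rng=rep)
            pvals.append(res.p)
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.01

    def test_collection_flags_follow_printed_rule(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(
            np.sort(rng.uniform(0.1, 5.0, 100))[::-1], index=_genes(100)
        )
        coll = {"top": list(scores.index[:10]), "rand": list(scores.index[40:50])}
        res = gsea_collection(scores, coll, n_perm=200, rng=5)
        assert bool(res.loc["top", "significant"]) == (
            res.loc["top", "adj_p"] < 0.05 and abs(res.loc["top", "nes"]) > 1
        )


class TestSSGSEA:
    def _expr(self, n_genes=60, n_samples=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(5, 2, (n_genes, n_samples)),
            index=_genes(n_genes),
            columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_top_gene_set_beats_bottom_gene_set(self):
        x = self._expr()
        sample = "s0"
        order = x[sample].sort_values(ascending=False)
        coll = {"top": [order.index[0]], "bottom": [order.index[-1]]}
        scores = ssgsea(x, coll, normalize=False)
        assert scores.loc[sample, "top"] > scores.loc[sample, "bottom"]

    def test_invariant_to_log_transform(self):
        x = self._expr() + 10  # positive
        coll = {"s1": _genes(60)[:8], "s2": _genes(60)[20:30]}
        a = ssgsea(x, coll)
        b = ssgsea(np.log2(x + 1), coll)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_invariant_to_random_monotone_maps(self):
        rng = np.random.default_rng(7)
        x = self._expr(seed=7)
        coll = {"s1": _genes(60)[:8], "s2": _genes(60)[30:45]}
        ref = ssgsea(x, coll)
        for _ in range(3):
            a, b, c = rng.uniform(0.5, 2, 3)
            transformed = a * np.exp(b * (x - x.values.min())) + c
            out = ssgsea(transformed, coll)
            assert np.allclose(ref.values, out.values, atol=1e-10)

    def test_empty_overlap_reported_missing(self):
        x = self._expr()
        with pytest.warns(UserWarning, match="no expressed"):
            scores = ssgsea(x, {"ok": _genes(60)[:5], "alien": ["zz1", "zz2"]})
        assert scores["alien"].isna().all()
        assert scores["ok"].notna().all()

    def test_normalized_scores_in_unit_interval(self):
        x = self._expr(seed=2)
        scores = ssgsea(x, {"a": _genes(60)[:5], "b": _genes(60)[10:20]})
        assert scores.values.min() >= 0.0 and scores.values.max() <= 1.0


class TestInfiltration:
    def test_identical_groups_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        sc = pd.DataFrame({"ct": vals + vals}, index=[f"s{i}" for i in range(8)])
        gr = pd.Series(["case"] * 4 + ["control"] * 4, index=sc.index)
        res = compare_infiltration(sc, gr)
        assert res.loc["ct", "p"] > 0.99

    def test_full_separation_hits_minimal_p(self):
        sc = pd.DataFrame(
            {"ct": list(range(10, 20)) + list(range(10))},
            index=[f"s{i}" for i in range(20)],
        )
        gr = pd.Series(["case"] * 10 + ["control"] * 10, index=sc.index)
        res = compare_infiltration(sc, gr)
        # minimal achievable for n=10/10 under the normal approximation
        ref = stats.mannwhitneyu(
            np.arange(10, 20), np.arange(10), alternative="two-sided",
            use_continuity=True, method="asymptotic",
        ).pvalue
        assert res.loc["ct", "p"] == pytest.approx(ref)
        assert res.loc["ct", "p"] < 1e-3
        assert res.loc["ct", "direction"] == "up"


class TestGeneCellCorrelation:
    def _scores(self, x):
        return pd.DataFrame({"ct": x}, index=[f"s{i}" for i in range(len(x))])

    def test_monotone_function_gives_unit_rho(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        expr = pd.DataFrame([v], index=["g"], columns=[f"s{i}" for i in range(30)])
        res = correlate_genes_cells(expr, self._scores(np.exp(v)))
        assert res["rho"].iloc[0] == pytest.approx(1.0)
        assert res["flagged"].iloc[0]

    def test_reversed_ranks_give_minus_one(self):
        v = np.arange(20.0)
        expr = pd.DataFrame([v], index=["g"], columns=[f"s{i}" for i in range(20)])
        res = correlate_genes_cells(expr, self._scores(-v))
        assert res["rho"].iloc[0] == pytest.approx(-1.0)
        assert not res["flagged"].iloc[0]  # signed rule: negative never flagged

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                            columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError):
            correlate_genes_cells(expr, self._scores([1.0, 2.0, 3.0]))
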