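import math

import numpy as np
import pandas as pd
import pytest

from mitostate.core_io import GeneCatalog, GeneSetCollection, ValidationError
from mitostate.differential_enrichment import (
    DifferentialResult,
    build_esdeg,
    correlate_fc,
    hypergeom_enrich,
    wilcoxon_de,
)


def _normed(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cols = [f"C{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


class TestWilcoxonDe:
    def test_exact_p_for_separated_triplets(self):
        # {1,2,3} vs {4,5,6}: all 6 ranks split extreme -> two-sided p = 2/20
        normed = _normed([[1, 2, 3, 4, 5, 6]])
        res = wilcoxon_de(normed, ["C0", "C1", "C2"], ["C3", "C4", "C5"])
        assert res.table["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_null(self):
        normed = _normed([[1, 2, 3, 1, 2, 3]])
        res = wilcoxon_de(normed, ["C0", "C1", "C2"], ["C3", "C4", "C5"])
        assert res.table["p"].iloc[0] == pytest.approx(1.0)
        assert res.table["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 24))
        a = [f"C{j}" for j in range(12)]
        b = [f"C{j}" for j in range(12, 24)]
        p1 = wilcoxon_de(_normed(x), a, b).table["p"]
        p2 = wilcoxon_de(_normed(np.exp(x)), a, b).table["p"]
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-12)

    def test_group_swap_negates_log2fc(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(2, size=(20, 20))
        a = [f"C{j}" for j in range(10)]
        b = [f"C{j}" for j in range(10, 20)]
        f1 = wilcoxon_de(_normed(x), a, b).table["log2fc"]
        f2 = wilcoxon_de(_normed(x), b, a).table["log2fc"]
        np.testing.assert_allclose(f1.to_numpy(), -f2.to_numpy(), atol=1e-12)

    def test_planted_twofold_genes_detected(self):
        rng = np.random.default_rng(2)
        n = 50
        mu = rng.uniform(5, 50, size=100)
        counts_a = rng.poisson(mu[:, None], size=(100, n)).astype(float)
        counts_b = rng.poisson(mu[:, None], size=(100, n)).astype(float)
        counts_a[:10] = rng.poisson(2 * mu[:10, None], size=(10, n))  # 2-fold up
        normed_a, normed_b = np.log1p(counts_a), np.log1p(counts_b)
        normed = _normed(np.hstack([normed_a, normed_b]))
        a = [f"C{j}" for j in range(n)]
        b = [f"C{j}" for j in range(n, 2 * n)]
        res = wilcoxon_de(normed, a, b)
        sig = res.table["significant"].to_numpy()
        assert sig[:10].mean() >= 0.9  # sensitivity
        assert sig[10:].mean() <= 0.05  # false positives

    def test_small_group_rejected(self):
        normed = _normed(np.ones((3, 5)))
        with pytest.raises(ValidationError):
            wilcoxon_de(normed, ["C0", "C1"], ["C2", "C3", "C4"])


def _result_from_sets(universe, sig_genes):
    """DifferentialResult whose significant set is exactly sig_genes."""
    table = pd.DataFrame(index=pd.Index(universe, name="gene"))
    table["log2fc"] = [1.0 if g in sig_genes else 0.0 for g in universe]
    table["p"] = [0.001 if g in sig_genes else 0.9 for g in universe]
    table["p_adj"] = table["p"]
    table["significant"] = table.index.isin(sig_genes)
    return DifferentialResult(table=table)


def _catalog_with_mangs(universe, mangs):
    table = pd.DataFrame(
        {
            "is_mito_encoded": False,
            "is_mito_mrna": False,
            "is_mang": [g in mangs for g in universe],
            "is_tf": False,
            "slc_family": None,
            "chromosome": "1",
        },
        index=pd.Index(universe, name="symbol"),
    )
    return GeneCatalog(table=table)


class TestBuildEsdeg:
    def test_set_arithmetic_with_mang_exclusion(self):
        universe = ["a", "b", "c", "m", "x"]
        da1 = _result_from_sets(universe, {"a", "b", "m"})
        da2 = _result_from_sets(universe, {"b", "c", "m"})
        cat = _catalog_with_mangs(universe, {"m"})
        part = build_esdeg(da1, da2, cat, min_exclusive=1)
        assert part.intersection == {"b"}
        assert part.da1_exclusive == {"a"}
        assert part.esdegs == {"c"}
        assert part.mangs_excluded == {"m"}
        assert not part.discarded

    def test_identical_analyses_give_empty_esdeg(self):
        universe = [f"g{i}" for i in range(10)]
        da = _result_from_sets(universe, set(universe[:4]))
        cat = _catalog_with_mangs(universe, set())
        part = build_esdeg(da, da, cat, min_exclusive=0)
        assert part.esdegs == set() and part.da1_exclusive == set()

    def test_disjoint_sets_preserve_counts(self):
        universe = [f"g{i:03d}" for i in range(400)]
        sig1 = set(universe[:120])
        sig2 = set(universe[120:270])  # 150, disjoint from sig1
        part = build_esdeg(
            _result_from_sets(universe, sig1),
            _result_from_sets(universe, sig2),
            _catalog_with_mangs(universe, set()),
            min_exclusive=100,
        )
        assert len(part.da1_exclusive) == 120
        assert len(part.esdegs) == 150
        assert len(part.intersection) == 0
        assert not part.discarded

    def test_insufficient_exclusive_genes_flagged(self):
        universe = [f"g{i}" for i in range(50)]
        part = build_esdeg(
            _result_from_sets(universe, set(universe[:10])),
            _result_from_sets(universe, set(universe[5:20])),
            _catalog_with_mangs(universe, set()),
            min_exclusive=100,
        )
        assert part.discarded

    def test_mismatched_universes_rejected(self):
        da1 = _result_from_sets(["a", "b"], {"a"})
        da2 = _result_from_sets(["a", "c"], {"a"})
        with pytest.raises(ValidationError):
            build_esdeg(da1, da2, _catalog_with_mangs(["a", "b"], set()), 1)


class TestCorrelateFc:
    def test_identity_line(self):
        fc = pd.Series([0.5, -1.0, 2.0, 0.1], index=list("abcd"))
        r, slope, intercept, p = correlate_fc(fc.index, fc, fc)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_negation_gives_minus_one(self):
        fc = pd.Series([0.5, -1.0, 2.0, 0.1], index=list("abcd"))
        r, *_ = correlate_fc(fc.index, fc, -fc)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        x = pd.Series(rng.normal(size=10), index=genes)
        y = pd.Series(rng.normal(size=10), index=genes)
        r, slope, intercept, _ = correlate_fc(genes, x, y)
        xv, yv = x.to_numpy(), y.to_numpy()
        cov = ((xv - xv.mean()) * (yv - yv.mean())).mean()
        r_direct = cov / (xv.std() * yv.std())
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert slope == pytest.approx(cov / xv.var(), abs=1e-12)

    def test_zero_variance_flagged(self):
        genes = list("abc")
        x = pd.Series([1.0, 1.0, 1.0], index=genes)
        y = pd.Series([1.0, 2.0, 3.0], index=genes)
        with pytest.raises(ValidationError, match="zero variance"):
            correlate_fc(genes, x, y)


class TestHypergeomEnrich:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        coll = GeneSetCollection(sets={"S": universe[:5]})
        table = hypergeom_enrich(universe[:5], universe, coll)
        assert table.loc["S", "p"] == pytest.approx(1.0 / math.comb(20, 5))
        assert table.loc["S", "k"] == 5

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(30)]
        coll = GeneSetCollection(sets={"S": universe[:3]})
        table = hypergeom_enrich(universe[10:15], universe, coll)
        assert table.loc["S", "p"] == pytest.approx(1.0)

    def test_query_equals_universe_forces_p_one(self):
        universe = [f"g{i}" for i in range(15)]
        coll = GeneSetCollection(
            sets={"A": universe[:4], "B": universe[4:10], "C": universe[2:8]}
        )
        table = hypergeom_enrich(universe, universe, coll)
        np.testing.assert_allclose(table["p"].to_numpy(), 1.0)

    def test_matches_bruteforce_tail_on_small_instances(self):
        # independent oracle: tail sum of the hypergeometric pmf via math.comb
        for N, K, n in [(10, 3, 4), (20, 5, 5), (30, 12, 7), (25, 10, 10)]:
            universe = [f"g{i}" for i in range(N)]
            members = universe[:K]
            query = universe[N - n :]
            coll = GeneSetCollection(sets={"S": members})
            table = hypergeom_enrich(query, universe, coll)
            k_obs = table.loc["S", "k"]
            tail = sum(
                math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
                for k in range(k_obs, min(K, n) + 1)
            )
            assert table.loc["S", "p"] == pytest.approx(tail, rel=1e-10)

    def test_top_n_truncation_and_sorting(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(100)]
        sets = {
            f"S{i}": list(rng.choice(universe, size=10, replace=False))
            for i in range(30)
        }
        coll = GeneSetCollection(sets=sets)
        table = hypergeom_enrich(universe[:20], universe, coll, top_n=20)
        assert len(table) == 20
        assert (np.diff(table["p"].to_numpy()) >= -1e-15).all()

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(
                ["zz"], ["a", "b"], GeneSetCollection(sets={"S": ["a"]})
            )
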