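import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mitostate.core_io import GeneSetCollection, ValidationError
from mitostate.pathway_scoring import cell_cycle_score, gsva, ssgsea


# ---------------------------------------------------------------------------
# Independent step-by-step oracles (scalar loops, no shared code with the
# implementation).
# ---------------------------------------------------------------------------

def gsva_oracle(expr: pd.DataFrame, gene_set, tau=1.0, max_diff=True):
    """Naive kernel-CDF random-walk score, one cell at a time."""
    genes = list(expr.index)
    cells = list(expr.columns)
    p = len(genes)
    # gene-level kernel CDF statistic
    z = {}
    for g in genes:
        x = expr.loc[g].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            z[g] = {c: 0.0 for c in cells}
            continue
        h = sd / 4.0
        z[g] = {}
        for c, xc in zip(cells, x):
            z[g][c] = float(np.mean([norm.cdf((xc - xk) / h) for xk in x]))
    in_set = set(gene_set)
    scores = {}
    for c in cells:
        ordered = sorted(genes, key=lambda g: (-z[g][c], g))
        weights = [abs(p / 2.0 - (i + 1)) ** tau for i in range(p)]
        denom_in = sum(w for g, w in zip(ordered, weights) if g in in_set)
        n_out = p - len(in_set & set(genes))
        v, cum_in, cum_out = [], 0.0, 0
        for g, w in zip(ordered, weights):
            if g in in_set:
                cum_in += w
            else:
                cum_out += 1
            win = cum_in / denom_in if denom_in > 0 else 0.0
            wout = cum_out / n_out if n_out > 0 else 0.0
            v.append(win - wout)
        if max_diff:
            scores[c] = max(max(v), 0.0) + min(min(v), 0.0)
        else:
            scores[c] = v[int(np.argmax(np.abs(v)))]
    return pd.Series(scores)


def ssgsea_oracle(expr: pd.DataFrame, gene_set, alpha=0.25):
    """Naive running-sum enrichment, one cell at a time (unnormalized)."""
    genes = list(expr.index)
    p = len(genes)
    in_set = set(gene_set)
    out = {}
    for c in expr.columns:
        vals = expr[c]
        ordered = sorted(genes, key=lambda g: (-vals[g], g))
        # rank value p for the top gene, descending
        rank_of = {g: p - i for i, g in enumerate(ordered)}
        denom_in = sum(rank_of[g] ** alpha for g in ordered if g in in_set)
        n_out = p - len(in_set & set(genes))
        es, cum_in, cum_out = 0.0, 0.0, 0
        for g in ordered:
            if g in in_set:
                cum_in += rank_of[g] ** alpha
            else:
                cum_out += 1
            es += cum_in / denom_in - cum_out / n_out
        out[c] = es
    return pd.Series(out)


def _random_instance(seed, p=5, n=5):
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.normal(size=(p, n)),
        index=[f"G{i}" for i in range(p)],
        columns=[f"C{j}" for j in range(n)],
    )
    k = rng.integers(2, p)
    members = list(rng.choice(expr.index, size=k, replace=False))
    return expr, members


class TestGsva:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_on_random_instances(self, seed):
        expr, members = _random_instance(seed)
        got = gsva(expr, GeneSetCollection(sets={"S": members})).scores.loc["S"]
        want = gsva_oracle(expr, members)
        np.testing.assert_allclose(got.to_numpy(), want[got.index].to_numpy(), atol=1e-8)

    def test_matches_oracle_max_magnitude_mode(self):
        expr, members = _random_instance(99)
        got = gsva(expr, GeneSetCollection(sets={"S": members}), max_diff=False).scores.loc["S"]
        want = gsva_oracle(expr, members, max_diff=False)
        np.testing.assert_allclose(got.to_numpy(), want[got.index].to_numpy(), atol=1e-8)

    def test_toy_4x3_matches_oracle(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 0.5], [0.2, 0.9, 1.5], [2.0, 0.1, 0.3], [0.7, 0.7, 2.2]],
            index=["G0", "G1", "G2", "G3"],
            columns=["C0", "C1", "C2"],
        )
        got = gsva(expr, GeneSetCollection(sets={"S": ["G0", "G2"]})).scores.loc["S"]
        want = gsva_oracle(expr, ["G0", "G2"])
        np.testing.assert_allclose(got.to_numpy(), want[got.index].to_numpy(), atol=1e-8)

    def test_all_gene_set_scores_zero(self):
        expr, _ = _random_instance(0)
        coll = GeneSetCollection(sets={"ALL": list(expr.index)})
        assert (gsva(expr, coll).scores.loc["ALL"] == 0).all()

    def test_scores_bounded(self):
        expr, members = _random_instance(5, p=30, n=20)
        scores = gsva(expr, GeneSetCollection(sets={"S": members})).scores
        assert (scores.to_numpy() >= -1).all() and (scores.to_numpy() <= 1).all()

    def test_zero_variance_gene_no_crash(self):
        expr, members = _random_instance(1)
        expr.loc["G0"] = 3.14
        scores = gsva(expr, GeneSetCollection(sets={"S": members})).scores
        assert np.isfinite(scores.to_numpy()).all()

    def test_duplicated_cell_leaves_others_stable(self):
        # well-separated values so kcdf re-estimation cannot flip ranks
        rng = np.random.default_rng(2)
        base = rng.permutation(np.arange(1.0, 41.0)).reshape(8, 5)
        expr = pd.DataFrame(
            base, index=[f"G{i}" for i in range(8)], columns=[f"C{j}" for j in range(5)]
        )
        dup = expr.copy()
        dup["C5"] = expr["C4"]
        coll = GeneSetCollection(sets={"S": ["G1", "G3", "G5"]})
        s1 = gsva(expr, coll).scores.loc["S"]
        s2 = gsva(dup, coll).scores.loc["S"]
        np.testing.assert_allclose(
            s1.to_numpy(), s2[s1.index].to_numpy(), atol=1e-6
        )

    def test_empty_surviving_collection_rejected(self):
        expr, _ = _random_instance(3)
        coll = GeneSetCollection(sets={"S": ["NOPE1", "NOPE2"]})
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                gsva(expr, coll)


class TestSsgsea:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_oracle_on_random_instances(self, seed):
        expr, members = _random_instance(seed, p=6, n=4)
        got = ssgsea(
            expr, GeneSetCollection(sets={"S": members}), normalize=False
        ).scores.loc["S"]
        want = ssgsea_oracle(expr, members)
        np.testing.assert_allclose(got.to_numpy(), want[got.index].to_numpy(), atol=1e-8)

    def test_six_gene_running_sum_value(self):
        # genes already in descending order; set at positions 1 and 4
        expr = pd.DataFrame(
            {"C0": [5.0, 4.0, 3.0, 2.0, 1.0, 0.0], "C1": [5.0, 4.0, 3.0, 2.0, 1.0, 0.0]},
            index=list("ABCDEF"),
        )
        got = ssgsea(
            expr, GeneSetCollection(sets={"S": ["A", "D"]}), normalize=False
        ).scores.loc["S"]
        # direct evaluation of the running sum (alpha = 0.25):
        w_a, w_d = 6**0.25, 3**0.25
        denom = w_a + w_d
        ecdf_in = [w_a / denom, w_a / denom, w_a / denom, 1.0, 1.0, 1.0]
        ecdf_out = [0.0, 0.25, 0.5, 0.5, 0.75, 1.0]
        expect = sum(i - o for i, o in zip(ecdf_in, ecdf_out))
        np.testing.assert_allclose(got.to_numpy(), [expect, expect], atol=1e-12)

    def test_top_ranked_set_is_extremal(self):
        rng = np.random.default_rng(4)
        values = np.sort(rng.normal(size=10))[::-1]
        genes = [f"G{i}" for i in range(10)]
        members = genes[:3]  # occupy the top ranks
        coll = GeneSetCollection(sets={"S": members})
        top = pd.DataFrame({"C0": values, "C1": values}, index=genes)
        s_top = ssgsea(top, coll, normalize=False).scores.loc["S", "C0"]
        for _ in range(30):
            perm = pd.DataFrame(
                {"C0": rng.permutation(values), "C1": values}, index=genes
            )
            s_perm = ssgsea(perm, coll, normalize=False).scores.loc["S", "C0"]
            assert s_perm <= s_top + 1e-12

    def test_identical_rank_order_gives_identical_scores(self):
        genes = [f"G{i}" for i in range(8)]
        v = np.arange(8, dtype=float)
        expr = pd.DataFrame({"C0": v, "C1": v * 10 + 3}, index=genes)  # same order
        scores = ssgsea(expr, GeneSetCollection(sets={"S": genes[:3]})).scores
        assert scores.loc["S", "C0"] == pytest.approx(scores.loc["S", "C1"])

    def test_rank_reversal_flips_sign(self):
        genes = [f"G{i}" for i in range(9)]
        v = np.arange(9, dtype=float)
        coll = GeneSetCollection(sets={"S": [genes[0], genes[1]]})
        fwd = pd.DataFrame({"C0": v, "C1": v}, index=genes)
        rev = pd.DataFrame({"C0": v[::-1], "C1": v[::-1]}, index=genes)
        s_f = ssgsea(fwd, coll, normalize=False).scores.loc["S", "C0"]
        s_r = ssgsea(rev, coll, normalize=False).scores.loc["S", "C0"]
        assert np.sign(s_f) == -np.sign(s_r) != 0

    def test_normalization_divides_by_range(self):
        expr, members = _random_instance(6, p=10, n=6)
        coll = GeneSetCollection(sets={"S": members, "T": list(expr.index[:2])})
        raw = ssgsea(expr, coll, normalize=False).scores
        normed = ssgsea(expr, coll, normalize=True).scores
        span = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(normed.to_numpy(), raw.to_numpy() / span)


class TestCellCycle:
    def test_all_zero_matrix_scores_zero_phase_g1(self):
        genes = [f"G{i}" for i in range(30)]
        expr = pd.DataFrame(
            np.zeros((30, 5)), index=genes, columns=[f"C{j}" for j in range(5)]
        )
        call = cell_cycle_score(expr, genes[:3], genes[3:6], n_bins=5, n_ctrl=5)
        assert (call.table["s_score"] == 0).all()
        assert (call.table["g2m_score"] == 0).all()
        assert (call.table["phase"] == "G1").all()

    def test_planted_g2m_program_detected(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(60)]
        g2m, s_sig = genes[:5], genes[5:10]
        expr = pd.DataFrame(
            rng.exponential(1.0, size=(60, 40)),
            index=genes,
            columns=[f"C{j}" for j in range(40)],
        )
        expr.loc[g2m, expr.columns[:20]] += 3.0  # first half cycles
        call = cell_cycle_score(expr, s_sig, g2m, n_bins=10, n_ctrl=10)
        frac_hi = (call.table["phase"].iloc[:20] == "G2M").mean()
        frac_lo = (call.table["phase"].iloc[20:] == "G2M").mean()
        assert frac_hi > frac_lo

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(40)]
        expr = pd.DataFrame(
            rng.exponential(1.0, size=(40, 10)),
            index=genes,
            columns=[f"C{j}" for j in range(10)],
        )
        shuffled = expr.sample(frac=1.0, random_state=1)
        a = cell_cycle_score(expr, genes[:4], genes[4:8], n_bins=8, n_ctrl=8)
        b = cell_cycle_score(shuffled, genes[:4], genes[4:8], n_bins=8, n_ctrl=8)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_absent_signature_rejected(self):
        expr = pd.DataFrame(
            np.ones((5, 4)), index=list("ABCDE"), columns=[f"C{j}" for j in range(4)]
        )
        with pytest.raises(ValidationError):
            cell_cycle_score(expr, ["ZZ1"], ["A", "B"], n_bins=2, n_ctrl=2)
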