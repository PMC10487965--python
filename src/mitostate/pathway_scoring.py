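"""Per-cell gene-set scoring engines.

Two rank-based single-sample scorers are implemented:

* :func:`gsva` — the kernel-CDF random-walk statistic: each gene's
  expression is first summarized across cells by a kernel estimate of its
  cumulative density (Gaussian kernel, bandwidth ``sd/4``; a Poisson kernel
  is available for raw counts), each cell's genes are then ranked by that
  statistic, and a weighted Kolmogorov-Smirnov-like random walk with
  symmetric rank weights ``|p/2 - rank|^tau`` yields the set score.  Scores
  are bounded in [-1, 1].
* :func:`ssgsea` — the single-sample enrichment statistic: per cell, the
  running difference between a weighted in-set ECDF (weight ``rank^alpha``)
  and the uniform out-of-set ECDF is summed over all ranks; scores are
  optionally normalized by the global max-min range.

:func:`cell_cycle_score` is an additive module score with expression-bin
matched control genes, used for S/G2M phase assignment.

Ties in any per-cell ranking are broken by gene-id lexicographic order so
results are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection, ValidationError

__all__ = ["PathwayScoreMatrix", "CellCycleCall", "gsva", "ssgsea", "cell_cycle_score"]


@dataclass
class PathwayScoreMatrix:
    scores: pd.DataFrame  # sets x cells
    method: str  # "gsva" | "ssgsea" | "module"
    params: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValidationError("non-finite pathway scores")


def _kcdf_statistic(expr: np.ndarray, kcdf: str) -> np.ndarray:
    """Per-gene kernel-CDF statistic across cells; zero-variance genes -> 0."""
    p, n = expr.shape
    z = np.zeros_like(expr, dtype=float)
    for g in range(p):
        x = expr[g]
        sd = x.std()
        if sd == 0:
            continue
        if kcdf == "gaussian":
            h = sd / 4.0
            z[g] = stats.norm.cdf((x[:, None] - x[None, :]) / h).mean(axis=1)
        elif kcdf == "poisson":
            lam = x[None, :] + 0.5
            z[g] = stats.poisson.cdf(np.floor(x)[:, None], lam).mean(axis=1)
        else:
            raise ValidationError(f"unknown kcdf {kcdf!r}")
    return z


def _order_desc(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Column-wise gene ordering by decreasing value, ties by gene id."""
    p, n = values.shape
    lex_rank = np.argsort(np.argsort(gene_ids, kind="stable"), kind="stable")
    order = np.empty((p, n), dtype=int)
    for j in range(n):
        order[:, j] = np.lexsort((lex_rank, -values[:, j]))
    return order


def gsva(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    kcdf: str = "gaussian",
    tau: float = 1.0,
    max_diff: bool = True,
) -> PathwayScoreMatrix:
    """Kernel-CDF random-walk set scores per cell.

    A set containing every gene of the matrix carries no ranking information
    and scores 0 by convention.
    """
    if expr.shape[1] < 2:
        raise ValidationError("need at least 2 cells")
    usable = sets.restrict(expr.index, min_size=2)
    dropped = set(sets.names) - set(usable.names)
    if dropped:
        warnings.warn(f"sets dropped (<2 genes in matrix): {sorted(dropped)}")
    if len(usable) == 0:
        raise ValidationError("no gene set overlaps the matrix")

    gene_ids = expr.index.to_numpy(dtype=object)
    z = _kcdf_statistic(expr.to_numpy(dtype=float), kcdf)
    p, n = z.shape
    order = _order_desc(z, gene_ids)
    # symmetric rank weights depend only on position in the ordering
    positions = np.arange(1, p + 1)
    w = np.abs(p / 2.0 - positions) ** tau  # shape (p,)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    rows = {}
    for name, genes in usable:
        ind = np.zeros(p, dtype=bool)
        ind[[gene_pos[g] for g in genes]] = True
        if ind.all():
            rows[name] = np.zeros(n)
            continue
        ind_ord = ind[order]  # (p, n) indicator arranged by each cell's order
        w_in = ind_ord * w[:, None]
        denom_in = w_in.sum(axis=0)
        denom_in[denom_in == 0] = 1.0  # all-weight-zero set: walk stays flat
        win = np.cumsum(w_in, axis=0) / denom_in[None, :]
        wout = np.cumsum(~ind_ord, axis=0) / float(p - ind.sum())
        v = win - wout
        if max_diff:
            score = np.maximum(v.max(axis=0), 0.0) + np.minimum(v.min(axis=0), 0.0)
        else:
            pick = np.abs(v).argmax(axis=0)
            score = v[pick, np.arange(n)]
        rows[name] = score
    scores = pd.DataFrame(rows, index=expr.columns).T
    scores = scores.loc[[s for s in usable.names]]
    return PathwayScoreMatrix(
        scores=scores,
        method="gsva",
        params={"kcdf": kcdf, "tau": tau, "max_diff": max_diff},
    )


def ssgsea(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> PathwayScoreMatrix:
    """Single-sample enrichment: summed weighted-ECDF difference per cell."""
    if expr.shape[1] < 2:
        raise ValidationError("need at least 2 cells")
    usable = sets.restrict(expr.index, min_size=2)
    dropped = set(sets.names) - set(usable.names)
    if dropped:
        warnings.warn(f"sets dropped (<2 genes in matrix): {sorted(dropped)}")
    if len(usable) == 0:
        raise ValidationError("no gene set overlaps the matrix")

    gene_ids = expr.index.to_numpy(dtype=object)
    x = expr.to_numpy(dtype=float)
    p, n = x.shape
    order = _order_desc(x, gene_ids)
    # rank value of the gene at descending position i is p - i
    rank_vals = np.arange(p, 0, -1, dtype=float)
    w = rank_vals**alpha

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    rows = {}
    for name, genes in usable:
        ind = np.zeros(p, dtype=bool)
        ind[[gene_pos[g] for g in genes]] = True
        n_out = p - int(ind.sum())
        ind_ord = ind[order]
        w_in = ind_ord * w[:, None]
        denom = w_in.sum(axis=0)
        denom[denom == 0] = 1.0
        ecdf_in = np.cumsum(w_in, axis=0) / denom[None, :]
        if n_out == 0:
            rows[name] = np.zeros(n)
            continue
        ecdf_out = np.cumsum(~ind_ord, axis=0) / float(n_out)
        rows[name] = (ecdf_in - ecdf_out).sum(axis=0)
    scores = pd.DataFrame(rows, index=expr.columns).T
    scores = scores.loc[[s for s in usable.names]]
    if normalize:
        rng_span = scores.to_numpy().max() - scores.to_numpy().min()
        if rng_span > 0:
            scores = scores / rng_span
    return PathwayScoreMatrix(
        scores=scores,
        method="ssgsea",
        params={"alpha": alpha, "normalize": normalize},
    )


@dataclass
class CellCycleCall:
    table: pd.DataFrame  # per-cell: s_score, g2m_score, phase

    def __post_init__(self) -> None:
        t = self.table
        pos = (t[["s_score", "g2m_score"]] > 0).any(axis=1)
        argmax = np.where(
            t["g2m_score"] > t["s_score"], "G2M", "S"
        )
        expected = np.where(pos, argmax, "G1")
        if not (t["phase"].to_numpy() == expected).all():
            raise ValidationError("phase must be argmax of positive scores, else G1")


def _module_score(
    expr: pd.DataFrame,
    signature: list[str],
    n_bins: int,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean(signature) - mean(bin-matched control genes), per cell."""
    present = [g for g in signature if g in expr.index]
    if not present:
        raise ValidationError("signature entirely absent from matrix")
    avg = expr.mean(axis=1)
    # bin genes by average expression; qcut on ranks avoids duplicate edges
    ranks = avg.rank(method="first")
    bins = pd.qcut(ranks, q=min(n_bins, len(avg)), labels=False, duplicates="drop")
    bins = pd.Series(bins, index=expr.index)
    ctrl: list[str] = []
    sig_set = set(present)
    for g in sorted(present):
        pool = bins.index[(bins == bins[g]) & (~bins.index.isin(sig_set))]
        if len(pool) == 0:
            pool = bins.index[~bins.index.isin(sig_set)]
        take = min(n_ctrl, len(pool))
        ctrl.extend(rng.choice(pool.to_numpy(object), size=take, replace=False))
    if not ctrl:
        raise ValidationError("no control genes available outside the signature")
    return (
        expr.loc[present].mean(axis=0).to_numpy()
        - expr.loc[ctrl].mean(axis=0).to_numpy()
    )


def cell_cycle_score(
    expr: pd.DataFrame,
    s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> CellCycleCall:
    """S/G2M module scores with bin-matched controls, and phase assignment.

    Phase is the argmax of the two scores when either is positive, else G1.
    """
    n_outside = len(set(expr.index) - set(s_genes) - set(g2m_genes))
    if n_outside < 1:
        raise ValidationError("no genes outside the signatures to draw controls from")
    expr = expr.sort_index()  # control pools must not depend on row order
    rng = np.random.default_rng(seed)
    s_score = _module_score(expr, sorted(s_genes), n_bins, n_ctrl, rng)
    g2m_score = _module_score(expr, sorted(g2m_genes), n_bins, n_ctrl, rng)
    phase = np.where(
        (s_score > 0) | (g2m_score > 0),
        np.where(g2m_score > s_score, "G2M", "S"),
        "G1",
    )
    table = pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=expr.columns,
    )
    return CellCycleCall(table=table)
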