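"""Regulon inference, AUC-based regulon activity, and the
receptor -> TF -> target cascade network.

Regulons (a transcription factor and its inferred targets) are built from
random-forest feature importances of TFs predicting each non-TF gene, the
co-expression approach of tree-ensemble network inference.  An optional
prior table (tf, target, nes) stands in for motif-based pruning: candidate
targets are intersected with the prior's motif-supported targets and a
regulon is kept only when its prior normalized enrichment score exceeds
3.0.  Without a prior, regulons are co-expression-only and labelled as
such.

Per-cell regulon activity is the area under the recovery curve of regulon
genes among the cell's top-ranked genes, normalized by the maximal
achievable area.  The cascade network joins significant ESDEG receptors to
TFs by Spearman co-expression (|rho| >= rho_min, BH-adjusted p < 0.05) and
TFs to their regulon targets, every edge annotated with its Spearman
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError
from .subpopulation import moderated_diff

__all__ = [
    "Regulon",
    "CascadeNetwork",
    "infer_regulons",
    "aucell",
    "regulon_diff",
    "build_cascade",
]

NES_MIN = 3.0


@dataclass
class Regulon:
    tf: str
    targets: dict[str, float]  # gene -> importance weight
    nes: float | None = None  # prior NES when a motif prior was supplied
    coexpression_only: bool = True

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValidationError("a TF cannot be its own target")
        if any(w < 0 for w in self.targets.values()):
            raise ValidationError("importance weights must be >= 0")


def infer_regulons(
    expr: pd.DataFrame,
    tf_list,
    n_trees: int = 100,
    top_k_targets: int = 20,
    prior: pd.DataFrame | None = None,
    seed: int = 0,
) -> list[Regulon]:
    """Random-forest co-expression regulons, optionally pruned by a prior.

    Parameters
    ----------
    expr
        Genes x cells expression table (UMI counts or normalized values).
    tf_list
        Candidate transcription factors; those absent from the matrix are
        ignored.
    prior
        Optional TSV-shaped frame with columns ``tf``, ``target``, ``nes``:
        candidate targets are pruned to the prior's targets per TF, and TFs
        whose best prior NES is <= 3.0 are dropped.

    Cells are canonicalized to a fixed order internally, so the result is
    invariant to shuffling the input cell order.
    """
    tfs = [t for t in tf_list if t in expr.index]
    if len(tfs) == 0:
        raise ValidationError("empty TF list (no TF present in matrix)")
    if expr.shape[1] < 50:
        raise ValidationError("need >=50 cells for forest-based inference")
    expr = expr[sorted(expr.columns)]  # cell order must not matter
    x_tf = expr.loc[tfs].to_numpy(dtype=float).T  # cells x TFs
    tf_sd = x_tf.std(axis=0)
    targets = [g for g in expr.index if g not in set(tfs)]

    importances: dict[str, dict[str, float]] = {t: {} for t in tfs}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(targets))
    for gene, gene_seed in zip(targets, child_seeds):
        y = expr.loc[gene].to_numpy(dtype=float)
        if y.std() == 0:
            continue
        y = (y - y.mean()) / y.std()  # unit variance: importances comparable across genes
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            # without a leaf-size floor, deep trees explain noise genes'
            # variance as well as true targets', washing out the importance signal
            min_samples_leaf=max(5, expr.shape[1] // 20),
            random_state=int(gene_seed % (2**31)),
            n_jobs=1,
        )
        forest.fit(x_tf, y)
        # unnormalized variance reduction per TF (sklearn's normalized
        # importances would erase between-gene differences in signal)
        imp = np.zeros(len(tfs))
        for est in forest.estimators_:
            imp += est.tree_.compute_feature_importances(normalize=False)
        imp /= len(forest.estimators_)
        imp = np.where(tf_sd == 0, 0.0, imp)  # constant TFs carry no signal
        for t, w in zip(tfs, imp):
            if w > 0:
                importances[t][gene] = float(w)

    prior_targets: dict[str, set[str]] = {}
    prior_nes: dict[str, float] = {}
    if prior is not None:
        for _, row in prior.iterrows():
            prior_targets.setdefault(row["tf"], set()).add(row["target"])
            nes = float(row["nes"])
            prior_nes[row["tf"]] = max(prior_nes.get(row["tf"], -np.inf), nes)

    regulons = []
    for t in tfs:
        ranked = sorted(importances[t].items(), key=lambda kv: (-kv[1], kv[0]))
        cand = dict(ranked[:top_k_targets])
        nes = None
        coexpr_only = True
        if prior is not None and t in prior_targets:
            cand = {g: w for g, w in cand.items() if g in prior_targets[t]}
            nes = prior_nes[t]
            coexpr_only = False
            if nes <= NES_MIN:
                continue
        if not cand:
            continue
        regulons.append(
            Regulon(tf=t, targets=cand, nes=nes, coexpression_only=coexpr_only)
        )
    return regulons


def aucell(
    normed: pd.DataFrame,
    regulons: list[Regulon],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Regulon x cell activity matrix by area under the recovery curve.

    Per cell, genes are ranked by decreasing expression (ties broken by a
    seeded random gene permutation); the recovery curve counts regulon
    genes among the top ``ceil(top_fraction * n_genes)`` ranks and its
    trapezoidal area is normalized by the maximal achievable area.
    """
    if not 0.0 < top_fraction <= 0.5:
        raise ValidationError("top_fraction must be in (0, 0.5]")
    p, n = normed.shape
    rng = np.random.default_rng(seed)
    tie_break = rng.permutation(p)  # one seeded permutation for all cells
    x = normed.to_numpy(dtype=float)
    max_rank = int(np.ceil(top_fraction * p))

    # per-cell rank position of each gene (0 = highest expression)
    order = np.empty((p, n), dtype=int)
    for j in range(n):
        order[:, j] = np.lexsort((tie_break, -x[:, j]))
    rank_of = np.empty((p, n), dtype=int)
    col = np.arange(n)
    for pos in range(p):
        rank_of[order[pos, :], col] = pos

    rows = {}
    for reg in regulons:
        members = [g for g in reg.targets if g in normed.index]
        if reg.tf in normed.index:
            pass  # activity is over target genes only
        if not members:
            warnings.warn(f"regulon {reg.tf!r} has no genes in the matrix")
            rows[reg.tf] = np.zeros(n)
            continue
        m_idx = [normed.index.get_loc(g) for g in members]
        n_reg = len(m_idx)
        member_ranks = rank_of[m_idx, :]  # (n_reg, n)
        # recovery curve y(x) = #{members with rank < x}, x = 1..max_rank
        steps = np.arange(1, max_rank + 1)
        y = (member_ranks[:, :, None] < steps[None, None, :]).sum(axis=0)  # (n, max_rank)
        y0 = np.zeros((n, 1))
        curve = np.concatenate([y0, y], axis=1)
        auc = np.trapezoid(curve, axis=1)
        ymax = np.minimum(steps, n_reg)
        max_curve = np.concatenate([[0.0], ymax])
        max_auc = np.trapezoid(max_curve)
        rows[reg.tf] = auc / max_auc if max_auc > 0 else np.zeros(n)
    return pd.DataFrame(rows, index=normed.columns).T


def regulon_diff(
    activity: pd.DataFrame,
    labels: pd.Series,
    top_n: int = 50,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Moderated differential test of regulon activities between two states.

    Rows with p < ``alpha`` (default 0.01) are kept and the ``top_n`` most
    significant returned; when fewer are significant, all of them are.
    """
    res = moderated_diff(activity, labels)
    table = res.table[res.table["p"] < alpha].sort_values(
        ["p", "log2fc"], kind="stable"
    )
    return table.head(top_n)


@dataclass
class CascadeNetwork:
    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["source", "target", "layer", "rho", "p"]
        )
    )

    def __post_init__(self) -> None:
        if len(self.edges):
            rho = self.edges["rho"].to_numpy(dtype=float)
            if ((rho < -1) | (rho > 1)).any():
                raise ValidationError("Spearman coefficients must lie in [-1, 1]")
            rt = self.edges[self.edges["layer"] == "receptor-tf"]
            tt = self.edges[self.edges["layer"] == "tf-target"]
            with_targets = set(tt["source"])
            orphan = set(rt["target"]) - with_targets
            if orphan:
                raise ValidationError(f"TFs without target edges: {sorted(orphan)}")

    @property
    def receptor_tf(self) -> pd.DataFrame:
        return self.edges[self.edges["layer"] == "receptor-tf"]

    @property
    def tf_target(self) -> pd.DataFrame:
        return self.edges[self.edges["layer"] == "tf-target"]


def build_cascade(
    receptors,
    regulons: list[Regulon],
    normed: pd.DataFrame,
    rho_min: float = 0.3,
    alpha: float = 0.05,
) -> CascadeNetwork:
    """Assemble the receptor -> TF -> target hierarchical network.

    A receptor-TF edge requires |Spearman rho| >= ``rho_min`` with
    BH-adjusted p < ``alpha`` across all candidate receptor-TF pairs; TFs
    with no incoming receptor edge, or with no surviving target in the
    matrix, are pruned.
    """
    receptors = [r for r in receptors if r in normed.index]
    if not receptors:
        raise ValidationError("no ESDEG receptor present in the matrix")
    tf_names = [reg.tf for reg in regulons if reg.tf in normed.index]
    reg_by_tf = {reg.tf: reg for reg in regulons}

    cand = []
    for rec in receptors:
        for tf in tf_names:
            if tf == rec:
                continue
            rho, p = stats.spearmanr(
                normed.loc[rec].to_numpy(), normed.loc[tf].to_numpy()
            )
            if np.isnan(rho):
                rho, p = 0.0, 1.0
            cand.append({"source": rec, "target": tf, "rho": float(rho), "p": float(p)})
    if not cand:
        warnings.warn("no candidate receptor-TF pair")
        return CascadeNetwork()
    cand = pd.DataFrame(cand)
    cand["p_adj"] = multipletests(cand["p"], method="fdr_bh")[1]
    kept = cand[(cand["rho"].abs() >= rho_min) & (cand["p_adj"] < alpha)]

    rows = []
    for _, edge in kept.iterrows():
        tf = edge["target"]
        reg = reg_by_tf[tf]
        targets = [g for g in reg.targets if g in normed.index and g != tf]
        if not targets:
            continue  # orphan TF: prune the receptor edge too
        rows.append(
            {
                "source": edge["source"],
                "target": tf,
                "layer": "receptor-tf",
                "rho": edge["rho"],
                "p": edge["p_adj"],
            }
        )
        for g in targets:
            rho, p = stats.spearmanr(
                normed.loc[tf].to_numpy(), normed.loc[g].to_numpy()
            )
            if np.isnan(rho):
                rho, p = 0.0, 1.0
            rows.append(
                {
                    "source": tf,
                    "target": g,
                    "layer": "tf-target",
                    "rho": float(rho),
                    "p": float(p),
                }
            )
    if not rows:
        warnings.warn("no surviving cascade edge")
        return CascadeNetwork()
    edges = pd.DataFrame(rows).drop_duplicates(subset=["source", "target", "layer"])
    return CascadeNetwork(edges=edges)
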