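"""The core discovery step: moderated differential scoring of pathway
activities, re-clustering of cells in pathway-score space, and labelling of
the resulting clusters as health-dominant (HDC) or disease-dominant (DDC).

The differential model is the two-group special case of the empirical-Bayes
moderated linear model: per-feature residual variances are shrunk towards a
common prior estimated by moment-matching the scaled-F law of sample
variances (trigamma inversion), and the moderated t-statistic gains the
prior degrees of freedom.  A feature is called significant when the
BH-adjusted p is below 0.05 and |log2FC| exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

__all__ = [
    "ModeratedDiffResult",
    "SubclusterAssignment",
    "moderated_diff",
    "recluster_on_scores",
    "classify_dominance",
    "trigamma_inverse",
]

SIG_ADJ_P = 0.05
SIG_LOG2FC = 0.5


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y  # good starting value for both tails
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < tol * x:
            break
    return float(x)


@dataclass
class ModeratedDiffResult:
    table: pd.DataFrame  # per feature: log2fc, mean_a, mean_b, t, p, p_adj, s2_post, significant
    prior_df: float  # d0
    prior_var: float  # s0^2

    def __post_init__(self) -> None:
        t = self.table
        if (t["p_adj"] < t["p"] - 1e-12).any():
            raise ValidationError("BH-adjusted p below raw p")

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def moderated_diff(
    scores: pd.DataFrame,
    groups: pd.Series,
    prior_df: float | None = None,
) -> ModeratedDiffResult:
    """Empirical-Bayes moderated two-group comparison of feature rows.

    Parameters
    ----------
    scores
        Features x observations table (e.g. pathway scores per cell).
    groups
        Two-level factor over the observations.  The log2FC reported is
        ``mean(second level) - mean(first level)`` with levels in sorted
        order, i.e. positive when the later-sorting group (e.g. DKD vs Ctrl)
        is higher.
    prior_df
        Override for the prior degrees of freedom d0; estimated from the
        data when None.  ``prior_df=0`` reproduces the ordinary pooled
        two-sample t-test exactly.
    """
    groups = groups.loc[scores.columns]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    mask_a = (groups == levels[0]).to_numpy()
    mask_b = (groups == levels[1]).to_numpy()
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if min(n_a, n_b) < 2:
        raise ValidationError("each group needs >=2 observations")

    x = scores.to_numpy(dtype=float)
    a, b = x[:, mask_a], x[:, mask_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    df = n_a + n_b - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df
    log2fc = mean_b - mean_a

    ok = s2 > 0
    if prior_df is None:
        if ok.sum() >= 2:
            z = np.log(s2[ok])
            e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
            evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
            if evar > 0:
                d0 = 2.0 * trigamma_inverse(evar)
                s0_sq = float(
                    np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
                )
            else:
                d0, s0_sq = np.inf, float(np.exp(e.mean()))
        else:
            d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[ok])) if ok.any() else 0.0
        if d0 == 0:
            s0_sq = 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        t_df = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        t_df = d0 + df
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(t_df):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df=t_df)
    # constant-in-both-groups features: no evidence, no fold change
    flat = ~ok & (np.abs(log2fc) < 1e-12)
    p = np.where(flat, 1.0, p)
    tstat = np.where(flat, 0.0, tstat)
    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            f"mean_{levels[0]}": mean_a,
            f"mean_{levels[1]}": mean_b,
            "t": tstat,
            "p": p,
            "p_adj": p_adj,
            "s2_post": s2_post,
        },
        index=scores.index,
    )
    table["significant"] = (table["p_adj"] < SIG_ADJ_P) & (
        table["log2fc"].abs() > SIG_LOG2FC
    )
    return ModeratedDiffResult(table=table, prior_df=float(d0), prior_var=s0_sq)


def _snn_graph(pcs: np.ndarray, k: int, prune: float) -> ig.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = pcs.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neigh = [set(row) for row in idx]  # includes self, as in the standard SNN
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            shared = len(neigh[i] & neigh[int(j)])
            union = len(neigh[i] | neigh[int(j)])
            jac = shared / union
            if jac >= prune:
                edges.append((i, int(j)))
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def recluster_on_scores(
    scores: pd.DataFrame,
    dims: int,
    resolution: float,
    k: int = 20,
    prune: float = 1.0 / 15.0,
    seed: int = 42,
) -> pd.Series:
    """Cluster cells on (significant-)pathway scores.

    Features are standardized, reduced by PCA to ``dims`` components, an
    SNN graph (k nearest neighbours, Jaccard weights, pruned below
    ``prune``) is built, and modularity communities are found at the given
    resolution with a fixed seed.  Cluster ids are 0..K-1 by decreasing
    size.
    """
    n_feat, n_cells = scores.shape
    if n_feat < 2:
        raise ValidationError("need >=2 features to cluster on")
    if dims > n_feat:
        raise ValidationError(f"dims={dims} exceeds feature count {n_feat}")
    x = scores.to_numpy(dtype=float).T  # cells x features
    sd = x.std(axis=0)
    if (sd == 0).all():
        # no variation at all: a single community by definition
        return pd.Series(0, index=scores.columns, name="cluster")
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    dims_eff = min(dims, n_cells - 1)
    pcs = PCA(n_components=dims_eff, svd_solver="full").fit_transform(x)
    g = _snn_graph(pcs, k=k, prune=prune)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    # relabel by decreasing cluster size, ties by original id
    sizes = pd.Series(membership).value_counts()
    mapping = {
        old: new
        for new, old in enumerate(
            sorted(sizes.index, key=lambda c: (-sizes[c], c))
        )
    }
    labels = np.array([mapping[m] for m in membership])
    return pd.Series(labels, index=scores.columns, name="cluster")


@dataclass
class SubclusterAssignment:
    labels: pd.Series  # per-cell "HDC"/"DDC" (or "unclassified")
    clusters: pd.Series  # per-cell score-space cluster id
    cluster_stats: pd.DataFrame  # per cluster: group means of fractions, t, p, call
    fractions: pd.DataFrame  # samples x clusters fraction table
    classified: bool
    params: dict


def classify_dominance(
    clusters: pd.Series,
    cell_meta: pd.DataFrame,
    groups: tuple[str, str] = ("Ctrl", "DKD"),
    alpha: float = 0.05,
    params: dict | None = None,
) -> SubclusterAssignment:
    """Label score-space clusters as disease-dominant (DDC) or not (HDC).

    For each cluster, the per-sample fraction of that sample's cells falling
    in the cluster is computed and the two groups' fractions are compared by
    an unpaired two-sided t-test.  Clusters with a significantly higher mean
    fraction in the disease group are pooled as DDC; the rest are HDC.  If
    no cluster reaches significance the cell population is left
    unclassified.  The labelling is invariant to cluster relabelling.
    """
    meta = cell_meta.loc[clusters.index]
    ctrl_g, dis_g = groups
    for g in groups:
        if not (meta["group"] == g).any():
            raise ValidationError(f"group {g!r} absent")
    for g in groups:
        n_samp = meta.loc[meta["group"] == g, "sample_id"].nunique()
        if n_samp < 2:
            raise ValidationError(f"group {g!r} has <2 samples")

    tab = pd.crosstab(meta["sample_id"], clusters)
    fractions = tab.div(tab.sum(axis=1), axis=0)
    sample_group = meta.groupby("sample_id")["group"].first()
    ctrl_rows = fractions.index[sample_group.loc[fractions.index] == ctrl_g]
    dis_rows = fractions.index[sample_group.loc[fractions.index] == dis_g]

    rows = []
    ddc_clusters = []
    for c in fractions.columns:
        a = fractions.loc[ctrl_rows, c]
        b = fractions.loc[dis_rows, c]
        t, p = stats.ttest_ind(b, a, equal_var=True)
        if np.isnan(p):  # zero variance in both groups
            t, p = 0.0, 1.0
        is_ddc = (b.mean() > a.mean()) and (p < alpha)
        if is_ddc:
            ddc_clusters.append(c)
        rows.append(
            {
                "cluster": c,
                f"mean_frac_{ctrl_g}": float(a.mean()),
                f"mean_frac_{dis_g}": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "call": "DDC" if is_ddc else "HDC",
            }
        )
    stats_tab = pd.DataFrame(rows).set_index("cluster")
    classified = len(ddc_clusters) > 0
    if classified:
        labels = clusters.map(
            lambda c: "DDC" if c in ddc_clusters else "HDC"
        ).rename("label")
    else:
        labels = pd.Series("unclassified", index=clusters.index, name="label")
    return SubclusterAssignment(
        labels=labels,
        clusters=clusters,
        cluster_stats=stats_tab,
        fractions=fractions,
        classified=classified,
        params=params or {},
    )
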