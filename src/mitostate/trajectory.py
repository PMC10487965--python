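"""Semi-supervised pseudotime over ESDEG space.

The trajectory backbone is a principal tree built as the minimum spanning
tree over k-means centroids of a 2-component PCA embedding of the
(standardized) ESDEG expression.  Cells are projected onto their nearest
tree edge and pseudotime is the geodesic distance from the root along the
tree.  Semi-supervision enters through the root rule: by default the root
is the leaf whose projected cells have the highest health-dominant (HDC)
fraction, encoding health as the origin of the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from scipy.spatial.distance import cdist

from .core_io import ValidationError

__all__ = ["PseudotimeResult", "fit_pseudotime", "compare_time_distributions"]


@dataclass
class PseudotimeResult:
    pseudotime: pd.Series  # per-cell geodesic distance from the root, >= 0
    branch: pd.Series  # id of the tree edge each cell projects onto
    tree: nx.Graph  # nodes = centroid ids, edge attr "length"
    root: int
    embedding: pd.DataFrame  # cells x 2 PCA coordinates

    def __post_init__(self) -> None:
        pt = self.pseudotime.to_numpy()
        if not np.isfinite(pt).all() or (pt < -1e-9).any():
            raise ValidationError("pseudotime must be finite and >= 0")
        if self.tree.number_of_nodes() > 1 and not nx.is_tree(self.tree):
            raise ValidationError("backbone must be an acyclic connected tree")


def _project_to_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Orthogonal projection of points onto segment a-b.

    Returns (t, dist): the clamped position along the segment in [0, 1] and
    the Euclidean distance of each point to its projection.
    """
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        t = np.zeros(len(points))
    else:
        t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    dist = np.linalg.norm(points - proj, axis=1)
    return t, dist


def fit_pseudotime(
    expr: pd.DataFrame,
    labels: pd.Series | None = None,
    n_centroids: int = 5,
    root_rule: str = "hdc_max",
    seed: int = 0,
) -> PseudotimeResult:
    """Order cells along a principal tree fit to ESDEG expression.

    Parameters
    ----------
    expr
        Genes x cells normalized expression restricted to the ESDEGs.
    labels
        Per-cell "HDC"/"DDC" labels; required for ``root_rule="hdc_max"``.
    n_centroids
        Number of k-means centroids forming the tree nodes.
    root_rule
        "hdc_max" roots the tree at the leaf whose cells are most
        health-dominant; "pc1_min" roots at the leaf with the smallest
        first-PC coordinate (unsupervised fallback).
    """
    n_genes, n_cells = expr.shape
    if n_genes < 5:
        raise ValidationError("need >=5 genes (ESDEGs)")
    if n_cells < n_centroids * 3:
        raise ValidationError(f"need >= {n_centroids * 3} cells")
    if root_rule == "hdc_max" and labels is None:
        raise ValidationError("root_rule 'hdc_max' requires HDC/DDC labels")

    x = expr.to_numpy(dtype=float).T  # cells x genes
    sd = x.std(axis=0)
    if (sd == 0).all():
        # all cells identical: degenerate single-node tree, pseudotime 0
        zeros = pd.Series(0.0, index=expr.columns, name="pseudotime")
        tree = nx.Graph()
        tree.add_node(0)
        return PseudotimeResult(
            pseudotime=zeros,
            branch=pd.Series(0, index=expr.columns, name="branch"),
            tree=tree,
            root=0,
            embedding=pd.DataFrame(
                np.zeros((n_cells, 2)), index=expr.columns, columns=["PC1", "PC2"]
            ),
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    x = (x - x.mean(axis=0)) / sd_safe
    emb = PCA(n_components=2, svd_solver="full").fit_transform(x)

    km = KMeans(n_clusters=n_centroids, random_state=seed, n_init=10).fit(emb)
    centroids = km.cluster_centers_
    dist = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dist).toarray()
    tree = nx.Graph()
    tree.add_nodes_from(range(n_centroids))
    for i, j in zip(*np.nonzero(mst)):
        tree.add_edge(int(i), int(j), length=float(dist[i, j]))

    # project every cell onto its nearest tree edge
    edges = list(tree.edges())
    best_dist = np.full(n_cells, np.inf)
    best_edge = np.zeros(n_cells, dtype=int)
    best_t = np.zeros(n_cells)
    for e_id, (u, v) in enumerate(edges):
        t, d = _project_to_segment(emb, centroids[u], centroids[v])
        better = d < best_dist
        best_dist[better] = d[better]
        best_edge[better] = e_id
        best_t[better] = t[better]

    # choose the root among leaves
    leaves = [nd for nd in tree.nodes if tree.degree(nd) <= 1]
    nearest_centroid = km.labels_
    if root_rule == "hdc_max":
        lab = labels.loc[expr.columns].to_numpy(dtype=object)
        best_frac, root = -1.0, leaves[0]
        for leaf in leaves:
            cells_here = nearest_centroid == leaf
            if cells_here.sum() == 0:
                continue
            frac = float((lab[cells_here] == "HDC").mean())
            if frac > best_frac:
                best_frac, root = frac, leaf
    elif root_rule == "pc1_min":
        root = min(leaves, key=lambda nd: centroids[nd, 0])
    else:
        raise ValidationError(f"unknown root_rule {root_rule!r}")

    node_dist = nx.single_source_dijkstra_path_length(tree, root, weight="length")
    pt = np.empty(n_cells)
    for e_id, (u, v) in enumerate(edges):
        on_edge = best_edge == e_id
        if not on_edge.any():
            continue
        length = tree[u][v]["length"]
        t = best_t[on_edge]
        via_u = node_dist[u] + t * length
        via_v = node_dist[v] + (1.0 - t) * length
        pt[on_edge] = np.minimum(via_u, via_v)
    pt = pt - pt.min()  # the root-projected extreme sits at 0

    return PseudotimeResult(
        pseudotime=pd.Series(pt, index=expr.columns, name="pseudotime"),
        branch=pd.Series(best_edge, index=expr.columns, name="branch"),
        tree=tree,
        root=int(root),
        embedding=pd.DataFrame(emb, index=expr.columns, columns=["PC1", "PC2"]),
    )


def compare_time_distributions(
    pseudotime: pd.Series, labels: pd.Series, n_grid: int = 100
) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Two-sided unpaired t-test of pseudotime between the two state labels.

    Also returns a kernel-density summary per label on a shared grid, for
    ridge-style reporting of the two distributions.
    """
    labels = labels.loc[pseudotime.index]
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValidationError("need both labels present")
    groups = {u: pseudotime[labels == u].to_numpy() for u in uniq}
    for u, vals in groups.items():
        if len(vals) < 3:
            raise ValidationError(f"label {u!r} has <3 cells")
    a, b = groups[uniq[0]], groups[uniq[1]]
    t, p = stats.ttest_ind(a, b, equal_var=True)
    lo = float(pseudotime.min())
    hi = float(pseudotime.max())
    grid = np.linspace(lo, hi if hi > lo else lo + 1.0, n_grid)
    densities = {}
    for u, vals in groups.items():
        if np.std(vals) > 0:
            dens = stats.gaussian_kde(vals)(grid)
        else:
            dens = np.zeros_like(grid)
        densities[u] = pd.DataFrame({"pseudotime": grid, "density": dens})
    return float(t), float(p), densities
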