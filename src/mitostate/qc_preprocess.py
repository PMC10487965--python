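"""Normalization, mitochondrial content, doublet scoring and marker finding.

Doublet detection follows the artificial-nearest-neighbour (pANN) scheme:
simulated doublets are mixed into the data, the merged set is embedded by
PCA, and each real cell is scored by the fraction of artificial cells among
its nearest neighbours.  Cells in the top ``expected_rate`` quantile of the
score are called doublets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .core_io import CountMatrix, GeneCatalog, ValidationError

__all__ = [
    "normalize_log",
    "compute_pmem",
    "pmem_group_test",
    "DoubletResult",
    "detect_doublets",
    "find_markers",
]


def normalize_log(cm: CountMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalize and log-transform: ``ln(1 + count/total * scale)``.

    Returns a dense genes x cells DataFrame.  Cells with zero total counts
    are rejected (they cannot be normalized).
    """
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = list(cm.cell_ids[totals == 0][:5])
        raise ValidationError(f"cells with zero total counts: {bad}")
    dense = np.asarray(cm.counts.todense(), dtype=float)
    normed = np.log1p(dense / totals[None, :] * scale)
    return pd.DataFrame(normed, index=list(cm.gene_ids), columns=list(cm.cell_ids))


def compute_pmem(cm: CountMatrix, catalog: GeneCatalog) -> pd.Series:
    """Percentage of mitochondrially encoded mRNA (PMEM) per cell.

    ``100 * (counts on the 13 mito-mRNA genes) / (total cell counts)``.
    """
    idx = cm.gene_index(catalog.mito_mrna)
    if idx.size == 0:
        raise ValidationError("no mito-mRNA gene of the catalog is in the matrix")
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = list(cm.cell_ids[totals == 0][:5])
        raise ValidationError(f"cells with zero total counts: {bad}")
    mito = np.asarray(cm.counts[idx, :].sum(axis=0)).ravel()
    return pd.Series(100.0 * mito / totals, index=list(cm.cell_ids), name="pmem")


def pmem_group_test(pmem: pd.Series, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type group comparison of PMEM by the rank-sum test.

    Returns one row per cell type with group medians and the two-sided
    Mann-Whitney p between the two groups present.
    """
    meta = cell_meta.loc[pmem.index]
    rows = []
    for ct, sub in meta.groupby("cell_type", sort=True):
        groups = sorted(sub["group"].unique())
        if len(groups) != 2:
            continue
        a = pmem[sub.index[sub["group"] == groups[0]]]
        b = pmem[sub.index[sub["group"] == groups[1]]]
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                f"median_{groups[0]}": float(a.median()),
                f"median_{groups[1]}": float(b.median()),
                "statistic": float(stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DoubletResult:
    pann: pd.Series  # per-cell score in [0, 1]
    call: pd.Series  # "singlet" / "doublet"
    params: dict

    def __post_init__(self) -> None:
        if ((self.pann < 0) | (self.pann > 1)).any():
            raise ValidationError("pANN outside [0, 1]")


def _variable_genes(normed: np.ndarray, n_top: int) -> np.ndarray:
    """Indices of the top genes by standardized dispersion (var/mean on counts' log scale)."""
    mean = normed.mean(axis=1)
    var = normed.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")
    return np.sort(order[: min(n_top, len(order))])


def detect_doublets(
    cm: CountMatrix,
    pN: float = 0.25,
    pK: float = 0.1,
    dims: int = 10,
    expected_rate: float = 0.075,
    scale: float = 1e4,
    n_variable_genes: int = 2000,
    seed: int = 0,
) -> DoubletResult:
    """Score each cell by its proportion of artificial nearest neighbours.

    ``pN * n`` artificial doublets (averages of random normalized cell-pair
    profiles) are appended, PCA to ``dims`` components is fit on the merged
    set, and each real cell's pANN is the artificial fraction among its
    ``k = max(1, round(pK * merged_n))`` nearest neighbours (Euclidean in PC
    space, self excluded).  The top ``expected_rate`` quantile is called
    doublet.
    """
    n = cm.n_cells
    if n < 20:
        raise ValidationError("need at least 20 cells")
    if dims > min(cm.n_genes, n) - 1:
        raise ValidationError(f"dims={dims} exceeds feasible rank")
    rng = np.random.default_rng(seed)
    # artificial doublets are averages of linear normalized profiles: a real
    # droplet pooling two cells' transcripts sits at (approximately) the
    # library-size-weighted average of their concentration vectors
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = list(cm.cell_ids[totals == 0][:5])
        raise ValidationError(f"cells with zero total counts: {bad}")
    linear = np.asarray(cm.counts.todense(), dtype=float) / totals[None, :] * scale
    n_art = max(1, int(round(pN * n)))
    pairs_a = rng.integers(0, n, size=n_art)
    pairs_b = (pairs_a + 1 + rng.integers(0, n - 1, size=n_art)) % n
    art = 0.5 * (linear[:, pairs_a] + linear[:, pairs_b])
    merged = np.log1p(np.column_stack([linear, art]))
    keep = _variable_genes(merged, n_variable_genes)
    merged = merged[keep, :].T  # observations x genes
    merged = merged - merged.mean(axis=0, keepdims=True)
    pcs = PCA(n_components=dims, svd_solver="full").fit_transform(merged)
    merged_n = n + n_art
    k = max(1, int(round(pK * merged_n)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    neighbor = idx[:, 1:]  # drop self
    pann = (neighbor >= n).mean(axis=1)
    cutoff = np.quantile(pann, 1.0 - expected_rate)
    call = np.where(pann > cutoff, "doublet", "singlet")
    # quantile ties can under-call; force exactly the expected count from the top
    n_expected = int(round(expected_rate * n))
    if n_expected > 0:
        top = np.argsort(-pann, kind="stable")[:n_expected]
        call = np.full(n, "singlet", dtype=object)
        call[top] = "doublet"
    cells = list(cm.cell_ids)
    return DoubletResult(
        pann=pd.Series(pann, index=cells, name="pann"),
        call=pd.Series(call, index=cells, name="call"),
        params={
            "pN": pN,
            "pK": pK,
            "dims": dims,
            "expected_rate": expected_rate,
            "k": k,
        },
    )


def find_markers(
    normed: pd.DataFrame,
    labels: pd.Series,
    top_k: int = 10,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker table per label.

    For each label, every gene is tested with the two-sided Mann-Whitney test
    against all remaining cells, and the log2 fold change of de-logged mean
    expression (pseudocount 1) is reported.  Rows are sorted by ascending p
    within label and the ``top_k`` best are retained.
    """
    labels = labels.loc[normed.columns]
    uniq = [l for l in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValidationError("need at least 2 labels")
    expr = normed.to_numpy()
    delog = np.expm1(expr)
    out = []
    for label in uniq:
        mask = (labels == label).to_numpy()
        if mask.sum() < min_cells:
            import warnings

            warnings.warn(f"label {label!r} has <{min_cells} cells; skipped")
            continue
        a, b = expr[:, mask], expr[:, ~mask]
        res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=1)
        m_in = delog[:, mask].mean(axis=1)
        m_out = delog[:, ~mask].mean(axis=1)
        log2fc = np.log2(m_in + 1.0) - np.log2(m_out + 1.0)
        table = pd.DataFrame(
            {
                "label": label,
                "gene": normed.index,
                "log2fc": log2fc,
                "p": res.pvalue,
            }
        )
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "gene"], kind="stable").head(top_k)
        table["rank"] = np.arange(1, len(table) + 1)
        out.append(table)
    if not out:
        raise ValidationError("no label had enough cells")
    return pd.concat(out, ignore_index=True)
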