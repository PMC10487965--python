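"""Differential expression (DA1/DA2), ESDEG partitioning, fold-change
correlation, and hypergeometric over-representation analysis.

Two differential comparisons define the gene classes of interest:

* DA1 — health-dominant cells of the control group vs disease-dominant
  cells of the disease group;
* DA2 — health-dominant vs disease-dominant cells within the disease group.

After removing mitochondria-associated nuclear genes (MANGs), genes
significant in DA2 but not DA1 are the *exclusive* significant DE genes
(ESDEGs) — the disease-state signature not explained by the group contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneCatalog, GeneSetCollection, ValidationError

__all__ = [
    "DifferentialResult",
    "EsdegPartition",
    "wilcoxon_de",
    "build_esdeg",
    "correlate_fc",
    "hypergeom_enrich",
]

SIG_P = 0.05
SIG_LOG2FC = 0.5


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per gene: log2fc, p, p_adj, significant

    def __post_init__(self) -> None:
        t = self.table
        expected = (t["p"] < SIG_P) & (t["log2fc"].abs() > SIG_LOG2FC)
        if not (t["significant"] == expected).all():
            raise ValidationError("significance flag inconsistent with fields")

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def wilcoxon_de(
    normed: pd.DataFrame, cells_a, cells_b
) -> DifferentialResult:
    """Per-gene two-sided Mann-Whitney comparison of cell group A vs B.

    Exact p-values are computed for small groups (both n <= 8); the
    tie-corrected normal approximation is used otherwise.  log2FC is the
    ratio of de-logged group means with pseudocount 1 (A relative to B).
    Significance follows the dual rule raw p < 0.05 and |log2FC| > 0.5.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValidationError("both groups need >=3 cells")
    a = normed[cells_a].to_numpy(dtype=float)
    b = normed[cells_b].to_numpy(dtype=float)
    method = "exact" if max(len(cells_a), len(cells_b)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=1, method=method)
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    m_a = np.expm1(a).mean(axis=1)
    m_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2(m_a + 1.0) - np.log2(m_b + 1.0)
    # identical constant rows: no information
    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (np.abs(log2fc) < 1e-12)
    p = np.where(flat, 1.0, p)
    table = pd.DataFrame({"log2fc": log2fc, "p": p}, index=normed.index)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = (table["p"] < SIG_P) & (table["log2fc"].abs() > SIG_LOG2FC)
    return DifferentialResult(table=table)


@dataclass
class EsdegPartition:
    intersection: set[str]  # significant in DA1 and DA2
    da1_exclusive: set[str]
    da2_exclusive: set[str]  # the ESDEGs
    mangs_excluded: set[str]
    discarded: bool  # too few exclusive genes to trust the cell type
    min_exclusive: int

    def __post_init__(self) -> None:
        if self.intersection & self.da1_exclusive:
            raise ValidationError("partition sets overlap")
        if self.intersection & self.da2_exclusive:
            raise ValidationError("partition sets overlap")
        if self.da1_exclusive & self.da2_exclusive:
            raise ValidationError("partition sets overlap")
        all_sets = self.intersection | self.da1_exclusive | self.da2_exclusive
        if all_sets & self.mangs_excluded:
            raise ValidationError("a MANG survived the exclusion")

    @property
    def esdegs(self) -> set[str]:
        return self.da2_exclusive


def build_esdeg(
    da1: DifferentialResult,
    da2: DifferentialResult,
    catalog: GeneCatalog,
    min_exclusive: int = 100,
) -> EsdegPartition:
    """Partition significant genes of the two comparisons, MANGs removed first.

    Cell types whose exclusive gene counts (in either comparison) fall below
    ``min_exclusive`` are flagged as discarded rather than erroring, so the
    caller can drop them.
    """
    if not da1.table.index.equals(da2.table.index):
        raise ValidationError("DA1 and DA2 cover different gene universes")
    mangs = set(catalog.mangs)
    sig1 = da1.significant_genes - mangs
    sig2 = da2.significant_genes - mangs
    inter = sig1 & sig2
    excl1 = sig1 - sig2
    excl2 = sig2 - sig1
    discarded = len(excl1) < min_exclusive or len(excl2) < min_exclusive
    return EsdegPartition(
        intersection=inter,
        da1_exclusive=excl1,
        da2_exclusive=excl2,
        mangs_excluded=mangs & (da1.significant_genes | da2.significant_genes),
        discarded=discarded,
        min_exclusive=min_exclusive,
    )


def correlate_fc(
    genes, fc1: pd.Series, fc2: pd.Series
) -> tuple[float, float, float, float]:
    """Pearson correlation and least-squares line between two fold-change vectors.

    Returns ``(r, slope, intercept, p)``; the line is fit by QR-based least
    squares of fc2 on fc1.  Zero variance in either vector is flagged by
    raising a validation error (r undefined).
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValidationError("need >=3 genes")
    x = fc1.loc[genes].to_numpy(dtype=float)
    y = fc2.loc[genes].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = scipy.linalg.lstsq(design, y, lapack_driver="gelsy")  # QR-based
    intercept, slope = float(coef[0]), float(coef[1])
    return float(r), slope, intercept, float(p)


def hypergeom_enrich(
    query,
    universe,
    collection: GeneSetCollection,
    top_n: int = 20,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Sets are intersected with the universe first.  The table is BH-adjusted,
    sorted by ascending p (ties by set name) and truncated to ``top_n``.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    query &= universe
    if not query:
        warnings.warn("empty query after intersecting with the universe")
        return pd.DataFrame(
            columns=["set", "k", "n", "K", "N", "p", "p_adj", "genes"]
        ).set_index("set")
    n = len(query)
    N = len(universe)
    rows = []
    for name, genes in collection:
        members = set(genes) & universe
        if not members:
            continue
        K = len(members)
        overlap = sorted(query & members)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set": name, "k": k, "n": n, "K": K, "N": N, "p": p, "genes": ",".join(overlap)}
        )
    if not rows:
        warnings.warn("no gene set overlaps the universe")
        return pd.DataFrame(
            columns=["set", "k", "n", "K", "N", "p", "p_adj", "genes"]
        ).set_index("set")
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table.sort_values(["p", "set"], kind="stable").head(top_n)
    return table.set_index("set")
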