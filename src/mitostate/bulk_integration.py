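"""Bulk RNA-seq integration: TPM, signature-based deconvolution, and
reference-based HDC/DDC label transfer.

Deconvolution regresses each bulk TPM profile on a signature matrix built
from the top markers of each single-cell subcluster.  The default solver is
non-negative least squares with post-hoc simplex renormalization, which is
deterministic and exact on noiseless mixtures; the result records when a
rank-deficient signature forced a pseudo-inverse fallback.

Label transfer scores each query cell by its Spearman correlation to every
reference cell over discriminative genes and assigns the label whose cells
reach the higher 0.8-quantile correlation, flagging calls with a score gap
below 0.05 as low-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import ValidationError
from .qc_preprocess import find_markers

__all__ = [
    "SignatureMatrix",
    "DeconvolutionResult",
    "compute_tpm",
    "build_signature",
    "deconvolve",
    "transfer_labels",
]


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw counts and per-gene lengths (bp)."""
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0][:5])
        raise ValidationError(f"non-positive gene lengths: {bad}")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


@dataclass
class SignatureMatrix:
    table: pd.DataFrame  # genes x subclusters mean expression
    markers: dict[str, list[str]]  # subcluster -> its top markers

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            raise ValidationError("duplicate subcluster names")
        for sub in self.table.columns:
            if len(self.markers.get(sub, [])) == 0:
                raise ValidationError(f"subcluster {sub!r} contributed no marker")


def build_signature(
    normed: pd.DataFrame, subcluster_labels: pd.Series, top_k: int = 10
) -> SignatureMatrix:
    """Signature from the union of top-``top_k`` markers per subcluster.

    Columns are per-subcluster means of de-logged normalized expression over
    the marker-gene union.
    """
    marker_tab = find_markers(normed, subcluster_labels, top_k=top_k)
    markers = {
        lab: list(sub["gene"]) for lab, sub in marker_tab.groupby("label", sort=True)
    }
    union = sorted({g for genes in markers.values() for g in genes})
    delog = np.expm1(normed.loc[union])
    labels = subcluster_labels.loc[normed.columns]
    cols = {
        lab: delog.loc[:, (labels == lab).to_numpy()].mean(axis=1)
        for lab in sorted(pd.unique(labels))
    }
    return SignatureMatrix(table=pd.DataFrame(cols), markers=markers)


@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame  # samples x subclusters, each row on the simplex
    residuals: pd.Series  # per-sample residual norm
    pinv_fallback: bool = False

    def __post_init__(self) -> None:
        props = self.proportions.to_numpy()
        if (props < -1e-9).any():
            raise ValidationError("negative proportions")
        if not np.allclose(props.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError("proportions must sum to 1")
        if (self.residuals < -1e-12).any():
            raise ValidationError("negative residual norm")


def deconvolve(
    bulk: pd.DataFrame, signature: SignatureMatrix, method: str = "nnls"
) -> DeconvolutionResult:
    """Estimate subcluster proportions of each bulk sample.

    Both the bulk profile and the signature are solved on their shared
    genes.  The estimates are scale-invariant: multiplying a bulk profile
    by a positive constant leaves the renormalized proportions unchanged.
    """
    if method != "nnls":
        raise ValidationError(f"unknown method {method!r}")
    sig = signature.table
    shared = bulk.index.intersection(sig.index)
    k = sig.shape[1]
    if len(shared) < k:
        raise ValidationError(
            f"only {len(shared)} shared genes for {k} subclusters"
        )
    a = sig.loc[shared].to_numpy(dtype=float)
    fallback = np.linalg.matrix_rank(a) < k
    if fallback:
        warnings.warn("rank-deficient signature; pseudo-inverse fallback")
    rows, resids = {}, {}
    for sample in bulk.columns:
        y = bulk.loc[shared, sample].to_numpy(dtype=float)
        if fallback:
            coef = np.clip(np.linalg.pinv(a) @ y, 0.0, None)
            resid = float(np.linalg.norm(a @ coef - y))
        else:
            coef, resid = optimize.nnls(a, y)
        total = coef.sum()
        rows[sample] = coef / total if total > 0 else np.full(k, 1.0 / k)
        resids[sample] = float(resid)
    proportions = pd.DataFrame(rows, index=sig.columns).T
    return DeconvolutionResult(
        proportions=proportions,
        residuals=pd.Series(resids, name="residual"),
        pinv_fallback=fallback,
    )


def transfer_labels(
    ref_normed: pd.DataFrame,
    ref_labels: pd.Series,
    query_normed: pd.DataFrame,
    n_top_genes: int = 50,
    quantile: float = 0.8,
    min_gap: float = 0.05,
) -> pd.DataFrame:
    """Transfer HDC/DDC labels from a reference to query cells.

    Discriminative genes are the union of top pairwise markers between the
    reference labels; each query cell is Spearman-correlated with every
    reference cell over those genes, each label is scored by the
    ``quantile`` of correlations to its cells, and the argmax label is
    assigned.  A score gap below ``min_gap`` flags the call low-confidence.
    """
    ref_labels = ref_labels.loc[ref_normed.columns]
    counts = ref_labels.value_counts()
    if (counts < 3).any():
        small = list(counts.index[counts < 3])
        raise ValidationError(f"reference labels with <3 cells: {small}")
    per_label = max(1, n_top_genes // ref_labels.nunique())
    marker_tab = find_markers(ref_normed, ref_labels, top_k=per_label)
    genes = sorted(set(marker_tab["gene"]))
    shared = [g for g in genes if g in query_normed.index]
    if len(shared) < max(2, n_top_genes // 2):
        raise ValidationError(
            f"only {len(shared)} marker genes shared with the query"
        )

    ref = ref_normed.loc[shared].to_numpy(dtype=float)
    qry = query_normed.loc[shared].to_numpy(dtype=float)
    # Spearman = Pearson on ranks
    ref_r = stats.rankdata(ref, axis=0)
    qry_r = stats.rankdata(qry, axis=0)

    def _standardize(m: np.ndarray) -> np.ndarray:
        m = m - m.mean(axis=0, keepdims=True)
        sd = m.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return m / sd

    corr = _standardize(qry_r).T @ _standardize(ref_r) / len(shared)

    labels = sorted(pd.unique(ref_labels))
    scores = {}
    for lab in labels:
        cols = (ref_labels == lab).to_numpy()
        scores[lab] = np.quantile(corr[:, cols], quantile, axis=1)
    score_tab = pd.DataFrame(scores, index=query_normed.columns)
    assigned = score_tab.idxmax(axis=1)
    ordered = np.sort(score_tab.to_numpy(), axis=1)
    gap = ordered[:, -1] - ordered[:, -2] if score_tab.shape[1] > 1 else ordered[:, -1]
    out = score_tab.add_prefix("score_")
    out["label"] = assigned
    out["low_confidence"] = gap < min_gap
    return out
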