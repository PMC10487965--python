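"""Cluster-to-cluster ligand-receptor communication with a permutation null.

The communication probability between a source and a target cluster for a
ligand-receptor pair is the Hill-type saturation ``l*r / (Kh + l*r)`` of
the product of 25%-trimmed mean ligand expression in the source and
receptor expression in the target (multi-subunit complexes enter as
geometric means).  Significance is assessed by permuting cluster labels and
recomputing the probability; pairs with permutation p < 0.05 are retained.

Pathways whose significant rows carry an ESDEG as the receptor of an
incoming edge or the ligand of an outgoing edge are the "different cell
communication pathways" (DCCPs) linking communication to the disease-state
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import warnings
from scipy import stats

from .core_io import LRDatabase, ValidationError

__all__ = [
    "CommunicationResult",
    "cluster_expression",
    "communication_prob",
    "permutation_test",
    "select_dccp",
]


@dataclass
class CommunicationResult:
    table: pd.DataFrame  # source, target, pathway, ligand, receptor, prob[, p, retained]
    outgoing: pd.Series | None = None  # per-cluster summed retained probability
    incoming: pd.Series | None = None

    def __post_init__(self) -> None:
        probs = self.table["prob"].to_numpy() if len(self.table) else np.empty(0)
        if ((probs < 0) | (probs >= 1)).any():
            raise ValidationError("probabilities must lie in [0, 1)")
        if "p" in self.table.columns:
            p = self.table["p"].to_numpy()
            if ((p <= 0) | (p > 1)).any():
                raise ValidationError("permutation p must lie in (0, 1]")

    @property
    def retained(self) -> pd.DataFrame:
        if "retained" not in self.table.columns:
            return self.table
        return self.table[self.table["retained"]]


def cluster_expression(
    normed: pd.DataFrame, labels: pd.Series, trim: float = 0.25
) -> pd.DataFrame:
    """Clusters x genes table of trimmed-mean expression."""
    if trim >= 0.5:
        raise ValidationError("trim must be < 0.5")
    labels = labels.loc[normed.columns]
    out = {}
    for cl in sorted(pd.unique(labels)):
        sub = normed.loc[:, (labels == cl).to_numpy()]
        if sub.shape[1] == 0:
            raise ValidationError(f"cluster {cl!r} has no cells")
        out[cl] = stats.trim_mean(sub.to_numpy(), proportiontocut=trim, axis=1)
    return pd.DataFrame(out, index=normed.index).T


def _pair_levels(cluster_expr: pd.DataFrame, lr_db: LRDatabase):
    """Per LR row: (pathway, ligand name, receptor name, l per cluster, r per cluster)."""
    genes = set(cluster_expr.columns)
    rows = []
    for pathway, ligands, receptors, _cat in lr_db.rows():
        have_l = [g for g in ligands if g in genes]
        have_r = [g for g in receptors if g in genes]
        if len(have_l) < len(ligands) or len(have_r) < len(receptors):
            warnings.warn(f"pathway {pathway!r}: missing ligand/receptor genes; dropped")
            continue
        # multi-subunit complexes: geometric mean of subunit levels
        l_lev = np.exp(np.log(cluster_expr[have_l].to_numpy() + 1e-300).mean(axis=1))
        r_lev = np.exp(np.log(cluster_expr[have_r].to_numpy() + 1e-300).mean(axis=1))
        l_lev = np.where(cluster_expr[have_l].to_numpy().min(axis=1) <= 0, 0.0, l_lev)
        r_lev = np.where(cluster_expr[have_r].to_numpy().min(axis=1) <= 0, 0.0, r_lev)
        rows.append((pathway, "+".join(ligands), "+".join(receptors), l_lev, r_lev))
    return rows


def communication_prob(
    cluster_expr: pd.DataFrame, lr_db: LRDatabase, Kh: float = 0.5
) -> CommunicationResult:
    """Hill-saturated communication probability for every (source, target, pair)."""
    clusters = list(cluster_expr.index)
    records = []
    for pathway, lig, rec, l_lev, r_lev in _pair_levels(cluster_expr, lr_db):
        lr = np.outer(l_lev, r_lev)
        prob = lr / (Kh + lr)
        for i, src in enumerate(clusters):
            for j, tgt in enumerate(clusters):
                records.append(
                    {
                        "source": src,
                        "target": tgt,
                        "pathway": pathway,
                        "ligand": lig,
                        "receptor": rec,
                        "prob": float(prob[i, j]),
                    }
                )
    columns = ["source", "target", "pathway", "ligand", "receptor", "prob"]
    return CommunicationResult(table=pd.DataFrame(records, columns=columns))


def permutation_test(
    normed: pd.DataFrame,
    labels: pd.Series,
    lr_db: LRDatabase,
    n_perm: int = 100,
    Kh: float = 0.5,
    trim: float = 0.25,
    seed: int = 0,
    alpha: float = 0.05,
) -> CommunicationResult:
    """Permutation p-values for the communication probabilities.

    Cluster labels are permuted ``n_perm`` times; for each (source, target,
    pair) the p-value is ``(1 + #{permuted prob >= observed}) / (1 + n_perm)``.
    Rows with p < ``alpha`` are flagged retained, and per-cluster
    incoming/outgoing strengths are summed over retained rows.
    """
    if n_perm < 20:
        raise ValidationError("n_perm must be >= 20")
    labels = labels.loc[normed.columns]
    # drop rows with missing genes once, so the permutation loop is silent
    genes = set(normed.index)
    keep_rows = [
        i
        for i, (_, ligands, receptors, _) in enumerate(lr_db.rows())
        if set(ligands) <= genes and set(receptors) <= genes
    ]
    if len(keep_rows) < len(lr_db):
        warnings.warn(
            f"{len(lr_db) - len(keep_rows)} LR rows dropped (genes missing)"
        )
    lr_db = LRDatabase(table=lr_db.table.iloc[keep_rows].reset_index(drop=True))
    observed = communication_prob(
        cluster_expression(normed, labels, trim=trim), lr_db, Kh=Kh
    ).table
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(observed))
    obs_prob = observed["prob"].to_numpy()
    lab_arr = labels.to_numpy(object)
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(lab_arr), index=labels.index)
        perm_tab = communication_prob(
            cluster_expression(normed, perm, trim=trim), lr_db, Kh=Kh
        ).table
        exceed += perm_tab["prob"].to_numpy() >= obs_prob
    table = observed.copy()
    table["p"] = (1.0 + exceed) / (1.0 + n_perm)
    table["retained"] = table["p"] < alpha
    kept = table[table["retained"]]
    outgoing = kept.groupby("source")["prob"].sum()
    incoming = kept.groupby("target")["prob"].sum()
    return CommunicationResult(table=table, outgoing=outgoing, incoming=incoming)


def _strip_state(cluster: str) -> tuple[str, str | None]:
    """Split 'CD-PC_DDC' into ('CD-PC', 'DDC'); plain labels get state None."""
    for suffix in ("_HDC", "_DDC"):
        if str(cluster).endswith(suffix):
            return str(cluster)[: -len(suffix)], suffix[1:]
    return str(cluster), None


def select_dccp(
    result: CommunicationResult, esdegs: dict[str, set[str]]
) -> pd.DataFrame:
    """Annotate retained communication rows whose genes are ESDEGs.

    A row is an incoming DCCP for its target cluster when any receptor
    subunit is an ESDEG of the target's cell type, and an outgoing DCCP for
    its source cluster when any ligand subunit is an ESDEG of the source's
    cell type.  Clusters must be named ``<cell type>_HDC`` / ``<cell
    type>_DDC``; clusters without a state suffix are passed through
    unflagged.
    """
    kept = result.retained.copy()
    if kept.empty:
        return kept.assign(incoming_dccp=pd.Series(dtype=bool),
                           outgoing_dccp=pd.Series(dtype=bool))
    inc, out = [], []
    for _, row in kept.iterrows():
        src_type, src_state = _strip_state(row["source"])
        tgt_type, tgt_state = _strip_state(row["target"])
        receptors = set(str(row["receptor"]).split("+"))
        ligands = set(str(row["ligand"]).split("+"))
        inc.append(
            tgt_state is not None
            and bool(receptors & esdegs.get(tgt_type, set()))
        )
        out.append(
            src_state is not None
            and bool(ligands & esdegs.get(src_type, set()))
        )
    kept["incoming_dccp"] = inc
    kept["outgoing_dccp"] = out
    return kept
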