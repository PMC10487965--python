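"""Synthetic kidney scRNA-seq data with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: multi-cell-type negative-binomial UMI matrices for two groups
(Ctrl, DKD) of four replicate animals each, two planted pathway-activity
states per cell type (a health-dominant and a disease-dominant program),
a known doublet fraction, a planted ligand -> receptor -> TF -> target
causal chain, and bulk mixtures of known cell-type composition.

Every planted feature is recorded in :class:`GroundTruth` so downstream
recovery tests never have to re-derive it.

Model
-----
Counts are negative binomial: for gene g in cell c,
``count ~ NB(mean = s_c * lam_gc, size = r_g)`` with per-cell size factors
``s_c`` log-normal, per-gene baselines ``lam_g`` log-normal, and gene-wise
inverse dispersions ``r_g`` log-normal.  Each cell carries a latent disease
progression ``t in [0, 1]`` (low in the health-dominant state, high in the
disease-dominant state); genes belonging to the shifted pathway sets have
``log2 lam_gc`` moved by ``±shift * t``, so the two states separate in
pathway-score space and ``t`` is the planted pseudotime.  Doublets are sums
(not means) of two distinct same-sample cells' counts, matching how droplets
pool transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import (
    CountMatrix,
    GeneCatalog,
    GeneSetCollection,
    LRDatabase,
    ValidationError,
)

__all__ = ["CascadeSpec", "SimulationConfig", "GroundTruth", "simulate", "simulate_bulk"]


@dataclass
class CascadeSpec:
    """A planted ligand -> receptor -> TF -> target causal chain.

    The ligand is expressed in ``source_cell_type``; the receptor's baseline
    in ``target_cell_type`` scales with the source's mean ligand level, and
    within target cells a latent activity couples receptor, TF and target
    expression monotonically.
    """

    source_cell_type: str = "EnC"
    target_cell_type: str = "CD-PC"
    ligand: str = "Wnt5a"
    receptor: str = "Fzd7"
    tf: str = "Tf01"
    n_targets: int = 10
    effect: float = 3.0  # log2 swing of the chain genes across the latent axis


@dataclass
class SimulationConfig:
    """Conditions of the emulated study, at desk scale.

    Defaults mirror the study design where it states one (two groups of four
    replicate animals; 13 mitochondrially encoded mRNAs; ~7.5% doublets; a
    70%/30% split of DKD/Ctrl cells into the disease-dominant state); sizes
    that the full dataset fixes at tens of thousands of cells and >1000
    mitochondria-associated nuclear genes are scaled down to a few hundred
    cells and genes so that every recovery test runs in seconds.
    """

    cell_types: tuple[str, ...] = ("CD-PC", "DLH", "EnC")
    cells_per_type_per_sample: int = 30
    samples_per_group: int = 4
    groups: tuple[str, str] = ("Ctrl", "DKD")
    n_genes: int = 400
    n_mito_mrna: int = 13
    n_mangs: int = 240
    n_pathways: int = 40
    genes_per_pathway: int = 8
    frac_pathways_shifted: float = 0.4
    log2_shift: float = 3.0
    ddc_frac_dkd: float = 0.85
    ddc_frac_ctrl: float = 0.15
    doublet_fraction: float = 0.075
    state_concentration: float = 10.0  # Beta concentration of the latent states
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    dispersion_log_mean: float = 0.7  # log of NB size r
    dispersion_log_sd: float = 0.5
    size_factor_log_sd: float = 0.3
    mito_boost: float = 3.0  # multiplier on mito-mRNA baselines (PMEM ~ 5-10%)
    n_markers_per_type: int = 5
    marker_fold: float = 4.0
    cascade: CascadeSpec = field(default_factory=CascadeSpec)
    bulk_proportions: dict[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_pathways_shifted": self.frac_pathways_shifted,
            "ddc_frac_dkd": self.ddc_frac_dkd,
            "ddc_frac_ctrl": self.ddc_frac_ctrl,
            "doublet_fraction": self.doublet_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.n_pathways * self.genes_per_pathway > self.n_mangs * 4:
            raise ValidationError("pathway demand far exceeds the MANG pool")
        if self.n_mangs + self.n_mito_mrna >= self.n_genes:
            raise ValidationError("gene budget too small for MANGs + mito genes")
        if not np.isfinite(self.log2_shift) or not np.isfinite(self.cascade.effect):
            raise ValidationError("effect sizes must be finite")
        if self.cascade.source_cell_type not in self.cell_types:
            raise ValidationError("cascade source cell type not simulated")
        if self.cascade.target_cell_type not in self.cell_types:
            raise ValidationError("cascade target cell type not simulated")


@dataclass
class GroundTruth:
    """Everything that was planted, keyed the same way the outputs are."""

    state: pd.Series  # per-cell "HDC"/"DDC" (doublets: state of first member)
    is_doublet: pd.Series
    pseudotime: pd.Series  # latent disease progression t in [0, 1]
    de_genes: dict[str, str]  # shifted gene -> "up"/"down" (in DDC)
    shifted_pathways: list[str]
    cascade_edges: list[tuple[str, str]]  # (source, target) directed
    cascade: CascadeSpec
    marker_genes: dict[str, list[str]]  # cell type -> planted markers
    type_mean_profiles: pd.DataFrame  # genes x cell types, mean expected expression
    bulk_proportions: pd.DataFrame | None = None

    def state_fraction(self, state: str = "DDC") -> float:
        singlets = self.state[~self.is_doublet]
        return float((singlets == state).mean())


_MITO_MRNA = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]


def _gene_universe(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    """Assemble gene symbols: mito mRNAs, MANGs, cascade genes, TFs, filler."""
    casc = config.cascade
    mito = _MITO_MRNA[: config.n_mito_mrna]
    mangs = [f"Mang{i:04d}" for i in range(config.n_mangs)]
    targets = [f"Tg{i:02d}" for i in range(casc.n_targets)]
    special = [casc.ligand, casc.receptor, casc.tf, *targets]
    n_filler = config.n_genes - len(mito) - len(mangs) - len(special)
    if n_filler < config.n_markers_per_type * len(config.cell_types):
        raise ValidationError("gene budget too small for markers and cascade")
    filler = [f"Gene{i:04d}" for i in range(n_filler)]
    genes = [*mito, *mangs, *special, *filler]
    groups = {"mito": mito, "mangs": mangs, "targets": targets, "filler": filler}
    return genes, groups


def simulate(
    config: SimulationConfig,
) -> tuple[CountMatrix, GeneCatalog, GeneSetCollection, LRDatabase, GroundTruth]:
    """Draw one synthetic dataset under ``config``; byte-identical per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    casc = config.cascade
    genes, parts = _gene_universe(config)
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # --- pathway collection over the MANG pool -----------------------------
    mang_arr = np.array(parts["mangs"], dtype=object)
    sets: dict[str, list[str]] = {}
    for k in range(config.n_pathways):
        members = rng.choice(mang_arr, size=config.genes_per_pathway, replace=False)
        sets[f"MitoPath{k:03d}"] = sorted(members.tolist())
    collection = GeneSetCollection(sets=sets)
    n_shift = int(round(config.frac_pathways_shifted * config.n_pathways))
    shifted_pathways = sorted(
        rng.choice(collection.names, size=n_shift, replace=False).tolist()
    )
    # Direction per shifted pathway: alternate up/down in the DDC state.
    directions = {
        name: (1.0 if i % 2 == 0 else -1.0)
        for i, name in enumerate(shifted_pathways)
    }
    de_genes: dict[str, str] = {}
    gene_shift = np.zeros(n_genes)
    for name in shifted_pathways:
        d = directions[name]
        for g in sets[name]:
            gene_shift[gene_pos[g]] = d * config.log2_shift
            de_genes[g] = "up" if d > 0 else "down"

    # --- baselines ---------------------------------------------------------
    lam = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    lam[[gene_pos[g] for g in parts["mito"]]] *= config.mito_boost
    # a program can only visibly switch off if it is well expressed in
    # health: down-shifted pathway genes start from an elevated baseline
    down_idx = [gene_pos[g] for g, d in de_genes.items() if d == "down"]
    lam[down_idx] *= 2.0 ** (config.log2_shift / 2.0)
    r_size = rng.lognormal(config.dispersion_log_mean, config.dispersion_log_sd, n_genes)

    # Cell-type markers: boosted filler genes, disjoint across types.
    marker_genes: dict[str, list[str]] = {}
    filler = parts["filler"]
    for i, ct in enumerate(config.cell_types):
        picks = filler[
            i * config.n_markers_per_type : (i + 1) * config.n_markers_per_type
        ]
        marker_genes[ct] = list(picks)

    # --- per-cell expected expression --------------------------------------
    samples = [
        (grp, f"{grp}{j + 1}")
        for grp in config.groups
        for j in range(config.samples_per_group)
    ]
    cells, metas, states, latents = [], [], [], []
    for grp, sample in samples:
        ddc_frac = config.ddc_frac_dkd if grp == "DKD" else config.ddc_frac_ctrl
        for ct in config.cell_types:
            for k in range(config.cells_per_type_per_sample):
                is_ddc = rng.random() < ddc_frac
                # latent progression: HDC concentrated low, DDC high
                c = config.state_concentration
                t = rng.beta(0.85 * c, 0.15 * c) if is_ddc else rng.beta(0.15 * c, 0.85 * c)
                cells.append(f"{sample}-{ct.replace(' ', '')}-{k:03d}")
                metas.append((sample, grp, ct))
                states.append("DDC" if is_ddc else "HDC")
                latents.append(t)
    n_cells = len(cells)
    latents = np.asarray(latents)
    state_arr = np.asarray(states, dtype=object)
    ct_arr = np.asarray([m[2] for m in metas], dtype=object)

    log2lam = np.log2(lam)[:, None] + gene_shift[:, None] * latents[None, :]
    # markers
    for ct, marks in marker_genes.items():
        idx = [gene_pos[g] for g in marks]
        log2lam[np.ix_(idx, ct_arr == ct)] += np.log2(config.marker_fold)

    # --- cascade -----------------------------------------------------------
    lig_i, rec_i, tf_i = (gene_pos[casc.ligand], gene_pos[casc.receptor], gene_pos[casc.tf])
    # chain genes need a solid baseline: a mostly-zero gene carries no
    # co-expression signal for the forest or the Spearman edges
    chain_idx = [lig_i, rec_i, tf_i] + [
        gene_pos[f"Tg{i:02d}"] for i in range(casc.n_targets)
    ]
    log2lam[chain_idx, :] = np.maximum(log2lam[chain_idx, :], 2.0)
    # a coupled regulatory module is not wildly overdispersed
    r_size[chain_idx] = np.maximum(r_size[chain_idx], 8.0)
    src_mask = ct_arr == casc.source_cell_type
    tgt_mask = ct_arr == casc.target_cell_type
    # ligand expressed in the source type only (modest baseline elsewhere)
    log2lam[lig_i, :] -= 3.0
    log2lam[lig_i, src_mask] += 3.0 + casc.effect
    # receptor baseline in the target type scales with the source ligand level
    source_ligand_level = float(np.mean(2.0 ** log2lam[lig_i, src_mask]))
    u = rng.random(int(tgt_mask.sum()))  # latent chain activity per target cell
    log2lam[rec_i, tgt_mask] += np.log2(1.0 + source_ligand_level) / 2 + casc.effect * u
    log2lam[tf_i, tgt_mask] += casc.effect * u
    for g in [f"Tg{i:02d}" for i in range(casc.n_targets)]:
        log2lam[gene_pos[g], tgt_mask] += casc.effect * u
    cascade_edges = [(casc.ligand, casc.receptor), (casc.receptor, casc.tf)] + [
        (casc.tf, f"Tg{i:02d}") for i in range(casc.n_targets)
    ]

    # --- sample counts ------------------------------------------------------
    sf = rng.lognormal(0.0, config.size_factor_log_sd, n_cells)
    mu = (2.0 ** log2lam) * sf[None, :]
    p = r_size[:, None] / (r_size[:, None] + mu)
    counts = rng.negative_binomial(r_size[:, None], p)

    # --- doublets: sums of two distinct same-sample cells -------------------
    n_doublets = int(round(config.doublet_fraction * n_cells))
    dbl_cols, dbl_meta, dbl_states, dbl_latents = [], [], [], []
    sample_arr = np.asarray([m[0] for m in metas], dtype=object)
    for d in range(n_doublets):
        sample = samples[d % len(samples)][1]
        pool = np.flatnonzero(sample_arr == sample)
        a, b = rng.choice(pool, size=2, replace=False)
        # plant heterotypic doublets where possible: homotypic ones are
        # expression-indistinguishable and would be untestable ground truth
        if len(config.cell_types) > 1:
            for _ in range(20):
                if ct_arr[a] != ct_arr[b]:
                    break
                a, b = rng.choice(pool, size=2, replace=False)
        dbl_cols.append(counts[:, a] + counts[:, b])
        dbl_meta.append((sample, metas[a][1], metas[a][2]))
        dbl_states.append(state_arr[a])
        dbl_latents.append(latents[a])
    if n_doublets:
        counts = np.column_stack([counts, np.column_stack(dbl_cols)])
        cells = cells + [f"DBL-{d:03d}" for d in range(n_doublets)]
        metas = metas + dbl_meta
        state_arr = np.concatenate([state_arr, np.asarray(dbl_states, object)])
        latents = np.concatenate([latents, np.asarray(dbl_latents)])

    cell_index = pd.Index(cells, name="barcode")
    cell_meta = pd.DataFrame(
        metas, index=cell_index, columns=["sample_id", "group", "cell_type"]
    )
    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=np.asarray(genes, dtype=object),
        cell_ids=np.asarray(cells, dtype=object),
        cell_meta=cell_meta,
    )

    # --- catalog ------------------------------------------------------------
    mito_set = set(parts["mito"])
    mang_set = set(parts["mangs"])
    catalog = GeneCatalog(
        table=pd.DataFrame(
            {
                "is_mito_encoded": [g in mito_set for g in genes],
                "is_mito_mrna": [g in mito_set for g in genes],
                "is_mang": [g in mang_set for g in genes],
                "is_tf": [g == casc.tf for g in genes],
                "slc_family": [None] * n_genes,
                "chromosome": ["MT" if g in mito_set else "1" for g in genes],
            },
            index=pd.Index(genes, name="symbol"),
        )
    )

    # --- LR database: planted pathway plus decoys ---------------------------
    decoy_rows = LRDatabase.toy().table
    decoy_rows = decoy_rows[
        ~decoy_rows["pathway"].isin(["ncWNT"])  # planted chain replaces it
    ]
    lr_table = pd.concat(
        [
            pd.DataFrame(
                [
                    {
                        "pathway": "PLANTED",
                        "ligands": casc.ligand,
                        "receptors": casc.receptor,
                        "category": "secreted",
                    }
                ]
            ),
            decoy_rows,
        ],
        ignore_index=True,
    )
    lr_db = LRDatabase(table=lr_table)

    # --- per-type mean profiles (for bulk mixing) ---------------------------
    profiles = pd.DataFrame(
        {
            ct: np.asarray(counts[:, np.asarray([m[2] for m in metas]) == ct]).mean(axis=1)
            for ct in config.cell_types
        },
        index=pd.Index(genes, name="gene"),
    )

    truth = GroundTruth(
        state=pd.Series(state_arr, index=cell_index, name="state"),
        is_doublet=pd.Series(
            [c.startswith("DBL-") for c in cells], index=cell_index, name="is_doublet"
        ),
        pseudotime=pd.Series(latents, index=cell_index, name="pseudotime"),
        de_genes=de_genes,
        shifted_pathways=shifted_pathways,
        cascade_edges=cascade_edges,
        cascade=casc,
        marker_genes=marker_genes,
        type_mean_profiles=profiles,
    )
    return cm, catalog, collection, lr_db, truth


def simulate_bulk(
    signature_truth: pd.DataFrame,
    proportions,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk profiles as proportion-weighted sums of per-type mean profiles.

    Parameters
    ----------
    signature_truth
        Genes x cell-types table of mean expression (e.g.
        ``GroundTruth.type_mean_profiles``).
    proportions
        Mapping / Series of cell-type -> proportion for one sample, or a
        DataFrame (samples x cell types) for several.  Each row must be
        non-negative and sum to 1.
    noise_sd
        Standard deviation of Gaussian noise applied on the natural-log
        scale (multiplicative log-normal noise).
    """
    if isinstance(proportions, (dict, pd.Series)):
        proportions = pd.DataFrame([pd.Series(proportions)], index=["bulk1"])
    proportions = proportions.astype(float)
    if (proportions.to_numpy() < 0).any():
        raise ValidationError("negative proportions")
    sums = proportions.sum(axis=1)
    if not np.allclose(sums, 1.0):
        raise ValidationError(f"proportions must sum to 1, got {sums.to_dict()}")
    missing = set(proportions.columns) - set(signature_truth.columns)
    if missing:
        raise ValidationError(f"unknown cell types: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mix = signature_truth[proportions.columns].to_numpy() @ proportions.to_numpy().T
    if noise_sd > 0:
        mix = mix * np.exp(rng.normal(0.0, noise_sd, size=mix.shape))
    return pd.DataFrame(mix, index=signature_truth.index, columns=proportions.index)
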