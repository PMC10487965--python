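"""Domain containers and readers/writers for the formats every pipeline stage touches.

The pipeline operates on four kinds of objects: a UMI count matrix with cell
metadata (:class:`CountMatrix`), a per-gene annotation table
(:class:`GeneCatalog`), named gene-set collections (:class:`GeneSetCollection`,
carried on disk as Broad-dialect GMT), and a ligand-receptor interaction
database (:class:`LRDatabase`).

Conventions
-----------
* Gene identifiers are case-sensitive symbols; no alias resolution is attempted.
* MatrixMarket files are 1-based per the standard; all in-memory indices are
  0-based.
* Cell metadata lives in a separate TSV keyed by barcode so that the
  ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` triple stays standard.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FormatError",
    "ValidationError",
    "CountMatrix",
    "GeneCatalog",
    "GeneSetCollection",
    "LRDatabase",
    "load_counts",
    "write_counts",
    "load_gmt",
    "write_gmt",
]

VALID_GROUPS = ("Ctrl", "DKD", "DM", "ARB", "SGLT2i", "HKC")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Structurally well-formed input violates a domain invariant."""


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with sample/group/cell-type metadata.

    Parameters
    ----------
    counts
        Sparse genes x cells matrix of non-negative integer UMI counts.
    gene_ids
        Unique gene symbols, one per matrix row.
    cell_ids
        Unique cell barcodes, one per matrix column.
    cell_meta
        Table indexed by barcode with at least ``sample_id``, ``group`` and
        ``cell_type`` columns; ``subcluster`` is optional.
    gene_meta
        Optional per-gene annotation (chromosome, flags), indexed by symbol.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene symbols")
        if len(set(self.cell_ids)) != n_cells:
            raise ValidationError("duplicate cell barcodes")
        data = self.counts.data
        if data.size and (data < 0).any():
            raise ValidationError("negative counts")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("non-integer counts")
        self.counts = self.counts.astype(np.int64)
        missing = [b for b in self.cell_ids if b not in self.cell_meta.index]
        if missing:
            raise ValidationError(
                f"barcodes absent from cell metadata: {missing[:5]}"
            )
        self.cell_meta = self.cell_meta.loc[list(self.cell_ids)]
        for col in ("sample_id", "group", "cell_type"):
            if col not in self.cell_meta.columns:
                raise ValidationError(f"cell metadata lacks column {col!r}")
        bad = set(self.cell_meta["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValidationError(f"unknown groups: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        """0-based row indices of the given symbols (missing ones dropped)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[s] for s in symbols if s in lookup], dtype=int)

    def subset_cells(self, mask_or_ids) -> "CountMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([lookup[c] for c in mask_or_ids], dtype=int)
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=self.cell_ids[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_meta=self.gene_meta,
        )


@dataclass
class GeneCatalog:
    """Per-gene annotation: mitochondrial provenance, MANG/TF flags, SLC family.

    A MANG (mitochondria-associated nuclear gene) is a nuclear gene encoding a
    mitochondrial component; the mitochondrially encoded genes themselves are
    flagged separately, with the mRNA-coding subset used for the per-cell
    mitochondrial-content statistic.
    """

    table: pd.DataFrame  # indexed by symbol

    REQUIRED = (
        "is_mito_encoded",
        "is_mito_mrna",
        "is_mang",
        "is_tf",
        "slc_family",
        "chromosome",
    )

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"catalog lacks column {col!r}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate symbols in catalog")
        bad = self.table["is_mito_mrna"] & ~self.table["is_mito_encoded"]
        if bad.any():
            raise ValidationError(
                "is_mito_mrna implies is_mito_encoded; violated by "
                f"{list(self.table.index[bad])[:5]}"
            )

    @property
    def mito_encoded(self) -> list[str]:
        return list(self.table.index[self.table["is_mito_encoded"]])

    @property
    def mito_mrna(self) -> list[str]:
        return list(self.table.index[self.table["is_mito_mrna"]])

    @property
    def mangs(self) -> list[str]:
        return list(self.table.index[self.table["is_mang"]])

    @property
    def tfs(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"]])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneCatalog":
        return cls(table=frame)

    @classmethod
    def load(cls, path) -> "GeneCatalog":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        for col in ("is_mito_encoded", "is_mito_mrna", "is_mang", "is_tf"):
            frame[col] = frame[col].astype(bool)
        frame["slc_family"] = frame["slc_family"].where(
            frame["slc_family"].notna(), None
        )
        return cls(table=frame)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="symbol")

    @classmethod
    def mouse_mito(cls) -> "GeneCatalog":
        """The bundled murine mitochondrial-genome catalog.

        The mouse mitochondrial genome encodes 37 genes: 13 mRNAs (respiratory
        chain subunits), 2 rRNAs and 22 tRNAs.  Only the 13 mRNAs appear in a
        polyA-primed UMI matrix and drive the PMEM statistic.
        """
        ref = resources.files("mitostate.data").joinpath("mouse_mito_catalog.tsv")
        raw = pd.read_csv(io.StringIO(ref.read_text()), sep="\t")
        table = pd.DataFrame(
            {
                "is_mito_encoded": True,
                "is_mito_mrna": (raw["biotype"] == "mRNA").to_numpy(),
                "is_mang": False,
                "is_tf": False,
                "slc_family": None,
                "chromosome": raw["chromosome"].to_numpy(),
            },
            index=pd.Index(raw["symbol"], name="symbol"),
        )
        return cls(table=table)


@dataclass
class GeneSetCollection:
    """Ordered, named, non-empty gene sets (GMT on disk)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not name:
                raise ValidationError("empty set name")
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe, min_size: int = 1) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets below ``min_size``."""
        uni = set(universe)
        kept = {}
        for name, genes in self.sets.items():
            hit = [g for g in genes if g in uni]
            if len(hit) >= min_size:
                kept[name] = hit
        return GeneSetCollection(
            sets=kept,
            descriptions={n: self.descriptions.get(n, "") for n in kept},
        )


def load_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name, description, genes...

    Duplicate genes within a set are de-duplicated (first occurrence wins);
    a duplicated set name is an error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >=3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class LRDatabase:
    """Ligand-receptor pathway rows: (pathway, ligands, receptors, category)."""

    table: pd.DataFrame

    CATEGORIES = ("secreted", "contact", "ECM")

    def __post_init__(self) -> None:
        for col in ("pathway", "ligands", "receptors", "category"):
            if col not in self.table.columns:
                raise ValidationError(f"LR database lacks column {col!r}")
        for _, row in self.table.iterrows():
            if not row["pathway"]:
                raise ValidationError("empty pathway name")
            if not row["ligands"] or not row["receptors"]:
                raise ValidationError(
                    f"pathway {row['pathway']!r} needs >=1 ligand and receptor"
                )

    def __len__(self) -> int:
        return len(self.table)

    def rows(self):
        """Yield (pathway, ligand genes, receptor genes, category) tuples."""
        for _, row in self.table.iterrows():
            yield (
                row["pathway"],
                tuple(row["ligands"].split(",")),
                tuple(row["receptors"].split(",")),
                row["category"],
            )

    @classmethod
    def load(cls, path) -> "LRDatabase":
        return cls(table=pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def toy(cls) -> "LRDatabase":
        """Bundled 12-pathway toy database for examples and tests."""
        ref = resources.files("mitostate.data").joinpath("toy_lr_database.tsv")
        return cls(table=pd.read_csv(io.StringIO(ref.read_text()), sep="\t", dtype=str))


def load_counts(matrix_path, features_path, barcodes_path, cell_meta_path) -> CountMatrix:
    """Load a 10x-style MTX triple plus a barcode-keyed metadata TSV.

    The metadata TSV must have a header and a ``barcode`` column; any barcode
    present in the matrix but absent from the metadata is rejected.
    """
    for p in (matrix_path, features_path, barcodes_path, cell_meta_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # noqa: BLE001 - normalize into domain error
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    mat = sp.csr_matrix(mat)
    genes = pd.read_csv(features_path, sep="\t", header=None)[0].to_numpy(object)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(object)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    meta = pd.read_csv(cell_meta_path, sep="\t").set_index("barcode")
    return CountMatrix(
        counts=mat, gene_ids=genes, cell_ids=barcodes, cell_meta=meta
    )


def write_counts(cm: CountMatrix, out_dir) -> None:
    """Write the MTX triple plus ``cell_meta.tsv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(cm.counts), field="integer")
    pd.Series(cm.gene_ids).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    cm.cell_meta.to_csv(out / "cell_meta.tsv", sep="\t", index_label="barcode")
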