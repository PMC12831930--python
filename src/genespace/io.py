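"""Readers and writers for the package's external formats.

Count matrices come in as Matrix Market triplets with one-id-per-line gene
and cell files (10x-style multi-column features files are accepted, first
column used), or as dense TSV with genes as columns. Gene sets are GMT,
gene-pair tables and landscapes are TSV, permutation results are JSON.

Matrix Market files are 1-based on disk (per the standard); everything in
memory is 0-based. All TSV output is UTF-8 with "." decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import FormatError
from .results import PermTestResult, read_result_json, write_result_json  # noqa: F401

logger = logging.getLogger(__name__)

# gene set collections are plain mappings: set name -> set of gene ids
GeneSetCollection = dict


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A cells×genes count matrix with optional derived layers.

    `counts` holds raw non-negative counts. `normalized` (library-size
    normalised, log1p) and `zscores` (per-gene z-scores over cells) are
    filled in by :func:`genespace.gene_space.normalize` and
    :func:`genespace.gene_space.zscore_genes`.
    """

    cell_ids: list
    gene_ids: list
    counts: np.ndarray
    normalized: np.ndarray | None = None
    zscores: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        for layer in (self.normalized, self.zscores):
            if layer is not None and layer.shape != self.counts.shape:
                raise ValueError("derived layer shape differs from counts")

    def with_layer(self, **layers) -> "ExpressionMatrix":
        """Return a copy sharing counts but with `normalized`/`zscores` replaced."""
        return replace(self, **layers)


@dataclass
class CellMetadata:
    """Per-cell annotation: cluster label and, optionally, condition."""

    cell_ids: list
    cell_cluster: list
    condition: list | None = None

    def __post_init__(self):
        if len(self.cell_cluster) != len(self.cell_ids):
            raise ValueError("cell_cluster length differs from cell_ids")
        if self.condition is not None and len(self.condition) != len(self.cell_ids):
            raise ValueError("condition length differs from cell_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in metadata")
        if any(str(c) == "" for c in self.cell_cluster):
            raise ValueError("empty cell cluster label")

    def labels_for(self, cell_ids, group_by: str) -> np.ndarray:
        """Group labels for `cell_ids` in that order; KeyError if a cell is missing."""
        if group_by == "cell_cluster":
            values = self.cell_cluster
        elif group_by == "condition":
            if self.condition is None:
                raise ValueError("metadata has no condition column")
            values = self.condition
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        lookup = dict(zip(self.cell_ids, values))
        missing = [c for c in cell_ids if c not in lookup]
        if missing:
            raise KeyError(f"{len(missing)} cells missing from metadata, e.g. {missing[0]!r}")
        return np.asarray([lookup[c] for c in cell_ids], dtype=object)


@dataclass
class PairTable:
    """Ordered gene pairs (e.g. ligand→receptor), no self-pairs.

    Tables read from disk are de-duplicated (`strict=True`); randomised
    null draws may repeat a pair and are built with `strict=False`.
    """

    pairs: list
    role_a: str = "gene_a"
    role_b: str = "gene_b"
    n_dropped_self: int = 0
    strict: bool = True

    def __post_init__(self):
        if any(a == b for a, b in self.pairs):
            raise ValueError("self-pair in PairTable")
        if self.strict and len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pair in PairTable")

    def __len__(self) -> int:
        return len(self.pairs)


def make_pair_table(pairs, role_a="gene_a", role_b="gene_b") -> PairTable:
    """Build a PairTable, dropping self-pairs (logged) and duplicates, keeping order."""
    pairs = [(str(a), str(b)) for a, b in pairs]
    kept = [p for p in pairs if p[0] != p[1]]
    n_self = len(pairs) - len(kept)
    if n_self:
        logger.info("dropped %d self-pair(s)", n_self)
    deduped = list(dict.fromkeys(kept))
    return PairTable(deduped, role_a=role_a, role_b=role_b, n_dropped_self=n_self)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _read_id_file(path) -> list:
    """One id per line; multi-column (10x features.tsv style) uses column 1."""
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def read_counts_mtx(matrix_path, genes_path, cells_path) -> ExpressionMatrix:
    """Read a Matrix Market triplet file plus gene/cell id files.

    The on-disk orientation is inferred from the id-file lengths; the
    returned matrix is always cells×genes. A square matrix whose two id
    files have equal length is rejected as ambiguous.
    """
    gene_ids = _read_id_file(genes_path)
    cell_ids = _read_id_file(cells_path)
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(f"duplicate gene ids in {genes_path}")
    if len(set(cell_ids)) != len(cell_ids):
        raise FormatError(f"duplicate cell ids in {cells_path}")
    mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    n_rows, n_cols = mat.shape
    n_genes, n_cells = len(gene_ids), len(cell_ids)
    if n_genes == n_cells:
        if n_rows == n_cols == n_genes:
            raise FormatError(
                "square matrix with equally many gene and cell ids: "
                "orientation is ambiguous"
            )
    if (n_rows, n_cols) == (n_cells, n_genes):
        counts = mat
    elif (n_rows, n_cols) == (n_genes, n_cells):
        counts = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={n_cells}, genes={n_genes}) nor its transpose"
        )
    return ExpressionMatrix(cell_ids=cell_ids, gene_ids=gene_ids, counts=counts)


def write_counts_mtx(matrix: ExpressionMatrix, matrix_path, genes_path, cells_path) -> None:
    """Write counts as Matrix Market (genes×cells on disk, 10x convention)."""
    sparse = scipy.sparse.coo_matrix(matrix.counts.T)
    scipy.io.mmwrite(str(matrix_path), sparse)
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n", encoding="utf-8")
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n", encoding="utf-8")


def read_counts_tsv(path) -> ExpressionMatrix:
    """Dense TSV: header row of gene ids, first column cell ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        cell_ids=[str(c) for c in frame.index],
        gene_ids=[str(g) for g in frame.columns],
        counts=frame.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# metadata, gene sets, pair tables
# ---------------------------------------------------------------------------

def read_cell_metadata(path) -> CellMetadata:
    """TSV with header; columns cell_id, cell_cluster and optionally condition."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "cell_cluster"):
        if col not in frame.columns:
            raise FormatError(f"metadata file missing column {col!r}")
    condition = list(frame["condition"]) if "condition" in frame.columns else None
    return CellMetadata(
        cell_ids=list(frame["cell_id"]),
        cell_cluster=list(frame["cell_cluster"]),
        condition=condition,
    )


def write_cell_metadata(meta: CellMetadata, path) -> None:
    data = {"cell_id": meta.cell_ids, "cell_cluster": meta.cell_cluster}
    if meta.condition is not None:
        data["condition"] = meta.condition
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, members... per tab-separated line."""
    collection: GeneSetCollection = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}, line {lineno}: expected at least 3 fields")
            name = fields[0]
            if name in collection:
                raise FormatError(f"{path}, line {lineno}: duplicate set name {name!r}")
            members = {f for f in fields[2:] if f}
            if not members:
                raise FormatError(f"{path}, line {lineno}: set {name!r} has no members")
            collection[name] = members
    return collection


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_pair_table(path) -> PairTable:
    """Two-column TSV of ordered gene pairs with a header row.

    Columns named gene_a/gene_b are used when present; otherwise the first
    two columns are taken and their header names become the role labels.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_a" in frame.columns and "gene_b" in frame.columns:
        col_a, col_b = "gene_a", "gene_b"
    elif len(frame.columns) >= 2:
        col_a, col_b = frame.columns[:2]
    else:
        raise FormatError(f"{path}: pair table needs columns gene_a and gene_b")
    return make_pair_table(
        zip(frame[col_a], frame[col_b]), role_a=str(col_a), role_b=str(col_b)
    )


def write_pair_table(table: PairTable, path) -> None:
    frame = pd.DataFrame(table.pairs, columns=[table.role_a, table.role_b])
    frame.to_csv(path, sep="\t", index=False)


def read_complex_table(path) -> dict:
    """Long-format TSV (complex_name, gene_id) -> mapping name → gene set."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: complex table needs columns complex_name, gene_id")
    name_col, gene_col = frame.columns[:2]
    complexes: dict = {}
    for name, sub in frame.groupby(name_col, sort=False):
        complexes[str(name)] = set(sub[gene_col])
    return complexes


# ---------------------------------------------------------------------------
# landscapes
# ---------------------------------------------------------------------------

def write_landscape_tsv(landscape, path) -> None:
    """Landscape TSV: one row per gene, one value column per group."""
    frame = pd.DataFrame(
        np.asarray(landscape.values, dtype=float),
        index=pd.Index(landscape.gene_ids, name="gene"),
        columns=[str(g) for g in landscape.groups],
    )
    frame.to_csv(path, sep="\t", float_format="%.12g")


def read_landscape_tsv(path, group_by: str = "cell_cluster"):
    from .landscapes import GroupLandscape

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return GroupLandscape(
        group_by=group_by,
        groups=[str(c) for c in frame.columns],
        gene_ids=[str(g) for g in frame.index],
        values=frame.to_numpy(dtype=float),
    )
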