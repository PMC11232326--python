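"""Expression matrix / metadata readers, normalization, per-cell-type profiles."""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Dense genes × cells matrix of non-negative counts or TPM-like values."""

    genes: list[str]
    cells: list[str]
    values: np.ndarray  # shape (n_genes, n_cells), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes × {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene symbols after collapsing")
        if len(set(self.cells)) != len(self.cells):
            raise DataError("duplicate cell names")
        if np.any(self.values < 0):
            raise DataError("expression matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(list(self.genes), list(self.cells), self.values.copy())


@dataclass
class CellMetadata:
    """Mapping from cell name to cell-type label."""

    types: dict[str, str]

    def __post_init__(self) -> None:
        for cell, label in self.types.items():
            if not label:
                raise DataError(f"cell {cell!r} has an empty cell-type label")

    def __len__(self) -> int:
        return len(self.types)

    def label_of(self, cell: str) -> str | None:
        return self.types.get(cell)

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.types.values()))


@dataclass
class CellTypeProfile:
    """Per cell type: mean normalized expression and expressed fraction per gene."""

    genes: list[str]
    cell_types: list[str]
    mean: np.ndarray  # (n_genes, n_types)
    frac: np.ndarray  # (n_genes, n_types), in [0, 1]
    n_cells: dict[str, int]
    _gene_index: dict[str, int] = field(init=False, repr=False)
    _type_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._type_index = {t: i for i, t in enumerate(self.cell_types)}

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene_index(self, gene: str) -> int | None:
        return self._gene_index.get(gene)

    def type_index(self, cell_type: str) -> int:
        return self._type_index[cell_type]

    def mean_expr(self, gene: str, cell_type: str) -> float:
        i = self._gene_index.get(gene)
        if i is None:
            return 0.0
        return float(self.mean[i, self._type_index[cell_type]])

    def expr_frac(self, gene: str, cell_type: str) -> float:
        i = self._gene_index.get(gene)
        if i is None:
            return 0.0
        return float(self.frac[i, self._type_index[cell_type]])


def _read_dense(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    values = df.to_numpy(dtype=np.float64)
    genes = [str(g) for g in df.index]
    cells = [str(c) for c in df.columns]
    return _finalize(genes, cells, values)


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    mtx = path / "matrix.mtx"
    genes_file = path / "genes.tsv"
    barcodes_file = path / "barcodes.tsv"
    for f in (mtx, genes_file, barcodes_file):
        if not f.exists():
            raise FormatError(f"mtx_dir layout requires {f.name} in {path}")
    mat = scipy.io.mmread(mtx)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    genes = [ln.split("\t")[0].strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
    cells = [ln.split("\t")[0].strip() for ln in barcodes_file.read_text().splitlines() if ln.strip()]
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{mtx}: matrix declares {mat.shape[0]} genes but genes.tsv lists {len(genes)}"
        )
    if mat.shape[1] != len(cells):
        raise FormatError(
            f"{mtx}: matrix declares {mat.shape[1]} cells but barcodes.tsv lists {len(cells)}"
        )
    return _finalize(genes, cells, mat)


def _finalize(genes: list[str], cells: list[str], values: np.ndarray) -> ExpressionMatrix:
    if np.any(values < 0):
        raise DataError("expression matrix contains negative values")
    if len(set(genes)) != len(genes):
        # collapse duplicate gene rows by summation, preserving first-seen order
        order: dict[str, int] = {}
        for g in genes:
            if g not in order:
                order[g] = len(order)
        collapsed = np.zeros((len(order), values.shape[1]), dtype=np.float64)
        for row, g in enumerate(genes):
            collapsed[order[g]] += values[row]
        n_dup = len(genes) - len(order)
        logger.warning("collapsed %d duplicate gene rows by summation", n_dup)
        genes = list(order)
        values = collapsed
    return ExpressionMatrix(genes, cells, values)


def read_expression(path: str | Path, format: str = "dense_tsv") -> ExpressionMatrix:
    """Read a genes × cells matrix.

    ``format="dense_tsv"``: delimited text, first column gene symbols, header
    row of cell names.  ``format="mtx_dir"``: directory containing
    ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv``.  Duplicate gene rows
    are collapsed by summation (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"expression input {path} does not exist")
    if format == "dense_tsv":
        return _read_dense(path)
    if format == "mtx_dir":
        return _read_mtx_dir(path)
    raise FormatError(f"unknown expression format {format!r}")


def read_metadata(path: str | Path) -> CellMetadata:
    """Read the two-column META table (cell, cell_type) with a header row."""
    path = Path(path)
    types: dict[str, str] = {}
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        if "cell" not in cols or "cell_type" not in cols:
            raise FormatError(f"{path}: META file must have columns 'cell' and 'cell_type'")
        for row in reader:
            cell = row["cell"].strip()
            label = (row["cell_type"] or "").strip()
            if cell in types:
                raise DataError(f"{path}: duplicate cell name {cell!r}")
            if not label:
                raise DataError(f"{path}: empty cell type for cell {cell!r}")
            types[cell] = label
    return CellMetadata(types)


def normalize(
    expr: ExpressionMatrix,
    mode: str = "cpm",
    on_zero_cell: str = "drop",
    target_sum: float = 10_000.0,
) -> ExpressionMatrix:
    """Library-size normalization.

    ``cpm`` scales each cell's column to sum to ``target_sum`` (linear scale,
    no log).  ``none`` passes values through unchanged (for TPM-like input).
    All-zero cells under ``cpm`` are dropped with a warning, or raise when
    ``on_zero_cell="error"``.
    """
    if mode == "none":
        return expr
    if mode != "cpm":
        raise DataError(f"unknown normalization mode {mode!r}")
    colsums = expr.values.sum(axis=0)
    zero = colsums == 0
    if np.any(zero):
        if on_zero_cell == "error":
            bad = [expr.cells[i] for i in np.flatnonzero(zero)]
            raise DataError(f"all-zero cells under cpm normalization: {bad}")
        dropped = [expr.cells[i] for i in np.flatnonzero(zero)]
        logger.warning("dropping %d all-zero cells under cpm: %s", len(dropped), dropped)
        keep = ~zero
        expr = ExpressionMatrix(
            list(expr.genes),
            [c for c, k in zip(expr.cells, keep) if k],
            expr.values[:, keep],
        )
        colsums = colsums[keep]
    scaled = expr.values * (target_sum / colsums)
    return ExpressionMatrix(list(expr.genes), list(expr.cells), scaled)


def profile_cell_types(expr: ExpressionMatrix, meta: CellMetadata) -> CellTypeProfile:
    """Aggregate to per-cell-type mean expression and expressed fraction.

    Every matrix cell must carry a label; META rows for cells absent from the
    matrix are ignored with a warning.
    """
    missing = [c for c in expr.cells if c not in meta.types]
    if missing:
        raise DataError(
            f"{len(missing)} matrix cells missing from META, e.g. {missing[:5]}"
        )
    extra = set(meta.types) - set(expr.cells)
    if extra:
        logger.warning(
            "%d META cells absent from the matrix are ignored", len(extra)
        )
    labels = [meta.types[c] for c in expr.cells]
    cell_types = sorted(set(labels))
    tidx = {t: i for i, t in enumerate(cell_types)}
    lab = np.array([tidx[l] for l in labels], dtype=np.intp)
    onehot = np.zeros((expr.n_cells, len(cell_types)), dtype=np.float64)
    onehot[np.arange(expr.n_cells), lab] = 1.0
    counts = onehot.sum(axis=0)
    mean = (expr.values @ onehot) / counts
    frac = ((expr.values > 0).astype(np.float64) @ onehot) / counts
    n_cells = {t: int(counts[tidx[t]]) for t in cell_types}
    return CellTypeProfile(
        genes=list(expr.genes),
        cell_types=cell_types,
        mean=mean,
        frac=frac,
        n_cells=n_cells,
    )
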