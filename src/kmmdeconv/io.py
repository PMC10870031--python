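"""Expression-matrix, label and proportion-table containers and readers.

Matrices are always stored genes-as-rows internally; readers transpose on
request when a file stores genes as columns. Gene identifiers are
canonicalized by stripping surrounding whitespace (case is preserved) and
duplicate gene rows are summed, which is count-preserving and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "ProportionTable",
    "ValidationError",
    "FormatError",
    "read_expression",
    "read_labels",
    "write_proportions",
    "read_proportions",
]

LAYER_TAGS = ("raw", "cell_normalized", "relative_abundance", "kmm_transformed")


class ValidationError(ValueError):
    """Raised when data violate a container invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the declared format."""


def _canon_ids(ids: Sequence[str]) -> list[str]:
    return [str(i).strip() for i in ids]


@dataclass
class ExpressionMatrix:
    """Non-negative genes x columns expression matrix with name vectors.

    ``columns`` are bulk samples or single cells depending on context;
    ``layer_tag`` records which normalization has been applied.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _canon_ids(self.gene_ids)
        self.column_ids = _canon_ids(self.column_ids)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(self.column_ids) != self.values.shape[1]:
            raise ValidationError(
                f"{len(self.column_ids)} column ids for {self.values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene ids must be unique after canonicalization")
        if self.layer_tag not in LAYER_TAGS:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, layer_tag: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, layer_tag=layer_tag or self.layer_tag)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in genes]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"gene {exc.args[0]!r} not present") from exc
        return replace(self, values=self.values[rows], gene_ids=list(genes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class CellAnnotation:
    """Cell -> cell-type assignment defining the clusters C_k."""

    cell_ids: list[str]
    cell_type: list[str]
    type_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.cell_ids = _canon_ids(self.cell_ids)
        self.cell_type = _canon_ids(self.cell_type)
        if len(self.cell_ids) != len(self.cell_type):
            raise ValidationError("cell_ids and cell_type lengths differ")
        if len(self.cell_ids) == 0:
            raise ValidationError("annotation is empty")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids in annotation")
        if self.type_order is None:
            # first-appearance order
            self.type_order = list(dict.fromkeys(self.cell_type))
        else:
            self.type_order = _canon_ids(self.type_order)
        missing = set(self.cell_type) - set(self.type_order)
        if missing:
            raise ValidationError(f"cell types {sorted(missing)} missing from type_order")
        counts = self.type_counts
        empty = [t for t, m in zip(self.type_order, counts) if m == 0]
        if empty:
            raise ValidationError(f"cell types with no cells: {empty}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_order)

    @property
    def type_counts(self) -> np.ndarray:
        """m_k = number of cells per type, in type_order."""
        ct = np.asarray(self.cell_type)
        return np.array([int(np.sum(ct == t)) for t in self.type_order])

    def type_indices(self, k: str) -> np.ndarray:
        ct = np.asarray(self.cell_type)
        return np.flatnonzero(ct == k)


@dataclass
class ProportionTable:
    """Per-sample cell-type proportion estimates with fit diagnostics."""

    sample_ids: list[str]
    type_order: list[str]
    proportions: np.ndarray
    residual_norm: np.ndarray = None  # type: ignore[assignment]
    n_iterations: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = _canon_ids(self.sample_ids)
        self.type_order = _canon_ids(self.type_order)
        self.proportions = np.asarray(self.proportions, dtype=float)
        n, k = self.proportions.shape
        if n != len(self.sample_ids) or k != len(self.type_order):
            raise ValidationError("proportions shape does not match id vectors")
        if np.any(self.proportions < -1e-12):
            raise ValidationError("proportions must be non-negative")
        sums = self.proportions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValidationError(f"proportions for sample {bad!r} do not sum to 1")
        if self.residual_norm is None:
            self.residual_norm = np.zeros(n)
        if self.n_iterations is None:
            self.n_iterations = np.zeros(n, dtype=int)
        self.residual_norm = np.asarray(self.residual_norm, dtype=float)
        self.n_iterations = np.asarray(self.n_iterations, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.sample_ids, columns=self.type_order)


def _collapse_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
    frame.index = [str(i).strip() for i in frame.index]
    if frame.index.is_unique:
        return frame
    # sum duplicate gene rows, keeping first-occurrence order
    order = list(dict.fromkeys(frame.index))
    return frame.groupby(level=0, sort=False).sum().loc[order]


def _read_sidecar(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    genes_path: str | Path | None = None,
    columns_path: str | Path | None = None,
    genes_as_columns: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from MTX or a delimited table.

    Delimited files carry genes as rows with a header line of column ids;
    MTX files need one-name-per-line sidecars for genes and columns. Set
    ``genes_as_columns`` when the file is oriented columns=genes; the matrix
    is transposed to the internal genes-as-rows convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv", ".txt": "tsv"}.get(suffix)
        if fmt is None:
            raise FormatError(f"cannot infer format from {path.name!r}")
    if fmt == "mtx":
        if genes_path is None or columns_path is None:
            raise ValidationError("mtx format requires genes_path and columns_path sidecars")
        try:
            raw = mmread(path)
        except Exception as exc:
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        genes = _read_sidecar(Path(genes_path))
        cols = _read_sidecar(Path(columns_path))
        if genes_as_columns:
            mat = mat.T
            genes, cols = cols, genes
        if mat.shape != (len(genes), len(cols)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecars ({len(genes)}, {len(cols)})"
            )
        frame = pd.DataFrame(mat, index=genes, columns=cols)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise FormatError(f"malformed {fmt.upper()} file {path}: {exc}") from exc
        if frame.shape[1] == 0:
            raise FormatError(f"{path}: no data columns parsed; malformed header?")
        if not all(np.issubdtype(d, np.number) for d in frame.dtypes):
            raise FormatError(f"{path}: non-numeric entries in expression table")
        if genes_as_columns:
            frame = frame.T
    else:
        raise FormatError(f"unknown format {fmt!r}")
    frame = _collapse_duplicates(frame)
    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"{path}: negative expression entries")
    return ExpressionMatrix(
        values=values,
        gene_ids=list(frame.index),
        column_ids=[str(c).strip() for c in frame.columns],
        layer_tag="raw",
    )


def read_labels(path: str | Path) -> CellAnnotation:
    """Read a two-column (cell_id, cell_type) table; a header row is detected
    and skipped if its second field repeats nowhere else as a type.

    Cell-type order is first-appearance order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise FormatError(f"{path}: expected two delimited columns, got {line!r}")
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ValidationError(f"{path}: empty label file")
    # header heuristic: common header tokens in either field
    header_tokens = {"cell", "cell_id", "cellid", "barcode", "type", "cell_type", "celltype", "label", "cluster"}
    if rows and (rows[0][0].lower() in header_tokens or rows[0][1].lower() in header_tokens):
        rows = rows[1:]
    if not rows:
        raise ValidationError(f"{path}: no data rows after header")
    return CellAnnotation(cell_ids=[r[0] for r in rows], cell_type=[r[1] for r in rows])


def write_proportions(pt: ProportionTable, path: str | Path) -> None:
    """Write a proportion table as TSV (samples as rows) at 6 significant digits."""
    frame = pt.to_frame()
    frame.index.name = "sample"
    frame.to_csv(path, sep="\t", float_format="%.6g")


def read_proportions(path: str | Path) -> ProportionTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    props = frame.to_numpy(dtype=float)
    # renormalize the 6-digit rounding so the simplex invariant holds exactly
    props = props / props.sum(axis=1, keepdims=True)
    return ProportionTable(
        sample_ids=[str(i) for i in frame.index],
        type_order=[str(c) for c in frame.columns],
        proportions=props,
    )
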