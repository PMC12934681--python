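"""Core data records for imaging-based single-cell spatial transcriptomics.

The unit of analysis is a flat cell table — one row per segmented cell with
its sample, field of view (FOV), centroid coordinates in microns, cell-type
label and optional total transcript count — optionally paired with a
cell × gene count matrix from a targeted panel (~1,000 genes on platforms
such as CosMx SMI).  This module defines those records, reads and writes
them from standard flat formats (CSV/TSV, MatrixMarket), and applies the
count-based quality filter used upstream of every spatial statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("spatialcoloc")

REQUIRED_COLUMNS = ("cell_id", "sample_id", "fov_id", "x_um", "y_um", "cell_type")
OPTIONAL_COLUMNS = ("total_counts", "niche")
DEFAULT_MIN_COUNTS = 50


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class ParseError(ValueError):
    """A value could not be parsed; carries offending row indices."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


class AlignmentError(ValueError):
    """Matrix dimensions and name files (or companion table) disagree."""


class VocabularyError(KeyError):
    """A cell-type label is outside the declared vocabulary."""


class ConfigurationError(ValueError):
    """The requested operation lacks required configuration or inputs."""


# ---------------------------------------------------------------------------
# CellTable
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """Validated per-cell spatial records.

    Parameters
    ----------
    df
        One row per cell with columns ``cell_id, sample_id, fov_id, x_um,
        y_um, cell_type`` and optionally ``total_counts`` and ``niche``.
        Coordinates are microns in a per-FOV local frame unless
        ``coordinate_frame == "global"``.
    fov_size_um
        Declared square FOV side length; when given, local coordinates are
        validated to lie inside ``[0, fov_size_um]``.
    fov_offsets
        Optional table (``fov_id, x0_um, y0_um``) lifting local FOV frames
        into a shared global frame (needed for per-sample neighbor graphs).
    vocabulary
        Controlled cell-type vocabulary.  Taken from the data when omitted;
        with ``strict=True`` unseen labels raise :class:`VocabularyError`.
    """

    df: pd.DataFrame
    fov_size_um: float | None = None
    fov_offsets: pd.DataFrame | None = None
    vocabulary: tuple[str, ...] | None = None
    coordinate_frame: str = "local"
    strict: bool = False

    def __post_init__(self):
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"cell table is missing required column(s): {missing}")
        df = df.reset_index(drop=True).copy()
        for col in ("cell_id", "sample_id", "fov_id", "cell_type"):
            df[col] = df[col].astype(str)
        for col in ("x_um", "y_um"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(~np.isfinite(coerced.to_numpy(dtype=float)))
            if bad.size:
                raise ParseError(
                    f"non-numeric or non-finite {col} at row(s) {bad[:10].tolist()}",
                    rows=bad.tolist(),
                )
            # astype goes through float() and is round-trip exact, unlike to_numeric
            df[col] = df[col].astype(float)
        if "total_counts" in df.columns and df["total_counts"].notna().any():
            tc = pd.to_numeric(df["total_counts"], errors="coerce")
            bad = np.flatnonzero(tc.isna() | (tc < 0))
            if bad.size:
                raise ParseError(
                    f"invalid total_counts at row(s) {bad[:10].tolist()}", rows=bad.tolist()
                )
            df["total_counts"] = tc.astype(np.int64)

        dup = df.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            rows = np.flatnonzero(dup.to_numpy())
            raise ParseError(
                f"duplicate (sample_id, cell_id) at row(s) {rows[:10].tolist()}",
                rows=rows.tolist(),
            )

        if self.fov_size_um is not None and self.coordinate_frame == "local":
            s = float(self.fov_size_um)
            xy = df[["x_um", "y_um"]].to_numpy()
            bad = np.flatnonzero((xy < 0).any(axis=1) | (xy > s).any(axis=1))
            if bad.size:
                raise ParseError(
                    f"coordinates outside [0, {s}] FOV bounds at row(s) {bad[:10].tolist()}",
                    rows=bad.tolist(),
                )

        if self.vocabulary is None:
            object.__setattr__(self, "vocabulary", tuple(sorted(df["cell_type"].unique())))
        else:
            self.vocabulary = tuple(self.vocabulary)
            unknown = sorted(set(df["cell_type"]) - set(self.vocabulary))
            if unknown and self.strict:
                raise VocabularyError(f"cell_type label(s) outside vocabulary: {unknown}")
            elif unknown:
                logger.warning("cell table contains labels outside vocabulary: %s", unknown)
        object.__setattr__(self, "df", df)

    # -- convenience ------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def cell_types(self) -> tuple[str, ...]:
        return self.vocabulary

    def labels(self) -> np.ndarray:
        return self.df["cell_type"].to_numpy()

    def global_xy(self) -> np.ndarray:
        """Centroid coordinates in a global frame (n × 2).

        Local frames are lifted with ``fov_offsets``; raises
        :class:`ConfigurationError` when offsets are required but missing.
        """
        xy = self.df[["x_um", "y_um"]].to_numpy(dtype=float)
        if self.coordinate_frame == "global":
            return xy
        if self.fov_offsets is None:
            raise ConfigurationError(
                "global coordinates requested but coordinate frame is per-FOV local "
                "and no fov_offsets table was provided"
            )
        off = self.fov_offsets.set_index("fov_id")
        missing = sorted(set(self.df["fov_id"]) - set(off.index.astype(str)))
        if missing:
            raise ConfigurationError(f"fov_offsets missing FOV(s): {missing}")
        o = off.loc[self.df["fov_id"], ["x0_um", "y0_um"]].to_numpy(dtype=float)
        return xy + o

    def subset(self, mask: np.ndarray) -> "CellTable":
        return CellTable(
            self.df.loc[np.asarray(mask)].reset_index(drop=True),
            fov_size_um=self.fov_size_um,
            fov_offsets=self.fov_offsets,
            vocabulary=self.vocabulary,
            coordinate_frame=self.coordinate_frame,
        )


def read_cell_table(
    path: str | Path,
    sep: str | None = None,
    column_map: Mapping[str, str] | None = None,
    **kwargs,
) -> CellTable:
    """Read a cell table from CSV/TSV.

    ``column_map`` maps *file* column names onto the logical schema, e.g.
    ``{"CenterX_local_px": "x_um"}`` for vendor exports.  The delimiter is
    inferred from the extension (``.csv`` → comma, otherwise tab) unless
    ``sep`` is given.  Extra keyword arguments are forwarded to
    :class:`CellTable`.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} is missing required column(s): {missing}")
    return CellTable(df, **kwargs)


def write_cell_table(table: CellTable, path: str | Path, sep: str = "\t") -> None:
    """Write the canonical column order as delimited text (byte-stable)."""
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in table.df.columns]
    table.df[cols].to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Cell × gene non-negative integer counts aligned to a cell table."""

    counts: sp.csr_matrix
    cells: np.ndarray  # cell_id per row
    genes: np.ndarray  # gene name per column

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cells = np.asarray(self.cells, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise AlignmentError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells × {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("expression counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)

    def align_to(self, cells: CellTable) -> "ExpressionMatrix":
        """Reorder rows to match a companion cell table (bijection required)."""
        order = {c: i for i, c in enumerate(self.cells)}
        want = cells.df["cell_id"].to_numpy()
        try:
            idx = np.array([order[c] for c in want])
        except KeyError as e:
            raise AlignmentError(f"cell {e} absent from expression matrix") from e
        if len(want) != len(self.cells):
            raise AlignmentError(
                f"cell table has {len(want)} cells but matrix has {len(self.cells)} rows"
            )
        return ExpressionMatrix(self.counts[idx], self.cells[idx], self.genes)

    def subset_rows(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(self.counts[mask], self.cells[mask], self.genes)


def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    cell_table: CellTable | None = None,
) -> ExpressionMatrix:
    """Read counts from MTX (+ name files) or a dense TSV.

    Dense TSV layout: first column cell ids, header row gene names.  MTX is
    cells × genes in coordinate form.  When ``cell_table`` is given the rows
    are reordered to match it.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ConfigurationError("MTX input requires genes_path and cells_path")
        m = sp.csr_matrix(scipy.io.mmread(matrix_path))
        genes = np.loadtxt(genes_path, dtype=str, ndmin=1)
        cells = np.loadtxt(cells_path, dtype=str, ndmin=1)
        if m.shape != (len(cells), len(genes)):
            raise AlignmentError(
                f"MTX shape {m.shape} does not match {len(cells)} cells × {len(genes)} genes"
            )
        expr = ExpressionMatrix(m, cells, genes)
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        expr = ExpressionMatrix(
            sp.csr_matrix(df.to_numpy()), df.index.astype(str).to_numpy(), df.columns.to_numpy()
        )
    if cell_table is not None:
        expr = expr.align_to(cell_table)
    return expr


def write_counts(
    expr: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(expr.counts.astype(np.int64)))
    Path(genes_path).write_text("\n".join(map(str, expr.genes)) + "\n")
    Path(cells_path).write_text("\n".join(map(str, expr.cells)) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_removed_low_counts: int
    n_kept: int
    threshold: int

    def __post_init__(self):
        assert self.n_input == self.n_removed_low_counts + self.n_kept

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def qc_filter(
    cells: CellTable,
    expr: ExpressionMatrix | None = None,
    min_counts: int = DEFAULT_MIN_COUNTS,
) -> tuple[CellTable, ExpressionMatrix | None, QCReport]:
    """Remove cells with fewer than ``min_counts`` total transcripts.

    The boundary is inclusive on the keep side: a cell with exactly
    ``min_counts`` counts survives.  Counts come from the ``total_counts``
    column when present, otherwise from expression row sums.  Expression
    rows are filtered in lockstep with the table.
    """
    df = cells.df
    if "total_counts" in df.columns and df["total_counts"].notna().all():
        totals = df["total_counts"].to_numpy(dtype=np.int64)
        if expr is not None:
            expr = expr.align_to(cells)
    elif expr is not None:
        expr = expr.align_to(cells)
        totals = expr.row_sums()
        df = df.assign(total_counts=totals)
        cells = CellTable(
            df,
            fov_size_um=cells.fov_size_um,
            fov_offsets=cells.fov_offsets,
            vocabulary=cells.vocabulary,
            coordinate_frame=cells.coordinate_frame,
        )
    else:
        raise ConfigurationError(
            "qc_filter needs total_counts on the cell table or an expression matrix"
        )
    keep = totals >= int(min_counts)
    report = QCReport(
        n_input=len(df),
        n_removed_low_counts=int((~keep).sum()),
        n_kept=int(keep.sum()),
        threshold=int(min_counts),
    )
    kept_cells = cells.subset(keep)
    kept_expr = expr.subset_rows(keep) if expr is not None else None
    logger.info(
        "qc: kept %d / %d cells (threshold %d counts)",
        report.n_kept, report.n_input, report.threshold,
    )
    return kept_cells, kept_expr, report
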