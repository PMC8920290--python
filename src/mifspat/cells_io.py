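"""Reading, validation, QC and unit handling for cell-level mIF tables.

Input tables emulate HALO-style exports: one row per segmented cell with a
sample id, subject id, x/y coordinates, one 0/1 column per marker (CD3, CD8,
FOXP3, ...) and an optional tumor/stroma compartment call.  Coordinates are
stored internally in microns; pixel coordinates are converted at read time
using the scanner resolution (0.4977 µm/pixel for the Vectra system these
exports emulate).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import RowParseError, SchemaError, UnknownMarkerError

#: Default image resolution in microns per pixel.
MPP_DEFAULT = 0.4977

#: Columns that are never interpreted as marker flags.
_META_COLUMNS = ("sample_id", "subject_id", "cell_id", "x", "y", "compartment")

COMPARTMENTS = ("tumor", "stroma", "unknown")

STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class CellTable:
    """All segmented cells of one tissue sample (TMA core or ROI).

    ``cells`` holds one row per cell with columns ``x``, ``y`` (microns),
    one int 0/1 column per marker, and ``compartment``.
    """

    sample_id: str
    subject_id: str
    cells: pd.DataFrame
    markers: tuple[str, ...]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coords(self) -> np.ndarray:
        """(n, 2) cell locations in microns."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    def positive_mask(self, phenotype: Iterable[str]) -> np.ndarray:
        """Boolean mask of cells positive for ALL markers of the phenotype."""
        markers = parse_phenotype(phenotype)
        unknown = [m for m in markers if m not in self.markers]
        if unknown:
            raise UnknownMarkerError(f"unknown marker(s) {unknown}; table has {list(self.markers)}")
        mask = np.ones(self.n_cells, dtype=bool)
        for m in markers:
            mask &= self.cells[m].to_numpy() == 1
        return mask

    def subset(self, mask) -> "CellTable":
        return replace(self, cells=self.cells.loc[np.asarray(mask)].reset_index(drop=True))


def parse_phenotype(phenotype) -> tuple[str, ...]:
    """Normalise a phenotype description to a tuple of marker names.

    Accepts an iterable of names or a string such as ``"CD3+CD8+"`` /
    ``"CD3,CD8"``.  A phenotype is a strict conjunction: a cell must be
    positive for every listed marker.
    """
    if isinstance(phenotype, str):
        markers = [m for m in phenotype.replace("+", ",").split(",") if m.strip()]
    else:
        markers = list(phenotype)
    if not markers:
        raise ValueError("phenotype must name at least one marker")
    return tuple(dict.fromkeys(m.strip() for m in markers))


def phenotype_name(phenotype) -> str:
    """Canonical display name, e.g. ('CD3','CD8') → 'CD3+CD8+'."""
    return "".join(f"{m}+" for m in parse_phenotype(phenotype))


def _coerce_flags(df: pd.DataFrame, column: str) -> pd.Series:
    vals = pd.to_numeric(df[column], errors="coerce")
    ok = vals.isin([0, 1]) | vals.isna()
    if not ok.all():
        bad = df.index[~ok][0]
        raise SchemaError(f"marker column {column!r} has non-binary value at row {bad}")
    if vals.isna().any():
        bad = df.index[vals.isna()][0]
        raise SchemaError(f"marker column {column!r} has missing/non-numeric value at row {bad}")
    return vals.astype(np.int8)


def read_cell_tables(
    path,
    coord_units: str = "microns",
    mpp: float = MPP_DEFAULT,
    sep: str | None = None,
) -> list[CellTable]:
    """Read a delimited cell-level export, one :class:`CellTable` per sample.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; auto-detected) with header columns
        ``sample_id, subject_id, x, y``, one 0/1 column per marker, and
        optional ``cell_id`` / ``compartment`` columns.  Lines starting with
        ``#`` are metadata comments.
    coord_units
        ``"pixels"`` (converted to microns by ``mpp``) or ``"microns"``.
    mpp
        Microns per pixel; must be positive.
    """
    if coord_units not in ("pixels", "microns"):
        raise ValueError("coord_units must be 'pixels' or 'microns'")
    if not mpp > 0:
        raise ValueError("mpp must be positive")
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    for col in ("sample_id", "subject_id", "x", "y"):
        if col not in df.columns:
            raise SchemaError(col)
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            raise RowParseError(f"non-numeric or non-finite coordinate {col!r} at row {df.index[bad][0]}")
        df[col] = vals.astype(float)
    if coord_units == "pixels":
        df["x"] = df["x"] * mpp
        df["y"] = df["y"] * mpp
    markers = tuple(c for c in df.columns if c not in _META_COLUMNS)
    if not markers:
        raise SchemaError("no marker columns found")
    for m in markers:
        df[m] = _coerce_flags(df, m)
    if "compartment" in df.columns:
        comp = df["compartment"].astype(str).str.lower()
        bad = ~comp.isin(COMPARTMENTS)
        if bad.any():
            raise SchemaError(f"invalid compartment value at row {df.index[bad][0]}")
        df["compartment"] = comp
    else:
        df["compartment"] = "unknown"
    tables = []
    keep = ["x", "y", *markers, "compartment"]
    for sample_id, grp in df.groupby("sample_id", sort=True):
        subjects = grp["subject_id"].astype(str).unique()
        if len(subjects) != 1:
            raise SchemaError(f"sample {sample_id!r} maps to multiple subjects {list(subjects)}")
        if len(grp) < 1:  # pragma: no cover - groupby never yields empty groups
            continue
        tables.append(
            CellTable(
                sample_id=str(sample_id),
                subject_id=subjects[0],
                cells=grp[keep].reset_index(drop=True),
                markers=markers,
            )
        )
    return tables


def read_cell_table(path, coord_units: str = "microns", mpp: float = MPP_DEFAULT, sep: str | None = None) -> CellTable:
    """Read a file expected to contain exactly one sample."""
    tables = read_cell_tables(path, coord_units=coord_units, mpp=mpp, sep=sep)
    if len(tables) != 1:
        raise SchemaError(f"expected one sample in {path}, found {len(tables)}")
    return tables[0]


def write_cell_tables(tables: Sequence[CellTable], path, sep: str = "\t") -> None:
    """Write normalised cell tables (micron coordinates) with a units header."""
    frames = []
    for t in tables:
        frame = t.cells.copy()
        frame.insert(0, "subject_id", t.subject_id)
        frame.insert(0, "sample_id", t.sample_id)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    buf = _io.StringIO()
    buf.write("# coordinates: microns\n")
    out.to_csv(buf, sep=sep, index=False, float_format="%.6f")
    Path(path).write_text(buf.getvalue())


def resolve_conflicting_phenotypes(table: CellTable) -> tuple[CellTable, int]:
    """QC for impossible cytotoxic+regulatory double calls.

    A cell flagged both CD8+ and FOXP3+ cannot be both a cytotoxic and a
    regulatory T-cell; its location is retained but its phenotype is demoted
    to CD3+ only (CD3=1, CD8=0, FOXP3=0).  Returns the cleaned table and the
    number of rewritten cells.  Idempotent.
    """
    for m in ("CD3", "CD8", "FOXP3"):
        if m not in table.markers:
            raise SchemaError(f"conflict QC needs marker column {m!r}")
    cells = table.cells.copy()
    conflict = (cells["CD8"] == 1) & (cells["FOXP3"] == 1)
    n = int(conflict.sum())
    if n:
        cells.loc[conflict, "CD3"] = 1
        cells.loc[conflict, "CD8"] = 0
        cells.loc[conflict, "FOXP3"] = 0
    return replace(table, cells=cells), n


def filter_compartment(table: CellTable, compartment: str) -> CellTable:
    """Restrict a sample to one tissue compartment.

    ``"all"`` is the identity.  When the export carried no compartment calls
    (every cell ``unknown``), only ``"all"`` is legal.  The result may be
    empty; downstream stages flag such samples as not estimable.
    """
    if compartment == "all":
        return table
    if compartment not in ("tumor", "stroma"):
        raise ValueError("compartment must be 'tumor', 'stroma' or 'all'")
    comp = table.cells["compartment"]
    if (comp == "unknown").all():
        raise ValueError("table has no compartment calls; only compartment='all' is valid")
    return table.subset((comp == compartment).to_numpy())


def phenotype_positive_cells(table: CellTable, phenotype) -> np.ndarray:
    """(k, 2) micron coordinates of cells positive for every listed marker."""
    return table.coords()[table.positive_mask(phenotype)]


def read_clinical_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read the per-subject clinical table.

    Columns: ``subject_id``, ``time_months`` (> 0), ``event`` (0/1),
    ``age_dx`` (years), ``stage`` (I–IV; arabic numerals accepted).
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    for col in ("subject_id", "time_months", "event", "age_dx", "stage"):
        if col not in df.columns:
            raise SchemaError(col)
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate subject_id {dup!r} in clinical table")
    df["time_months"] = pd.to_numeric(df["time_months"], errors="coerce")
    if (df["time_months"].isna() | (df["time_months"] <= 0)).any():
        raise SchemaError("time_months must be numeric and > 0")
    ev = pd.to_numeric(df["event"], errors="coerce")
    if not ev.isin([0, 1]).all():
        raise SchemaError("event must be 0 or 1")
    df["event"] = ev.astype(int)
    df["age_dx"] = pd.to_numeric(df["age_dx"], errors="coerce")
    if df["age_dx"].isna().any():
        raise SchemaError("age_dx must be numeric")
    arabic = {"1": "I", "2": "II", "3": "III", "4": "IV"}
    stage = df["stage"].astype(str).str.strip().str.upper().replace(arabic)
    if not stage.isin(STAGES).all():
        bad = stage[~stage.isin(STAGES)].iloc[0]
        raise SchemaError(f"invalid stage {bad!r}; expected one of {STAGES}")
    df["stage"] = stage
    return df
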