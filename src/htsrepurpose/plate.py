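"""Plate data model and CSV I/O for dual-readout (luminescence/fluorescence) screens.

The layout of a 96-well screening plate is kept separate from the measured
values: a :class:`PlateLayout` says what each well *is* (library compound,
DMSO vehicle, positive/negative control, empty), while the measurement table
says what each well *read* in a given run (replicate x concentration).
:func:`read_measurements` joins the two into a :class:`ScreenDataset`, the
container every downstream analysis consumes.

Conventions: rows are letters A-H, columns 1-12 (well label "A01"); the
measurement CSV is long-format so replicate and concentration metadata travel
with every row. Loading never silently drops rows -- wells that cannot be
normalized (fluo = 0) are retained but flagged invalid, and the dataset keeps
a load report with the full accounting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import LayoutError, MeasurementError

log = logging.getLogger(__name__)

ROWS = tuple("ABCDEFGH")
COLUMNS = tuple(range(1, 13))
ROLES = ("compound", "vehicle", "positive_control", "negative_control", "empty")
CONTROL_ROLES = ("vehicle", "positive_control", "negative_control")

#: canonical column order of the layout CSV
LAYOUT_COLUMNS = ["row", "column", "role", "compound_id"]
#: canonical column order of the measurement CSV
MEASUREMENT_COLUMNS = [
    "plate_id", "row", "column", "replicate_id", "concentration_uM", "lum", "fluo",
]

_WELL_LABEL = re.compile(r"^([A-H])(\d{1,2})$")


@dataclass(frozen=True)
class WellAddress:
    """A well position: plate, row letter (A-H), 1-based column (1-12)."""

    plate_id: str
    row: str
    column: int

    def __post_init__(self):
        if self.row not in ROWS:
            raise LayoutError(f"row {self.row!r} outside A-H")
        if self.column not in COLUMNS:
            raise LayoutError(f"column {self.column!r} outside 1-12")

    @property
    def label(self) -> str:
        """Plate-reader style label, e.g. ``A01``."""
        return f"{self.row}{self.column:02d}"

    @classmethod
    def from_label(cls, plate_id: str, label: str) -> "WellAddress":
        m = _WELL_LABEL.match(label.strip().upper())
        if not m:
            raise LayoutError(f"malformed well label {label!r}")
        return cls(plate_id, m.group(1), int(m.group(2)))


@dataclass
class PlateLayout:
    """Role map of one plate.

    ``wells`` has columns row, column, role, compound_id (compound_id is
    empty/NaN except for role == compound). A full screening plate carries
    exactly 80 compound wells with controls confined to ``control_columns``.
    """

    plate_id: str
    wells: pd.DataFrame
    control_columns: frozenset = frozenset({1, 12})

    def __post_init__(self):
        self.wells = _normalize_layout_frame(self.wells)
        self.validate()

    def validate(self) -> None:
        df = self.wells
        dup = df.duplicated(subset=["row", "column"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise LayoutError(
                f"plate {self.plate_id}: duplicate well "
                f"{first['row']}{int(first['column']):02d}"
            )
        bad_role = ~df["role"].isin(ROLES)
        if bad_role.any():
            raise LayoutError(
                f"plate {self.plate_id}: unknown role(s) "
                f"{sorted(df.loc[bad_role, 'role'].unique())}"
            )
        is_compound = df["role"] == "compound"
        has_id = df["compound_id"].notna() & (df["compound_id"] != "")
        if (is_compound & ~has_id).any():
            raise LayoutError(f"plate {self.plate_id}: compound well without compound_id")
        if (~is_compound & has_id).any():
            raise LayoutError(f"plate {self.plate_id}: compound_id on a non-compound well")
        control = df["role"].isin(CONTROL_ROLES)
        outside = control & ~df["column"].isin(self.control_columns)
        if outside.any():
            raise LayoutError(
                f"plate {self.plate_id}: control wells outside control columns "
                f"{sorted(self.control_columns)}"
            )

    @property
    def role_counts(self) -> dict:
        return self.wells["role"].value_counts().to_dict()

    @property
    def n_compound_wells(self) -> int:
        return int((self.wells["role"] == "compound").sum())

    @property
    def compound_ids(self) -> list:
        sel = self.wells["role"] == "compound"
        return self.wells.loc[sel, "compound_id"].tolist()

    def is_full_screening_plate(self) -> bool:
        """80 compound wells, controls only in the control columns."""
        return self.n_compound_wells == 80


def _normalize_layout_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"layout missing column(s) {missing}")
    df = df.loc[:, LAYOUT_COLUMNS].copy()
    df["row"] = df["row"].astype(str).str.strip().str.upper()
    df["column"] = pd.to_numeric(df["column"], errors="coerce")
    if df["column"].isna().any():
        raise LayoutError("non-numeric column index in layout")
    df["column"] = df["column"].astype(int)
    if (~df["row"].isin(ROWS)).any() or (~df["column"].isin(COLUMNS)).any():
        raise LayoutError("well address outside the A-H / 1-12 grid")
    df["role"] = df["role"].astype(str).str.strip()
    df["compound_id"] = df["compound_id"].where(df["compound_id"].notna(), None)
    df["compound_id"] = df["compound_id"].map(
        lambda v: None if v is None or str(v).strip() == "" else str(v).strip()
    )
    return df.reset_index(drop=True)


def read_layout(path, plate_id: str | None = None,
                control_columns=(1, 12)) -> PlateLayout:
    """Read a layout CSV (columns row,column,role,compound_id).

    ``plate_id`` defaults to the file stem. Duplicate addresses and unknown
    roles are rejected.
    """
    import pathlib

    path = pathlib.Path(path)
    if plate_id is None:
        plate_id = path.stem
    try:
        df = pd.read_csv(path, dtype={"compound_id": str})
    except pd.errors.EmptyDataError:
        raise LayoutError(f"{path}: empty layout file") from None
    return PlateLayout(plate_id, df, frozenset(control_columns))


def write_layout(layout: PlateLayout, path) -> None:
    """Write a layout back to CSV in the canonical column order."""
    out = layout.wells.loc[:, LAYOUT_COLUMNS].copy()
    out["compound_id"] = out["compound_id"].fillna("")
    out.to_csv(path, index=False)


@dataclass
class ScreenDataset:
    """All well-level measurements of a screen joined to their layouts.

    ``wells`` columns: plate_id, row, column, replicate_id, concentration_uM,
    lum, fluo, role, compound_id, valid. ``load_report`` accounts for every
    input row: rows_read = loaded = valid + invalid (rejected rows raise).
    """

    layouts: dict
    wells: pd.DataFrame
    load_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.load_report:
            n = len(self.wells)
            n_invalid = int((~self.wells["valid"]).sum()) if n else 0
            self.load_report = {"rows_read": n, "loaded": n,
                                "valid": n - n_invalid, "invalid": n_invalid}

    @property
    def concentrations(self) -> list:
        sel = self.wells["role"] == "compound"
        return sorted(self.wells.loc[sel, "concentration_uM"].unique())

    @property
    def replicate_count(self) -> int:
        return int(self.wells["replicate_id"].nunique())

    @property
    def compound_ids(self) -> list:
        out = []
        for layout in self.layouts.values():
            out.extend(layout.compound_ids)
        return out

    def validate(self) -> None:
        dup = self.wells.duplicated(
            subset=["plate_id", "row", "column", "replicate_id", "concentration_uM"]
        )
        if dup.any():
            r = self.wells.loc[dup.idxmax()]
            raise MeasurementError(
                f"duplicate measurement for {r['plate_id']} {r['row']}"
                f"{int(r['column']):02d} replicate {r['replicate_id']} "
                f"at {r['concentration_uM']} uM"
            )


def read_measurements(path, layouts) -> ScreenDataset:
    """Read a long-format measurement CSV and join it to the layouts.

    ``layouts`` is a dict, list, or single :class:`PlateLayout`. Rows whose
    address is absent from the layouts, or with negative readings, are
    rejected with an error; ``fluo == 0`` on a non-empty well is retained but
    flagged invalid (a dead well must not abort a 16-plate run).
    """
    if isinstance(layouts, PlateLayout):
        layouts = [layouts]
    if not isinstance(layouts, dict):
        layouts = {lay.plate_id: lay for lay in layouts}

    try:
        df = pd.read_csv(path, dtype={"plate_id": str})
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise MeasurementError(f"measurement table missing column(s) {missing}")
    if not len(df):
        log.warning("empty measurement table: %s", path)
        empty = pd.DataFrame(columns=MEASUREMENT_COLUMNS + ["role", "compound_id", "valid"])
        return ScreenDataset(layouts, empty,
                             {"rows_read": 0, "loaded": 0, "valid": 0, "invalid": 0})

    n_read = len(df)
    df = df.loc[:, MEASUREMENT_COLUMNS].copy()
    df["row"] = df["row"].astype(str).str.strip().str.upper()
    df["column"] = df["column"].astype(int)
    for col in ("lum", "fluo", "concentration_uM"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    if (df[["lum", "fluo"]] < 0).any().any():
        raise MeasurementError("negative lum/fluo reading")
    if (df["concentration_uM"] < 0).any():
        raise MeasurementError("negative concentration")

    # join roles from the layouts
    frames = []
    for pid, sub in df.groupby("plate_id", sort=False):
        if pid not in layouts:
            raise MeasurementError(f"plate {pid!r} has no layout")
        lay = layouts[pid].wells
        merged = sub.merge(lay, on=["row", "column"], how="left", validate="many_to_one")
        unknown = merged["role"].isna()
        if unknown.any():
            r = merged.loc[unknown.idxmax()]
            raise MeasurementError(
                f"well {r['row']}{int(r['column']):02d} not in layout of plate {pid}"
            )
        frames.append(merged)
    out = pd.concat(frames, ignore_index=True)

    out["valid"] = ~((out["fluo"] == 0) & (out["role"] != "empty"))
    n_invalid = int((~out["valid"]).sum())
    if n_invalid:
        log.warning("%d well(s) with fluo=0 flagged invalid", n_invalid)

    ds = ScreenDataset(layouts, out,
                       {"rows_read": n_read, "loaded": len(out),
                        "valid": len(out) - n_invalid, "invalid": n_invalid})
    ds.validate()
    return ds


def write_measurements(dataset: ScreenDataset, path) -> None:
    dataset.wells.loc[:, MEASUREMENT_COLUMNS].to_csv(path, index=False)


def write_results(path, table: pd.DataFrame) -> None:
    """Write any tabular result as UTF-8 CSV with a stable column order."""
    table.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
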