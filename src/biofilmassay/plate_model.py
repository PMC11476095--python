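"""Domain types, validation, and tidy readers/writers for 96-well assay data.

Data flows through the package as tidy :class:`pandas.DataFrame` tables with
fixed column schemas (one absorbance measurement per row), the way plate-reader
exports are usually munged in practice.  Two tables describe an experiment:

``readings``
    one row per (plate, well, channel, timepoint, stage) absorbance value;
    columns :data:`READING_COLUMNS`.

``layout``
    one row per plate well, mapping it to a role (sample / sterility control /
    reference control), an isolate, an assay condition and replicate indices;
    columns :data:`LAYOUT_COLUMNS`.

Wells use the SBS convention: row letter A-H plus 1-based column 1-12.
Absorbance values may legitimately be negative after instrument blanking and
are never clamped on input.  Files are UTF-8 CSV with "." as decimal point.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGH"
N_PLATE_COLUMNS = 12
_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


class Channel(str, enum.Enum):
    """Absorbance channel of the plate reader."""

    OD570 = "OD570"
    OD600 = "OD600"


class Stage(str, enum.Enum):
    """Measurement stage within one assay plate.

    ``growth_endpoint``: crystal-violet read after biofilm staining.
    ``rz_baseline``: resazurin read immediately after dye addition (oxidized).
    ``rz_final``: resazurin read after the reduction incubation.
    """

    GROWTH_ENDPOINT = "growth_endpoint"
    RZ_BASELINE = "rz_baseline"
    RZ_FINAL = "rz_final"


class Role(str, enum.Enum):
    SAMPLE = "sample"
    STERILITY_CONTROL = "sterility_control"
    REFERENCE_CONTROL = "reference_control"


#: Factors of the incubation-condition design.  ``baseline`` is growth medium
#: at 37 degC with no additional stressor and carries no level.
FACTORS = ("baseline", "temperature", "nacl", "ph")

#: The condition grid of the study design (levels per stress factor):
#: temperature in degC, NaCl in % w/v, pH in pH units.
DESIGN_GRID = {
    "temperature": (4.0, 10.0, 20.0, 37.0),
    "nacl": (1.0, 2.0, 4.0, 8.0),
    "ph": (5.0, 6.0, 7.0, 8.0, 9.0),
}

READING_COLUMNS = ["plate_id", "well", "channel", "timepoint_h", "stage", "absorbance"]
READING_KEY = ["plate_id", "well", "channel", "timepoint_h", "stage"]
LAYOUT_COLUMNS = ["plate_id", "well", "role", "isolate_id", "factor", "level", "bio_rep", "tech_rep"]

#: Grouping key identifying one isolate x condition x timepoint cell.
CELL_KEY = ["isolate_id", "factor", "level", "timepoint_h"]


@dataclass(frozen=True)
class AssayCondition:
    """One incubation condition: a stress factor and its level.

    ``baseline`` has ``level=None``; other factors carry a numeric level
    (degC, % NaCl, or pH units).
    """

    factor: str
    level: float | None = None

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}; expected one of {FACTORS}")
        if self.factor == "baseline":
            if self.level is not None:
                raise ValueError("baseline condition carries no level")
        elif self.level is None:
            raise ValueError(f"factor {self.factor!r} requires a level")

    @property
    def label(self) -> str:
        if self.factor == "baseline":
            return "baseline"
        return f"{self.factor}:{self.level:g}"

    def in_design_grid(self) -> bool:
        if self.factor == "baseline":
            return True
        return self.level in DESIGN_GRID[self.factor]

    @classmethod
    def from_label(cls, label: str) -> "AssayCondition":
        if label == "baseline":
            return cls("baseline")
        factor, _, level = label.partition(":")
        return cls(factor, float(level))


def condition_label(factor: str, level: float | None) -> str:
    """Human-readable label for a (factor, level) pair; NaN level == None."""
    if factor == "baseline" or level is None or (isinstance(level, float) and np.isnan(level)):
        return str(factor) if factor != "baseline" else "baseline"
    return f"{factor}:{level:g}"


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    message: str
    location: str


@dataclass
class ValidationReport:
    """Outcome of structural cross-checks between readings and layout.

    An empty issue list means the dataset passed all checks.
    """

    issues: list[ValidationIssue]

    @property
    def ok(self) -> bool:
        return not self.issues

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    def raise_on_error(self) -> None:
        errs = self.errors()
        if errs:
            lines = "; ".join(f"{i.location}: {i.message}" for i in errs[:10])
            raise ValueError(f"{len(errs)} validation error(s): {lines}")


def well_sort_key(well: str) -> tuple[int, int]:
    return (ROW_LETTERS.index(well[0]), int(well[1:]))


def well_name(index: int) -> str:
    """Row-major well name for a 0-based position on an 8x12 plate."""
    if not 0 <= index < 8 * N_PLATE_COLUMNS:
        raise ValueError(f"well index {index} outside the 96-well grid")
    return f"{ROW_LETTERS[index // N_PLATE_COLUMNS]}{index % N_PLATE_COLUMNS + 1}"


def _first_bad_line(mask: pd.Series) -> int:
    # +2: one for the header line, one for 0-based positional index
    return int(np.flatnonzero(mask.to_numpy())[0]) + 2


def read_plate_long(path: str | Path) -> pd.DataFrame:
    """Read a long-format readings CSV into the canonical readings table.

    Raises ``ValueError`` naming the offending line for malformed rows, and on
    duplicated (plate, well, channel, timepoint, stage) keys.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "channel": str, "stage": str},
                     encoding="utf-8")
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"readings file {path} lacks column(s) {missing}")
    df = df[READING_COLUMNS].copy()
    if df.empty:
        df["timepoint_h"] = df["timepoint_h"].astype(float)
        df["absorbance"] = df["absorbance"].astype(float)
        return df

    bad_well = ~df["well"].astype(str).str.match(_WELL_RE)
    if bad_well.any():
        raise ValueError(f"line {_first_bad_line(bad_well)}: well {df.loc[bad_well.idxmax(), 'well']!r} "
                         "is not a valid A1-H12 coordinate")
    bad_channel = ~df["channel"].isin([c.value for c in Channel])
    if bad_channel.any():
        raise ValueError(f"line {_first_bad_line(bad_channel)}: unknown channel "
                         f"{df.loc[bad_channel.idxmax(), 'channel']!r}")
    bad_stage = ~df["stage"].isin([s.value for s in Stage])
    if bad_stage.any():
        raise ValueError(f"line {_first_bad_line(bad_stage)}: unknown stage "
                         f"{df.loc[bad_stage.idxmax(), 'stage']!r}")

    df["timepoint_h"] = pd.to_numeric(df["timepoint_h"], errors="coerce")
    bad_tp = df["timepoint_h"].isna() | (df["timepoint_h"] <= 0)
    if bad_tp.any():
        raise ValueError(f"line {_first_bad_line(bad_tp)}: timepoint_h must be a positive number")
    df["absorbance"] = pd.to_numeric(df["absorbance"], errors="coerce")
    bad_abs = ~np.isfinite(df["absorbance"].to_numpy())
    if bad_abs.any():
        raise ValueError(f"line {_first_bad_line(pd.Series(bad_abs))}: absorbance must be finite")

    dup = df.duplicated(READING_KEY, keep=False)
    if dup.any():
        key = tuple(df.loc[dup.idxmax(), READING_KEY])
        raise ValueError(f"duplicate reading key {key} (first at line {_first_bad_line(dup)})")
    return df


def read_plate_grid(path: str | Path, plate_id: str, channel: str, timepoint_h: float,
                    stage: str) -> pd.DataFrame:
    """Convert an 8x12 grid CSV export (rows A-H, columns 1-12) to the long table.

    The grid carries a single plate/channel/timepoint/stage, supplied by the
    caller; empty cells are skipped.
    """
    grid = pd.read_csv(path, index_col=0, encoding="utf-8")
    records = []
    for row_letter, row in grid.iterrows():
        for col, value in row.items():
            if pd.isna(value):
                continue
            records.append({"plate_id": plate_id, "well": f"{row_letter}{int(col)}",
                            "channel": channel, "timepoint_h": float(timepoint_h),
                            "stage": stage, "absorbance": float(value)})
    out = pd.DataFrame(records, columns=READING_COLUMNS)
    bad = ~out["well"].str.match(_WELL_RE)
    if bad.any():
        raise ValueError(f"grid file {path}: invalid well {out.loc[bad.idxmax(), 'well']!r}")
    return out


def read_layout(path: str | Path) -> pd.DataFrame:
    """Read a plate-layout CSV and enforce the layout invariants.

    Every sample well must name an isolate; every plate must contain at least
    one sterility-control well (required downstream for the ODc cutoff); the
    (isolate, condition, bio_rep, tech_rep) key must be unique within a plate.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str,
                                  "isolate_id": str, "factor": str},
                     encoding="utf-8")
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"layout file {path} lacks column(s) {missing}")
    df = df[LAYOUT_COLUMNS].copy()
    df["isolate_id"] = df["isolate_id"].fillna("")
    df["level"] = pd.to_numeric(df["level"], errors="coerce")
    if df.empty:
        raise ValueError(f"layout file {path} is empty")

    bad_well = ~df["well"].astype(str).str.match(_WELL_RE)
    if bad_well.any():
        raise ValueError(f"line {_first_bad_line(bad_well)}: invalid well coordinate")
    bad_role = ~df["role"].isin([r.value for r in Role])
    if bad_role.any():
        raise ValueError(f"line {_first_bad_line(bad_role)}: unknown role "
                         f"{df.loc[bad_role.idxmax(), 'role']!r}")
    bad_factor = ~df["factor"].isin(FACTORS)
    if bad_factor.any():
        raise ValueError(f"line {_first_bad_line(bad_factor)}: unknown factor "
                         f"{df.loc[bad_factor.idxmax(), 'factor']!r}")
    for col in ("bio_rep", "tech_rep"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].isna() | (df[col] < 1) | (df[col] % 1 != 0)
        if bad.any():
            raise ValueError(f"line {_first_bad_line(bad)}: {col} must be an integer >= 1")
        df[col] = df[col].astype(int)

    samples = df[df["role"] == Role.SAMPLE.value]
    anon = samples["isolate_id"] == ""
    if anon.any():
        raise ValueError(f"line {_first_bad_line(anon.reindex(df.index, fill_value=False))}: "
                         "sample well without isolate_id")
    plates_without_control = set(df["plate_id"]) - set(
        df.loc[df["role"] == Role.STERILITY_CONTROL.value, "plate_id"])
    if plates_without_control:
        raise ValueError(
            f"plate(s) {sorted(plates_without_control)} have no sterility_control well "
            "(sterility control required for ODc)")
    dup_well = df.duplicated(["plate_id", "well"], keep=False)
    if dup_well.any():
        raise ValueError(f"duplicate (plate_id, well) at line {_first_bad_line(dup_well)}")
    dup_key = samples.duplicated(["plate_id", "isolate_id", "factor", "level", "bio_rep", "tech_rep"],
                                 keep=False)
    if dup_key.any():
        raise ValueError("duplicate (isolate, condition, bio_rep, tech_rep) sample key "
                         f"within a plate, first at line {_first_bad_line(dup_key.reindex(df.index, fill_value=False))}")
    return df


def validate(readings: pd.DataFrame, layout: pd.DataFrame) -> ValidationReport:
    """Cross-check readings against the layout; report, never raise.

    Errors: a reading whose (plate, well) is absent from the layout; a sample
    well with no growth-endpoint reading.  Warnings: a plate carrying
    resazurin-final reads but no resazurin-baseline read for its sterility
    wells (the per-plate Ro factor is then not computable).
    """
    issues: list[ValidationIssue] = []
    layout_wells = set(map(tuple, layout[["plate_id", "well"]].itertuples(index=False)))
    read_wells = readings[["plate_id", "well"]].drop_duplicates()
    for plate, well in read_wells.itertuples(index=False):
        if (plate, well) not in layout_wells:
            issues.append(ValidationIssue("error", "reading from a well absent from the layout",
                                          f"{plate}:{well}"))

    growth = readings[readings["stage"] == Stage.GROWTH_ENDPOINT.value]
    growth_wells = set(map(tuple, growth[["plate_id", "well"]].itertuples(index=False)))
    samples = layout[layout["role"] == Role.SAMPLE.value]
    for plate, well in samples[["plate_id", "well"]].itertuples(index=False):
        if (plate, well) not in growth_wells:
            issues.append(ValidationIssue("error", "sample well has no growth_endpoint reading",
                                          f"{plate}:{well}"))

    rz_final_plates = set(readings.loc[readings["stage"] == Stage.RZ_FINAL.value, "plate_id"])
    sterility = layout[layout["role"] == Role.STERILITY_CONTROL.value]
    baseline = readings[readings["stage"] == Stage.RZ_BASELINE.value]
    baseline_wells = set(map(tuple, baseline[["plate_id", "well"]].itertuples(index=False)))
    for plate in sorted(rz_final_plates):
        plate_controls = sterility.loc[sterility["plate_id"] == plate, "well"]
        if not any((plate, w) in baseline_wells for w in plate_controls):
            issues.append(ValidationIssue(
                "warning", "plate has rz_final readings but no rz_baseline sterility read "
                "(Ro not computable)", plate))
    return ValidationReport(issues)


def write_tidy(table: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as a TSV with header; round-trips via read_tidy."""
    if table is None:
        raise ValueError("cannot write a null table")
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
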