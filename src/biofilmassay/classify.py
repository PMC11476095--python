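"""Sterility-based cutoffs and four-class biofilm-producer categories.

The cutoff ODc for a condition is derived from its sterility-control wells:

    ODc = mean(control OD) + 3 * SD(control OD)

and isolates are binned by their mean crystal-violet OD570 relative to ODc:

    non-producer (NP)       OD <= ODc
    weak producer (WP)      ODc < OD <= 2*ODc
    moderate producer (MP)  2*ODc < OD <= 4*ODc
    strong producer (SP)    OD > 4*ODc

The published inequalities are strict on both sides and leave the exact
boundaries unassigned; this module adopts half-open bands (boundary value goes
to the lower class) so that classification is deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate_model import CELL_KEY, Channel, Role, Stage, condition_label


class ProducerClass(enum.IntEnum):
    """Producer category, ordered NP < WP < MP < SP."""

    NP = 0
    WP = 1
    MP = 2
    SP = 3

    @classmethod
    def from_label(cls, label: str) -> "ProducerClass":
        return cls[label.strip().replace(".", "").upper()]


CLASS_LABELS = [c.name for c in ProducerClass]


@dataclass(frozen=True)
class CutoffRecord:
    """ODc cutoff for one condition x timepoint (or a pooled dataset)."""

    control_mean: float
    control_sd: float
    odc: float
    n_controls: int
    factor: str | None = None
    level: float | None = None
    timepoint_h: float | None = None


def compute_cutoff(control_ods: Sequence[float], **key) -> CutoffRecord:
    """ODc = mean + 3*SD of the sterility-control ODs (sample SD, n-1).

    A single control well has SD 0 by convention, so ODc equals its OD.
    """
    values = np.asarray(list(control_ods), dtype=float)
    if values.size == 0:
        raise ValueError("cannot compute a cutoff from an empty control list")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return CutoffRecord(control_mean=mean, control_sd=sd, odc=mean + 3.0 * sd,
                        n_controls=int(values.size), **key)


def cutoff_table(readings: pd.DataFrame, layout: pd.DataFrame, pool: bool = False) -> pd.DataFrame:
    """Cutoffs from growth-endpoint OD570 of sterility wells.

    By default one cutoff per condition x timepoint (controls pooled over the
    replicate plates of that condition).  With ``pool=True`` a single cutoff is
    computed from every sterility well in the dataset and broadcast to all
    condition x timepoint cells present.
    """
    controls = layout[layout["role"] == Role.STERILITY_CONTROL.value]
    growth = readings[(readings["stage"] == Stage.GROWTH_ENDPOINT.value)
                      & (readings["channel"] == Channel.OD570.value)]
    merged = growth.merge(controls, on=["plate_id", "well"], how="inner")
    if merged.empty:
        raise ValueError("no growth_endpoint sterility-control readings found")

    def _one(group: pd.DataFrame) -> pd.Series:
        rec = compute_cutoff(group["absorbance"])
        return pd.Series({"control_mean": rec.control_mean, "control_sd": rec.control_sd,
                          "odc": rec.odc, "n_controls": rec.n_controls})

    if pool:
        rec = compute_cutoff(merged["absorbance"])
        cells = merged[["factor", "level", "timepoint_h"]].drop_duplicates()
        out = cells.assign(control_mean=rec.control_mean, control_sd=rec.control_sd,
                           odc=rec.odc, n_controls=rec.n_controls)
    else:
        out = (merged.groupby(["factor", "level", "timepoint_h"], dropna=False)
               .apply(_one, include_groups=False).reset_index())
        out["n_controls"] = out["n_controls"].astype(int)
    return out.reset_index(drop=True)


def classify_od(od: float, odc: float) -> ProducerClass:
    """Assign a producer class from one OD value against the cutoff ODc."""
    if not odc > 0:
        raise ValueError(f"ODc must be positive, got {odc}")
    if od <= odc:
        return ProducerClass.NP
    if od <= 2.0 * odc:
        return ProducerClass.WP
    if od <= 4.0 * odc:
        return ProducerClass.MP
    return ProducerClass.SP


def classify_all(cv_summary: pd.DataFrame, cutoffs: pd.DataFrame) -> pd.DataFrame:
    """Classify each isolate x condition x timepoint from its mean OD.

    ``cv_summary`` is an aggregate table (see :func:`quantify.aggregate_wells`)
    with ``mean_od``; ``cutoffs`` comes from :func:`cutoff_table`.  Raises if
    any summary key lacks a matching cutoff.
    """
    merged = cv_summary.merge(cutoffs[["factor", "level", "timepoint_h", "odc"]],
                              on=["factor", "level", "timepoint_h"], how="left")
    missing = merged["odc"].isna()
    if missing.any():
        row = merged.loc[missing.idxmax()]
        key = (row["isolate_id"], condition_label(row["factor"], row["level"]), row["timepoint_h"])
        raise ValueError(f"no cutoff for summary key {key}")
    merged["producer_class"] = [
        classify_od(od, odc).name for od, odc in zip(merged["mean_od"], merged["odc"])
    ]
    cols = CELL_KEY + ["mean_od", "odc", "producer_class"]
    return merged[cols].reset_index(drop=True)


def _select(table: pd.DataFrame, timepoint_h: float, factor: str, level: float | None) -> pd.DataFrame:
    sel = table[(table["timepoint_h"] == timepoint_h) & (table["factor"] == factor)]
    if factor != "baseline" and level is not None:
        sel = sel[sel["level"] == level]
    return sel


def tally(table: pd.DataFrame, timepoint_h: float, factor: str = "baseline",
          level: float | None = None) -> dict[str, int]:
    """Producer-class counts at one condition x timepoint; all classes reported."""
    sel = _select(table, timepoint_h, factor, level)
    counts = sel["producer_class"].value_counts()
    return {label: int(counts.get(label, 0)) for label in CLASS_LABELS}


def tally_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long tally of every condition x timepoint present in a classification table."""
    rows = []
    cells = table[["factor", "level", "timepoint_h"]].drop_duplicates()
    for factor, level, tp in cells.itertuples(index=False):
        lv = None if pd.isna(level) else level
        counts = tally(table, tp, factor, lv)
        for label, n in counts.items():
            rows.append({"factor": factor, "level": level, "timepoint_h": tp,
                         "producer_class": label, "count": n})
    return pd.DataFrame(rows)


def cross_tab(table: pd.DataFrame, timepoint_a: float = 24.0, timepoint_b: float = 48.0,
              factor: str = "baseline", level: float | None = None) -> pd.DataFrame:
    """4x4 cross-tabulation of producer classes between two timepoints.

    Cell (i, j) holds the sorted tuple of isolates classified *i* at the first
    timepoint and *j* at the second; every isolate present at both timepoints
    appears in exactly one cell.
    """
    a = _select(table, timepoint_a, factor, level).set_index("isolate_id")["producer_class"]
    b = _select(table, timepoint_b, factor, level).set_index("isolate_id")["producer_class"]
    if a.empty or b.empty:
        raise ValueError(f"both timepoints {timepoint_a} and {timepoint_b} must be present")
    shared = a.index.intersection(b.index)
    grid = pd.DataFrame([[() for _ in CLASS_LABELS] for _ in CLASS_LABELS],
                        index=CLASS_LABELS, columns=CLASS_LABELS)
    cells: dict[tuple[str, str], list[str]] = {}
    for iso in shared:
        cells.setdefault((a[iso], b[iso]), []).append(iso)
    for (ca, cb), isolates in cells.items():
        grid.loc[ca, cb] = tuple(sorted(isolates))
    grid.index.name = f"{timepoint_a:g}h"
    grid.columns.name = f"{timepoint_b:g}h"
    return grid


def ever_producer(table: pd.DataFrame) -> set[str]:
    """Isolates classified as a producer (non-NP) in at least one cell."""
    mask = table["producer_class"] != ProducerClass.NP.name
    return set(table.loc[mask, "isolate_id"])
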