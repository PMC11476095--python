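"""Biofilm absorbance per viable cell and condition-level summaries.

The index divides the crystal-violet biomass signal by the corrected
resazurin viability signal (AR570) of the same isolate x condition x
timepoint cell.  Cells whose viability is non-detectable have no defined
index and are flagged (the "asterisk" cells); they are excluded from every
average rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import CELL_KEY

logger = logging.getLogger(__name__)

UNDEFINED_NONE = "none"
UNDEFINED_NONDETECTABLE = "nondetectable_viability"


@dataclass(frozen=True)
class IndexRecord:
    """CV-OD per AR570 unit, or undefined when viability was not detectable."""

    index: float | None
    undefined_reason: str = UNDEFINED_NONE

    @property
    def defined(self) -> bool:
        return self.index is not None


def biofilm_per_viable(cv_mean: float, ar570: float, detectable: bool) -> IndexRecord:
    """Index for one cell: cv_mean / ar570 when viability is detectable."""
    if not detectable:
        return IndexRecord(None, UNDEFINED_NONDETECTABLE)
    return IndexRecord(cv_mean / ar570)


def index_table(cv_summary: pd.DataFrame, viability: pd.DataFrame) -> pd.DataFrame:
    """Join CV means with viability records and compute the per-cell index.

    Output columns: the cell key, ``cv_mean``, ``ar570``, ``detectable``,
    ``index`` (NaN when undefined) and ``undefined_reason``.
    """
    merged = cv_summary[CELL_KEY + ["mean_od"]].rename(columns={"mean_od": "cv_mean"}).merge(
        viability[CELL_KEY + ["ar570", "detectable"]], on=CELL_KEY, how="inner")
    merged["index"] = np.where(merged["detectable"], merged["cv_mean"] / merged["ar570"], np.nan)
    merged["undefined_reason"] = np.where(merged["detectable"], UNDEFINED_NONE,
                                          UNDEFINED_NONDETECTABLE)
    return merged.sort_values(CELL_KEY, na_position="first").reset_index(drop=True)


def condition_average(indices: pd.DataFrame) -> pd.DataFrame:
    """Mean defined index per condition x timepoint over isolates.

    Undefined cells are excluded from both numerator and denominator; a cell
    key with no defined index at all gets a NaN average and a log warning.
    """
    keys = ["factor", "level", "timepoint_h"]
    grouped = indices.groupby(keys, dropna=False)["index"]
    out = grouped.agg(average="mean", n_defined="count", n_total="size").reset_index()
    empty = out["n_defined"] == 0
    if empty.any():
        logger.warning("%d condition cell(s) have no defined per-cell index", int(empty.sum()))
    return out.sort_values(keys, na_position="first").reset_index(drop=True)


def flag_max_conditions(averages: pd.DataFrame, per_factor: bool = True,
                        per_timepoint: bool = True) -> set[tuple[str, float, float]]:
    """Conditions with the highest average index; ties all flagged.

    The argmax is taken within each factor family (temperature / NaCl / pH /
    baseline) and, by default, separately per timepoint, matching how the
    highest-production conditions are highlighted per assay panel.  Returns a
    set of (factor, level, timepoint_h) tuples (level is NaN for baseline).
    """
    if averages.empty:
        raise ValueError("cannot flag maxima of an empty average table")
    defined = averages.dropna(subset=["average"])
    group_cols = []
    if per_factor:
        group_cols.append("factor")
    if per_timepoint:
        group_cols.append("timepoint_h")
    flagged: set[tuple[str, float, float]] = set()
    groups = defined.groupby(group_cols, dropna=False) if group_cols else [((), defined)]
    for _, group in groups:
        if group.empty:
            continue
        top = group["average"].max()
        best = group[group["average"] == top]
        for factor, level, tp in best[["factor", "level", "timepoint_h"]].itertuples(index=False):
            flagged.add((factor, float(level) if pd.notna(level) else float("nan"), float(tp)))
    return flagged
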