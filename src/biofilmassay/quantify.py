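"""Replicate aggregation and the resazurin viability correction.

Viable biofilm cells reduce resazurin (blue) to resorufin (pink).  When only
absorbance (not fluorescence) is available, the reduced-dye signal is
recovered from the 570 nm read by subtracting the oxidized-dye contribution
estimated from the 600 nm read:

    AR570 = (OD570 - OD600 * Ro) * 100

where Ro = OD570/OD600 of the oxidized substrate, measured on sterility wells
at the resazurin-baseline stage of the same plate.  AR570 is on a percent-like
scale; values <= 0 mean no detectable reduction and are stored as 0 with
``detectable=False`` (the "asterisk" rule for non-quantifiable viability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_model import CELL_KEY, Channel, Role, Stage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RoFactor:
    """Oxidized-substrate 570/600 nm absorbance ratio for one plate."""

    plate_id: str
    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"Ro must be positive, got {self.value}")


@dataclass(frozen=True)
class ViabilityValue:
    """Corrected reduced-resazurin signal; clamped at 0 when non-detectable."""

    ar570: float
    detectable: bool


def aggregate_wells(readings: pd.DataFrame, layout: pd.DataFrame, channel: str,
                    stage: str, by_bio_rep: bool = False) -> pd.DataFrame:
    """Mean/SD of one channel+stage over the replicate wells of each cell.

    Groups sample wells by isolate x condition x timepoint (optionally also by
    biological replicate) and reports ``n_wells``, ``mean_od`` and ``sd_od``
    (sample SD, 0 for a single well).  Isolates in the layout with no reading
    for the requested channel/stage are omitted with a log warning.
    """
    samples = layout[layout["role"] == Role.SAMPLE.value]
    sel = readings[(readings["channel"] == channel) & (readings["stage"] == stage)]
    merged = sel.merge(samples, on=["plate_id", "well"], how="inner")
    keys = CELL_KEY + (["bio_rep"] if by_bio_rep else [])
    grouped = merged.groupby(keys, dropna=False)["absorbance"]
    out = grouped.agg(n_wells="size", mean_od="mean", sd_od="std").reset_index()
    out["sd_od"] = out["sd_od"].fillna(0.0)
    out["channel"] = channel
    out["stage"] = stage

    missing = set(samples["isolate_id"]) - set(out["isolate_id"])
    if missing:
        logger.warning("omitting %d isolate(s) with no %s/%s readings: %s",
                       len(missing), channel, stage, sorted(missing)[:5])
    return out.sort_values(keys, na_position="first").reset_index(drop=True)


def compute_ro(od570, od600) -> float:
    """Ro = mean(OD570) / mean(OD600) over oxidized-substrate wells."""
    num = float(np.mean(np.asarray(od570, dtype=float)))
    den = float(np.mean(np.asarray(od600, dtype=float)))
    if den <= 0:
        raise ValueError(f"Ro undefined: mean OD600 of the oxidized substrate is {den}")
    return num / den


def ro_by_plate(readings: pd.DataFrame, layout: pd.DataFrame) -> dict[str, RoFactor]:
    """Per-plate Ro from sterility wells at the resazurin-baseline stage."""
    controls = layout[layout["role"] == Role.STERILITY_CONTROL.value]
    base = readings[readings["stage"] == Stage.RZ_BASELINE.value]
    merged = base.merge(controls, on=["plate_id", "well"], how="inner")
    factors: dict[str, RoFactor] = {}
    for plate, group in merged.groupby("plate_id"):
        wide = group.pivot_table(index="well", columns="channel", values="absorbance")
        if Channel.OD570.value not in wide or Channel.OD600.value not in wide:
            raise ValueError(f"plate {plate}: rz_baseline sterility wells need both "
                             "OD570 and OD600 readings")
        factors[plate] = RoFactor(plate, compute_ro(wide[Channel.OD570.value],
                                                    wide[Channel.OD600.value]))
    return factors


def compute_ar570(od570: float, od600: float, ro: float | RoFactor) -> ViabilityValue:
    """Apply the oxidized-substrate correction to one 570/600 nm pair."""
    r = ro.value if isinstance(ro, RoFactor) else float(ro)
    raw = (od570 - od600 * r) * 100.0
    detectable = raw > 0
    return ViabilityValue(ar570=raw if detectable else 0.0, detectable=detectable)


def viability_table(readings: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """One viability record per isolate x condition x timepoint.

    Each sample well's resazurin-final pair is corrected with its own plate's
    Ro; the unclamped per-well values are averaged over all replicate wells of
    the cell, then the aggregate is clamped and flagged.  Averaging before
    clamping keeps the correction linear; the detectability flag refers to the
    aggregated value.
    """
    ro = ro_by_plate(readings, layout)
    samples = layout[layout["role"] == Role.SAMPLE.value]
    final = readings[readings["stage"] == Stage.RZ_FINAL.value]
    merged = final.merge(samples, on=["plate_id", "well"], how="inner")
    if merged.empty:
        raise ValueError("no rz_final readings for sample wells")
    # NaN levels (baseline) would be dropped from the pivot index; mask them
    merged = merged.assign(level=merged["level"].fillna(np.inf))
    wide = merged.pivot_table(index=["plate_id", "well"] + CELL_KEY, columns="channel",
                              values="absorbance").reset_index()
    wide["level"] = wide["level"].replace(np.inf, np.nan)
    for ch in (Channel.OD570.value, Channel.OD600.value):
        if ch not in wide or wide[ch].isna().any():
            bad = wide.loc[wide[ch].isna()] if ch in wide else wide
            key = tuple(bad.iloc[0][["plate_id", "well"]]) if len(bad) else ("?", "?")
            raise ValueError(f"missing {ch} rz_final reading for well {key}")
    missing_ro = set(wide["plate_id"]) - set(ro)
    if missing_ro:
        raise ValueError(f"no Ro factor computable for plate(s) {sorted(missing_ro)}")

    ro_values = wide["plate_id"].map({p: f.value for p, f in ro.items()})
    wide["ar570_raw"] = (wide[Channel.OD570.value]
                         - wide[Channel.OD600.value] * ro_values) * 100.0
    agg = (wide.groupby(CELL_KEY, dropna=False)["ar570_raw"].mean().reset_index())
    agg["detectable"] = agg["ar570_raw"] > 0
    agg["ar570"] = agg["ar570_raw"].where(agg["detectable"], 0.0)
    return (agg[CELL_KEY + ["ar570", "detectable"]]
            .sort_values(CELL_KEY, na_position="first").reset_index(drop=True))
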