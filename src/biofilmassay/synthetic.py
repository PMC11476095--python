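"""Synthetic 96-well plate datasets with known producer-class ground truth.

The generator emulates the study design end to end: a panel of isolates with
a latent producer class per condition x timepoint, assayed over three
independent days (biological replicates) with three wells per plate
(technical replicates), plus per-plate sterility-control wells.  Each
condition x timepoint x day is one plate (the crystal-violet stain is
destructive, so 24 h and 48 h reads come from separate plates).

Signal model
------------
* Sterility wells: crystal-violet OD ~ Normal(control_mean, control_sd)
  truncated at 0.  The implied cutoff is ODc = control_mean + 3*control_sd.
* Sample wells: OD = multiplier(class) * ODc * lognormal noise with overall
  coefficient of variation ``noise_cv``, split into a per-day (biological)
  and a per-well (technical) component with a 2:1 variance ratio.  The noise
  is mean-one, so the expected OD sits at the class multiplier times ODc.
* Resazurin: baseline reads share the exact oxidized-substrate ratio ``ro``
  (OD570 = ro * OD600), so the per-plate correction factor is recovered
  exactly; final reads add a reduced-dye term such that the corrected AR570
  of a sample well is ``viability_slope`` times its expected crystal-violet
  signal, with the same multiplicative noise law.  Sterile wells gain no
  reduced dye, so their corrected AR570 is 0.

All randomness flows from the mandatory design seed; the same design produces
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import datasets
from .plate_model import (AssayCondition, DESIGN_GRID, READING_COLUMNS, LAYOUT_COLUMNS,
                          Channel, Role, Stage, condition_label, well_name)

#: Multiplier bands implied by the producer-class thresholds: a class
#: multiplier places the expected OD inside its band of ODc.
CLASS_BANDS = {"NP": (0.0, 1.0), "WP": (1.0, 2.0), "MP": (2.0, 4.0), "SP": (4.0, math.inf)}

DEFAULT_MULTIPLIERS = {"NP": 0.5, "WP": 1.5, "MP": 3.0, "SP": 6.0}


@dataclass(frozen=True)
class ExperimentDesign:
    """Complete specification of a synthetic assay experiment.

    ``truth`` maps every isolate x condition x timepoint cell to its latent
    producer class (columns: isolate_id, factor, level, timepoint_h,
    producer_class) and must cover exactly the design grid.
    """

    truth: pd.DataFrame
    conditions: tuple[AssayCondition, ...]
    timepoints: tuple[float, ...] = (24.0, 48.0)
    n_bio: int = 3
    n_tech: int = 3
    control_mean: float = 0.10
    control_sd: float = 0.02
    class_multipliers: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MULTIPLIERS))
    noise_cv: float = 0.15
    bio_noise_share: float = 2.0 / 3.0  # share of log-variance carried by the day effect
    viability_slope: float = 50.0       # AR570 units per CV-OD unit
    ro: float = 1.25                    # oxidized resazurin OD570/OD600 ratio
    rz_od600: float = 0.40              # typical oxidized-dye OD600 level
    rz_od600_cv: float = 0.05
    n_control_wells: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def isolate_ids(self) -> list[str]:
        return list(dict.fromkeys(self.truth["isolate_id"]))

    @property
    def implied_odc(self) -> float:
        return self.control_mean + 3.0 * self.control_sd

    def validate(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if not (self.control_mean > 0 and self.control_sd > 0):
            raise ValueError("control_mean and control_sd must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        order = ["NP", "WP", "MP", "SP"]
        mults = [self.class_multipliers[c] for c in order]
        if sorted(mults) != mults or len(set(mults)) != 4:
            raise ValueError("class multipliers must be strictly ordered NP < WP < MP < SP")
        for cls, m in self.class_multipliers.items():
            lo, hi = CLASS_BANDS[cls]
            in_band = (m > lo) if hi == math.inf else (lo < m < hi)
            if not in_band:
                raise ValueError(f"multiplier {m} for class {cls} outside its band {CLASS_BANDS[cls]}")

        expected = {(c.label, tp) for c in self.conditions for tp in self.timepoints}
        got = {(condition_label(f, None if pd.isna(l) else l), tp)
               for f, l, tp in self.truth[["factor", "level", "timepoint_h"]]
               .drop_duplicates().itertuples(index=False)}
        if expected != got:
            raise ValueError("truth table does not cover exactly the design grid")
        per_cell = self.truth.groupby(["factor", "level", "timepoint_h"], dropna=False)["isolate_id"]
        if (per_cell.nunique() != len(self.isolate_ids)).any() or \
                (per_cell.size() != len(self.isolate_ids)).any():
            raise ValueError("every condition x timepoint must list every isolate exactly once")


def _log_noise_sigmas(design: ExperimentDesign) -> tuple[float, float]:
    var_log = math.log1p(design.noise_cv ** 2)
    return (math.sqrt(design.bio_noise_share * var_log),
            math.sqrt((1.0 - design.bio_noise_share) * var_log))


def simulate_experiment(design: ExperimentDesign
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (readings, layout, truth) for a design; deterministic per seed."""
    design.validate()
    rng = np.random.default_rng(design.seed)
    sigma_bio, sigma_tech = _log_noise_sigmas(design)
    odc = design.implied_odc
    isolates = design.isolate_ids

    capacity = (96 - design.n_control_wells) // design.n_tech
    if capacity < 1:
        raise ValueError("plate capacity exhausted by control wells")
    chunks = [isolates[i:i + capacity] for i in range(0, len(isolates), capacity)]

    truth_mult = {
        (row.isolate_id, condition_label(row.factor, None if pd.isna(row.level) else row.level),
         row.timepoint_h): design.class_multipliers[row.producer_class]
        for row in design.truth.itertuples(index=False)
    }

    readings: list[tuple] = []
    layout: list[tuple] = []
    for cond in design.conditions:
        for tp in design.timepoints:
            for bio in range(1, design.n_bio + 1):
                for ci, chunk in enumerate(chunks):
                    plate = f"{cond.label.replace(':', '-')}_{tp:g}h_b{bio}" + (
                        f"_p{ci + 1}" if len(chunks) > 1 else "")
                    _simulate_plate(design, rng, plate, cond, tp, bio, chunk, truth_mult,
                                    odc, sigma_bio, sigma_tech, readings, layout)

    readings_df = pd.DataFrame(readings, columns=READING_COLUMNS)
    layout_df = pd.DataFrame(layout, columns=LAYOUT_COLUMNS)
    truth_df = design.truth.copy().reset_index(drop=True)
    return readings_df, layout_df, truth_df


def _simulate_plate(design, rng, plate, cond, tp, bio, chunk, truth_mult, odc,
                    sigma_bio, sigma_tech, readings, layout):
    level = np.nan if cond.level is None else float(cond.level)
    idx = 0
    slope = design.viability_slope

    def emit(well, channel, stage, value):
        readings.append((plate, well, channel, float(tp), stage, float(value)))

    for iso in chunk:
        mult = truth_mult[(iso, cond.label, tp)]
        mu = mult * odc
        # day effect shared by this isolate's wells on this plate
        bio_eff = rng.normal(0.0, sigma_bio) if sigma_bio > 0 else 0.0
        bio_eff_v = rng.normal(0.0, sigma_bio) if sigma_bio > 0 else 0.0
        for tech in range(1, design.n_tech + 1):
            well = well_name(idx)
            idx += 1
            layout.append((plate, well, Role.SAMPLE.value, iso, cond.factor, level, bio, tech))

            tech_eff = rng.normal(0.0, sigma_tech) if sigma_tech > 0 else 0.0
            cv_od = mu * math.exp(bio_eff + tech_eff - (sigma_bio**2 + sigma_tech**2) / 2.0)
            emit(well, Channel.OD570.value, Stage.GROWTH_ENDPOINT.value, cv_od)

            od600_b = design.rz_od600 * math.exp(
                rng.normal(0.0, design.rz_od600_cv) - design.rz_od600_cv**2 / 2.0)
            emit(well, Channel.OD600.value, Stage.RZ_BASELINE.value, od600_b)
            emit(well, Channel.OD570.value, Stage.RZ_BASELINE.value, design.ro * od600_b)

            tech_eff_v = rng.normal(0.0, sigma_tech) if sigma_tech > 0 else 0.0
            ar = slope * mu * math.exp(bio_eff_v + tech_eff_v
                                       - (sigma_bio**2 + sigma_tech**2) / 2.0)
            od600_f = design.rz_od600 * math.exp(
                rng.normal(0.0, design.rz_od600_cv) - design.rz_od600_cv**2 / 2.0)
            emit(well, Channel.OD600.value, Stage.RZ_FINAL.value, od600_f)
            emit(well, Channel.OD570.value, Stage.RZ_FINAL.value, design.ro * od600_f + ar / 100.0)

    for tech in range(1, design.n_control_wells + 1):
        well = well_name(idx)
        idx += 1
        layout.append((plate, well, Role.STERILITY_CONTROL.value, "", cond.factor, level, bio, tech))
        cv = max(0.0, rng.normal(design.control_mean, design.control_sd))
        emit(well, Channel.OD570.value, Stage.GROWTH_ENDPOINT.value, cv)
        od600_b = design.rz_od600 * math.exp(
            rng.normal(0.0, design.rz_od600_cv) - design.rz_od600_cv**2 / 2.0)
        emit(well, Channel.OD600.value, Stage.RZ_BASELINE.value, od600_b)
        emit(well, Channel.OD570.value, Stage.RZ_BASELINE.value, design.ro * od600_b)
        od600_f = design.rz_od600 * math.exp(
            rng.normal(0.0, design.rz_od600_cv) - design.rz_od600_cv**2 / 2.0)
        emit(well, Channel.OD600.value, Stage.RZ_FINAL.value, od600_f)
        emit(well, Channel.OD570.value, Stage.RZ_FINAL.value, design.ro * od600_f)


def default_study_design(seed: int, **overrides) -> ExperimentDesign:
    """The 10-isolate selected-panel design over the full condition grid.

    Latent classes come from the packaged panel classification tables; the
    grid is 1 baseline + 4 temperatures + 4 NaCl + 5 pH conditions at 24 and
    48 h, with 3 biological x 3 technical replicates.
    """
    truth = datasets.load_panel_truth()
    conditions = [AssayCondition("baseline")]
    for factor in ("temperature", "nacl", "ph"):
        conditions += [AssayCondition(factor, lv) for lv in DESIGN_GRID[factor]]
    return ExperimentDesign(truth=truth, conditions=tuple(conditions), seed=seed, **overrides)
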