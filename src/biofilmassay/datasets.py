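"""Loaders for the packaged reference classification tables.

The package ships the published producer-class labels of a cheese-enterococci
collection as small TSV fixtures:

* ``collection_baseline_classes``: 72 isolates classified at 24 h and 48 h in
  plain growth medium at 37 degC.
* ``panel_*_classes``: the 10-isolate selected panel classified across the
  temperature / NaCl / pH condition grids (plus its own baseline table).

Two documented internal inconsistencies of the source tables are preserved
as printed rather than resolved:

* summing the 72-isolate table gives 56 ever-producers and 33 weak producers
  at 48 h, while the accompanying narrative reports 53 and 32;
* one panel isolate (N9.25.2016) is listed as a weak producer at 48 h in the
  72-isolate table but as a non-producer in the panel cross-tabulation.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

PANEL_ISOLATES = [
    "A2.48.2016", "N9.25.2016", "A1.6.2017", "N10.27.2017", "A4.16.2019",
    "N9.1.2019", "A4.26.2021", "N10.1.2021", "A1.14.2022", "N10.55.2022",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("biofilmassay.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def _to_long(wide: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Melt a (isolate, [level,] class_24h, class_48h) table to one row per cell."""
    id_vars = [c for c in ("isolate_id", "level") if c in wide.columns]
    long = wide.melt(id_vars=id_vars, value_vars=["class_24h", "class_48h"],
                     var_name="timepoint_h", value_name="producer_class")
    long["timepoint_h"] = long["timepoint_h"].str.removeprefix("class_").str.removesuffix("h").astype(float)
    long["factor"] = factor
    if "level" not in long.columns:
        long["level"] = np.nan
    long["level"] = long["level"].astype(float)
    return long[["isolate_id", "factor", "level", "timepoint_h", "producer_class"]]


def load_collection_baseline() -> pd.DataFrame:
    """72-isolate baseline classifications, long format (one row per cell)."""
    return _to_long(_read("collection_baseline_classes.tsv"), "baseline")


def load_panel_baseline() -> pd.DataFrame:
    """Selected 10-isolate panel baseline classifications, long format."""
    return _to_long(_read("panel_baseline_classes.tsv"), "baseline")


def load_panel_factor(factor: str) -> pd.DataFrame:
    """Panel classifications for one stress factor (temperature/nacl/ph)."""
    if factor not in ("temperature", "nacl", "ph"):
        raise ValueError(f"no packaged table for factor {factor!r}")
    return _to_long(_read(f"panel_{factor}_classes.tsv"), factor)


def load_panel_truth() -> pd.DataFrame:
    """Full panel truth table: 10 isolates x 14 conditions x 2 timepoints.

    Concatenates the baseline table with the three stress-factor tables; used
    as the latent ground truth of the default synthetic study design.
    """
    parts = [load_panel_baseline()] + [load_panel_factor(f) for f in ("temperature", "nacl", "ph")]
    truth = pd.concat(parts, ignore_index=True)
    truth["isolate_id"] = pd.Categorical(truth["isolate_id"], categories=PANEL_ISOLATES,
                                         ordered=True)
    truth = truth.sort_values(["factor", "level", "timepoint_h", "isolate_id"],
                              na_position="first").reset_index(drop=True)
    truth["isolate_id"] = truth["isolate_id"].astype(str)
    return truth
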