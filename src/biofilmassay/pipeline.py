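"""End-to-end pipeline: raw readings + layout to every report table.

``run_pipeline`` executes the full analysis in stage order and writes plain
TSV artifacts plus a JSON manifest (config, seed, package version, SHA-256
checksums) so a run can be audited and reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import classify as _classify
from . import multivariate as mv
from . import percell
from . import plate_model as pm
from . import quantify

logger = logging.getLogger(__name__)

ARTIFACT_NAMES = [
    "cv_summary.tsv", "viability.tsv", "classes.tsv", "tallies.tsv", "cross_tab.tsv",
    "index.tsv", "averages.tsv", "flags.tsv", "rp.tsv", "pca.tsv", "clusters.tsv",
    "tree.nwk", "radar_long.tsv",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass
class PipelineConfig:
    readings: str
    layout: str
    outdir: str
    seed: int
    pool_cutoffs: bool = False
    rp_permutations: int = 10_000
    alpha: float = 0.05
    bh_correction: bool = False
    pca_components: int = 3
    standardize: bool = True
    include_viability_features: bool = True
    cluster_k: int = 3
    ratio_timepoints: tuple[float, float] = (24.0, 48.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ratio_timepoints"] = list(self.ratio_timepoints)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "ratio_timepoints" in data:
            data["ratio_timepoints"] = tuple(data["ratio_timepoints"])
        return cls(**data)


def feature_matrix(cv_summary: pd.DataFrame, viability: pd.DataFrame | None) -> pd.DataFrame:
    """Isolate x variable matrix: CV means and (optionally) AR570 per cell.

    Column names encode method, condition and timepoint (``CV|nacl:8|48h``).
    Non-detectable viability enters as 0, consistent with the clamp rule.
    """
    def widen(table: pd.DataFrame, value: str, tag: str) -> pd.DataFrame:
        t = table.copy()
        t["variable"] = [f"{tag}|{pm.condition_label(f, None if pd.isna(l) else l)}|{tp:g}h"
                         for f, l, tp in t[["factor", "level", "timepoint_h"]]
                         .itertuples(index=False)]
        return t.pivot_table(index="isolate_id", columns="variable", values=value)

    mat = widen(cv_summary, "mean_od", "CV")
    if viability is not None:
        mat = mat.join(widen(viability, "ar570", "RZ"), how="left")
    if mat.isna().any().any():
        raise PipelineError("feature matrix has missing cells; cannot ordinate")
    return mat.sort_index()


def radar_long(cv_summary: pd.DataFrame, viability: pd.DataFrame | None = None) -> pd.DataFrame:
    """Radar-chart-ready long table: one row per isolate x condition x
    timepoint x method, values identical to the source summary tables."""
    parts = [cv_summary[pm.CELL_KEY + ["mean_od"]]
             .rename(columns={"mean_od": "value"}).assign(method="CV")]
    if viability is not None:
        parts.append(viability[pm.CELL_KEY + ["ar570"]]
                     .rename(columns={"ar570": "value"}).assign(method="RZ"))
    out = pd.concat(parts, ignore_index=True)
    out["condition"] = [pm.condition_label(f, None if pd.isna(l) else l)
                        for f, l in out[["factor", "level"]].itertuples(index=False)]
    cols = ["isolate_id", "condition", "factor", "level", "timepoint_h", "method", "value"]
    return out[cols].sort_values(cols[:6]).reset_index(drop=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all artifacts; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    readings = stage("read_readings", pm.read_plate_long, config.readings)
    layout = stage("read_layout", pm.read_layout, config.layout)
    report = stage("validate", pm.validate, readings, layout)
    if report.errors():
        raise PipelineError(f"stage 'validate' failed: {len(report.errors())} error(s), "
                            f"first: {report.errors()[0].message} at {report.errors()[0].location}")

    cv_summary = stage("aggregate", quantify.aggregate_wells, readings, layout,
                       pm.Channel.OD570.value, pm.Stage.GROWTH_ENDPOINT.value)
    viability = stage("viability", quantify.viability_table, readings, layout)
    cutoffs = stage("cutoffs", _classify.cutoff_table, readings, layout, config.pool_cutoffs)
    classes = stage("classify", _classify.classify_all, cv_summary, cutoffs)
    tallies = stage("tally", _classify.tally_table, classes)
    for factor, level, tp in tallies[["factor", "level", "timepoint_h"]].drop_duplicates().itertuples(index=False):
        t = _classify.tally(classes, tp, factor, None if pd.isna(level) else level)
        n = sum(t.values())
        logger.info("%s %gh: %s", pm.condition_label(factor, None if pd.isna(level) else level),
                    tp, ", ".join(f"{v}/{n} {k}" for k, v in t.items()))

    tp_a, tp_b = config.ratio_timepoints
    xt = stage("cross_tab", _classify.cross_tab, classes, tp_a, tp_b)
    xt_long = [{"class_a": ca, "class_b": cb,
                "isolates": ",".join(xt.loc[ca, cb])}
               for ca in xt.index for cb in xt.columns if xt.loc[ca, cb]]

    idx = stage("index", percell.index_table, cv_summary, viability)
    averages = stage("averages", percell.condition_average, idx)
    flags = stage("flags", percell.flag_max_conditions, averages)
    flags_df = pd.DataFrame(sorted(flags, key=lambda t: (t[0], t[2], t[1])),
                            columns=["factor", "level", "timepoint_h"])

    cv_bio = stage("aggregate_bio", quantify.aggregate_wells, readings, layout,
                   pm.Channel.OD570.value, pm.Stage.GROWTH_ENDPOINT.value, True)
    baseline_bio = cv_bio[cv_bio["factor"] == "baseline"]
    rp = pd.DataFrame()
    if not baseline_bio.empty:
        ratios = stage("ratios", mv.ratio_24_48, baseline_bio, tp_a, tp_b)
        if ratios["isolate_id"].nunique() >= 2:
            rp = stage("rank_product", mv.rank_product_test, ratios, config.rp_permutations,
                       config.seed, config.alpha, "bh" if config.bh_correction else None)

    features = stage("features", feature_matrix, cv_summary,
                     viability if config.include_viability_features else None)
    rank = int(np.linalg.matrix_rank(features.to_numpy() - features.to_numpy().mean(axis=0)))
    n_comp = min(config.pca_components, rank)
    if n_comp < config.pca_components:
        logger.info("reducing PCA components from %d to matrix rank %d",
                    config.pca_components, n_comp)
    pca_res = stage("pca", mv.pca, features, n_comp, config.standardize)
    pca_long = pd.concat([
        pca_res.scores.rename_axis("name").reset_index().melt(
            id_vars="name", var_name="component", value_name="value").assign(kind="score"),
        pca_res.loadings.rename_axis("name").reset_index().melt(
            id_vars="name", var_name="component", value_name="value").assign(kind="loading"),
        pd.DataFrame({"kind": "variance_fraction", "name": "",
                      "component": [f"PC{i+1}" for i in range(n_comp)],
                      "value": pca_res.variance_fraction}),
    ], ignore_index=True)[["kind", "name", "component", "value"]]

    dend = stage("upgma", mv.upgma, features, None, config.standardize)
    production = cv_summary.groupby("isolate_id")["mean_od"].mean()
    labels = stage("cut_clusters", mv.cut_clusters, dend, config.cluster_k, production)
    clusters_df = pd.DataFrame(
        [{"isolate_id": leaf, "cluster": cid,
          "quality": labels.quality[cid] if labels.quality else ""}
         for leaf, cid in sorted(labels.assignments.items())])
    newick = stage("newick", mv.to_newick, dend)
    radar = stage("radar", radar_long, cv_summary, viability)

    artifacts = {
        "cv_summary.tsv": cv_summary, "viability.tsv": viability, "classes.tsv": classes,
        "tallies.tsv": tallies, "cross_tab.tsv": pd.DataFrame(xt_long),
        "index.tsv": idx, "averages.tsv": averages, "flags.tsv": flags_df,
        "rp.tsv": rp, "pca.tsv": pca_long, "clusters.tsv": clusters_df,
        "radar_long.tsv": radar,
    }
    for name, table in artifacts.items():
        pm.write_tidy(table, outdir / name)
    (outdir / "tree.nwk").write_text(newick + "\n", encoding="utf-8")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": {name: _sha256(outdir / name) for name in ARTIFACT_NAMES},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                          encoding="utf-8")
    return manifest
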