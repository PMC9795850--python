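"""Experiment orchestration: screening, ablation ladder and date sweep.

The ablation ladder fits every method on the nested feature sets
VIs -> VIs+TI -> VIs+TI+CC -> VIs+TI+CC+CHM -> VIs+TI+CC+CHM+Lodging
(after shadow screening of the texture/spectral/height candidates and
one-class-SVM row filtering), for both yield components.

The date sweep extracts the per-date feature inventory for every acquisition
date and records each method's validation accuracy, reporting the best date
per target as the argmax of the method-averaged validation R^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ModelError
from .models import METHODS, ModelResult, ModelSpec, fit_predict, split_data
from .pipeline import ExtractionConfig, FeatureTable, estimate_field_dem, extract_scene_features
from .raster import PlotRecord, SceneStack
from .screening import BorutaScreener, OneClassOutlierFilter, ScreeningReport

#: nested feature sets of the ablation ladder, in order
ABLATION_SETS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("VIs", ("VI",)),
    ("VIs+TI", ("VI", "TI")),
    ("VIs+TI+CC", ("VI", "TI", "CC")),
    ("VIs+TI+CC+CHM", ("VI", "TI", "CC", "CHM")),
    ("VIs+TI+CC+CHM+Lodging", ("VI", "TI", "CC", "CHM", "LODGING")),
)

#: feature groups never entered into the shadow screen (always kept)
SCREENING_EXCLUDED_GROUPS = ("CC", "LODGING")

DEFAULT_TARGETS = ("grain_number", "grain_weight")


@dataclass
class AblationPlan:
    """The nested sets with their realized column counts."""

    sets: tuple[tuple[str, tuple[str, ...]], ...] = ABLATION_SETS
    column_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class SweepResult:
    """Per-date validation accuracy and the chosen best date per target."""

    frame: pd.DataFrame  # date, method, target, split, r2, rmse, rrmse
    best_date: dict[str, int]


def screen_feature_table(
    table: FeatureTable,
    y,
    n_runs: int = 100,
    cutoff: int = 80,
    n_trees: int = 100,
    random_state: int | None = None,
) -> tuple[FeatureTable, ScreeningReport]:
    """Shadow-screen the candidate features, keeping CC and lodging aside.

    Canopy cover and lodging never enter the screen and are always kept; the
    remaining columns (spectral, texture, height) are screened with the
    ``cutoff``-of-``n_runs`` removal rule.
    """
    excluded_cols = [
        c for c in table.data.columns if table.groups[c] in SCREENING_EXCLUDED_GROUPS
    ]
    screened_cols = [c for c in table.data.columns if c not in set(excluded_cols)]
    screener = BorutaScreener(
        n_runs=n_runs, cutoff=cutoff, n_trees=n_trees, random_state=random_state
    )
    screener.fit(table.data[screened_cols], np.asarray(y, dtype=float))
    report = screener.report_
    report.excluded = tuple(excluded_cols)
    kept = [c for c in table.data.columns if c in set(report.kept)]
    return table.subset(kept), report


def filter_outlier_plots(
    table: FeatureTable,
    gamma: float = 0.001,
    nu: float = 0.03,
    tol: float = 1e-3,
) -> tuple[FeatureTable, np.ndarray]:
    """Drop rows the one-class SVM flags as outliers (pre-split cleaning)."""
    filt = OneClassOutlierFilter(gamma=gamma, nu=nu, tol=tol)
    filt.fit(table.data.to_numpy(dtype=float))
    mask = filt.inlier_mask(table.data.to_numpy(dtype=float))
    reduced = FeatureTable(data=table.data.loc[mask].copy(), groups=dict(table.groups), date=table.date)
    return reduced, mask


def run_ablation(
    features: FeatureTable,
    ground: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    targets: tuple[str, ...] = DEFAULT_TARGETS,
    seed: int = 0,
    train_fraction: float = 0.7,
) -> tuple[list[ModelResult], AblationPlan]:
    """Fit every method on the nested feature sets for each target.

    ``features`` is the (screened) feature table; ``ground`` holds the yield
    components indexed by plot_id.  Raises when a feature group of the ladder
    is absent, naming it.
    """
    plan = AblationPlan()
    for label, groups in plan.sets:  # raises on a missing group, up front
        plan.column_counts[label] = len(features.columns_for(groups))
    merged = features.data.join(ground[list(targets)], how="inner")
    if merged.empty:
        raise ModelError("no plots shared between features and ground table")
    results: list[ModelResult] = []
    train, val = split_data(merged, train_fraction=train_fraction, seed=seed)
    for label, groups in plan.sets:
        cols = features.columns_for(groups)
        for target in targets:
            for method in methods:
                results.append(
                    fit_predict(
                        ModelSpec(method=method, seed=seed),
                        train,
                        val,
                        cols,
                        target,
                        feature_set=label,
                    )
                )
    return results, plan


def run_date_sweep(
    scenes: dict[int, SceneStack],
    plots: list[PlotRecord],
    ground: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    targets: tuple[str, ...] = DEFAULT_TARGETS,
    seed: int = 0,
    config: ExtractionConfig | None = None,
    train_fraction: float = 0.7,
) -> SweepResult:
    """Per-date extraction + modeling; best date = argmax mean validation R^2.

    The earliest scene doubles as the bare-ground reference for the height
    block of every date.
    """
    if len(scenes) < 2:
        raise ConfigurationError("date sweep needs at least 2 dates with scenes")
    config = config or ExtractionConfig(texture_bands=("R", "G", "B"))
    dates = sorted(scenes)
    dem = estimate_field_dem(scenes[dates[0]], plots)
    rows = []
    for date in dates:
        table = extract_scene_features(scenes[date], plots, dem=dem, config=config)
        merged = table.data.join(ground[list(targets)], how="inner")
        train, val = split_data(merged, train_fraction=train_fraction, seed=seed)
        cols = list(table.data.columns)
        for target in targets:
            for method in methods:
                res = fit_predict(
                    ModelSpec(method=method, seed=seed), train, val, cols, target,
                    feature_set=f"day{date}",
                )
                for split, m in (
                    ("train", res.train_metrics),
                    ("validation", res.validation_metrics),
                ):
                    rows.append(
                        dict(date=date, method=method, target=target, split=split, **m)
                    )
    frame = pd.DataFrame(rows)
    best: dict[str, int] = {}
    vals = frame[frame["split"] == "validation"]
    for target in targets:
        sub = vals[vals["target"] == target]
        mean_r2 = sub.groupby("date")["r2"].mean()
        best[target] = int(mean_r2.idxmax())
    return SweepResult(frame=frame, best_date=best)


def results_frame(results: list[ModelResult]) -> pd.DataFrame:
    """One row per (feature set, method, target, split)."""
    rows = []
    for r in results:
        for split, m in (("train", r.train_metrics), ("validation", r.validation_metrics)):
            rows.append(
                dict(
                    feature_set=r.feature_set,
                    n_features=r.n_features,
                    method=r.method,
                    target=r.target,
                    split=split,
                    r2=m["r2"],
                    rmse=m["rmse"],
                    rrmse=m["rrmse"],
                )
            )
    return pd.DataFrame(rows)


def write_report(results: list[ModelResult] | pd.DataFrame, outdir) -> dict[str, Path]:
    """Write the machine-readable results table and a human-readable summary.

    Produces ``results.csv`` (one row per feature set x method x target x
    split) and ``summary.json`` with a per-target ladder of validation R^2.
    Deterministic content for a deterministic input.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if frame.empty:
        raise ModelError("no results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "results.csv"
    frame.to_csv(csv_path, index=False, float_format="%.6f")

    summary: dict = {}
    for target, sub in frame.groupby("target"):
        val = sub[sub["split"] == "validation"]
        ladder = (
            val.pivot_table(index="feature_set", columns="method", values="r2", sort=False)
            .round(4)
            .to_dict()
        )
        summary[target] = ladder
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return {"results": csv_path, "summary": json_path}
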