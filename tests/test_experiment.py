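"""Pipeline orchestration: extraction inventory, ablation ladder, date sweep."""

import numpy as np
import pandas as pd
import pytest

import uavyield as uy
from uavyield.errors import ConfigurationError, ModelError
from uavyield.experiment import ABLATION_SETS
from uavyield.pipeline import ExtractionConfig, FeatureTable, features_long_format


def test_day48_inventory_composition(table48):
    groups = pd.Series(table48.groups)
    counts = groups.value_counts().to_dict()
    assert counts == {"TI": 45, "VI": 24, "CC": 1, "CHM": 1, "LODGING": 1}
    assert table48.n_features == 72


def test_all_band_texture_inventory(season300, dem300):
    plots, _, scenes = season300
    config = ExtractionConfig(texture_bands=("R", "G", "B"))
    table = uy.extract_scene_features(scenes[48], plots[:5], dem=dem300, config=config)
    counts = pd.Series(table.groups).value_counts().to_dict()
    assert counts["TI"] == 135
    assert table.n_features == 162


def test_long_format_roundtrip(table48):
    long = features_long_format(table48)
    assert set(long.columns) == {"plot_id", "date", "feature_name", "feature_group", "value"}
    assert len(long) == len(table48.data) * table48.n_features
    wide = long.pivot(index="plot_id", columns="feature_name", values="value")
    assert np.allclose(
        wide[table48.data.columns].to_numpy(), table48.data.to_numpy(), equal_nan=True
    )


def test_screen_excludes_lodging_and_canopy_cover(screen48):
    screened, report = screen48
    assert set(report.excluded) == {"canopy_cover", "lodging"}
    assert "canopy_cover" in screened.data.columns
    assert "lodging" in screened.data.columns
    assert not set(report.frame.index) & {"canopy_cover", "lodging"}


def test_screen_removes_degenerate_minmax_texture_features(table48, screen48):
    """Features pinning the min/max of a near-constant window metric carry no
    information and are rejected in (essentially) every run."""
    _, report = screen48
    ti_cols = [c for c, g in table48.groups.items() if g == "TI"]
    degenerate = {c for c in ti_cols if table48.data[c].std() == 0}
    assert len(degenerate) == 9
    assert all(c.endswith(("_min", "_max")) for c in degenerate)
    removed = set(report.removed)
    assert degenerate <= removed
    assert (report.frame.loc[sorted(degenerate), "times_below_best_shadow"] >= 95).all()


def test_ablation_sets_are_nested(screen48, ground300):
    screened, _ = screen48
    prev: list[str] = []
    for label, groups in ABLATION_SETS:
        cols = screened.columns_for(groups)
        assert set(prev) <= set(cols), label
        prev = cols


def test_ablation_grid_bookkeeping(ablation300):
    results, plan = ablation300
    assert len(results) == 5 * 5 * 2
    labels = [label for label, _ in ABLATION_SETS]
    assert list(plan.column_counts) == labels
    counts = [plan.column_counts[label] for label in labels]
    assert all(b > a for a, b in zip(counts, counts[1:]))
    frame = uy.results_frame(results)
    assert len(frame) == 5 * 5 * 2 * 2  # x splits


def test_ablation_missing_group_named():
    data = pd.DataFrame({"a": [1.0, 2.0] * 10, "b": [3.0, 4.0] * 10})
    table = FeatureTable(data=data, groups={"a": "VI", "b": "TI"})
    ground = pd.DataFrame(
        {"grain_number": np.arange(20.0), "grain_weight": np.arange(20.0)},
        index=data.index,
    )
    with pytest.raises(ConfigurationError, match="CC"):
        uy.run_ablation(table, ground)


def test_best_feature_set_beats_vi_only_and_has_skill(ablation300):
    """Fusing structure/texture/lodging with the spectral block raises the
    training fit for most methods, and the best validation R^2 for grain
    number clears 0.4 on the default synthetic season."""
    results, _ = ablation300
    frame = uy.results_frame(results)
    gn = frame[(frame.target == "grain_number")]
    best_val = gn[gn.split == "validation"]["r2"].max()
    assert best_val > 0.4
    train = gn[gn.split == "train"].pivot(index="method", columns="feature_set", values="r2")
    improved = (train["VIs+TI+CC+CHM+Lodging"] >= train["VIs"] - 0.02).sum()
    assert improved >= 4


def test_date_sweep_records_and_best_date(tiny_season):
    design, plots, truth, scenes = tiny_season
    ground = uy.ground_table(plots, truth)
    result = uy.run_date_sweep(
        scenes, plots, ground, methods=("rf",), seed=0,
        config=ExtractionConfig(texture_bands=("R",)),
    )
    assert len(result.frame) == 3 * 1 * 2 * 2  # dates x methods x targets x splits
    assert set(result.best_date) == {"grain_number", "grain_weight"}
    for target, day in result.best_date.items():
        assert day in scenes
    # pre-emergence scenes carry no canopy signal: day 6 never wins
    assert all(day != 6 for day in result.best_date.values())
    vals = result.frame.query("split == 'validation' and target == 'grain_number'")
    r2_by_date = vals.set_index("date")["r2"]
    assert r2_by_date[6] < max(r2_by_date[27], r2_by_date[48])


def test_date_sweep_needs_two_dates(tiny_season):
    design, plots, truth, scenes = tiny_season
    ground = uy.ground_table(plots, truth)
    with pytest.raises(ConfigurationError):
        uy.run_date_sweep({6: scenes[6]}, plots, ground)


def test_write_report_deterministic(tmp_path, ablation300):
    results, _ = ablation300
    paths1 = uy.write_report(results, tmp_path / "a")
    paths2 = uy.write_report(results, tmp_path / "b")
    assert paths1["results"].read_bytes() == paths2["results"].read_bytes()
    assert paths1["summary"].read_bytes() == paths2["summary"].read_bytes()
    with pytest.raises(ModelError):
        uy.write_report([], tmp_path / "c")


def test_outlier_filter_drops_flagged_rows(table48):
    reduced, mask = uy.filter_outlier_plots(table48)
    assert mask.dtype == bool
    assert len(reduced.data) == mask.sum()
    flagged = 1.0 - mask.mean()
    assert 0.0 <= flagged <= 0.10
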