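"""Shared fixtures: a reduced synthetic season and its derived products.

The heavy session fixtures (rendered field, day-48 feature table, 100-run
shadow screen, ablation grid) are computed once and shared between the module
tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import uavyield as uy

#: reduced field used for screening/modeling tests (runtime-scaled)
FIELD_SEED = 7
SCREEN_SEED = 11
MODEL_SEED = 5


@pytest.fixture(scope="session")
def design300():
    return uy.FieldDesign(n_cultivar_plots=270, n_control_plots=30)


@pytest.fixture(scope="session")
def season300(design300):
    plots, truth, scenes = uy.simulate_season(
        design300, seed=FIELD_SEED, dates=(6, 48)
    )
    return plots, truth, scenes


@pytest.fixture(scope="session")
def ground300(design300, season300):
    plots, truth, _ = season300
    return uy.ground_table(plots, truth)


@pytest.fixture(scope="session")
def dem300(season300):
    plots, _, scenes = season300
    return uy.estimate_field_dem(scenes[6], plots)


@pytest.fixture(scope="session")
def table48(season300, dem300):
    plots, _, scenes = season300
    return uy.extract_scene_features(scenes[48], plots, dem=dem300)


@pytest.fixture(scope="session")
def screen48(table48, ground300):
    """100-run shadow screen of the day-48 candidates against grain number."""
    y = ground300.loc[table48.data.index, "grain_number"]
    screened, report = uy.screen_feature_table(
        table48, y, n_runs=100, cutoff=80, random_state=SCREEN_SEED
    )
    return screened, report


@pytest.fixture(scope="session")
def ablation300(screen48, ground300):
    screened, _ = screen48
    results, plan = uy.run_ablation(screened, ground300, seed=MODEL_SEED)
    return results, plan


@pytest.fixture(scope="session")
def tiny_season():
    """A 30-plot field with three dates, for raster/structure/sweep tests."""
    design = uy.FieldDesign(n_cultivar_plots=27, n_control_plots=3)
    plots, truth, scenes = uy.simulate_season(design, seed=1, dates=(6, 27, 48))
    return design, plots, truth, scenes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
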