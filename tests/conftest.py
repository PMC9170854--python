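"""Shared fixtures.

The expensive session fixtures (`study` in particular) run the full
default simulation once and are shared by the metric-trend and
estimator-validity tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import suvvar
from suvvar.config import RunConfig
from suvvar.metrics import measure_frame, records_to_frame
from suvvar.pipeline import simulate_records
from suvvar.simulate import frame_rng, simulate_frame

MASTER_SEED = 20260925


@pytest.fixture(scope="session")
def geometry():
    return suvvar.build_phantom_geometry()


@pytest.fixture(scope="session")
def grid():
    return suvvar.GridSpec()


@pytest.fixture(scope="session")
def truth(geometry, grid):
    return suvvar.rasterize_activity(geometry, grid, supersample=5)


@pytest.fixture(scope="session")
def rois(truth, geometry):
    return suvvar.detect_spheres(truth, geom_hint=geometry)


@pytest.fixture(scope="session")
def noise_model():
    return suvvar.NoiseModel()


@pytest.fixture(scope="session")
def study(truth, rois, noise_model):
    """Full default study: all 14 subsets measured, plus 100 independent
    150 s frames measured directly, with fitted variation results."""
    records, schedules, _ = simulate_records(RunConfig(), seed=MASTER_SEED)
    direct_records = []
    for k in range(100):
        frame = simulate_frame(truth, 0.0, 150.0, noise_model, frame_rng(MASTER_SEED, 10_000, k))
        direct_records.extend(measure_frame(frame, rois, rl_s=150.0, frame_index=k))
    direct = records_to_frame(direct_records)
    results = suvvar.SUVVariationModel(records, schedules=schedules, target_rl_s=150.0).fit()
    return {
        "records": records,
        "schedules": schedules,
        "direct": direct,
        "results": results,
    }


@pytest.fixture(scope="session")
def measured_cov_150(study):
    """Directly measured CoV% at 150 s per (metric, sphere)."""
    return (
        study["direct"]
        .groupby(["metric", "sphere_id"])["value_kbq_ml"]
        .agg(lambda v: 100.0 * v.std(ddof=1) / v.mean())
        .rename("measured_cov")
        .reset_index()
    )


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size configuration for pipeline-level tests."""
    return RunConfig(
        grid={"shape": (96, 96, 20)},
        schedule={"total_s": 60.0, "rls_s": [10.0, 15.0, 30.0]},
        analysis={"target_rl_s": 60.0},
    )
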