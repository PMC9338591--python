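"""Shared fixtures: phantom pipeline runs are expensive, so the grids used by
several test modules are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from camangle.config import RunConfig
from camangle.phantoms import FemurPhantomSpec, generate_phantom
from camangle.pipeline import measure_alpha

BASELINE_RATIOS = (0.5, 0.6, 0.7, 0.8)
CAM_THETA_MAX = (55.0, 65.0, 75.0, 85.0)
SEED = 17


def run_config() -> RunConfig:
    cfg = RunConfig()
    cfg.geometry.n_slices = 72  # 5 deg azimuth grid: full validation coverage
    return cfg


def baseline_spec(ratio: float) -> FemurPhantomSpec:
    return FemurPhantomSpec(neck_radius_mm=24.0 * ratio)


def cam_spec(theta_max: float) -> FemurPhantomSpec:
    return FemurPhantomSpec(cam_present=True,
                            cam_theta_min_deg=theta_max - 20.0,
                            cam_theta_max_deg=theta_max,
                            cam_phi_min_deg=0.0, cam_phi_max_deg=60.0,
                            cam_height_frac=0.15)


@pytest.fixture(scope="session")
def baseline_runs():
    """ratio -> (spec, mask, MeasureResult) over the neck/head ratio grid."""
    out = {}
    for ratio in BASELINE_RATIOS:
        spec = baseline_spec(ratio)
        mask = generate_phantom(spec, spacing_mm=1.0)
        out[ratio] = (spec, mask, measure_alpha(mask, run_config(), seed=SEED))
    return out


@pytest.fixture(scope="session")
def cam_runs():
    """cam_theta_max -> (spec, mask, MeasureResult) over the cam severity grid."""
    out = {}
    for tmax in CAM_THETA_MAX:
        spec = cam_spec(tmax)
        mask = generate_phantom(spec, spacing_mm=1.0)
        out[tmax] = (spec, mask, measure_alpha(mask, run_config(), seed=SEED))
    return out


@pytest.fixture(scope="session")
def default_run(baseline_runs):
    """The default phantom (ratio 2/3 is not in the grid; 0.7 is closest in
    shape, but geometry unit tests want the canonical R=24 / r=16 femur)."""
    spec = FemurPhantomSpec()
    mask = generate_phantom(spec, spacing_mm=1.0)
    return spec, mask, measure_alpha(mask, run_config(), seed=SEED)


def angle_between(u, v) -> float:
    u = np.asarray(u) / np.linalg.norm(u)
    v = np.asarray(v) / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))
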