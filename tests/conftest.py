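"""Shared fixtures.

The expensive end-to-end simulations (20-seed shadowed-pair recovery, the
intersection-angle sweep) are run once per session and shared between the
module tests and the acceptance tests as small summary dicts — the full
echo matrices are hundreds of MB and are discarded immediately.
"""

from __future__ import annotations

import numpy as np
import pytest

from bioradar import (
    RunConfig,
    angle_sweep_scene,
    noise_only_scene,
    run_pipeline,
    shadowed_pair_scene,
    single_target_scene,
)

BIN_M = 9.0 / 200  # range-bin width after accumulation


def scene_summary(scene) -> dict:
    """Run the full pipeline on a scene, keep only small summaries."""
    res = run_pipeline(RunConfig(scene=scene), write_artifacts=False)
    return {
        "accepted": [(p.range_m, p.width_m) for p in res.report.accepted],
        "detections": [
            (p.range_m, p.width_m, p.status) for p in res.report.detections
        ],
        "peaks": list(res.power_peaks_m),
        "H": res.spectrum.H.copy(),
        "r": res.spectrum.range_axis_m.copy(),
        "profile": res.power_profile.copy(),
        "threshold": res.report.threshold,
        "h_max": res.spectrum.h_max,
    }


def within_bins(found_m: float, true_m: float, n_bins: int = 2) -> bool:
    return abs(found_m - true_m) <= n_bins * BIN_M + BIN_M / 2


@pytest.fixture(scope="session")
def pair6_summaries() -> list[dict]:
    """Twenty seeded shadowed-pair scenes: blocker 3 m, target 6 m in shadow."""
    return [scene_summary(shadowed_pair_scene(6.0, seed=s)) for s in range(20)]


@pytest.fixture(scope="session")
def angle_summaries() -> dict[int, dict]:
    """Intersection-angle sweep: blocker 2.5 m, target 4 m at each bearing."""
    return {
        ang: scene_summary(angle_sweep_scene(ang, seed=3))
        for ang in (10, 15, 20, 25, 30)
    }


@pytest.fixture(scope="session")
def noise_summary() -> dict:
    return scene_summary(noise_only_scene(seed=11))


@pytest.fixture(scope="session")
def single_summary() -> dict:
    return scene_summary(single_target_scene(3.0, seed=12))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250930)
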