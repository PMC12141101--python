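"""Shared fixtures: expensive optimizer runs are computed once per session."""

import math

import numpy as np
import pytest

from soartrade import (
    CollocationGrid,
    ProblemSpec,
    SyntheticCohortSpec,
    analyze_tracks,
    generate_cohort,
    minimum_wind_speed,
    solve,
    sweep_shear,
)

SEED = 1
DEG = math.pi / 180.0


@pytest.fixture(scope="session")
def validation_minwind():
    """Minimum-wind solve in the validation configuration (z >= 1.5 m, free
    direction, N = 50, 5 starts)."""
    return minimum_wind_speed(None, z_min=1.5, grid=CollocationGrid(N=50),
                              n_starts=5, seed=SEED)


@pytest.fixture(scope="session")
def main_minwind():
    """Minimum-wind solve with the main-text altitude floor z >= 0.5 m."""
    return minimum_wind_speed(None, z_min=0.5, grid=CollocationGrid(N=50),
                              n_starts=5, seed=SEED)


@pytest.fixture(scope="session")
def directional_bounds():
    """Minimum soarable wind for fixed travel directions 60/90/120 deg."""
    out = {}
    for th in (60.0, 90.0, 120.0):
        out[th] = minimum_wind_speed(th * DEG, z_min=0.5,
                                     grid=CollocationGrid(N=40),
                                     n_starts=4, seed=SEED)
    return out


@pytest.fixture(scope="session")
def sweep_table():
    """Trade-off sweep: theta in {60, 90, 120} deg, W_ref from just above the
    feasibility bound to 20 m/s in 1 m/s steps, warm-started continuation."""
    import pandas as pd

    frames = []
    for th, w_lo in ((60.0, 9.0), (90.0, 7.0), (120.0, 6.0)):
        frames.append(sweep_shear([th * DEG], np.arange(w_lo, 20.5, 1.0),
                                  grid=CollocationGrid(N=40), seed=SEED))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def cohort_analysis():
    """Default synthetic cohort (4 individuals, W_ref 8-20, 1-m noise) pushed
    through the track pipeline; returns (segments+truth merge, segments)."""
    spec = SyntheticCohortSpec(seed=7)
    tracks, truth = generate_cohort(spec)
    segments = analyze_tracks(tracks)
    merged = segments.merge(truth.table, on=["id", "t0"])
    return merged, segments
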