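"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from glyload import SimulationConfig, compute_records, simulate_study
from glyload.io import load_table3_fixture


def fine_grid_iauc(times, glucose, step=0.001):
    """Independent numerical oracle for the incremental AUC.

    Linearly interpolates the readings on a fine grid and applies the
    trapezoid rule to the clipped excursion max(g(t) - g(0), 0).  Kept free
    of any package code so it can cross-check the exact piecewise formula.
    """
    times = np.asarray(times, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    t = np.arange(0.0, times[-1] + step / 2, step)
    g = np.interp(t, times, glucose)
    return float(np.trapezoid(np.clip(g - glucose[0], 0.0, None), t))


def random_curve(rng, n_points=7, allow_dips=True):
    """A random glucose trajectory on the standard grid, dips included."""
    times = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])[:n_points]
    baseline = rng.uniform(70.0, 110.0)
    spread = rng.uniform(2.0, 60.0)
    lo = -spread if allow_dips else 0.0
    increments = rng.uniform(lo, spread, size=n_points)
    increments[0] = 0.0
    glucose = np.maximum(baseline + increments, 1.0)
    return times, glucose


@pytest.fixture(scope="session")
def table3():
    meals, summaries = load_table3_fixture()
    return {m.meal_id: m for m in meals}, {s.meal_id: s for s in summaries}


@pytest.fixture(scope="session")
def default_study():
    """One default-size synthetic study, reused read-only across tests."""
    return simulate_study(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_records(default_study):
    return compute_records(default_study.curves, default_study.meals)
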