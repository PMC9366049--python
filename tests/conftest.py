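"""Shared fixtures: branch geometry tables and reference runs are expensive,
so they are computed once per session and shared across test modules."""

import numpy as np
import pytest

import hedgehog as hh


@pytest.fixture(scope="session")
def geom_l():
    return hh.branch_table("left")


@pytest.fixture(scope="session")
def geom_r():
    return hh.branch_table("right")


@pytest.fixture(scope="session")
def fhn_params():
    return hh.ModelParams(cos_amp=0.0)


@pytest.fixture(scope="session")
def fhn_geoms(fhn_params):
    # without the wavy term both folds sit at |y| = 2/3; use windows that
    # span most of the bistable range on both branches
    return (
        hh.branch_table("left", (-0.6, 0.6), 2000, fhn_params),
        hh.branch_table("right", (-0.6, 0.6), 2000, fhn_params),
    )


@pytest.fixture(scope="session")
def deterministic_traj():
    """sigma = 0 run long enough for >= 2 full bursting cycles."""
    return hh.integrate(
        hh.DEFAULT_PARAMS, x0=-1.5, y0=-0.4, tau_end=3e4, dt=5e-3,
        seed=1, record_every=10,
    )


@pytest.fixture(scope="session")
def deterministic_stats(deterministic_traj):
    return hh.segment_bursts(deterministic_traj)


@pytest.fixture(scope="session")
def staircase_curve(geom_l, geom_r):
    grid = np.logspace(-3, np.log10(0.25), 16)
    return hh.staircase(grid, geom_l, geom_r)


def simulate_scenario_bursts(sigma, n_seeds=5, tau_end=3e4, seed0=100):
    """Pooled burst list for one noise strength over several seeds."""
    bursts = []
    for i in range(n_seeds):
        traj = hh.integrate(
            hh.DEFAULT_PARAMS, x0=-1.5, y0=-0.4, tau_end=tau_end, dt=5e-3,
            seed=seed0 + i, record_every=10, sigma=sigma,
        )
        bursts.extend(hh.segment_bursts(traj).bursts)
    return bursts


@pytest.fixture(scope="session")
def s_scenario_bursts():
    """Pooled bursts for the four coherent (single-escape) noise strengths."""
    return {s: simulate_scenario_bursts(s) for s in (0.00455, 0.0207, 0.0695, 0.16)}
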