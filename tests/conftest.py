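"""Shared fixtures: Monte-Carlo tables are expensive, so they are built
once per session at reduced replicate counts and reused across tests."""

import pytest

from ldhotscan.composite import LikelihoodGrids
from ldhotscan.simulate import (
    RecombinationMap,
    SimulationParams,
    build_hotspot_map,
    simulate_haplotypes,
)
from ldhotscan.twolocus import build_two_locus_table

# moderate-resolution grids used by the heavier simulation tests
FAST_RHO0 = (0.0, 0.1, 0.2, 0.35, 0.5, 0.7, 1.0, 1.5, 2.5, 5.0)
FAST_RHO1 = tuple(sorted(set(FAST_RHO0) | {7.5, 10.0, 15.0, 25.0, 50.0, 100.0}))


@pytest.fixture(scope="session")
def fast_grids():
    return LikelihoodGrids(const_grid=FAST_RHO0, rho0_grid=FAST_RHO0, rho1_grid=FAST_RHO1)


@pytest.fixture(scope="session")
def table30():
    """Two-locus table for the study sample size n = 30.

    Replicate count matters here: table Monte-Carlo noise inflates the
    null tails of the LRT and blurs the power comparisons downstream.
    """
    return build_two_locus_table(n=30, reps=10_000, seed=11)


@pytest.fixture(scope="session")
def table10():
    """Smaller-sample table for the cheap calibration experiments."""
    return build_two_locus_table(n=10, reps=4000, seed=13)


@pytest.fixture(scope="session")
def window_20kb(table30):
    """One 20 kb constant-rate window at the study conditions."""
    params = SimulationParams(n=30, theta=1.0, region_length=20_000, seed=42)
    return simulate_haplotypes(params, build_hotspot_map(20_000, 0.5))


@pytest.fixture(scope="session")
def hotspot_window_20kb(table30):
    """A 20 kb window with a central 2 kb, 50-fold (25/kb) hotspot."""
    params = SimulationParams(n=30, theta=1.0, region_length=20_000, seed=43)
    rmap = build_hotspot_map(20_000, 0.5, [((9_000, 11_000), 25.0)])
    return simulate_haplotypes(params, rmap)
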