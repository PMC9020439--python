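"""Shared fixtures: one small synthetic survey and its fitted models.

Session-scoped so the expensive hierarchical fit happens once; individual
tests treat the fitted objects as read-only.
"""

import numpy as np
import pytest

import flywaytrend as ft
from flywaytrend.gridding import assign_sites, build_grid


@pytest.fixture(scope="session")
def small_sim():
    """25-cell, 3-sites-per-cell survey drawn from the default truth."""
    land = ft.generate_landscape(n_cells=25, sites_per_cell=3, seed=41)
    sim = ft.generate_counts(land, ft.truth_params_default(), seed=42)
    sim.table = ft.project_coordinates(sim.table)
    return sim


@pytest.fixture(scope="session")
def small_assignment(small_sim):
    grid = build_grid(small_sim.table)
    return assign_sites(small_sim.table, grid), grid


@pytest.fixture(scope="session")
def hier_fit(small_sim, small_assignment):
    assignment, _ = small_assignment
    fit = ft.fit_hierarchical(small_sim.table, assignment)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def prelim_fit(small_sim):
    fit = ft.fit_preliminary(small_sim.table)
    assert fit.converged
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
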