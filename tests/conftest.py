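"""Shared fixtures: tiny hand-built planning problems and a quick phantom."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

import lexiplan as lp
from lexiplan.beams import Beamlet, DoseInfluence
from lexiplan.phantom import GridSpec, Phantom


def make_tiny_problem(matrix: np.ndarray, ptv_rows, oar_rows=(), body_rows=None):
    """Build a Phantom + DoseInfluence pair from a dense (n_voxels x
    n_beamlets) matrix laid out on a 1-D voxel grid. Used for closed-form
    and brute-force oracle tests."""
    matrix = np.asarray(matrix, dtype=float)
    m, n = matrix.shape
    grid = GridSpec((m, 1, 1), (1.0, 1.0, 1.0))

    def mask_from(rows):
        mk = np.zeros((m, 1, 1), dtype=bool)
        for r in rows:
            mk[r, 0, 0] = True
        return mk

    body = mask_from(range(m) if body_rows is None else body_rows)
    structures = {"body": body, "ptv": mask_from(ptv_rows)}
    if oar_rows:
        structures["oar"] = mask_from(oar_rows)
    phantom = Phantom(grid=grid, structures=structures, seed=0)
    infl = DoseInfluence(
        matrix=sparse.csc_matrix(matrix),
        beamlets=[Beamlet(beam=0, angle_deg=0.0, offset_mm=float(j)) for j in range(n)],
        voxel_rows=np.flatnonzero(body.ravel()),
        grid_shape=grid.shape,
    )
    return phantom, infl


@pytest.fixture(scope="session")
def tiny_problem_factory():
    return make_tiny_problem


@pytest.fixture(scope="session")
def default_phantom():
    """Default-parameter phantom, seed 1 (matches the study conditions)."""
    return lp.generate_phantom(1)


@pytest.fixture(scope="session")
def quick_plan(default_phantom):
    """One full planning run on the default phantom with 20 beams.

    Session-scoped: several test modules inspect the same optimized plan
    (trace invariants, evaluation consistency, planner API)."""
    planner = lp.FluencePlanner(default_phantom)
    return planner.fit()


#: settings tight enough for oracle comparisons on tiny instances
TIGHT = lp.OptimizerSettings(
    solver_tol=1e-8, ftol=1e-9, feas_accept=1e-5, inner_solver="newton",
    al_max_outer=120, inner_maxiter=100, al_rho_max=1e9, al_growth=8.0,
)


@pytest.fixture(scope="session")
def tight_settings():
    return TIGHT
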