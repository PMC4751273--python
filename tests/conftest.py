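"""Shared fixtures: default parameters, rasterized grids, cached case runs."""

from __future__ import annotations

import numpy as np
import pytest

import periclear as pc


@pytest.fixture(scope="session")
def params() -> pc.Parameters:
    return pc.Parameters()


@pytest.fixture(scope="session")
def coronal25(params) -> pc.GeometryGrid:
    """Coronal-like slice at the production resolution (25 um)."""
    return pc.make_slice(pc.coronal_like_spec(dx=25e-6))


@pytest.fixture(scope="session")
def coronal_run(params, coronal25):
    """Factory returning (and caching) full 32-min runs of canonical cases."""
    cache: dict[str, pc.SimulationResult] = {}

    def run(case_id: str) -> pc.SimulationResult:
        if case_id not in cache:
            cache[case_id] = pc.run_simulation(
                pc.build_case(case_id), coronal25, params)
        return cache[case_id]

    return run


@pytest.fixture(scope="session")
def heat_kernel_run(params):
    """Instantaneous point release on a calibration domain, diffusion only.

    Returns (grid, result, release time, released moles per unit depth).
    """
    grid = pc.make_calibration_domain(6e-3, 6e-3, 25e-6, source="none")
    state = pc.FieldState.zeros(grid)
    state.c[grid.nx // 2, grid.ny // 2] = 1.0
    moles = grid.dx**2 * 1.0
    result = pc.run_simulation(
        pc.build_case("A1"), grid, params.replace(t_inject=0.0),
        initial_state=state, t_total=600.0, record_dt=100.0,
        snapshot_dt=100.0, injection_mode="no_flux")
    return grid, result, 600.0, moles


def interp_distance(result: pc.SimulationResult, t: float,
                    compartment: str = "combined") -> float:
    times, dist = result.distance_series(compartment)
    return float(np.interp(t, times, dist))
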