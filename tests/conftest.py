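import numpy as np
import pytest

from ribotraffic import ResponseCurve, SimConfig, synthetic_rate_table


@pytest.fixture(scope="session")
def quick_cfg():
    """Short sampling plan for desk-scale unit tests."""
    return SimConfig(burn_in_time=200.0, measure_time=1000.0, seed=5)


@pytest.fixture(scope="session")
def synth_table():
    return synthetic_rate_table(k_fast=20.0, k_slow=1.0)


@pytest.fixture
def analytic_curve():
    """Factory for noise-free response curves from closed-form J/rho functions."""

    def make(grid, J_fn, rho_fn, gene_id="analytic"):
        grid = np.asarray(grid, dtype=float)
        J = np.array([J_fn(a) for a in grid], dtype=float)
        rho = np.array([rho_fn(a) for a in grid], dtype=float)
        return ResponseCurve(
            gene_id=gene_id,
            alpha_grid=grid,
            J_raw=J,
            rho_raw=rho,
            J_stderr=np.zeros_like(grid),
            rho_stderr=np.zeros_like(grid),
            J_smooth=J.copy(),
            rho_smooth=rho.copy(),
        )

    return make
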