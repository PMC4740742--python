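import numpy as np
import pytest

import bioelectric as be


@pytest.fixture(scope="session")
def model():
    """Reference cell: G_in=G_out=1 nS, V_th=-25 mV, z=3, E_in=-60,
    E_out=0, V_T=27 mV, C_0=100 pF."""
    return be.default_model()


@pytest.fixture(scope="session")
def reference_roots():
    """Dense-scan oracle for the reference cell's fixed points.

    Independent of the package: the logistic currents are written out
    directly and roots are located by sign change on a 0.01 mV grid,
    refined by bisection.
    """

    def total(v, ratio=1.0, e_in=-60.0):
        p_in = 1.0 / (1.0 + np.exp(3.0 * (v + 25.0) / 27.0))
        p_out = 1.0 / (1.0 + np.exp(-3.0 * (v + 25.0) / 27.0))
        return p_in * (v - e_in) + ratio * p_out * v

    def scan(ratio=1.0, e_in=-60.0, lo=-100.0, hi=40.0):
        grid = np.arange(lo, hi + 1e-9, 0.01)
        f = total(grid, ratio, e_in)
        roots = []
        for k in np.nonzero(f[:-1] * f[1:] < 0)[0]:
            a, b = grid[k], grid[k + 1]
            for _ in range(60):  # bisection to ~1e-14 mV
                mid = 0.5 * (a + b)
                if total(mid, ratio, e_in) * total(a, ratio, e_in) <= 0:
                    b = mid
                else:
                    a = mid
            roots.append(0.5 * (a + b))
        return roots

    return scan


@pytest.fixture(scope="session")
def euler_reference():
    """Explicit-Euler lattice integrator written from scratch as an
    independent oracle for the IMEX stepper."""

    def run(v0, lattice, ratio_grid, g, dt, n_steps, model):
        L = be.build_laplacian(lattice, be.CouplingParams(g=g)).toarray()
        from bioelectric.single_cell import dimensionless_total_current

        v = np.asarray(v0, dtype=float).copy()
        r = np.asarray(ratio_grid, dtype=float).ravel()
        for _ in range(n_steps):
            v = v + dt * (-dimensionless_total_current(v, r, model) - L @ v)
        return v

    return run
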