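"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's closed-form code paths:
the variance oracle iterates the one-cycle law-of-total-variance recursion
directly, and the slope oracle minimizes the calibration residual by
iterative grid refinement.  Tests compare the package's closed forms
against these independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from pcruq.moments import EfficiencyParams, InputCase, InputDistribution, mean_matrix


def variance_recursion(
    eff: EfficiencyParams,
    mean_U0: np.ndarray,
    var_U0: np.ndarray,
    n_cycles: int,
) -> np.ndarray:
    """Iterate the one-cycle variance update directly.

    Var[U_i] = A Var[U_{i-1}] A^T
               + diag(p_rf (1 - p_rf) E[Y_{i-1}], p_fr (1 - p_fr) E[X_{i-1}])

    with the mean propagated by repeated multiplication with A.  This is
    the independent route against which the geometric-series closed form
    is validated.
    """
    A = mean_matrix(eff)
    mean = np.asarray(mean_U0, dtype=float).copy()
    var = np.asarray(var_U0, dtype=float).copy()
    out = np.empty((n_cycles + 1, 2, 2))
    out[0] = var
    a_rf = eff.p_rf * (1.0 - eff.p_rf)
    a_fr = eff.p_fr * (1.0 - eff.p_fr)
    for i in range(1, n_cycles + 1):
        var = A @ var @ A.T + np.diag([a_rf * mean[1], a_fr * mean[0]])
        mean = A @ mean
        out[i] = var
    return out


def grid_search_slope(C: np.ndarray, F: np.ndarray, refinements: int = 40) -> float:
    """Minimize ||F - f C||^2 over f by iterative grid refinement."""
    C = np.asarray(C, dtype=float)
    F = np.asarray(F, dtype=float)
    scale = max(np.abs(F).max() / max(C.min(), 1e-300), 1.0)
    lo, hi = -2.0 * scale, 2.0 * scale
    best = 0.0
    for _ in range(refinements):
        grid = np.linspace(lo, hi, 33)
        sse = ((F[None, :] - grid[:, None] * C[None, :]) ** 2).sum(axis=1)
        k = int(sse.argmin())
        best = grid[k]
        step = grid[1] - grid[0]
        lo, hi = best - step, best + step
    return float(best)


def random_efficiency(rng: np.random.Generator, with_r: bool = False) -> EfficiencyParams:
    """A random parameter point inside the usual assay ranges."""
    p_bar = rng.uniform(0.8, 0.99)
    # keep both directional probabilities p_bar*R and p_bar/R inside (0, 1]
    R = rng.uniform(max(0.9, p_bar), min(1.1, 1.0 / p_bar))
    r = rng.uniform(0.2, 0.99) if with_r else None
    return EfficiencyParams(p_bar=p_bar, R=R, r=r)


def random_input(rng: np.random.Generator, case=None) -> InputDistribution:
    if case is None:
        case = rng.choice(["D", "RF", "RR"])
    return InputDistribution(
        case=InputCase(case), mean_I=float(rng.uniform(5.0, 200.0))
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230814)
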