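"""Detectability constraint and analytic limits of detection.

A run is called detected after ``n`` cycles if the expected fluorescence
exceeds the background by at least ``kappa`` standard deviations,

    E[F_{n,w}] - kappa * sqrt(Var[F_{n,w}]) >= b_{n,w},

which after substituting the affine fluorescence model reduces to the
well-independent criterion ``CV[DeltaX_n] <= 1/kappa``.  For cycle counts
in the usual 35-50 range the squared CV is indistinguishable from its
asymptote ``alpha * CV[I]^2 + beta / E[I]``; with the variance-to-mean
ratio ``Var[I] = chi * E[I]`` the criterion rearranges to
``E[I] >= (chi * alpha + beta) * kappa**2``.  The limit of detection

    L = min{ y in positive integers : y >= (chi*alpha + beta) * kappa**2 }

is the smallest reliably detectable expected input copy number, and
``M = sqrt(chi / L)`` is the largest detectable input coefficient of
variation.  ``lod_grid`` scans these quantities over ranges of the
amplification parameters; ``feasibility_check`` evaluates the finite-n
inequality with exact moments instead of the asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluorescence import FluorescenceParams
from .moments import (
    EfficiencyParams,
    InputCase,
    InputDistribution,
    alpha_beta,
    alpha_beta_arrays,
    moment_trajectory,
)

__all__ = [
    "DetectionSpec",
    "LODResult",
    "LODGrid",
    "FeasibilityResult",
    "lod_point",
    "lod_grid",
    "feasibility_check",
]


@dataclass(frozen=True)
class DetectionSpec:
    """Detection criterion and parameter grid for the LOD scan.

    Default grid: 100 equally spaced values (endpoints included) of
    ``p_bar`` in [0.8, 0.99], ``R`` in [0.9, 1.1] and, for RNA input,
    ``r`` in [0.2, 0.99].  The ``r`` dimension is collapsed for Case D.
    """

    case: InputCase
    kappa: float = 3.0
    chi: float = 1.0
    p_bar_range: tuple = (0.8, 0.99)
    p_bar_count: int = 100
    R_range: tuple = (0.9, 1.1)
    R_count: int = 100
    r_range: tuple = (0.2, 0.99)
    r_count: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "case", InputCase(self.case))
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.chi <= 0:
            raise ValueError("chi must be positive")
        for name in ("p_bar_count", "R_count", "r_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p = np.linspace(*self.p_bar_range, self.p_bar_count)
        R = np.linspace(*self.R_range, self.R_count)
        if self.case is InputCase.D:
            r = np.array([np.nan])
        else:
            r = np.linspace(*self.r_range, self.r_count)
        return p, R, r


@dataclass(frozen=True)
class LODResult:
    """Limit of detection at one parameter point.

    ``L`` is in expected input copies; ``M = sqrt(chi / L)`` is the
    largest detectable input CV.
    """

    L: int
    M: float
    alpha: float
    beta: float


def _smallest_detectable(threshold: float) -> int:
    """Smallest positive integer ``y`` with ``y >= threshold``.

    The inequality is non-strict, so an exactly integral threshold is
    itself the limit; thresholds below 1 give ``L = 1`` (an expected
    input of zero copies is never detectable).
    """
    if not math.isfinite(threshold):
        raise ValueError(f"non-finite detection threshold {threshold}")
    return max(1, math.ceil(threshold))


def lod_point(eff: EfficiencyParams, spec: DetectionSpec) -> LODResult:
    """Limit of detection from the asymptotic CV criterion."""
    a, b = alpha_beta(eff, spec.case)
    L = _smallest_detectable((spec.chi * a + b) * spec.kappa**2)
    return LODResult(L=L, M=math.sqrt(spec.chi / L), alpha=a, beta=b)


@dataclass
class LODGrid:
    """Vectorized LOD scan over a parameter grid (flattened arrays)."""

    spec: DetectionSpec
    p_bar: np.ndarray
    R: np.ndarray
    r: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    L: np.ndarray
    M: np.ndarray

    @property
    def min_L(self) -> int:
        return int(self.L.min())

    @property
    def max_L(self) -> int:
        return int(self.L.max())

    @property
    def max_M(self) -> float:
        """Largest detectable input CV, attained at the grid minimum of L."""
        return float(math.sqrt(self.spec.chi / self.min_L))

    @property
    def min_M(self) -> float:
        return float(math.sqrt(self.spec.chi / self.max_L))

    def _argpoint(self, idx: int) -> dict:
        point = {
            "p_bar": float(self.p_bar[idx]),
            "R": float(self.R[idx]),
            "L": int(self.L[idx]),
            "M": float(self.M[idx]),
        }
        if self.spec.case is not InputCase.D:
            point["r"] = float(self.r[idx])
        return point

    def summary(self) -> dict:
        """Extremes of L with the parameter points attaining them.

        Pairs min-L with max-M and max-L with min-M, mirroring how the
        detection limits are usually reported.
        """
        return {
            "case": self.spec.case.value,
            "kappa": self.spec.kappa,
            "chi": self.spec.chi,
            "n_grid_points": int(self.L.size),
            "min_L": self.min_L,
            "max_M": self.max_M,
            "argmin_L": self._argpoint(int(self.L.argmin())),
            "max_L": self.max_L,
            "min_M": self.min_M,
            "argmax_L": self._argpoint(int(self.L.argmax())),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_bar": self.p_bar,
                "R": self.R,
                "r": self.r,
                "alpha": self.alpha,
                "beta": self.beta,
                "L": self.L,
                "M": self.M,
            }
        )


def lod_grid(spec: DetectionSpec) -> LODGrid:
    """Evaluate the LOD over the full Cartesian parameter grid."""
    p_axis, R_axis, r_axis = spec.axes()
    p, R, r = np.meshgrid(p_axis, R_axis, r_axis, indexing="ij")
    p, R, r = p.ravel(), R.ravel(), r.ravel()
    alpha, beta = alpha_beta_arrays(
        p, R, None if spec.case is InputCase.D else r, spec.case
    )
    threshold = (spec.chi * alpha + beta) * spec.kappa**2
    if not np.all(np.isfinite(threshold)):
        raise ValueError("non-finite detection threshold on grid")
    L = np.maximum(1, np.ceil(threshold)).astype(np.int64)
    return LODGrid(
        spec=spec,
        p_bar=p,
        R=R,
        r=r,
        alpha=alpha,
        beta=beta,
        L=L,
        M=np.sqrt(spec.chi / L),
    )


@dataclass
class FeasibilityResult:
    """Finite-cycle detectability verdicts.

    ``per_well`` evaluates the kappa-sigma inequality with exact moments
    well by well; ``well_independent`` is the equivalent criterion
    ``CV[DeltaX_n]^2 <= 1/kappa^2`` in which the per-well brightness
    cancels.  A zero expected signal is infeasible by definition.
    """

    per_well: np.ndarray
    well_independent: bool
    cv2_delta_x: float
    kappa: float
    n_cycles: int


def feasibility_check(
    eff: EfficiencyParams,
    inp: InputDistribution,
    params: FluorescenceParams,
    n_cycles: int,
    kappa: float = 3.0,
) -> FeasibilityResult:
    """Exact-moment detectability check after ``n_cycles`` cycles."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be at least 1")
    traj = moment_trajectory(eff, inp, n_cycles)
    mean_dx, var_dx = traj.delta_x_moments()
    mean_n, var_n = float(mean_dx[n_cycles]), float(var_dx[n_cycles])

    row = int(np.nonzero(params.cycles == n_cycles)[0][0]) if np.any(
        params.cycles == n_cycles
    ) else -1
    if row < 0:
        raise ValueError(f"parameters do not cover cycle {n_cycles}")
    b = params.b[row]
    d = params.d[row]
    if mean_n <= 0:
        per_well = np.zeros_like(b, dtype=bool)
        return FeasibilityResult(per_well, False, math.inf, kappa, n_cycles)
    mean_F = b + d * mean_n
    sd_F = d * math.sqrt(var_n)
    per_well = mean_F - kappa * sd_F >= b
    cv2 = var_n / mean_n**2
    return FeasibilityResult(per_well, cv2 <= 1.0 / kappa**2, cv2, kappa, n_cycles)
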