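"""Exact and asymptotic moments of the strand-specific PCR branching process.

PCR is modelled as a two-type Galton-Watson process tracking the counts of
forward and reverse strands, ``U_i = (X_i, Y_i)``, after each cycle ``i``.
During a cycle every reverse strand templates a new forward strand with
probability ``p_rf = p_bar * R`` and every forward strand templates a new
reverse strand with probability ``p_fr = p_bar / R``, all trials
independent.  Here ``p_bar = sqrt(p_rf * p_fr)`` is the geometric mean of
the two directional amplification efficiencies (the quantity conventionally
called *the* PCR efficiency) and ``R = sqrt(p_rf / p_fr)`` measures their
asymmetry.

The per-cycle mean map is the matrix::

    A = | 1      p_bar*R |
        | p_bar/R     1  |

with eigenvalues ``lambda1 = 1 + p_bar`` (exponential growth) and
``lambda2 = 1 - p_bar`` (relaxation of the forward/reverse ratio toward its
critical value ``R``).  This module provides

* the spectral decomposition of ``A`` in closed form,
* initial strand-count moments for the three input types (double-stranded
  DNA, forward-stranded RNA, reverse-stranded RNA -- Cases D, RF, RR),
* exact per-cycle mean vectors, covariance matrices, and the
  cross-covariance ``Cov[X_i, X_0]``,
* the single-type ("conventional") closed forms used when ``R = 1``, and
* the asymptotic squared coefficient of variation
  ``alpha * CV[I]^2 + beta / E[I]`` with its case-dependent coefficients.

All moments are computed in double precision; cycle counts above 500 are
rejected because ``lambda1**(2*i)`` would overflow.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InputCase",
    "EfficiencyParams",
    "InputDistribution",
    "SpectralDecomposition",
    "MomentTrajectory",
    "spectral",
    "mean_matrix",
    "initial_moments",
    "expected_counts",
    "ratio_limit",
    "variance_counts",
    "cross_cov",
    "conventional_moments",
    "alpha_beta",
    "alpha_beta_arrays",
    "asymptotic_cv2",
    "moment_trajectory",
]

#: Largest supported cycle count; lambda1**(2*i) must stay below ~1.8e308.
MAX_CYCLES = 500

_FAMILIES = ("poisson", "negative_binomial", "fixed")


class InputCase(str, enum.Enum):
    """Input nucleic-acid type.

    D  -- double-stranded DNA: both strands input, i.i.d. copy numbers.
    RF -- forward-stranded RNA: reverse-transcription yields reverse cDNA.
    RR -- reverse-stranded RNA: reverse-transcription yields forward cDNA.
    """

    D = "D"
    RF = "RF"
    RR = "RR"


def _as_case(case: "InputCase | str") -> InputCase:
    if isinstance(case, InputCase):
        return case
    try:
        return InputCase(str(case).upper())
    except ValueError:
        raise ValueError(
            f"unknown input case {case!r}; expected one of 'D', 'RF', 'RR'"
        ) from None


def _check_cycles(n_cycles: int) -> int:
    n = int(n_cycles)
    if n < 0:
        raise ValueError("cycle count must be nonnegative")
    if n > MAX_CYCLES:
        raise ValueError(
            f"cycle count {n} exceeds {MAX_CYCLES}; second moments would "
            "overflow double precision"
        )
    return n


@dataclass(frozen=True)
class EfficiencyParams:
    """Amplification efficiencies of the two-type process.

    Parameters
    ----------
    p_bar:
        Geometric-mean amplification efficiency, in ``(0, 1]``.
    R:
        Directional-efficiency ratio parameter (``sqrt(p_rf / p_fr)``),
        positive.  ``R = 1`` recovers the strand-symmetric process.
    r:
        Reverse-transcription efficiency in ``(0, 1]``; only required for
        RNA input (Cases RF and RR).

    The derived strand-specific probabilities ``p_fr = p_bar / R`` and
    ``p_rf = p_bar * R`` must both lie in ``(0, 1]``.  The closed right
    endpoint (perfect efficiency) is accepted as the natural doubling
    limit; zero efficiency is not.
    """

    p_bar: float
    R: float = 1.0
    r: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_bar <= 1.0:
            raise ValueError(f"p_bar must be in (0, 1], got {self.p_bar}")
        if not self.R > 0.0:
            raise ValueError(f"R must be positive, got {self.R}")
        for name, value in (("p_fr", self.p_fr), ("p_rf", self.p_rf)):
            if not 0.0 < value <= 1.0:
                raise ValueError(
                    f"derived probability {name} = {value:.6g} falls outside "
                    f"(0, 1]; p_bar = {self.p_bar} and R = {self.R} are "
                    "incompatible"
                )
        if self.r is not None and not 0.0 < self.r <= 1.0:
            raise ValueError(f"r must be in (0, 1], got {self.r}")

    @property
    def p_fr(self) -> float:
        """Probability a forward strand templates a new reverse strand."""
        return self.p_bar / self.R

    @property
    def p_rf(self) -> float:
        """Probability a reverse strand templates a new forward strand."""
        return self.p_bar * self.R

    @property
    def lambda1(self) -> float:
        return 1.0 + self.p_bar

    @property
    def lambda2(self) -> float:
        return 1.0 - self.p_bar

    def require_r(self) -> float:
        if self.r is None:
            raise ValueError(
                "reverse-transcription efficiency r is required for RNA "
                "input (Case RF or RR) but was not provided"
            )
        return self.r


@dataclass(frozen=True)
class InputDistribution:
    """Distribution of the input copy number ``I``.

    The variance is specified either through the variance-to-mean ratio
    ``chi`` (``Var[I] = chi * E[I]``) or directly as ``var_I``.  The
    ``family`` is used by the Monte-Carlo simulator only; the moment
    formulas depend on the first two moments alone.
    """

    case: InputCase
    mean_I: float
    family: str = "poisson"
    chi: float | None = None
    var_I: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "case", _as_case(self.case))
        if self.mean_I < 0:
            raise ValueError(f"mean_I must be nonnegative, got {self.mean_I}")
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.chi is not None and self.var_I is not None:
            raise ValueError("specify chi or var_I, not both")
        if self.chi is not None and self.chi <= 0:
            raise ValueError(f"chi must be positive, got {self.chi}")
        if self.var_I is not None and self.var_I < 0:
            raise ValueError(f"var_I must be nonnegative, got {self.var_I}")
        if self.family == "poisson":
            if self.var_I is not None:
                raise ValueError("a Poisson input has Var[I] = E[I]; use chi")
            if self.chi is None:
                object.__setattr__(self, "chi", 1.0)
            elif self.chi != 1.0:
                raise ValueError("a Poisson input requires chi = 1")
        elif self.family == "negative_binomial":
            if self.chi is None or self.chi <= 1.0:
                raise ValueError(
                    "a negative-binomial input requires chi > 1 "
                    "(chi = 1/phi for success probability phi)"
                )
        elif self.family == "fixed":
            if self.chi is not None:
                raise ValueError("a fixed input has zero variance; omit chi")
            if self.var_I not in (None, 0, 0.0):
                raise ValueError("a fixed input requires var_I = 0")
            object.__setattr__(self, "var_I", 0.0)

    @property
    def variance(self) -> float:
        """``Var[I]``, resolved from ``chi`` or ``var_I``."""
        if self.var_I is not None:
            return float(self.var_I)
        return float(self.chi) * float(self.mean_I)

    @property
    def cv2(self) -> float:
        """Squared coefficient of variation of ``I``."""
        if self.mean_I <= 0:
            raise ValueError("CV[I] is undefined for mean_I = 0")
        return self.variance / self.mean_I**2


@dataclass(frozen=True)
class SpectralDecomposition:
    """Closed-form eigendecomposition ``A = sum_j lambda_j x_j z_j^T``.

    The eigenvectors use the deterministic scaling in which all four
    vectors have unit Euclidean norm when ``R = 1``; a generic eigensolver
    is deliberately not used, so signs and scale are reproducible.
    """

    lambda1: float
    lambda2: float
    x1: np.ndarray
    x2: np.ndarray
    z1: np.ndarray
    z2: np.ndarray

    @property
    def eigenvalues(self) -> tuple[float, float]:
        return (self.lambda1, self.lambda2)

    @property
    def right_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.x1, self.x2)

    @property
    def left_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.z1, self.z2)

    def matrix(self) -> np.ndarray:
        """Reconstruct ``A`` from the rank-one terms."""
        return self.lambda1 * np.outer(self.x1, self.z1) + self.lambda2 * np.outer(
            self.x2, self.z2
        )


def mean_matrix(eff: EfficiencyParams) -> np.ndarray:
    """The per-cycle mean map ``A = [[1, p_bar*R], [p_bar/R, 1]]``."""
    return np.array([[1.0, eff.p_rf], [eff.p_fr, 1.0]])


def spectral(eff: EfficiencyParams) -> SpectralDecomposition:
    """Closed-form spectral decomposition of the mean matrix."""
    R = eff.R
    s = 1.0 / math.sqrt(2.0)
    return SpectralDecomposition(
        lambda1=eff.lambda1,
        lambda2=eff.lambda2,
        x1=np.array([R, 1.0]) * s,
        x2=np.array([R, -1.0]) * s,
        z1=np.array([1.0, R]) / (R * math.sqrt(2.0)),
        z2=np.array([1.0, -R]) / (R * math.sqrt(2.0)),
    )


def initial_moments(
    inp: InputDistribution, eff: EfficiencyParams
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance matrix of the initial strand count ``U_0``.

    Case D passes the input moments through to both strands.  For RNA input
    the reverse-transcription step thins ``I`` binomially with efficiency
    ``r``, so by the law of total variance
    ``Var[B(I; r)] = r**2 * Var[I] + r*(1 - r) * E[I]``.  The off-diagonal
    covariance is zero in every case (the strand counts are independent at
    cycle zero).
    """
    m = float(inp.mean_I)
    v = inp.variance
    if inp.case is InputCase.D:
        return np.array([m, m]), np.diag([v, v]).astype(float)
    r = eff.require_r()
    vb = v * r * r + r * (1.0 - r) * m
    if inp.case is InputCase.RF:
        return np.array([0.0, r * m]), np.diag([0.0, vb])
    return np.array([r * m, 0.0]), np.diag([vb, 0.0])


def expected_counts(
    eff: EfficiencyParams, mean_U0: np.ndarray, n_cycles: int
) -> np.ndarray:
    """Expected strand counts ``E[U_i]`` for ``i = 0 .. n_cycles``.

    Returns an ``(n_cycles + 1, 2)`` array; row ``i`` equals
    ``A**i @ mean_U0`` evaluated through the spectral decomposition:
    ``E[U_i] = (z1 . E[U_0]) lambda1**i x1 + (z2 . E[U_0]) lambda2**i x2``.
    """
    n = _check_cycles(n_cycles)
    mean_U0 = np.asarray(mean_U0, dtype=float)
    sd = spectral(eff)
    c1 = float(sd.z1 @ mean_U0)
    c2 = float(sd.z2 @ mean_U0)
    i = np.arange(n + 1)
    return np.outer(c1 * sd.lambda1**i, sd.x1) + np.outer(c2 * sd.lambda2**i, sd.x2)


def ratio_limit(eff: EfficiencyParams) -> float:
    """Limiting ratio ``E[X_i] / E[Y_i]`` as ``i`` grows.

    The ratio of expected forward to reverse strand counts relaxes from its
    input value to the critical value ``R`` once the ``lambda2**i`` term has
    decayed (the lag phase, typically a few cycles).
    """
    return float(eff.R)


def _eta_coefficients(
    sd: SpectralDecomposition, eff: EfficiencyParams, mean_U0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-series coefficients of the closed-form variance.

    Returns ``(K, eta)`` where ``K[l]`` is the 2x2 reproduction-variance
    matrix attached to eigenvalue ``lambda_l`` and
    ``eta[j, k, l] = z_j^T K_l z_k / (lambda_j lambda_k - lambda_l)``.
    The denominator cannot vanish for ``p_bar`` in (0, 1); at the accepted
    boundary ``p_bar = 1`` it vanishes only where the binomial-variance
    factor makes the numerator exactly zero, in which case the term is 0.
    """
    a_rf = eff.p_rf * (1.0 - eff.p_rf)
    a_fr = eff.p_fr * (1.0 - eff.p_fr)
    lams = (sd.lambda1, sd.lambda2)
    xs = sd.right_vectors
    zs = sd.left_vectors
    K = np.empty((2, 2, 2))
    for l in range(2):
        scale = float(zs[l] @ mean_U0)
        K[l] = np.diag([a_rf * xs[l][1], a_fr * xs[l][0]]) * scale
    eta = np.empty((2, 2, 2))
    for j in range(2):
        for k in range(2):
            for l in range(2):
                num = float(zs[j] @ K[l] @ zs[k])
                den = lams[j] * lams[k] - lams[l]
                if abs(den) < 1e-12:
                    if num == 0.0:
                        eta[j, k, l] = 0.0
                    else:
                        raise ZeroDivisionError(
                            f"degenerate eigenvalue combination lambda_{j+1}"
                            f"*lambda_{k+1} == lambda_{l+1} with nonzero "
                            "numerator"
                        )
                else:
                    eta[j, k, l] = num / den
    return K, eta


def variance_counts(
    eff: EfficiencyParams,
    mean_U0: np.ndarray,
    var_U0: np.ndarray,
    n_cycles: int,
) -> np.ndarray:
    """Covariance matrices ``Var[U_i]`` for ``i = 0 .. n_cycles``.

    Evaluates the closed form obtained by resolving the variance recursion
    ``Var[U_i] = A Var[U_{i-1}] A^T + sum_l lambda_l**(i-1) K_l`` into
    geometric series::

        Var[U_i] = sum_{j,k} { (nu_jk + sum_l eta_jk^l) (lambda_j lambda_k)^i
                               - sum_l eta_jk^l lambda_l^i } x_j x_k^T

    with ``nu_jk = z_j^T Var[U_0] z_k``.  Output is symmetrized to remove
    ~1e-16 floating-point asymmetry.
    """
    n = _check_cycles(n_cycles)
    mean_U0 = np.asarray(mean_U0, dtype=float)
    var_U0 = np.asarray(var_U0, dtype=float)
    if var_U0.shape != (2, 2):
        raise ValueError("var_U0 must be a 2x2 matrix")
    if not np.allclose(var_U0, var_U0.T):
        raise ValueError("var_U0 must be symmetric")
    if np.any(np.diag(var_U0) < 0):
        raise ValueError("var_U0 must have nonnegative diagonal")

    sd = spectral(eff)
    lams = np.array([sd.lambda1, sd.lambda2])
    xs = sd.right_vectors
    zs = sd.left_vectors
    nu = np.array([[zs[j] @ var_U0 @ zs[k] for k in range(2)] for j in range(2)])
    _, eta = _eta_coefficients(sd, eff, mean_U0)

    i = np.arange(n + 1)
    out = np.zeros((n + 1, 2, 2))
    for j in range(2):
        for k in range(2):
            coef = (nu[j, k] + eta[j, k].sum()) * (lams[j] * lams[k]) ** i
            coef = coef - eta[j, k, 0] * lams[0] ** i - eta[j, k, 1] * lams[1] ** i
            out += coef[:, None, None] * np.outer(xs[j], xs[k])
    out = 0.5 * (out + np.swapaxes(out, 1, 2))
    out[0] = var_U0  # the closed form is exact at i = 0; avoid ~1e-16 noise
    return out


def cross_cov(eff: EfficiencyParams, var_X0: float, n_cycles: int) -> np.ndarray:
    """``Cov[X_i, X_0] = (Var[X_0] / 2) (lambda1**i + lambda2**i)``."""
    n = _check_cycles(n_cycles)
    if var_X0 < 0:
        raise ValueError("var_X0 must be nonnegative")
    i = np.arange(n + 1)
    return 0.5 * var_X0 * (eff.lambda1**i + eff.lambda2**i)


def conventional_moments(
    p: float, mean_N0: float, var_N0: float, n_cycles: int
) -> tuple[np.ndarray, np.ndarray]:
    """Single-type closed forms for total strand count when ``R = 1``.

    ``E[N_i] = E[N_0] (1 + p)**i`` and::

        Var[N_i] = {Var[N_0] + E[N_0] (1-p)/(1+p)} (1+p)**(2i)
                   - E[N_0] (1-p) (1+p)**(i-1)

    Returned as a pair of ``(n_cycles + 1,)`` arrays.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    n = _check_cycles(n_cycles)
    i = np.arange(n + 1)
    growth = (1.0 + p) ** i
    mean = mean_N0 * growth
    var = (var_N0 + mean_N0 * (1.0 - p) / (1.0 + p)) * growth**2
    var = var - mean_N0 * (1.0 - p) * (1.0 + p) ** (i - 1.0)
    return mean, var


def alpha_beta_arrays(
    p_bar: np.ndarray,
    R: np.ndarray,
    r: "np.ndarray | float | None",
    case: "InputCase | str",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized asymptotic-CV coefficients ``(alpha, beta)``.

    Broadcasts over ``p_bar``, ``R`` and (for RNA cases) ``r``.  Used by
    the limit-of-detection grid scan, where ~1e6 points are evaluated.
    """
    case = _as_case(case)
    p = np.asarray(p_bar, dtype=float)
    R = np.asarray(R, dtype=float)
    l1 = 1.0 + p
    l2 = 1.0 - p
    h = l2 / l1  # imperfect-amplification factor
    g = p * l1 / (l1 * l1 - l2)
    if case is InputCase.D:
        alpha = (R * R + 1.0) / (R + 1.0) ** 2
        beta = 0.5 * h - 0.5 * g * ((R - 1.0) / (R + 1.0)) ** 2
        return np.broadcast_arrays(alpha, beta)
    if r is None:
        raise ValueError("r is required for Case RF or RR")
    r = np.asarray(r, dtype=float)
    lead = (1.0 - r) / r
    if case is InputCase.RF:
        beta = lead + h * (R + 1.0) / (2.0 * R * r) - g * (R - 1.0) / (2.0 * R * r)
    else:  # Case RR
        beta = lead + h * (R + 1.0) / (2.0 * r) + g * (R - 1.0) / (2.0 * r)
    alpha = np.ones_like(beta)
    return alpha, beta


def alpha_beta(
    eff: EfficiencyParams, case: "InputCase | str"
) -> tuple[float, float]:
    """Asymptotic-CV coefficients for one parameter point.

    ``CV[U_i]^2 -> alpha * CV[I]^2 + beta / E[I]`` as ``i`` grows.  For
    Case D, ``alpha = (R^2 + 1)/(R + 1)^2`` (0.5 at ``R = 1``); for RNA
    input ``alpha = 1`` and ``beta`` carries the reverse-transcription
    shot noise ``(1 - r)/r``.
    """
    case = _as_case(case)
    r = eff.require_r() if case is not InputCase.D else None
    a, b = alpha_beta_arrays(eff.p_bar, eff.R, r, case)
    return float(a), float(b)


def asymptotic_cv2(eff: EfficiencyParams, inp: InputDistribution) -> float:
    """Large-cycle limit of every entry of ``CV[U_i]^2``.

    Equals ``alpha * CV[I]^2 + beta / E[I]``; the exact squared CV
    approaches this value at rate ``O(lambda1**-i)``.
    """
    if inp.mean_I <= 0:
        raise ValueError("asymptotic CV is undefined for mean_I = 0")
    a, b = alpha_beta(eff, inp.case)
    return a * inp.cv2 + b / inp.mean_I


@dataclass
class MomentTrajectory:
    """Per-cycle first and second moments of the strand counts.

    Attributes
    ----------
    mean_U:
        ``(n + 1, 2)`` expected forward/reverse counts per cycle.
    var_U:
        ``(n + 1, 2, 2)`` covariance matrices per cycle.
    cov_X_X0:
        ``(n + 1,)`` cross-covariance ``Cov[X_i, X_0]``.
    """

    mean_U: np.ndarray
    var_U: np.ndarray
    cov_X_X0: np.ndarray

    def __post_init__(self) -> None:
        self.mean_U = np.asarray(self.mean_U, dtype=float)
        self.var_U = np.asarray(self.var_U, dtype=float)
        self.cov_X_X0 = np.asarray(self.cov_X_X0, dtype=float)
        n = self.mean_U.shape[0]
        if self.var_U.shape != (n, 2, 2) or self.cov_X_X0.shape != (n,):
            raise ValueError("inconsistent trajectory array shapes")

    @property
    def n_cycles(self) -> int:
        return self.mean_U.shape[0] - 1

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1)

    @property
    def total_mean(self) -> np.ndarray:
        """``E[N_i] = E[X_i] + E[Y_i]``."""
        return self.mean_U.sum(axis=1)

    @property
    def total_var(self) -> np.ndarray:
        """``Var[N_i]``: sum of all four covariance entries."""
        return self.var_U.sum(axis=(1, 2))

    def delta_x_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean and variance of the synthesized-forward-strand count.

        ``Delta X_i = X_i - X_0`` is what a hydrolysis probe bound to the
        reverse strand reports.  ``Var[Delta X_i] = Var[X_i] + Var[X_0]
        - 2 Cov[X_i, X_0]``.
        """
        mean = self.mean_U[:, 0] - self.mean_U[0, 0]
        var = self.var_U[:, 0, 0] + self.var_U[0, 0, 0] - 2.0 * self.cov_X_X0
        return mean, np.maximum(var, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "EX": self.mean_U[:, 0],
                "EY": self.mean_U[:, 1],
                "VarX": self.var_U[:, 0, 0],
                "VarY": self.var_U[:, 1, 1],
                "CovXY": self.var_U[:, 0, 1],
                "CovX_X0": self.cov_X_X0,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MomentTrajectory":
        frame = frame.sort_values("cycle").reset_index(drop=True)
        n = len(frame)
        var = np.empty((n, 2, 2))
        var[:, 0, 0] = frame["VarX"]
        var[:, 1, 1] = frame["VarY"]
        var[:, 0, 1] = var[:, 1, 0] = frame["CovXY"]
        return cls(
            mean_U=np.column_stack([frame["EX"], frame["EY"]]),
            var_U=var,
            cov_X_X0=frame["CovX_X0"].to_numpy(dtype=float),
        )


def moment_trajectory(
    eff: EfficiencyParams, inp: InputDistribution, n_cycles: int
) -> MomentTrajectory:
    """Compute all moments for cycles ``0 .. n_cycles`` in one pass."""
    mean0, var0 = initial_moments(inp, eff)
    return MomentTrajectory(
        mean_U=expected_counts(eff, mean0, n_cycles),
        var_U=variance_counts(eff, mean0, var0, n_cycles),
        cov_X_X0=cross_cov(eff, float(var0[0, 0]), n_cycles),
    )
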