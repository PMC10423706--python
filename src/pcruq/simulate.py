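"""Monte-Carlo simulation of the strand-specific PCR branching process.

The simulator draws the exact stochastic model rather than a diffusion or
normal approximation: an integer input copy number per replicate, an
optional Bernoulli-thinned reverse-transcription step for RNA input, and a
synchronous binomial update per cycle,

    X_i = X_{i-1} + Binomial(Y_{i-1}; p_bar * R)
    Y_i = Y_{i-1} + Binomial(X_{i-1}; p_bar / R)

with both draws conditioned on the cycle ``i - 1`` counts.  Randomness is
driven by one seed per run; independent sub-streams for the input draw,
the reverse-transcription step, and the cycling are derived from it with
``numpy.random.SeedSequence.spawn`` so partial reruns agree bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moments import EfficiencyParams, InputCase, InputDistribution, MomentTrajectory

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "EmpiricalMoments",
    "draw_input",
    "apply_rt",
    "run_cycles",
    "simulate",
    "ensemble_moments",
]


@dataclass(frozen=True)
class SimulationConfig:
    eff: EfficiencyParams
    input: InputDistribution
    n_cycles: int
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class TrajectoryEnsemble:
    """Replicate strand-count trajectories.

    ``counts`` has shape ``(n_replicates, n_cycles + 1, 2)`` with the last
    axis ordered (forward, reverse); ``input_draws`` has shape
    ``(n_replicates, 2)`` holding ``(I_X, I_Y)``.  Strands are never
    destroyed, so each component is nondecreasing in cycle, and per cycle
    at most one copy is made from each template.
    """

    counts: np.ndarray
    input_draws: np.ndarray
    config: SimulationConfig | None = None

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[1] - 1

    def total_counts(self) -> np.ndarray:
        """``N_i = X_i + Y_i`` per replicate and cycle."""
        return self.counts.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        reps, ncol, _ = self.counts.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(reps), ncol),
                "cycle": np.tile(np.arange(ncol), reps),
                "X": self.counts[:, :, 0].ravel(),
                "Y": self.counts[:, :, 1].ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def draw_input(
    inp: InputDistribution, n_replicates: int, seed_or_rng
) -> np.ndarray:
    """Draw ``(I_X, I_Y)`` for each replicate.

    Case D draws the two strand counts i.i.d. from the input family; RNA
    cases put the single draw on the strand that carries the template
    (``I_Y = 0`` for Case RF, ``I_X = 0`` for Case RR).  The
    negative-binomial family is parameterized by mean ``m`` and variance
    ``chi * m`` (size ``m / (chi - 1)``, success probability ``1 / chi``).
    """
    rng = _rng(seed_or_rng)
    m = inp.mean_I

    def sample(size: int) -> np.ndarray:
        if inp.family == "poisson":
            return rng.poisson(m, size)
        if inp.family == "negative_binomial":
            if inp.chi is None or inp.chi <= 1.0:
                raise ValueError("negative_binomial requires chi > 1")
            return rng.negative_binomial(m / (inp.chi - 1.0), 1.0 / inp.chi, size)
        return np.full(size, int(round(m)), dtype=np.int64)

    draws = np.zeros((n_replicates, 2), dtype=np.int64)
    if inp.case is InputCase.D:
        draws[:, 0] = sample(n_replicates)
        draws[:, 1] = sample(n_replicates)
    elif inp.case is InputCase.RF:
        draws[:, 0] = sample(n_replicates)
    else:
        draws[:, 1] = sample(n_replicates)
    return draws


def apply_rt(
    input_draws: np.ndarray,
    r: float | None,
    case: InputCase | str,
    seed_or_rng,
) -> np.ndarray:
    """Reverse-transcription step mapping input draws to ``U_0``.

    Each RNA strand yields its complementary cDNA with probability ``r``;
    Case RF input (forward RNA) therefore produces reverse cDNA and vice
    versa.  Case D passes through unchanged.
    """
    case = InputCase(case)
    draws = np.asarray(input_draws)
    if case is InputCase.D:
        return draws.copy()
    if r is None:
        raise ValueError("r is required for Case RF or RR")
    rng = _rng(seed_or_rng)
    U0 = np.zeros_like(draws)
    if case is InputCase.RF:
        U0[:, 1] = rng.binomial(draws[:, 0], r)
    else:
        U0[:, 0] = rng.binomial(draws[:, 1], r)
    return U0


def run_cycles(
    U0: np.ndarray, eff: EfficiencyParams, n_cycles: int, seed_or_rng
) -> np.ndarray:
    """Amplify an ensemble of initial counts for ``n_cycles`` cycles.

    Returns the ``(n_replicates, n_cycles + 1, 2)`` count array.  Both
    binomial draws within a cycle use the previous cycle's counts
    (synchronous update); EfficiencyParams guarantees both success
    probabilities lie in ``(0, 1]``.
    """
    rng = _rng(seed_or_rng)
    U0 = np.asarray(U0, dtype=np.int64)
    reps = U0.shape[0]
    counts = np.zeros((reps, n_cycles + 1, 2), dtype=np.int64)
    counts[:, 0, :] = U0
    X = U0[:, 0].copy()
    Y = U0[:, 1].copy()
    for i in range(1, n_cycles + 1):
        new_forward = rng.binomial(Y, eff.p_rf)
        new_reverse = rng.binomial(X, eff.p_fr)
        X = X + new_forward
        Y = Y + new_reverse
        counts[:, i, 0] = X
        counts[:, i, 1] = Y
    return counts


def simulate(config: SimulationConfig) -> TrajectoryEnsemble:
    """Run a full simulation: input draw, RT step, and cycling."""
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(3)
    ]
    draws = draw_input(config.input, config.n_replicates, streams[0])
    if config.input.case is InputCase.D:
        U0 = draws.copy()
    else:
        U0 = apply_rt(draws, config.eff.require_r(), config.input.case, streams[1])
    counts = run_cycles(U0, config.eff, config.n_cycles, streams[2])
    return TrajectoryEnsemble(counts=counts, input_draws=draws, config=config)


@dataclass
class EmpiricalMoments:
    """Sample moments of an ensemble with attached standard errors.

    Means and covariances are the unbiased (``ddof=1``) estimators.  The
    standard error of a sample variance uses the fourth-central-moment
    formula ``Var[s^2] ~ (m4 - s^4 (n-3)/(n-1)) / n``; covariance standard
    errors use the analogous mixed-moment expression.
    """

    mean_U: np.ndarray
    var_U: np.ndarray
    cov_X_X0: np.ndarray
    se_mean: np.ndarray
    se_var: np.ndarray
    se_cov_X_X0: np.ndarray
    n_replicates: int

    @property
    def n_cycles(self) -> int:
        return self.mean_U.shape[0] - 1

    def to_trajectory(self) -> MomentTrajectory:
        return MomentTrajectory(
            mean_U=self.mean_U, var_U=self.var_U, cov_X_X0=self.cov_X_X0
        )

    def to_frame(self) -> pd.DataFrame:
        frame = self.to_trajectory().to_frame()
        frame["se_EX"] = self.se_mean[:, 0]
        frame["se_EY"] = self.se_mean[:, 1]
        frame["se_VarX"] = self.se_var[:, 0, 0]
        frame["se_VarY"] = self.se_var[:, 1, 1]
        frame["se_CovXY"] = self.se_var[:, 0, 1]
        frame["se_CovX_X0"] = self.se_cov_X_X0
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ensemble_moments(ensemble: TrajectoryEnsemble) -> EmpiricalMoments:
    """Unbiased per-cycle sample moments of a trajectory ensemble."""
    counts = ensemble.counts.astype(float)
    n = counts.shape[0]
    if n < 2:
        raise ValueError("ensemble moments require at least 2 replicates")
    mean_U = counts.mean(axis=0)
    dev = counts - mean_U  # (reps, cycles, 2)
    var_U = np.einsum("rci,rcj->cij", dev, dev) / (n - 1)

    dev_X0 = dev[:, 0, 0]
    cov_X_X0 = dev[:, :, 0].T @ dev_X0 / (n - 1)

    se_mean = np.sqrt(np.maximum(np.einsum("cii->ci", var_U), 0.0) / n)
    m22 = np.einsum("rci,rcj->cij", dev**2, dev**2) / n
    se_var = np.sqrt(
        np.maximum(m22 - var_U**2 * (n - 3) / (n - 1), 0.0) / n
    )
    m22_x0 = (dev[:, :, 0] ** 2).T @ (dev_X0**2) / n
    se_cov = np.sqrt(np.maximum(m22_x0 - cov_X_X0**2 * (n - 3) / (n - 1), 0.0) / n)
    return EmpiricalMoments(
        mean_U=mean_U,
        var_U=var_U,
        cov_X_X0=cov_X_X0,
        se_mean=se_mean,
        se_var=se_var,
        se_cov_X_X0=se_cov,
        n_replicates=n,
    )
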