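"""Hydrolysis-probe fluorescence model and molar-fluorescence calibration.

Fluorescence in a well is treated as the fluorescence analog of Beer's
law: the measured signal is the sum over fluorescent species of (molar
fluorescence) x (molar concentration).  With a hydrolysis probe bound to
the reverse strand, one probe molecule is cleaved (activated) per forward
strand synthesized, which gives the affine model

    F_{i,w} = b_{i,w} + d_{i,w} * DeltaX_{i,w}

where ``b = f_minus * C`` is the background of the inactive probe at total
probe concentration ``C``, ``d = (f_plus - f_minus) / (V * N_A)`` is the
fluorescence gained per synthesized forward strand in reaction volume
``V``, and ``DeltaX_i = X_i - X_0``.  The molar fluorescences ``f_minus``
and ``f_plus`` are cycle- and well-dependent (photobleaching, optics) and
are estimated from template-free control plates run at several probe
concentrations by least squares through the origin.

Units: concentrations in mol/L, volumes in litres, molar fluorescence in
fluorescence units * L / mol, ``d`` in fluorescence units per molecule.
Helpers convert from the pmol/L and microlitre values typical of assay
protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .moments import (
    EfficiencyParams,
    InputDistribution,
    MomentTrajectory,
    moment_trajectory,
)

__all__ = [
    "AVOGADRO",
    "WELL_LABELS",
    "PlateMeasurement",
    "MolarFluorescenceTable",
    "FluorescenceParams",
    "FluorescenceCurve",
    "pmol_per_l_to_mol_per_l",
    "microliters_to_liters",
    "read_plates_csv",
    "write_plates_csv",
    "fit_molar_fluorescence",
    "build_molar_table",
    "derive_params",
    "uniform_params",
    "fluorescence_moments",
    "fluorescence_cv2",
    "qc_summary",
]

AVOGADRO = 6.02214076e23  # mol^-1

#: Row-major 96-well labels: A1 -> 1, A2 -> 2, ..., H12 -> 96.
WELL_LABELS = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]

PLATE_COLUMNS = [
    "plate_id",
    "probe_state",
    "concentration_mol_per_L",
    "cycle",
    "well",
    "fluorescence",
]


def pmol_per_l_to_mol_per_l(value: float) -> float:
    return value * 1e-12

def microliters_to_liters(value: float) -> float:
    return value * 1e-6


@dataclass
class PlateMeasurement:
    """Fluorescence of one control plate at a known probe concentration.

    ``fluorescence`` is a (cycle x well) matrix; ``cycles`` are 1-based
    (a reading is taken after each completed cycle) and ``well_labels``
    follow the row-major 96-well convention.
    """

    plate_id: str
    probe_state: str
    concentration: float  # mol / L
    fluorescence: np.ndarray
    cycles: np.ndarray = None
    well_labels: list = None

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be a (cycle x well) matrix")
        n, m = self.fluorescence.shape
        if self.concentration <= 0:
            raise ValueError("probe concentration must be positive")
        if self.probe_state not in ("active", "inactive"):
            raise ValueError(
                f"probe_state must be 'active' or 'inactive', got "
                f"{self.probe_state!r}"
            )
        if m > 96:
            raise ValueError("at most 96 wells per plate")
        if self.cycles is None:
            self.cycles = np.arange(1, n + 1)
        else:
            self.cycles = np.asarray(self.cycles, dtype=int)
            if len(self.cycles) != n:
                raise ValueError("cycles length does not match fluorescence rows")
        if self.well_labels is None:
            self.well_labels = WELL_LABELS[:m]
        elif len(self.well_labels) != m:
            raise ValueError("well_labels length does not match fluorescence columns")

    @property
    def n_cycles(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_wells(self) -> int:
        return self.fluorescence.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n, m = self.fluorescence.shape
        return pd.DataFrame(
            {
                "plate_id": self.plate_id,
                "probe_state": self.probe_state,
                "concentration_mol_per_L": self.concentration,
                "cycle": np.repeat(self.cycles, m),
                "well": np.tile(np.asarray(self.well_labels, dtype=object), n),
                "fluorescence": self.fluorescence.ravel(),
            }
        )


def write_plates_csv(plates: "list[PlateMeasurement]", path) -> None:
    """Write plates in the long CSV dialect (one row per reading)."""
    pd.concat([p.to_frame() for p in plates], ignore_index=True).to_csv(
        path, index=False
    )


def read_plates_csv(path) -> "list[PlateMeasurement]":
    """Read the long plate CSV back into per-plate matrices.

    Malformed rows (missing fields, non-numeric values) raise with the
    1-based data line numbers rather than being dropped.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"plate CSV is missing required columns: {missing}")
    numeric = frame[["concentration_mol_per_L", "cycle", "fluorescence"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = frame[PLATE_COLUMNS].isna().any(axis=1) | numeric.isna().any(axis=1)
    if bad.any():
        lines = (frame.index[bad] + 2).tolist()  # +1 header, +1 one-based
        raise ValueError(f"malformed plate CSV rows at lines {lines[:10]}")
    frame[numeric.columns] = numeric
    plates = []
    for plate_id, group in frame.groupby("plate_id", sort=False):
        states = group["probe_state"].unique()
        concs = group["concentration_mol_per_L"].unique()
        if len(states) != 1 or len(concs) != 1:
            raise ValueError(
                f"plate {plate_id!r} mixes probe states or concentrations"
            )
        pivot = group.pivot_table(
            index="cycle", columns="well", values="fluorescence", sort=False
        )
        pivot = pivot.sort_index()
        labels = [w for w in WELL_LABELS if w in pivot.columns]
        labels += [w for w in pivot.columns if w not in labels]
        pivot = pivot[labels]
        plates.append(
            PlateMeasurement(
                plate_id=str(plate_id),
                probe_state=str(states[0]),
                concentration=float(concs[0]),
                fluorescence=pivot.to_numpy(),
                cycles=pivot.index.to_numpy(),
                well_labels=list(pivot.columns),
            )
        )
    return plates


def fit_molar_fluorescence(
    plates: "list[PlateMeasurement]",
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise molar fluorescence from ``q`` control plates.

    For each cycle/well the readings across plates follow ``F^j = f C^j``
    plus noise, so the least-squares line through the origin gives
    ``f = sum_j F^j C^j / sum_j (C^j)^2`` and the dispersion estimate
    ``sigma = ||F - f C|| / sqrt(q - 1)``.  With a single plate ``f`` is
    the pointwise ratio ``F / C`` and ``sigma`` is undefined (returned as
    NaN).
    """
    if not plates:
        raise ValueError("at least one plate is required")
    states = {p.probe_state for p in plates}
    if len(states) != 1:
        raise ValueError("all plates must share one probe_state")
    ref = plates[0]
    for p in plates[1:]:
        if (
            p.fluorescence.shape != ref.fluorescence.shape
            or not np.array_equal(p.cycles, ref.cycles)
            or list(p.well_labels) != list(ref.well_labels)
        ):
            raise ValueError("all plates must share the same cycle/well grid")
    C = np.array([p.concentration for p in plates])
    if np.all(C == 0):
        raise ValueError("all-zero probe concentrations")
    q = len(plates)
    if q > 1 and len(np.unique(C)) != q:
        raise ValueError("plate concentrations must be distinct")
    F = np.stack([p.fluorescence for p in plates])  # (q, cycles, wells)
    f = np.einsum("j,jcw->cw", C, F) / float(C @ C)
    if q == 1:
        return f, np.full_like(f, np.nan)
    resid = F - f[None, :, :] * C[:, None, None]
    sigma = np.sqrt(np.einsum("jcw,jcw->cw", resid, resid)) / math.sqrt(q - 1)
    return f, sigma


@dataclass
class MolarFluorescenceTable:
    """Fitted molar fluorescence of inactive (-) and active (+) probe."""

    cycles: np.ndarray
    well_labels: list
    f_minus: np.ndarray
    sigma_minus: np.ndarray
    f_plus: np.ndarray
    sigma_plus: np.ndarray

    def __post_init__(self) -> None:
        for name in ("f_minus", "sigma_minus", "f_plus", "sigma_plus"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.cycles = np.asarray(self.cycles, dtype=int)
        if not np.all(self.f_plus > self.f_minus):
            i, w = np.argwhere(self.f_plus <= self.f_minus)[0]
            raise ValueError(
                "active probe must be brighter than inactive probe; violated "
                f"at cycle {self.cycles[i]}, well {self.well_labels[w]}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.sigma_minus < 0) or np.any(self.sigma_plus < 0):
                raise ValueError("sigma must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        n, m = self.f_minus.shape
        return pd.DataFrame(
            {
                "cycle": np.repeat(self.cycles, m),
                "well": np.tile(np.asarray(self.well_labels, dtype=object), n),
                "f_minus": self.f_minus.ravel(),
                "sigma_minus": self.sigma_minus.ravel(),
                "f_plus": self.f_plus.ravel(),
                "sigma_plus": self.sigma_plus.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MolarFluorescenceTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        cycles = np.sort(frame["cycle"].unique())
        labels = [w for w in WELL_LABELS if w in set(frame["well"])]
        labels += [w for w in frame["well"].unique() if w not in labels]
        pivots = {
            name: frame.pivot_table(
                index="cycle", columns="well", values=name, sort=False
            )
            .sort_index()[labels]
            .to_numpy()
            for name in ("f_minus", "sigma_minus", "f_plus", "sigma_plus")
        }
        return cls(cycles=cycles, well_labels=labels, **pivots)


def build_molar_table(
    inactive_plates: "list[PlateMeasurement]",
    active_plates: "list[PlateMeasurement]",
) -> MolarFluorescenceTable:
    """Fit both probe states and assemble the joint table."""
    f_minus, sigma_minus = fit_molar_fluorescence(inactive_plates)
    f_plus, sigma_plus = fit_molar_fluorescence(active_plates)
    ref = inactive_plates[0]
    return MolarFluorescenceTable(
        cycles=ref.cycles,
        well_labels=list(ref.well_labels),
        f_minus=f_minus,
        sigma_minus=sigma_minus,
        f_plus=f_plus,
        sigma_plus=sigma_plus,
    )


@dataclass
class FluorescenceParams:
    """Background ``b`` and incremental fluorescence ``d`` per cycle/well."""

    b: np.ndarray
    d: np.ndarray
    C: float  # total probe concentration, mol/L
    V: float  # reaction volume, L
    cycles: np.ndarray = None
    well_labels: list = None

    def __post_init__(self) -> None:
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        self.d = np.atleast_2d(np.asarray(self.d, dtype=float))
        if self.b.shape != self.d.shape:
            raise ValueError("b and d must have the same (cycle x well) shape")
        if np.any(self.d <= 0):
            raise ValueError("d must be positive everywhere")
        n, m = self.b.shape
        if self.cycles is None:
            self.cycles = np.arange(1, n + 1)
        else:
            self.cycles = np.asarray(self.cycles, dtype=int)
        if self.well_labels is None:
            self.well_labels = WELL_LABELS[:m]

    @property
    def n_wells(self) -> int:
        return self.b.shape[1]


def derive_params(
    table: MolarFluorescenceTable, C: float, V: float
) -> FluorescenceParams:
    """Convert molar fluorescences into the affine model parameters.

    ``b = f_minus * C`` and ``d = (f_plus - f_minus) / (V * N_A)``.  The
    table constructor already enforces ``f_plus > f_minus`` elementwise.
    """
    return FluorescenceParams(
        b=table.f_minus * C,
        d=(table.f_plus - table.f_minus) / (V * AVOGADRO),
        C=C,
        V=V,
        cycles=table.cycles,
        well_labels=list(table.well_labels),
    )


def uniform_params(
    b: float,
    d: float,
    n_cycles: int,
    n_wells: int = 1,
    C: float = 1.25e-13,
    V: float = 2e-5,
) -> FluorescenceParams:
    """Spatially and cycle-uniform parameters for analytic studies."""
    shape = (n_cycles, n_wells)
    return FluorescenceParams(b=np.full(shape, b), d=np.full(shape, d), C=C, V=V)


@dataclass
class FluorescenceCurve:
    """Mean and variance of fluorescence per cycle and well.

    ``band`` multiplier ``kappa`` gives ``lo = mean - kappa * sd`` and
    ``hi = mean + kappa * sd``; under the central-limit normality
    assumption, ``kappa = 2`` covers ~95 % of realizations.
    """

    cycles: np.ndarray
    well_labels: list
    mean_F: np.ndarray
    var_F: np.ndarray
    kappa: float
    background: np.ndarray

    @property
    def sd_F(self) -> np.ndarray:
        return np.sqrt(self.var_F)

    @property
    def lo(self) -> np.ndarray:
        return self.mean_F - self.kappa * self.sd_F

    @property
    def hi(self) -> np.ndarray:
        return self.mean_F + self.kappa * self.sd_F

    def first_detection(self) -> "list[int | None]":
        """Per well, the first cycle with ``mean - kappa*sd > background``."""
        out = []
        above = self.lo > self.background
        for w in range(self.mean_F.shape[1]):
            idx = np.nonzero(above[:, w])[0]
            out.append(int(self.cycles[idx[0]]) if idx.size else None)
        return out

    def to_frame(self) -> pd.DataFrame:
        n, m = self.mean_F.shape
        return pd.DataFrame(
            {
                "cycle": np.repeat(self.cycles, m),
                "well": np.tile(np.asarray(self.well_labels, dtype=object), n),
                "mean_F": self.mean_F.ravel(),
                "sd_F": self.sd_F.ravel(),
                "lo": self.lo.ravel(),
                "hi": self.hi.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def fluorescence_moments(
    params: FluorescenceParams,
    traj: MomentTrajectory,
    kappa: float = 3.0,
    mode: str = "hydrolysis",
) -> FluorescenceCurve:
    """First two moments of fluorescence from strand-count moments.

    ``mode='hydrolysis'`` (default): ``F_i = b_i + d_i * DeltaX_i`` with
    ``E[DeltaX_i] = E[X_i] - E[X_0]`` and ``Var[DeltaX_i] = Var[X_i] +
    Var[X_0] - 2 Cov[X_i, X_0]``.  ``mode='annealing'`` models probes that
    fluoresce while annealed to the forward strand, read during the
    annealing step of cycle ``i``: ``F_i = b_i + d_i * X_{i-1}``.
    """
    cycles = params.cycles
    if cycles.max() > traj.n_cycles:
        raise ValueError(
            f"trajectory covers cycles 0..{traj.n_cycles} but parameters "
            f"extend to cycle {cycles.max()}"
        )
    if mode == "hydrolysis":
        mean_dx, var_dx = traj.delta_x_moments()
        mean_sig = mean_dx[cycles]
        var_sig = var_dx[cycles]
    elif mode == "annealing":
        mean_sig = traj.mean_U[cycles - 1, 0]
        var_sig = traj.var_U[cycles - 1, 0, 0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mean_F = params.b + params.d * mean_sig[:, None]
    var_F = params.d**2 * var_sig[:, None]
    return FluorescenceCurve(
        cycles=cycles,
        well_labels=list(params.well_labels),
        mean_F=mean_F,
        var_F=var_F,
        kappa=kappa,
        background=params.b,
    )


def fluorescence_cv2(
    eff: EfficiencyParams, inp: InputDistribution, n_cycles: int
) -> np.ndarray:
    """Exact squared CV of background-subtracted fluorescence, cycles 1..n.

    ``CV[F_i - b_i]^2 = Var[DeltaX_i] / E[DeltaX_i]^2`` (the per-molecule
    brightness ``d`` cancels).  Converges to the asymptote
    ``alpha * CV[I]^2 + beta / E[I]`` at rate ``O(lambda1**-i)``.  Cycles
    with zero expected signal (cycle 1 of Case RR, where no reverse
    templates exist yet) are reported as NaN.
    """
    if inp.mean_I <= 0:
        raise ValueError("CV of fluorescence is undefined for mean_I = 0")
    traj = moment_trajectory(eff, inp, n_cycles)
    mean_dx, var_dx = traj.delta_x_moments()
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mean_dx[1:] > 0, var_dx[1:] / mean_dx[1:] ** 2, np.nan)
    return out


def qc_summary(
    table: MolarFluorescenceTable, threshold: float = 0.022
) -> pd.DataFrame:
    """Coefficient-of-variation summary of a fitted molar-fluorescence table.

    Returns one row per (probe_state, cycle, well) with ``cv = sigma / f``
    and a flag for entries above ``threshold`` (the boundary beyond which
    well-specific artifacts dominated the control data).  Requires the
    dispersion estimates, i.e. fits with ``q >= 2`` plates.
    """
    rows = []
    for state, f, sigma in (
        ("inactive", table.f_minus, table.sigma_minus),
        ("active", table.f_plus, table.sigma_plus),
    ):
        if np.isnan(sigma).all():
            raise ValueError(
                f"{state} probe has no dispersion estimates (single-plate fit)"
            )
        cv = sigma / f
        n, m = cv.shape
        rows.append(
            pd.DataFrame(
                {
                    "probe_state": state,
                    "cycle": np.repeat(table.cycles, m),
                    "well": np.tile(np.asarray(table.well_labels, dtype=object), n),
                    "cv": cv.ravel(),
                    "flagged": (cv > threshold).ravel(),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["threshold"] = threshold
    out.attrs["flagged_fraction"] = float(out["flagged"].mean())
    return out
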