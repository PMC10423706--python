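"""Synthetic control plates and amplification runs.

Generates fixture data with the statistical structure the models assume,
so calibration and curve computation can be exercised end to end without
instrument data.

Control plates: the ground-truth molar fluorescence of each probe state is
``base * (1 + well effect) * trend(i)``, where the well effect is a small
normal perturbation fixed per well and the cycle trend is a low-order bump
with an early maximum (near cycle 2-3) times a slow exponential decay that
emulates photobleaching.  The trend shape is a fixture choice, not a
scientific claim.  Observed readings are ``F = f * C * (1 + eps)`` with
multiplicative normal noise, consistent with treating ``F / C`` across
plates as i.i.d. normal at fixed cycle and well.

Amplification runs: one branching-process trajectory per well, converted
to fluorescence through ``F = b + d * DeltaX``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import simulate as sim
from .fluorescence import (
    FluorescenceParams,
    MolarFluorescenceTable,
    PlateMeasurement,
    fit_molar_fluorescence,
)
from .moments import EfficiencyParams, InputCase, InputDistribution

__all__ = [
    "PlateGeneratorConfig",
    "generate_control_plates",
    "generate_amplification_runs",
    "write_manifest",
]

# Concentration scale: the assay working concentration 0.125 pmol/L.
_C_WORK = 1.25e-13  # mol/L


@dataclass(frozen=True)
class PlateGeneratorConfig:
    """Configuration of the control-plate generator.

    Defaults follow the calibration design of four active-probe and three
    inactive-probe plates, 96 wells, 45 cycles, 1 % multiplicative noise.
    The concentration levels bracket the 0.125 pmol/L working point in a
    narrow (0.8-1.6x) series: because the regression through the origin
    weights each plate by C**2, a wide dilution series concentrates the
    leverage in the top plate, and because the incremental fluorescence is
    the *difference* f_plus - f_minus, its propagated relative error is
    about twice that of the fits; the narrow bracket keeps the propagated
    CV of d below ~1 %.  The base molar fluorescences are chosen so that
    the derived background is about 1 fluorescence unit and the
    incremental fluorescence about 1e-6 per molecule at C = 0.125 pmol/L
    and V = 20 uL.
    """

    concentrations_active: tuple = (
        0.8 * _C_WORK,
        1.0 * _C_WORK,
        1.25 * _C_WORK,
        1.6 * _C_WORK,
    )
    concentrations_inactive: tuple = (0.8 * _C_WORK, 1.0 * _C_WORK, 1.25 * _C_WORK)
    n_cycles: int = 45
    n_wells: int = 96
    f_minus_base: float = 8.0e12  # fluorescence * L / mol
    f_plus_base: float = 2.004428152e13
    well_effect_sd: float = 0.05
    bump_amplitude: float = 0.04
    bump_peak_cycle: float = 2.5
    decay_rate: float = 0.002
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("concentrations_active", "concentrations_inactive"):
            conc = np.asarray(getattr(self, name), dtype=float)
            if conc.size < 1 or np.any(conc <= 0):
                raise ValueError(f"{name} must be positive")
            if not np.all(np.diff(conc) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not 1 <= self.n_wells <= 96:
            raise ValueError("n_wells must be in 1..96")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.f_plus_base <= self.f_minus_base:
            raise ValueError("f_plus_base must exceed f_minus_base")


def _cycle_trend(cfg: PlateGeneratorConfig, cycles: np.ndarray) -> np.ndarray:
    i = cycles.astype(float)
    peak = cfg.bump_peak_cycle
    bump = 1.0 + cfg.bump_amplitude * (i / peak) * np.exp(1.0 - i / peak)
    return bump * np.exp(-cfg.decay_rate * (i - 1.0))


def generate_control_plates(
    cfg: PlateGeneratorConfig,
) -> tuple["list[PlateMeasurement]", MolarFluorescenceTable]:
    """Generate noisy control plates plus the ground-truth table.

    Returns the inactive plates followed by the active plates, and the
    truth table against which fitted molar fluorescences can be checked.
    """
    rng = np.random.default_rng(cfg.seed)
    cycles = np.arange(1, cfg.n_cycles + 1)
    trend = _cycle_trend(cfg, cycles)[:, None]
    # Per-well multiplicative effects, clipped so both surfaces stay
    # positive and ordered (f_plus_base / f_minus_base >> 1 + 0.3).
    eff_minus = np.clip(rng.normal(0.0, cfg.well_effect_sd, cfg.n_wells), -0.3, 0.3)
    eff_plus = np.clip(rng.normal(0.0, cfg.well_effect_sd, cfg.n_wells), -0.3, 0.3)
    f_minus = cfg.f_minus_base * (1.0 + eff_minus)[None, :] * trend
    f_plus = cfg.f_plus_base * (1.0 + eff_plus)[None, :] * trend

    plates = []
    for state, truth, concs in (
        ("inactive", f_minus, cfg.concentrations_inactive),
        ("active", f_plus, cfg.concentrations_active),
    ):
        for j, C in enumerate(concs, start=1):
            noise = 1.0 + rng.normal(0.0, cfg.noise_cv, truth.shape)
            plates.append(
                PlateMeasurement(
                    plate_id=f"{state}-{j}",
                    probe_state=state,
                    concentration=float(C),
                    fluorescence=truth * C * noise,
                    cycles=cycles,
                )
            )
    truth_table = MolarFluorescenceTable(
        cycles=cycles,
        well_labels=plates[0].well_labels,
        f_minus=f_minus,
        sigma_minus=np.zeros_like(f_minus),
        f_plus=f_plus,
        sigma_plus=np.zeros_like(f_plus),
    )
    return plates, truth_table


def fit_generated_plates(
    plates: "list[PlateMeasurement]",
) -> MolarFluorescenceTable:
    """Convenience: fit both probe states of a generated plate set."""
    inactive = [p for p in plates if p.probe_state == "inactive"]
    active = [p for p in plates if p.probe_state == "active"]
    f_minus, s_minus = fit_molar_fluorescence(inactive)
    f_plus, s_plus = fit_molar_fluorescence(active)
    ref = inactive[0]
    return MolarFluorescenceTable(
        cycles=ref.cycles,
        well_labels=list(ref.well_labels),
        f_minus=f_minus,
        sigma_minus=s_minus,
        f_plus=f_plus,
        sigma_plus=s_plus,
    )


def generate_amplification_runs(
    eff: EfficiencyParams,
    inp: InputDistribution,
    params: FluorescenceParams,
    n_wells: int,
    n_cycles: int,
    seed: int,
    plate_id: str = "amplification",
) -> PlateMeasurement:
    """Simulate one amplification trajectory per well and report fluorescence.

    Wells are independent replicates of the branching process; the
    fluorescence of well ``w`` after cycle ``i`` is
    ``b[i, w] + d[i, w] * (X_{i,w} - X_{0,w})``.
    """
    if params.b.shape[0] < n_cycles or params.n_wells < n_wells:
        raise ValueError("parameters must cover all requested wells and cycles")
    ensemble = sim.simulate(
        sim.SimulationConfig(
            eff=eff, input=inp, n_cycles=n_cycles, n_replicates=n_wells, seed=seed
        )
    )
    delta_x = (
        ensemble.counts[:, 1:, 0] - ensemble.counts[:, :1, 0]
    ).T  # (cycle, well)
    b = params.b[:n_cycles, :n_wells]
    d = params.d[:n_cycles, :n_wells]
    return PlateMeasurement(
        plate_id=plate_id,
        probe_state="active",
        concentration=params.C,
        fluorescence=b + d * delta_x.astype(float),
        cycles=np.arange(1, n_cycles + 1),
        well_labels=list(params.well_labels[:n_wells]),
    )


def write_manifest(path, cfg: PlateGeneratorConfig, truth_path=None, **extra) -> None:
    """Record generator configuration, seed, and truth-table location."""
    record = {"generator": asdict(cfg), "seed": cfg.seed}
    if truth_path is not None:
        record["truth_table"] = str(truth_path)
    record.update(extra)
    with open(path, "w") as handle:
        json.dump(record, handle, indent=2, default=list)
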