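"""Forward models of the transwell assays, with seeded measurement noise.

Three generators:

* two-compartment donor/receiver diffusion across a (filter + endothelium)
  barrier, solved in closed form — full equilibration dynamics, no sink
  assumption, optional first-order nonspecific loss from the donor side;
* intracellular accumulation of an efflux-pump substrate (rhodamine 123
  style) under partial or full transporter inhibition;
* Hill-type concentration-dependent barrier disruption feeding complete
  simulated permeability batches, and an inverse-model constructor for
  compound-transport (C0, CD, CR) triplets with prescribed recovery and
  Kp,uu,brain.

Measurement noise is multiplicative log-normal with unit mean, parameterised
by its coefficient of variation, applied to measured concentrations only; the
underlying kinetics stay exact. Every generator takes an explicit seed and
owns its RNG (no global state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import ValidationError
from .plate_formats import PlateFormat, get_format
from .timecourse import TranswellTimecourse

#: Baseline endothelial Pe of sodium fluorescein across an intact barrier
#: under non-disrupting conditions, cm/min.
BASELINE_PE_NAF = 0.33e-3

#: Synthetic coated-filter (blank) Pe, cm/min — roughly 30× leakier than the
#: endothelium, as expected for a Matrigel-coated PET membrane.
DEFAULT_FILTER_PE = 10e-3


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and sampling scheme for one permeability timecourse."""

    format: PlateFormat = field(default_factory=lambda: get_format("96tw_corning"))
    true_pe_endothelium: float = BASELINE_PE_NAF  # cm/min
    true_pe_filter: float = DEFAULT_FILTER_PE  # cm/min
    initial_donor_concentration: float = 1.0  # µM (1 µM NaF)
    sampling_times: tuple[float, ...] = (60.0,)  # min; 1-h single-point assay
    noise_cv: float = 0.0
    nonspecific_loss_rate: float = 0.0  # fraction of donor amount lost per min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_pe_filter <= 0:
            raise ValidationError("true_pe_filter must be > 0")
        if self.true_pe_endothelium < 0:
            raise ValidationError("true_pe_endothelium must be >= 0")
        if self.true_pe_filter < self.true_pe_endothelium:
            raise ValidationError(
                "true_pe_filter must be >= true_pe_endothelium: the bare filter "
                "is always leakier than filter plus cells"
            )
        if self.initial_donor_concentration <= 0:
            raise ValidationError("initial_donor_concentration must be > 0")
        t = np.asarray(self.sampling_times, float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("sampling_times must be strictly increasing and > 0")
        if self.noise_cv < 0 or self.nonspecific_loss_rate < 0:
            raise ValidationError("noise_cv and nonspecific_loss_rate must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if isinstance(d.get("format"), str):
            d["format"] = get_format(d["format"])
        if "sampling_times" in d:
            d["sampling_times"] = tuple(float(t) for t in d["sampling_times"])
        return cls(**d)


def _effective_pe(config: SimulationConfig, with_cells: bool) -> float:
    if not with_cells:
        return config.true_pe_filter
    if config.true_pe_endothelium == 0.0:
        return 0.0
    return 1.0 / (1.0 / config.true_pe_endothelium + 1.0 / config.true_pe_filter)


def _amounts(
    ps_ul_min: float,
    v_l: float,
    v_r: float,
    x0: float,
    loss_rate: float,
    times: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact donor/receiver amounts of the linear two-compartment model."""
    if loss_rate == 0.0:
        k = ps_ul_min * (1.0 / v_l + 1.0 / v_r)
        x_eq = x0 * v_r / (v_l + v_r)
        x_r = x_eq * -np.expm1(-k * times) if k > 0 else np.zeros_like(times)
        return x0 - x_r, x_r
    # With first-order donor loss the system stays linear; use the matrix
    # exponential of d/dt [X_L, X_R] = A [X_L, X_R].
    a = np.array(
        [
            [-(ps_ul_min / v_l + loss_rate), ps_ul_min / v_r],
            [ps_ul_min / v_l, -ps_ul_min / v_r],
        ]
    )
    x_l = np.empty_like(times)
    x_r = np.empty_like(times)
    for i, t in enumerate(times):
        x_l[i], x_r[i] = expm(a * t) @ np.array([x0, 0.0])
    return x_l, x_r


def simulate_timecourse(config: SimulationConfig, with_cells: bool = True) -> TranswellTimecourse:
    """Simulate one well's donor/receiver timecourse.

    ``with_cells`` selects the total barrier (filter and endothelium as
    resistances in series) versus the coating-only filter. Donor and receiver
    are both "sampled" at every requested time and at t = 0 for the donor;
    each measured concentration gets an independent noise factor.
    """
    fmt = config.format
    times = np.asarray(config.sampling_times, float)
    pe_eff = _effective_pe(config, with_cells)
    ps_ul_min = pe_eff * fmt.filter_area * 1000.0  # cm/min × cm² = cm³/min → µL/min
    x0 = config.initial_donor_concentration * fmt.luminal_volume
    x_l, x_r = _amounts(
        ps_ul_min,
        fmt.luminal_volume,
        fmt.abluminal_volume,
        x0,
        config.nonspecific_loss_rate,
        times,
    )
    donor_conc = np.concatenate([[config.initial_donor_concentration], x_l / fmt.luminal_volume])
    receiver_conc = x_r / fmt.abluminal_volume
    rng = np.random.default_rng(config.seed)
    donor_conc = donor_conc * _lognormal_factors(rng, config.noise_cv, donor_conc.size)
    receiver_conc = receiver_conc * _lognormal_factors(rng, config.noise_cv, receiver_conc.size)
    return TranswellTimecourse(
        well=f"sim-{'cells' if with_cells else 'blank'}-{config.seed}",
        role="cell_insert" if with_cells else "blank_filter",
        format_name=fmt.name,
        donor_times=np.concatenate([[0.0], times]),
        donor_conc=donor_conc,
        receiver_times=times,
        receiver_conc=receiver_conc,
    )


# ---------------------------------------------------------------------------
# Efflux accumulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffluxSimConfig:
    """Kinetics of substrate accumulation in the endothelial monolayer.

    The medium concentration is treated as constant (the substrate pool is
    large relative to cell uptake). ``inhibition_fraction`` = 1 models a full
    Elacridar-style block of active efflux.
    """

    substrate_concentration: float = 5.0  # µM, R123 assay concentration
    uptake_rate: float = 0.02  # min⁻¹
    passive_efflux_rate: float = 0.01  # min⁻¹
    active_efflux_rate: float = 0.008  # min⁻¹
    inhibition_fraction: float = 0.0
    duration: float = 120.0  # min, 2-h incubation
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substrate_concentration", "duration"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("uptake_rate", "passive_efflux_rate", "active_efflux_rate", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise ValidationError("inhibition_fraction must be in [0, 1]")


def simulate_efflux_assay(config: EffluxSimConfig, n_replicates: int = 1) -> np.ndarray:
    """Intracellular signal (arbitrary fluorescence units) after ``duration``.

    Solves dX/dt = uptake·C_medium − (passive + active·(1 − inhibition))·X
    in closed form and returns one noisy signal per replicate.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    k_out = config.passive_efflux_rate + config.active_efflux_rate * (
        1.0 - config.inhibition_fraction
    )
    influx = config.uptake_rate * config.substrate_concentration
    if k_out > 0:
        x = influx / k_out * -math.expm1(-k_out * config.duration)
    else:
        x = influx * config.duration
    rng = np.random.default_rng(config.seed)
    return x * _lognormal_factors(rng, config.noise_cv, n_replicates)


# ---------------------------------------------------------------------------
# Concentration-dependent barrier disruption
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisruptionModel:
    """Hill-type concentration → Pe dose–response of a barrier-disrupting compound."""

    baseline_pe: float = BASELINE_PE_NAF  # cm/min, intact barrier
    max_pe: float = 5e-3  # cm/min, fully disrupted
    ec50: float = 2.0  # µM
    hill_coefficient: float = 2.0

    def __post_init__(self) -> None:
        if not self.max_pe >= self.baseline_pe > 0:
            raise ValidationError("need max_pe >= baseline_pe > 0")
        if self.ec50 <= 0 or self.hill_coefficient <= 0:
            raise ValidationError("ec50 and hill_coefficient must be > 0")

    def pe_at(self, concentration: float) -> float:
        """True endothelial Pe (cm/min) after exposure at ``concentration`` µM."""
        if concentration < 0:
            raise ValidationError("concentration must be >= 0")
        if concentration == 0:
            return self.baseline_pe
        ch = concentration**self.hill_coefficient
        frac = ch / (self.ec50**self.hill_coefficient + ch)
        return self.baseline_pe + (self.max_pe - self.baseline_pe) * frac


def simulate_dose_response(
    model: DisruptionModel,
    concentrations: Sequence[float],
    n_replicates: int,
    assay: SimulationConfig,
    compound: str = "compound",
    n_blank_wells: int = 3,
    n_vehicle_replicates: int | None = None,
):
    """Simulate a full barrier-integrity screen across a concentration ladder.

    Each replicate at each concentration is a complete simulated timecourse at
    the Hill-model Pe, pushed through the estimation pipeline against a shared
    set of simulated blank filters; vehicle controls are replicates at the
    baseline Pe. Returns a :class:`~bbbassay.screening.DoseResponseSeries`.
    """
    from .permeability import estimate_pe
    from .screening import DoseResponseSeries

    conc = [float(c) for c in concentrations]
    if any(c < 0 for c in conc):
        raise ValidationError("concentrations must be non-negative")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    n_vehicle = n_replicates if n_vehicle_replicates is None else n_vehicle_replicates
    rng = np.random.default_rng(assay.seed)

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    blanks = [
        simulate_timecourse(replace(assay, seed=child_seed()), with_cells=False)
        for _ in range(n_blank_wells)
    ]

    def pe_replicates(true_pe: float, n: int) -> np.ndarray:
        cells = [
            simulate_timecourse(
                replace(assay, true_pe_endothelium=true_pe, seed=child_seed()),
                with_cells=True,
            )
            for _ in range(n)
        ]
        return np.array([r.pe for r in estimate_pe(cells, blanks, assay.format)])

    controls = pe_replicates(model.baseline_pe, n_vehicle)
    per_conc = [pe_replicates(model.pe_at(c), n_replicates) for c in conc]
    return DoseResponseSeries(
        compound=compound,
        concentrations=tuple(conc),
        pe_replicates=tuple(per_conc),
        control_pe=controls,
    )


# ---------------------------------------------------------------------------
# Inverse-model compound transport triplets (IVIVC datasets)
# ---------------------------------------------------------------------------

def simulate_ivivc_dataset(
    true_kpuu_values: Sequence[float],
    recovery_targets: Sequence[float],
    c0: float = 2.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Construct (C0, CD, CR) triplets with prescribed Kp,uu,brain and recovery.

    Inverse-model construction: CD = C0/(1 + Kp,uu/(U/100)) and
    CR = (U/100)·C0 − CD, so pushing the noise-free triplets through the
    recovery and Kp,uu estimators returns exactly the requested values.
    Compounds dosed at 2 µM by default, matching the donor-side assay
    concentration. Requires U/100 + Kp,uu ≥ 1 (otherwise CR < 0).
    """
    kpuu = np.asarray(true_kpuu_values, float)
    rec = np.asarray(recovery_targets, float)
    if kpuu.shape != rec.shape or kpuu.ndim != 1:
        raise ValidationError("true_kpuu_values and recovery_targets must be equal-length 1-D")
    if np.any(kpuu <= 0):
        raise ValidationError("all Kp,uu values must be > 0")
    if np.any((rec <= 0) | (rec > 100)):
        raise ValidationError("recovery targets must be in (0, 100] percent")
    if c0 <= 0:
        raise ValidationError("c0 must be > 0")
    u = rec / 100.0
    cd = c0 / (1.0 + kpuu / u)
    cr = u * c0 - cd
    if np.any(cr < -1e-12):
        bad = int(np.argmin(cr))
        raise ValidationError(
            f"infeasible (Kp,uu={kpuu[bad]}, recovery={rec[bad]}%): CR would be "
            "negative; need recovery/100 + Kp,uu >= 1"
        )
    cr = np.clip(cr, 0.0, None)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        cd = cd * _lognormal_factors(rng, noise_cv, cd.size)
        cr = cr * _lognormal_factors(rng, noise_cv, cr.size)
    names = (
        list(compounds)
        if compounds is not None
        else [f"compound_{i + 1}" for i in range(kpuu.size)]
    )
    if len(names) != kpuu.size:
        raise ValidationError("compounds must match the number of Kp,uu values")
    return pd.DataFrame(
        {"compound": names, "C0_uM": c0, "CD_uM": cd, "CR_uM": cr}
    )
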