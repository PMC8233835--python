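"""Dose–response barrier-integrity screening, efflux accumulation, qPCR
relative expression, and two-group comparison."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

_GRID_MANTISSAS = (1.0, 3.0)


def _grid_decompose(value: float) -> tuple[float, int]:
    """Split a 1–3–10 half-log grid value into (mantissa, exponent) or raise."""
    if value <= 0:
        raise ValidationError(f"grid values must be > 0, got {value}")
    exp = math.floor(math.log10(value) + 1e-9)
    mant = value / 10.0**exp
    for m in _GRID_MANTISSAS:
        if math.isclose(mant, m, rel_tol=1e-6):
            return m, exp
    lo = 10.0**exp if mant < 3 else 3 * 10.0**exp
    hi = 3 * 10.0**exp if mant < 3 else 10.0 ** (exp + 1)
    raise ValidationError(
        f"{value} is not on the 1–3–10 dilution grid; nearest grid points are {lo} and {hi}"
    )


def dilution_series(low: float, high: float) -> list[float]:
    """Ascending 1–3–10 half-log concentration ladder from ``low`` to ``high``.

    Both bounds must sit on the grid (1×10ⁿ or 3×10ⁿ) and are included, e.g.
    (0.001, 100) gives the 11-point screening ladder
    0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1, 3, 10, 30, 100 µM.
    """
    if not low < high:
        raise ValidationError(f"need low < high, got low={low}, high={high}")
    m, e = _grid_decompose(low)
    m_hi, e_hi = _grid_decompose(high)
    out = []
    while (e, m) <= (e_hi, m_hi):
        out.append(float(f"{int(m)}e{e}"))  # exact decimal literal, no 10**e rounding
        if m == 1.0:
            m = 3.0
        else:
            m, e = 1.0, e + 1
    return out


@dataclass(frozen=True)
class DoseResponseSeries:
    """Estimated Pe readouts across a concentration ladder, with vehicle controls."""

    compound: str
    concentrations: tuple[float, ...]
    pe_replicates: tuple[np.ndarray, ...] = field(repr=False)  # cm/min, per concentration
    control_pe: np.ndarray = field(repr=False)  # cm/min, vehicle wells

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, float)
        if conc.size and np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        if len(self.pe_replicates) != conc.size:
            raise ValidationError("one replicate array required per concentration")
        if any(np.asarray(r).size < 1 for r in self.pe_replicates):
            raise ValidationError("each concentration needs at least one Pe replicate")
        object.__setattr__(self, "control_pe", np.asarray(self.control_pe, float))
        object.__setattr__(
            self, "pe_replicates", tuple(np.asarray(r, float) for r in self.pe_replicates)
        )


@dataclass(frozen=True)
class IntegrityScreenResult:
    compound: str
    concentrations: tuple[float, ...]
    disrupting: tuple[bool, ...]
    threshold: float  # cm/min: control mean + k_sd × control SD
    lowest_disrupting_concentration: float | None


def integrity_screen(series: DoseResponseSeries, k_sd: float = 3.0) -> IntegrityScreenResult:
    """Flag concentrations whose mean Pe exceeds control mean + k·SD.

    With the screen's tiny per-dose replication, per-dose t-tests are
    uninformative; the flag rule depends only on the standardized excess over
    vehicle control, so it is invariant to affine rescaling of all Pe values.
    Returns the lowest flagged concentration, or None if the barrier is intact
    across the ladder.
    """
    if series.control_pe.size < 2:
        raise ValidationError("integrity_screen needs at least 2 vehicle-control replicates")
    if k_sd <= 0:
        raise ValidationError("k_sd must be > 0")
    mu = float(series.control_pe.mean())
    sd = float(series.control_pe.std(ddof=1))
    threshold = mu + k_sd * sd
    flags = tuple(bool(np.mean(r) > threshold) for r in series.pe_replicates)
    lowest = None
    for c, f in zip(series.concentrations, flags):
        if f:
            lowest = c
            break
    return IntegrityScreenResult(
        compound=series.compound,
        concentrations=series.concentrations,
        disrupting=flags,
        threshold=threshold,
        lowest_disrupting_concentration=lowest,
    )


class GroupComparison(NamedTuple):
    mean_difference: float
    p_value: float


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns the mean difference (b − a) and the p-value. Identical groups
    give a difference of 0 and p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("compare_groups needs at least 2 values per group")
    diff = float(b.mean() - a.mean())
    with warnings.catch_warnings():  # near-constant groups are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b, a, equal_var=False)
    p = float(res.pvalue)
    if math.isnan(p):  # both groups have zero variance
        p = 1.0 if diff == 0.0 else 0.0
    return GroupComparison(diff, p)


@dataclass(frozen=True)
class EffluxResult:
    """Substrate-accumulation contrast between control and inhibitor-treated wells."""

    control_mean: float
    inhibitor_mean: float
    accumulation_increase_pct: float  # (inhibitor − control)/control × 100
    n_control: int
    n_inhibitor: int
    p_value: float


def efflux_analysis(
    control_signals: Sequence[float], inhibitor_signals: Sequence[float]
) -> EffluxResult:
    """Percent increase of intracellular substrate signal under efflux inhibition.

    The accumulation increase is reported relative to the uninhibited control
    mean (so it is invariant to rescaling all signals), with a Welch
    two-sample p-value for the contrast.
    """
    ctrl = np.asarray(control_signals, float)
    inh = np.asarray(inhibitor_signals, float)
    if ctrl.size < 2 or inh.size < 2:
        raise ValidationError("efflux_analysis needs at least 2 observations per group")
    if np.any(ctrl <= 0) or np.any(inh <= 0):
        raise ValidationError("fluorescence signals must be strictly positive")
    increase = (inh.mean() - ctrl.mean()) / ctrl.mean() * 100.0
    comparison = compare_groups(ctrl, inh)
    return EffluxResult(
        control_mean=float(ctrl.mean()),
        inhibitor_mean=float(inh.mean()),
        accumulation_increase_pct=float(increase),
        n_control=int(ctrl.size),
        n_inhibitor=int(inh.size),
        p_value=comparison.p_value,
    )


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    ct_target: float
    ct_reference: float
    relative_expression: float


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """qPCR relative expression 2^−ΔCt against a housekeeping reference.

    ΔCt = Ct_target − Ct_reference; the reference is typically RPLP0. Ct
    values must lie in the instrument's (0, 50) cycle range.
    """
    for name, ct in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not 0.0 < ct < 50.0:
            raise ValidationError(f"{name} must be in (0, 50) cycles, got {ct}")
    return 2.0 ** -(ct_target - ct_reference)
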