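"""Endothelial permeability estimation from transwell clearance kinetics.

The clearance principle converts receiver concentrations into a cleared
volume, Cl(t) = C_R(t)·V_R / C_L0, whose slope against time is the
permeability–surface product PS (µL/min) independently of the donor
concentration. Filter-only (blank) inserts run alongside give PSf; the total
PSt of cells-on-filter is corrected to the endothelium-only PSe through the
series-resistance relation

    1/PSe = 1/PSt − 1/PSf

and the endothelial permeability coefficient is Pe = PSe / area (reported in
cm/min: 1 µL/min per cm² = 1e-3 cm/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import NonPhysicalMeasurementError, ValidationError
from .plate_formats import PlateFormat
from .timecourse import TranswellTimecourse

#: 1 µL/min divided by 1 cm² equals 1e-3 cm/min.
UL_PER_MIN_PER_CM2_TO_CM_PER_MIN = 1e-3

#: Default mass-balance QC pass band, percent of initial amount recovered.
DEFAULT_QC_BOUNDS = (80.0, 120.0)


@dataclass(frozen=True)
class ClearanceCurve:
    """Cleared volume against time for one well, with its linear fit."""

    well: str
    times: np.ndarray = field(repr=False)  # min, includes the t=0 anchor
    cleared_volumes: np.ndarray = field(repr=False)  # µL
    slope: float  # µL/min == PS for this well
    intercept: float  # µL
    r_squared: float


@dataclass(frozen=True)
class PermeabilityResult:
    """Permeability–surface products and endothelial Pe for one cell insert."""

    well: str
    ps_total: float  # PSt, µL/min (filter + cells)
    ps_filter: float  # PSf, µL/min (batch mean over blank filters)
    ps_endothelium: float  # PSe, µL/min; NaN when flagged
    area: float  # cm²
    pe: float  # cm/min; NaN when flagged
    qc_mass_balance: float  # % of initial amount recovered; NaN if no final donor sample
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


def clearance_curve(tc: TranswellTimecourse, fmt: PlateFormat) -> ClearanceCurve:
    """Cleared-volume curve and PS slope for one well.

    The cleared volume is identically zero at t = 0, so (0, 0) is included as
    a data point; with two or more receiver samples the slope comes from
    ordinary least squares, with exactly one it reduces to Cl(t)/t (a fit
    through the origin).
    """
    if tc.c_l0 <= 0:
        raise ValidationError(f"well {tc.well}: C_L0 must be > 0")
    t_post, c_post = tc.receiver_after_zero()
    if t_post.size == 0:
        raise ValidationError(f"well {tc.well}: no post-zero receiver samples")
    cleared = c_post * fmt.abluminal_volume / tc.c_l0  # µL
    t = np.concatenate([[0.0], t_post])
    cl = np.concatenate([[0.0], cleared])
    if t_post.size == 1:
        slope = float(cleared[0] / t_post[0])
        intercept = 0.0
        r2 = 1.0
    else:
        slope, intercept = np.polyfit(t, cl, 1)
        resid = cl - (slope * t + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((cl - cl.mean()) ** 2))
        if ss_tot == 0.0:
            r2 = 1.0 if ss_res == 0.0 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
    return ClearanceCurve(
        well=tc.well,
        times=t,
        cleared_volumes=cl,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
    )


def correct_filter(ps_total: float, ps_filter: float) -> float:
    """Remove the filter's series resistance: PSe = 1 / (1/PSt − 1/PSf).

    Raises
    ------
    NonPhysicalMeasurementError
        If ``ps_filter`` ≤ ``ps_total`` — the cells would contribute no
        resistance, which is a non-physical measurement, not a value to clip.
    """
    if ps_total <= 0 or ps_filter <= 0:
        raise ValidationError(
            f"permeability-surface products must be > 0 (PSt={ps_total}, PSf={ps_filter})"
        )
    if ps_filter <= ps_total:
        raise NonPhysicalMeasurementError(
            f"PSf ({ps_filter}) must exceed PSt ({ps_total}): the endothelium "
            "contributes no measurable resistance"
        )
    return 1.0 / (1.0 / ps_total - 1.0 / ps_filter)


def series_ps(ps_a: float, ps_b: float) -> float:
    """Combine two permeability–surface products as resistances in series."""
    return 1.0 / (1.0 / ps_a + 1.0 / ps_b)


def _mass_balance(tc: TranswellTimecourse, fmt: PlateFormat) -> float:
    """Percent of the initial amount found in donor + receiver at the last
    common sampling time; NaN when the donor was not re-sampled after t=0."""
    if tc.donor_times.size < 2:
        return math.nan
    t_final = tc.donor_times[-1]
    x0 = tc.c_l0 * fmt.luminal_volume
    x_donor = tc.donor_conc[-1] * fmt.luminal_volume
    mask = tc.receiver_times == t_final
    if not mask.any():
        return math.nan
    x_recv = float(tc.receiver_conc[mask][0]) * fmt.abluminal_volume
    return (x_donor + x_recv) / x0 * 100.0


def estimate_pe(
    cell_wells: Iterable[TranswellTimecourse],
    blank_wells: Iterable[TranswellTimecourse],
    fmt: PlateFormat,
    qc_bounds: tuple[float, float] = DEFAULT_QC_BOUNDS,
) -> list[PermeabilityResult]:
    """Estimate Pe for each cell insert against the batch's blank filters.

    PSf is the mean clearance slope over the blank (coating-only) wells run
    alongside; each cell well's PSt is corrected through the series-resistance
    relation. Wells where the correction is non-physical (PSf ≤ PSt) are
    flagged and reported with NaN Pe rather than failing the batch; mass
    balance outside ``qc_bounds`` adds a ``mass_balance`` flag.
    """
    blank_wells = list(blank_wells)
    cell_wells = list(cell_wells)
    if not blank_wells:
        raise ValidationError("at least one blank filter well is required to estimate PSf")
    ps_filter = float(np.mean([clearance_curve(b, fmt).slope for b in blank_wells]))
    results: list[PermeabilityResult] = []
    for tc in cell_wells:
        flags: list[str] = []
        ps_total = clearance_curve(tc, fmt).slope
        ps_e = math.nan
        pe = math.nan
        if ps_total <= 0:
            flags.append("nonpositive_slope")
        else:
            try:
                ps_e = correct_filter(ps_total, ps_filter)
                pe = ps_e * UL_PER_MIN_PER_CM2_TO_CM_PER_MIN / fmt.filter_area
            except NonPhysicalMeasurementError:
                flags.append("filter_not_leakier_than_total")
        qc = _mass_balance(tc, fmt)
        if not math.isnan(qc) and not (qc_bounds[0] <= qc <= qc_bounds[1]):
            flags.append("mass_balance")
        results.append(
            PermeabilityResult(
                well=tc.well,
                ps_total=ps_total,
                ps_filter=ps_filter,
                ps_endothelium=ps_e,
                area=fmt.filter_area,
                pe=pe,
                qc_mass_balance=qc,
                flags=tuple(flags),
            )
        )
    return results


def mean_pe(results: Sequence[PermeabilityResult]) -> tuple[float, float, int]:
    """Mean, sample SD (n−1 denominator) and n of Pe over unflagged wells.

    With a single unflagged well the SD is undefined and reported as NaN.
    """
    values = [r.pe for r in results if r.ok]
    if not values:
        raise ValidationError("no unflagged permeability results to summarise")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return float(arr.mean()), sd, int(arr.size)
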