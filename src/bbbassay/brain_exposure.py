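"""Compound recovery, in vitro Kp,uu,brain, and in vitro–in vivo correlation.

A compound dosed at C0 in the donor (luminal, "blood") compartment is
quantified after incubation as free concentrations CD (donor) and CR
(receiver, "brain"). The assay's two headline quantities are

    recovery     U = (CD + CR) · 100 / C0          (percent)
    Kp,uu,brain  = ((C0 − CD) / CD) · (U / 100)    (dimensionless)

Recovery enters the partition coefficient as a fraction: it discounts the
apparent donor depletion for compound that was lost (adsorbed, metabolised)
rather than transported. Note U sums concentrations from compartments of
unequal volume, so it is not a mass balance; an amount-based mass balance is
reported separately when the geometry is known.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .plate_formats import PlateFormat


def recovery(c0: float, cd: float, cr: float) -> float:
    """Percent of the applied concentration accounted for at assay end."""
    if c0 <= 0:
        raise ValidationError(f"C0 must be > 0, got {c0}")
    if cd < 0 or cr < 0:
        raise ValidationError("CD and CR must be >= 0")
    return (cd + cr) * 100.0 / c0


def kpuu_brain(c0: float, cd: float, u: float) -> float:
    """In vitro unbound brain-to-plasma partition coefficient.

    ``u`` is the recovery in percent and is applied as a fraction (u/100).
    CD > C0 (apparent negative transport) is treated as a measurement
    artefact: a warning is issued and 0 is returned.
    """
    if c0 <= 0:
        raise ValidationError(f"C0 must be > 0, got {c0}")
    if cd <= 0:
        raise ValidationError(f"CD must be > 0 for a defined donor-depletion ratio, got {cd}")
    if u < 0:
        raise ValidationError(f"recovery must be >= 0, got {u}")
    if cd > c0:
        warnings.warn(
            f"CD ({cd}) exceeds C0 ({c0}): apparent negative transport treated "
            "as QC failure; Kp,uu reported as 0",
            stacklevel=2,
        )
        return 0.0
    return (c0 - cd) / cd * (u / 100.0)


@dataclass(frozen=True)
class CompoundTransportRecord:
    compound: str
    c0: float  # µM
    cd: float  # µM
    cr: float  # µM
    recovery_pct: float
    kpuu_invitro: float
    qc_mass_balance: float  # amount-based, %; NaN when geometry unknown
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags


def compute_records(
    assay_table: pd.DataFrame,
    fmt: PlateFormat | None = None,
) -> list[CompoundTransportRecord]:
    """Apply recovery then Kp,uu to a per-compound (C0, CD, CR) table.

    Expects columns compound, C0_uM, CD_uM, CR_uM with one row per compound.
    Rows that cannot be evaluated (CD = 0, CD > C0) are flagged, not fatal.
    When ``fmt`` is given, an amount-based mass balance
    (CD·V_L + CR·V_R)/(C0·V_L) is reported alongside the concentration-based
    recovery.
    """
    required = {"compound", "C0_uM", "CD_uM", "CR_uM"}
    missing = required - set(assay_table.columns)
    if missing:
        raise ValidationError(f"assay table missing columns {sorted(missing)}")
    if assay_table["compound"].duplicated().any():
        dups = assay_table["compound"][assay_table["compound"].duplicated()].tolist()
        raise ValidationError(f"duplicate compound ids: {dups}")
    records: list[CompoundTransportRecord] = []
    for _, row in assay_table.iterrows():
        c0, cd, cr = float(row["C0_uM"]), float(row["CD_uM"]), float(row["CR_uM"])
        flags: list[str] = []
        u = recovery(c0, cd, cr)
        if cd <= 0:
            flags.append("undefined_ratio")
            kp = math.nan
        elif cd > c0:
            flags.append("apparent_negative_transport")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kp = kpuu_brain(c0, cd, u)
        else:
            kp = kpuu_brain(c0, cd, u)
        if fmt is not None:
            qc = (cd * fmt.luminal_volume + cr * fmt.abluminal_volume) / (
                c0 * fmt.luminal_volume
            ) * 100.0
        else:
            qc = math.nan
        records.append(
            CompoundTransportRecord(
                compound=str(row["compound"]),
                c0=c0,
                cd=cd,
                cr=cr,
                recovery_pct=u,
                kpuu_invitro=kp,
                qc_mass_balance=qc,
                flags=tuple(flags),
            )
        )
    return records


@dataclass(frozen=True)
class IVIVCPair:
    """One compound's in vitro prediction against its in vivo CSF reference."""

    compound: str
    kpuu_invitro: float
    kpuu_invivo_csf: float
    invivo_sd: float | None = None


@dataclass(frozen=True)
class IVIVCFit:
    """Power-law fit kpuu_invivo = scale · kpuu_invitro^exponent (log-log OLS)."""

    scale: float
    exponent: float
    r_squared: float
    n: int

    def predict(self, kpuu_invitro) -> np.ndarray:
        return self.scale * np.asarray(kpuu_invitro, float) ** self.exponent


def ivivc_fit(pairs: Sequence[IVIVCPair]) -> IVIVCFit:
    """Fit the in vitro–in vivo correlation as a power law.

    Kp,uu values span orders of magnitude and the comparison is ratio-scaled,
    so the fit is ordinary least squares in log-log space:
    log(kpuu_invivo) = log(scale) + exponent·log(kpuu_invitro), with R²
    computed on the log scale. Invariant under reordering of the pairs.
    """
    if len(pairs) < 3:
        raise ValidationError(f"ivivc_fit needs at least 3 pairs, got {len(pairs)}")
    x = np.array([p.kpuu_invitro for p in pairs], float)
    y = np.array([p.kpuu_invivo_csf for p in pairs], float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("all Kp,uu values must be > 0 for a log-scale fit")
    lx, ly = np.log(x), np.log(y)
    exponent, log_scale = np.polyfit(lx, ly, 1)
    resid = ly - (log_scale + exponent * lx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return IVIVCFit(
        scale=float(np.exp(log_scale)),
        exponent=float(exponent),
        r_squared=float(r2),
        n=len(pairs),
    )
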