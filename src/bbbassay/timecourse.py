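"""Sampled donor/receiver concentration timecourse for one transwell insert.

The donor (luminal) compartment must include a time-zero sample: its
concentration ``C_L0`` anchors the clearance calculation. Receiver samples at
t = 0 are allowed (and are normally zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Well roles understood by the pipeline.
ROLES = ("cell_insert", "blank_filter", "vehicle_control", "condition")


def _as_sorted_series(times, conc, label: str) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValidationError(f"{label}: times and concentrations must be 1-D and equal length")
    if t.size and np.any(np.diff(t) <= 0):
        raise ValidationError(f"{label}: times must be unique and strictly increasing")
    if np.any(t < 0):
        raise ValidationError(f"{label}: negative times")
    if np.any(c < 0):
        raise ValidationError(f"{label}: negative concentrations")
    return t, c


@dataclass(frozen=True)
class TranswellTimecourse:
    """Concentration samples (µM) over time (min) for one well."""

    well: str
    role: str
    format_name: str
    donor_times: np.ndarray = field(repr=False)
    donor_conc: np.ndarray = field(repr=False)
    receiver_times: np.ndarray = field(repr=False)
    receiver_conc: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        dt, dc = _as_sorted_series(self.donor_times, self.donor_conc, f"well {self.well} donor")
        rt, rc = _as_sorted_series(
            self.receiver_times, self.receiver_conc, f"well {self.well} receiver"
        )
        object.__setattr__(self, "donor_times", dt)
        object.__setattr__(self, "donor_conc", dc)
        object.__setattr__(self, "receiver_times", rt)
        object.__setattr__(self, "receiver_conc", rc)
        if dt.size == 0 or dt[0] != 0.0:
            raise ValidationError(f"well {self.well}: donor series must include a t=0 sample")
        if dc[0] <= 0:
            raise ValidationError(f"well {self.well}: initial donor concentration must be > 0")

    @property
    def c_l0(self) -> float:
        """Initial (t = 0) donor concentration, µM."""
        return float(self.donor_conc[0])

    def receiver_after_zero(self) -> tuple[np.ndarray, np.ndarray]:
        """Receiver samples at strictly positive times."""
        mask = self.receiver_times > 0
        return self.receiver_times[mask], self.receiver_conc[mask]
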