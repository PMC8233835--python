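"""Plate/insert geometry registry, assay-resource arithmetic, and file I/O.

Three insert systems are built in: the original 12-well transwell model and
two miniaturized 96-well systems (Falcon and Corning). Each format stores two
volume pairs: the *assay* volumes used in permeability runs (Ringer-HEPES in
the luminal/abluminal compartments) and the *culture* volumes of growth medium
used during the 6-day coculture — the latter drive the resource calculator.

Canonical units: volumes µL (resource totals reported in mL), area cm²,
time min, concentration µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields, is_dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, UnknownFormatError, ValidationError
from .timecourse import ROLES, TranswellTimecourse


@dataclass(frozen=True)
class PlateFormat:
    """Immutable geometry and volume constants of one insert system."""

    name: str
    filter_area: float  # cm²
    luminal_volume: float  # µL, assay (donor) compartment
    abluminal_volume: float  # µL, assay (receiver) compartment
    culture_luminal_volume: float  # µL growth medium, insert
    culture_abluminal_volume: float  # µL growth medium, bottom well
    wells_per_plate: int
    matrigel_volume_per_filter: float  # µL
    gelatine_volume_per_well: float  # µL
    ec_seeding_density: int  # endothelial cells per filter
    pc_seeding_density: int  # pericytes per bottom well

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name != "name" and v <= 0:
                raise ValidationError(f"PlateFormat.{f.name} must be strictly positive, got {v}")


_REGISTRY: dict[str, PlateFormat] = {
    fmt.name: fmt
    for fmt in (
        PlateFormat(
            name="12tw",
            filter_area=1.13,
            luminal_volume=500.0,
            abluminal_volume=1500.0,
            culture_luminal_volume=500.0,
            culture_abluminal_volume=1500.0,
            wells_per_plate=12,
            matrigel_volume_per_filter=500.0,
            gelatine_volume_per_well=1000.0,
            ec_seeding_density=80_000,
            pc_seeding_density=50_000,
        ),
        PlateFormat(
            name="96tw_falcon",
            filter_area=0.0804,
            luminal_volume=70.0,
            abluminal_volume=300.0,
            culture_luminal_volume=75.0,
            culture_abluminal_volume=300.0,
            wells_per_plate=96,
            matrigel_volume_per_filter=35.0,
            gelatine_volume_per_well=75.0,
            ec_seeding_density=18_000,
            pc_seeding_density=15_000,
        ),
        PlateFormat(
            name="96tw_corning",
            filter_area=0.143,
            luminal_volume=70.0,
            abluminal_volume=300.0,
            culture_luminal_volume=75.0,
            culture_abluminal_volume=300.0,
            wells_per_plate=96,
            matrigel_volume_per_filter=35.0,
            gelatine_volume_per_well=75.0,
            ec_seeding_density=22_000,
            pc_seeding_density=15_000,
        ),
    )
}


def available_formats() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def get_format(name: str) -> PlateFormat:
    """Look up a registered insert system by name.

    Raises
    ------
    UnknownFormatError
        If ``name`` is not registered; the message lists the valid names.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownFormatError(
            f"unknown plate format {name!r}; available formats: {', '.join(_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class ResourceEstimate:
    """Consumables needed for a run of ``n_points`` experimental points."""

    n_points: int
    plates_needed: int
    medium_total: float  # mL
    matrigel_total: float  # mL
    gelatine_total: float  # mL
    n_medium_fills: int


def estimate_resources(
    n_points: int, fmt: PlateFormat, n_medium_fills: int = 3
) -> ResourceEstimate:
    """Plates and consumable volumes for ``n_points`` experimental points.

    ``n_medium_fills`` defaults to 3: the seeding fill plus the two medium
    changes of the 6-day coculture. Whole plates are coated and filled, so
    totals scale with ``plates_needed × wells_per_plate``.
    """
    if int(n_points) != n_points or n_points < 1:
        raise ValidationError(f"n_points must be a positive integer, got {n_points}")
    if int(n_medium_fills) != n_medium_fills or n_medium_fills < 1:
        raise ValidationError(f"n_medium_fills must be a positive integer, got {n_medium_fills}")
    plates = math.ceil(n_points / fmt.wells_per_plate)
    wells = plates * fmt.wells_per_plate
    per_fill_ul = fmt.culture_luminal_volume + fmt.culture_abluminal_volume
    return ResourceEstimate(
        n_points=int(n_points),
        plates_needed=plates,
        medium_total=wells * per_fill_ul * n_medium_fills / 1000.0,
        matrigel_total=wells * fmt.matrigel_volume_per_filter / 1000.0,
        gelatine_total=wells * fmt.gelatine_volume_per_well / 1000.0,
        n_medium_fills=int(n_medium_fills),
    )


# ---------------------------------------------------------------------------
# Plate maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WellEntry:
    well: str
    role: str
    compound: str | None
    concentration_uM: float | None
    format_name: str


@dataclass(frozen=True)
class PlateMap:
    """Assignment of wells to roles (cell insert, blank filter, control, condition)."""

    entries: tuple[WellEntry, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.well in seen:
                raise ValidationError(f"duplicate well id {e.well!r} in plate map")
            seen.add(e.well)
            if e.role not in ROLES:
                raise ValidationError(f"well {e.well}: unknown role {e.role!r}")
            if e.role == "condition" and (e.compound is None or e.concentration_uM is None):
                raise ValidationError(
                    f"well {e.well}: condition wells must name a compound and concentration"
                )

    def __getitem__(self, well: str) -> WellEntry:
        for e in self.entries:
            if e.well == well:
                return e
        raise KeyError(well)

    def __contains__(self, well: str) -> bool:
        return any(e.well == well for e in self.entries)

    def wells_with_role(self, role: str) -> tuple[str, ...]:
        return tuple(e.well for e in self.entries if e.role == role)


def read_plate_map(path: str | Path) -> PlateMap:
    """Read a plate-map CSV (columns: well,role,compound,concentration_uM,format)."""
    df = pd.read_csv(path, dtype=str)
    required = {"well", "role", "compound", "concentration_uM", "format"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"plate map {path}: missing columns {sorted(missing)}")
    entries = []
    for i, row in df.iterrows():
        compound = None if pd.isna(row["compound"]) else str(row["compound"])
        conc = None if pd.isna(row["concentration_uM"]) else float(row["concentration_uM"])
        entries.append(
            WellEntry(
                well=str(row["well"]),
                role=str(row["role"]),
                compound=compound,
                concentration_uM=conc,
                format_name=str(row["format"]),
            )
        )
    return PlateMap(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Timecourse CSV
# ---------------------------------------------------------------------------

_TC_COLUMNS = ("well", "compartment", "time_min", "concentration_uM")


def read_timecourses(path: str | Path, plate_map: PlateMap) -> list[TranswellTimecourse]:
    """Read a long-format timecourse CSV and join it to plate-map roles.

    Expected columns: well, compartment ∈ {donor, receiver}, time_min,
    concentration_uM. Returns one :class:`TranswellTimecourse` per well with
    rows sorted by time; malformed rows raise :class:`ParseError` carrying the
    offending CSV row number (1-based, header = row 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TC_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"timecourse file {path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    df = df.copy()
    df["_row"] = df.index + 2  # CSV line number (header is line 1)
    bad = df[~df["compartment"].isin(["donor", "receiver"])]
    if len(bad):
        r = bad.iloc[0]
        raise ParseError(f"row {r['_row']}: unknown compartment {r['compartment']!r}")
    bad = df[df["concentration_uM"] < 0]
    if len(bad):
        r = bad.iloc[0]
        raise ParseError(f"row {r['_row']}: negative concentration {r['concentration_uM']}")
    bad = df[df["time_min"] < 0]
    if len(bad):
        r = bad.iloc[0]
        raise ParseError(f"row {r['_row']}: negative time {r['time_min']}")
    dup = df.duplicated(subset=["well", "compartment", "time_min"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ParseError(
            f"row {r['_row']}: duplicate sample for well {r['well']!r}, "
            f"{r['compartment']} compartment at t={r['time_min']}"
        )
    out: list[TranswellTimecourse] = []
    for well, grp in df.groupby("well", sort=False):
        well = str(well)
        if well not in plate_map:
            row = int(grp["_row"].iloc[0])
            raise ParseError(f"row {row}: well {well!r} not present in the plate map")
        entry = plate_map[well]
        donor = grp[grp["compartment"] == "donor"].sort_values("time_min")
        recv = grp[grp["compartment"] == "receiver"].sort_values("time_min")
        out.append(
            TranswellTimecourse(
                well=well,
                role=entry.role,
                format_name=entry.format_name,
                donor_times=donor["time_min"].to_numpy(float),
                donor_conc=donor["concentration_uM"].to_numpy(float),
                receiver_times=recv["time_min"].to_numpy(float),
                receiver_conc=recv["concentration_uM"].to_numpy(float),
            )
        )
    return out


def write_timecourses(timecourses: Iterable[TranswellTimecourse], path: str | Path) -> None:
    """Write timecourses back to the long CSV dialect read by :func:`read_timecourses`."""
    rows = []
    for tc in timecourses:
        for t, c in zip(tc.donor_times, tc.donor_conc):
            rows.append((tc.well, "donor", t, c))
        for t, c in zip(tc.receiver_times, tc.receiver_conc):
            rows.append((tc.well, "receiver", t, c))
    pd.DataFrame(rows, columns=_TC_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _record_to_dict(record) -> dict:
    if is_dataclass(record):
        d = asdict(record)
    elif isinstance(record, Mapping):
        d = dict(record)
    else:
        raise ValidationError(f"cannot serialise record of type {type(record).__name__}")
    out = {}
    for k, v in d.items():
        if isinstance(v, (list, tuple, np.ndarray)):
            v = ";".join(str(x) for x in np.asarray(v).ravel())
        out[k] = v
    return out


def write_results(records: Sequence, path: str | Path) -> None:
    """Write result records as TSV with stable column order and full float precision.

    Works for any of this package's result dataclasses (or plain mappings);
    list-valued fields (e.g. QC flags) are serialised ';'-separated. An empty
    collection still needs a schema, so it writes a header-only file when the
    records' type can be inferred, else an empty file.
    """
    records = list(records)
    if not records:
        Path(path).write_text("")
        return
    rows = [_record_to_dict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(rows[0].keys()))
    for col in df.columns:  # shortest round-tripping float representation
        if df[col].dtype.kind == "f":
            df[col] = df[col].map(lambda x: repr(float(x)))
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results` back into a DataFrame."""
    text = Path(path).read_text()
    if not text.strip():
        return pd.DataFrame()
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
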