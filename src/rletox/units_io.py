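"""Canonical units, CSV ingest/emit, and the packaged literature fixture.

Everything downstream of this module works in micrograms per litre and
days.  Conversion happens exactly once, at ingest; the supported source
units are the ones that occur in published fish acute-toxicity tables
(µg/L, mg/L, g/L, ppm, ppb for concentration; seconds through days for
exposure time).  ppm and ppb are treated as mg/L and µg/L equivalents,
which assumes dilute aqueous solution of density 1 g/mL — the ambient-water
setting these data come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import math

import pandas as pd

from .errors import UnitError, ValidationError

logger = logging.getLogger(__name__)

#: multiplicative factors to µg/L
_CONC_FACTORS = {
    "ug/l": 1.0,
    "µg/l": 1.0,
    "μg/l": 1.0,  # greek mu vs micro sign
    "mg/l": 1e3,
    "g/l": 1e6,
    "ppm": 1e3,  # mg/L equivalent in dilute aqueous solution
    "ppb": 1.0,  # µg/L equivalent
}

#: multiplicative factors to days
_TIME_FACTORS = {
    "seconds": 1.0 / 86400.0,
    "second": 1.0 / 86400.0,
    "sec": 1.0 / 86400.0,
    "s": 1.0 / 86400.0,
    "minutes": 1.0 / 1440.0,
    "minute": 1.0 / 1440.0,
    "min": 1.0 / 1440.0,
    "hours": 1.0 / 24.0,
    "hour": 1.0 / 24.0,
    "hr": 1.0 / 24.0,
    "hrs": 1.0 / 24.0,
    "h": 1.0 / 24.0,
    "days": 1.0,
    "day": 1.0,
    "d": 1.0,
}


def normalize_concentration(value: float, unit: str) -> float:
    """Convert a concentration to µg/L.

    Parameters
    ----------
    value : non-negative concentration in `unit`.
    unit : one of µg/L, mg/L, g/L, ppm, ppb (case-insensitive).
    """
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"concentration must be finite and >= 0, got {value!r}")
    try:
        factor = _CONC_FACTORS[unit.strip().lower()]
    except (KeyError, AttributeError):
        raise UnitError(f"unknown concentration unit: {unit!r}") from None
    return value * factor


def normalize_time(value: float, unit: str) -> float:
    """Convert an exposure duration to days.  `value` must be > 0."""
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"exposure time must be finite and > 0, got {value!r}")
    try:
        factor = _TIME_FACTORS[unit.strip().lower()]
    except (KeyError, AttributeError):
        raise UnitError(f"unknown time unit: {unit!r}") from None
    return value * factor


@dataclass(frozen=True)
class ToxicityRecord:
    """One (exposure time, LC50) observation in canonical units."""

    time_days: float
    lc50_ugL: float

    def __post_init__(self):
        if not math.isfinite(self.time_days) or self.time_days <= 0:
            raise ValidationError(f"time_days must be > 0, got {self.time_days!r}")
        if not math.isfinite(self.lc50_ugL) or self.lc50_ugL < 0:
            raise ValidationError(f"lc50_ugL must be finite and >= 0, got {self.lc50_ugL!r}")


@dataclass
class ToxicitySeries:
    """An ordered set of observations for one species × toxicant dataset.

    Records are kept sorted by exposure time.  `reported_nlt_days` is the
    literature value of the species' normal life expectancy, when known.
    """

    species: str
    toxicant: str
    records: list[ToxicityRecord]
    reported_nlt_days: Optional[float] = None
    dataset_id: Optional[str] = None

    def __post_init__(self):
        if not self.species or not self.toxicant:
            raise ValidationError("species and toxicant must be non-empty")
        if self.reported_nlt_days is not None and not self.reported_nlt_days > 0:
            raise ValidationError("reported_nlt_days must be positive when given")
        self.records = sorted(self.records, key=lambda r: r.time_days)

    @property
    def times_days(self) -> list[float]:
        return [r.time_days for r in self.records]

    @property
    def lc50s_ugL(self) -> list[float]:
        return [r.lc50_ugL for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FixtureEntry:
    """One coefficient-bearing dataset from the packaged literature table."""

    species: str
    toxicant: str
    intercept_b: float  # µg/L
    slope_a: float  # µg/L per ln(day)
    r_squared: float
    reported_nlt_days: Optional[float] = None
    reported_calculated_ln_nlt: Optional[float] = None  # species-level printed value
    flags: frozenset[str] = field(default_factory=frozenset)
    source_ref: str = ""


_REQUIRED_COLUMNS = ("species", "toxicant", "time_value", "time_unit", "conc_value", "conc_unit")


def read_series_csv(path: str | Path) -> list[ToxicitySeries]:
    """Read toxicity datasets from CSV, normalizing to µg/L and days.

    Expected columns: species, toxicant, time_value, time_unit, conc_value,
    conc_unit; optional dataset_id and reported_nlt_days.  Rows are grouped
    by (species, toxicant, dataset_id).  Malformed rows raise with their
    line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if df.empty and df.columns.size == 0:
        logger.warning("empty input file: %s", path)
        return []
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("no data rows in %s", path)
        return []

    groups: dict[tuple, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            t = normalize_time(float(row["time_value"]), row["time_unit"])
            c = normalize_concentration(float(row["conc_value"]), row["conc_unit"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
        dataset_id = row.get("dataset_id")
        dataset_id = None if pd.isna(dataset_id) else str(dataset_id)
        nlt = row.get("reported_nlt_days")
        nlt = None if pd.isna(nlt) else float(nlt)
        key = (row["species"], row["toxicant"], dataset_id)
        grp = groups.setdefault(key, {"records": [], "nlt": nlt})
        grp["records"].append(ToxicityRecord(t, c))
        if grp["nlt"] is None:
            grp["nlt"] = nlt

    return [
        ToxicitySeries(species=sp, toxicant=tox, records=g["records"],
                       reported_nlt_days=g["nlt"], dataset_id=ds)
        for (sp, tox, ds), g in groups.items()
    ]


def write_series_csv(series_list: Iterable[ToxicitySeries], path: str | Path) -> None:
    """Write datasets in the same schema `read_series_csv` accepts.

    Values are emitted in canonical units (days, µg/L) at full precision so
    a write/read round trip is exact.
    """
    rows = []
    for s in series_list:
        for rec in s.records:
            rows.append({
                "species": s.species,
                "toxicant": s.toxicant,
                "dataset_id": s.dataset_id,
                "time_value": repr(rec.time_days),
                "time_unit": "days",
                "conc_value": repr(rec.lc50_ugL),
                "conc_unit": "ug/L",
                "reported_nlt_days": s.reported_nlt_days,
            })
    pd.DataFrame(rows, columns=["species", "toxicant", "dataset_id", "time_value",
                                "time_unit", "conc_value", "conc_unit",
                                "reported_nlt_days"]).to_csv(path, index=False)


def _fixture_path(name: str):
    return resources.files("rletox.data").joinpath(name)


def load_table1_fixture() -> list[FixtureEntry]:
    """Load the packaged regression-coefficient table (67 fish datasets).

    Each entry carries the printed intercept b (µg/L), slope a (µg/L per
    ln day), R², the literature normal life expectancy of the species, and,
    for species with at least four datasets, the species-level calculated
    ln NLT printed in the source table.  Rows whose coefficients were not
    printed are omitted (see `load_table1_omissions`).
    """
    with resources.as_file(_fixture_path("table1.csv")) as p:
        df = pd.read_csv(p)
    entries = []
    for _, row in df.iterrows():
        flags = frozenset() if pd.isna(row["flag"]) else frozenset(str(row["flag"]).split(";"))
        entries.append(FixtureEntry(
            species=row["species"],
            toxicant=row["toxicant"],
            intercept_b=float(row["intercept_b_ugL"]),
            slope_a=float(row["slope_a"]),
            r_squared=float(row["r_squared"]),
            reported_nlt_days=None if pd.isna(row["reported_nlt_days"]) else float(row["reported_nlt_days"]),
            reported_calculated_ln_nlt=None if pd.isna(row["printed_calculated_ln_nlt"]) else float(row["printed_calculated_ln_nlt"]),
            flags=flags,
            source_ref="" if pd.isna(row["source_ref"]) else str(row["source_ref"]),
        ))
    return entries


def load_table1_omissions() -> pd.DataFrame:
    """Manifest of source-table rows shipped without coefficients."""
    with resources.as_file(_fixture_path("table1_omissions.csv")) as p:
        return pd.read_csv(p)
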