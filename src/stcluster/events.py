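"""Event records: reading, validating, and writing point-located event tables.

An *event* is one case: a unique id, a school location in decimal degrees
(WGS-84 assumed), a calendar date (day resolution), and a set of categorical
covariates describing the case.  Missing categorical cells are represented by
the explicit level ``"missing"`` and are never imputed; downstream statistics
use pairwise- or listwise-complete cases as appropriate.

The on-disk format is delimited text (comma by default) with a header.  A
schema mapping (dict or YAML file) can rename source columns onto the
canonical field names.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING = "missing"

#: canonical categorical fields and their allowed (non-missing) levels
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "school_type": ("elementary", "middle", "high"),
    "family_structure": ("both_parents", "other"),
    "economic_status": ("upper", "middle", "lower"),
    "method": ("jumping", "hanging", "other"),
    "concern_family": ("yes", "no"),
    "concern_academic": ("yes", "no"),
    "concern_peer": ("yes", "no"),
    "psychiatric_history": ("yes", "no"),
    "attempt_history": ("yes", "no"),
    "selfharm_history": ("yes", "no"),
}

#: optional numeric fields (age in years, six teacher-rated SDQ scores)
NUMERIC_FIELDS: tuple[str, ...] = (
    "age",
    "sdq_prosocial",
    "sdq_hyperactivity",
    "sdq_emotional",
    "sdq_conduct",
    "sdq_peer",
    "sdq_total",
)

REQUIRED_FIELDS: tuple[str, ...] = ("id", "lat", "lon", "date")

ALL_FIELDS: tuple[str, ...] = (
    REQUIRED_FIELDS + tuple(CATEGORICAL_LEVELS) + NUMERIC_FIELDS
)


class EventValidationError(ValueError):
    """Raised when an input row or table violates the event contract."""


def _parse_date(value, row_label) -> dt.date:
    """Parse an ISO-8601 (YYYY-MM-DD) date; reject anything unparseable.

    Events whose dates cannot be determined are excluded from this kind of
    study at the source, so an unparseable date here is a hard, row-addressed
    error rather than a silent drop.
    """
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, (dt.datetime, pd.Timestamp)):
        return value.date()
    text = str(value).strip()
    try:
        return dt.date.fromisoformat(text)
    except ValueError:
        raise EventValidationError(
            f"row {row_label}: unparseable date {value!r} (expected YYYY-MM-DD)"
        ) from None


@dataclass(frozen=True)
class Event:
    """A single point-located case."""

    id: str
    lat: float
    lon: float
    date: dt.date
    sex: str = MISSING
    school_type: str = MISSING
    family_structure: str = MISSING
    economic_status: str = MISSING
    method: str = MISSING
    concern_family: str = MISSING
    concern_academic: str = MISSING
    concern_peer: str = MISSING
    psychiatric_history: str = MISSING
    attempt_history: str = MISSING
    selfharm_history: str = MISSING
    age: float | None = None
    sdq_prosocial: float | None = None
    sdq_hyperactivity: float | None = None
    sdq_emotional: float | None = None
    sdq_conduct: float | None = None
    sdq_peer: float | None = None
    sdq_total: float | None = None

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise EventValidationError(f"event {self.id!r}: lat {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise EventValidationError(f"event {self.id!r}: lon {self.lon} out of [-180, 180]")
        for name, levels in CATEGORICAL_LEVELS.items():
            value = getattr(self, name)
            if value != MISSING and value not in levels:
                raise EventValidationError(
                    f"event {self.id!r}: {name}={value!r} not in {levels + (MISSING,)}"
                )

    @property
    def year(self) -> int:
        """Calendar year of the event, used for year dummy coding."""
        return self.date.year


def derive_year(event: Event) -> int:
    """Calendar year of an event (reference level 2016 in regression coding)."""
    return event.year


@dataclass
class EventSet:
    """An ordered collection of events, optionally bounded by a study window."""

    events: list[Event]
    window: tuple[dt.date, dt.date] | None = None

    def __post_init__(self):
        ids = [e.id for e in self.events]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})
            raise EventValidationError(f"duplicate event ids: {dups}")
        if self.window is not None:
            lo, hi = self.window
            if lo > hi:
                raise EventValidationError(f"window start {lo} after end {hi}")
            for e in self.events:
                if not lo <= e.date <= hi:
                    raise EventValidationError(
                        f"event {e.id!r} date {e.date} outside window {lo}..{hi}"
                    )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i: int) -> Event:
        return self.events[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return self.events == other.events and self.window == other.window

    def to_frame(self) -> pd.DataFrame:
        """Events as a pandas DataFrame, one row per event, order preserved."""
        rows = []
        for e in self.events:
            row = {f: getattr(e, f) for f in ALL_FIELDS}
            row["date"] = e.date.isoformat()
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(ALL_FIELDS))
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, window: tuple[dt.date, dt.date] | None = None
    ) -> "EventSet":
        events = []
        for idx, row in df.iterrows():
            kwargs: dict = {}
            missing_required = [f for f in REQUIRED_FIELDS if f not in df.columns]
            if missing_required:
                raise EventValidationError(f"missing required columns: {missing_required}")
            kwargs["id"] = str(row["id"])
            try:
                kwargs["lat"] = float(row["lat"])
                kwargs["lon"] = float(row["lon"])
            except (TypeError, ValueError):
                raise EventValidationError(
                    f"row {idx}: non-numeric coordinates lat={row['lat']!r} lon={row['lon']!r}"
                ) from None
            kwargs["date"] = _parse_date(row["date"], idx)
            for name in CATEGORICAL_LEVELS:
                if name in df.columns:
                    v = row[name]
                    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                        kwargs[name] = MISSING
                    else:
                        kwargs[name] = str(v).strip()
            for name in NUMERIC_FIELDS:
                if name in df.columns:
                    v = row[name]
                    if v is None or str(v).strip() == "" or (isinstance(v, float) and np.isnan(v)):
                        kwargs[name] = None
                    else:
                        kwargs[name] = float(v)
            try:
                events.append(Event(**kwargs))
            except EventValidationError as err:
                raise EventValidationError(f"row {idx}: {err}") from None
        return cls(events=events, window=window)


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a YAML schema mapping of source column name -> canonical field."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise EventValidationError(f"schema file {path} must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def read_events(
    path: str | Path,
    schema: Mapping[str, str] | str | Path | None = None,
    sep: str = ",",
    window: tuple[dt.date, dt.date] | None = None,
) -> EventSet:
    """Read a delimited-text event table into a validated :class:`EventSet`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    schema
        Optional mapping from source column names to canonical field names,
        or the path of a YAML file containing one.
    sep
        Field delimiter (comma default, tab for TSV).
    window
        Optional (start, end) study window; events outside it are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if schema is not None:
        if isinstance(schema, (str, Path)):
            schema = load_schema(schema)
        df = df.rename(columns=dict(schema))
    unknown = [c for c in df.columns if c not in ALL_FIELDS]
    df = df.drop(columns=unknown)
    return EventSet.from_frame(df, window=window)


def write_events(events: EventSet, path: str | Path, sep: str = ",") -> None:
    """Write an :class:`EventSet` as delimited text; inverse of :func:`read_events`."""
    df = events.to_frame()
    # blank cells for explicit missing so the file round-trips cleanly
    for name in CATEGORICAL_LEVELS:
        df[name] = df[name].replace(MISSING, "")
    df.to_csv(path, sep=sep, index=False)


def to_geojson(events: EventSet) -> dict:
    """Events as a GeoJSON FeatureCollection of Points (lon-lat order)."""
    features = []
    for e in events:
        props = {f: getattr(e, f) for f in ALL_FIELDS if f not in ("lat", "lon")}
        props["date"] = e.date.isoformat()
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [e.lon, e.lat]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(events: EventSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(to_geojson(events), fh)
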