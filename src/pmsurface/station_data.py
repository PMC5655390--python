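"""Data model and I/O for particulate-matter monitoring station tables.

A *station table* is the unit of input for every analysis in this package: one
row per monitoring site with its projected planar coordinates (UTM metres),
the number of samples collected there, and per-pollutant concentration
summaries (mean, standard error, observed range) for PM2.5 and PM10.

The packaged fixture (:func:`sabzevar_fixture`) is the 48-station network
measured in the city of Sabzevar, Iran over a 9-month campaign; it is the
dataset all the printed reference numbers in the test suite refer to.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "StationRecord",
    "StationSet",
    "Anomaly",
    "CSV_COLUMNS",
    "load_stations",
    "write_stations",
    "sabzevar_fixture",
    "validate_stations",
]

#: Column order of the canonical CSV schema.
CSV_COLUMNS = [
    "station_id", "name", "easting", "northing", "n_samples", "fabric",
    "pm25_mean", "pm25_se", "pm25_min", "pm25_max",
    "pm10_mean", "pm10_se", "pm10_min", "pm10_max", "ratio",
]

Pollutant = Literal["pm25", "pm10"]


@dataclass(frozen=True)
class StationRecord:
    """One monitoring site with its per-pollutant concentration summary."""

    station_id: int
    name: str
    easting: float   # UTM easting, metres
    northing: float  # UTM northing, metres
    n_samples: int
    fabric: str      # urban-fabric class (Square / Avenue / Boulevard / ...)
    pm25_mean: float
    pm25_se: float
    pm25_min: float
    pm25_max: float
    pm10_mean: float
    pm10_se: float
    pm10_min: float
    pm10_max: float
    ratio: float     # printed PM2.5/PM10 ratio, as reported in the source table

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError(
                f"station {self.station_id}: n_samples must be >= 1, got {self.n_samples}"
            )
        if not (math.isfinite(self.easting) and math.isfinite(self.northing)):
            raise ValidationError(f"station {self.station_id}: non-finite coordinates")

    def mean(self, pollutant: Pollutant) -> float:
        return getattr(self, f"{pollutant}_mean")


@dataclass(frozen=True)
class StationSet:
    """An ordered, validated collection of monitoring stations.

    Hard invariants (checked at construction): unique station ids and
    pairwise-distinct locations.  Soft data-quality issues (e.g. a mean
    outside its own printed range) are *not* rejected here; they are surfaced
    by :func:`validate_stations` so that source tables can be loaded verbatim.
    """

    records: tuple[StationRecord, ...]
    crs_label: str = "UTM zone 40N, metres"

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.station_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate station ids: {dupes}")
        seen: dict[tuple[float, float], int] = {}
        for r in self.records:
            key = (r.easting, r.northing)
            if key in seen:
                raise ValidationError(
                    f"stations {seen[key]} and {r.station_id} share coordinates {key}"
                )
            seen[key] = r.station_id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[StationRecord]:
        return iter(self.records)

    def get(self, station_id: int) -> StationRecord:
        for r in self.records:
            if r.station_id == station_id:
                return r
        raise KeyError(station_id)

    @property
    def station_ids(self) -> np.ndarray:
        return np.array([r.station_id for r in self.records], dtype=int)

    def locations(self) -> np.ndarray:
        """(n, 2) array of (easting, northing) in metres."""
        return np.array([[r.easting, r.northing] for r in self.records], dtype=float)

    def values(self, pollutant: Pollutant) -> np.ndarray:
        return np.array([r.mean(pollutant) for r in self.records], dtype=float)

    def pollutant_data(self, pollutant: Pollutant) -> tuple[np.ndarray, np.ndarray]:
        """(locations, station-mean concentrations) for one pollutant."""
        return self.locations(), self.values(pollutant)

    def bbox(self) -> tuple[float, float, float, float]:
        """(min_easting, max_easting, min_northing, max_northing)."""
        xy = self.locations()
        return (xy[:, 0].min(), xy[:, 0].max(), xy[:, 1].min(), xy[:, 1].max())

    def subset(self, keep: Iterable[int]) -> "StationSet":
        """New StationSet restricted to positional indices ``keep`` (order kept)."""
        keep = list(keep)
        return replace(self, records=tuple(self.records[i] for i in keep))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{c: getattr(r, c) for c in CSV_COLUMNS} for r in self.records],
                            columns=CSV_COLUMNS)


@dataclass(frozen=True)
class Anomaly:
    """A flagged (non-fatal) data-quality issue in a station table."""

    station_id: int
    field: str
    message: str


def validate_stations(stations: StationSet, tol: float = 0.01) -> list[Anomaly]:
    """Report soft data-quality anomalies without rejecting the data.

    Checks, per station:

    * ``min <= mean <= max`` for each pollutant (the Sabzevar fixture is known
      to violate this for station 48's PM10 row — a range/mean inconsistency
      in the source table);
    * the printed PM2.5/PM10 ratio agrees with the ratio recomputed from the
      printed means to within ``tol`` after rounding to 2 decimals (station 15
      of the fixture prints 0.42 where its means give 0.46).
    """
    out: list[Anomaly] = []
    for r in stations:
        for pol in ("pm25", "pm10"):
            lo, mu, hi = (getattr(r, f"{pol}_min"), getattr(r, f"{pol}_mean"),
                          getattr(r, f"{pol}_max"))
            if not (lo <= mu <= hi):
                out.append(Anomaly(r.station_id, f"{pol}_mean",
                                   f"mean {mu} outside printed range [{lo}, {hi}]"))
        if r.pm10_mean > 0:
            recomputed = round(r.pm25_mean / r.pm10_mean, 2)
            if abs(recomputed - r.ratio) > tol + 1e-12:
                out.append(Anomaly(r.station_id, "ratio",
                                   f"printed ratio {r.ratio} vs recomputed {recomputed}"))
    return out


def _records_from_dataframe(df: pd.DataFrame) -> tuple[StationRecord, ...]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    recs = []
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields(StationRecord):
            v = row[f.name]
            if f.type in ("int", int):
                v = int(v)
            elif f.type in ("float", float):
                v = float(v)
            else:
                v = str(v)
            kwargs[f.name] = v
        recs.append(StationRecord(**kwargs))
    return tuple(recs)


def load_stations(path: str | Path, format: str | None = None,
                  crs_label: str = "UTM zone 40N, metres") -> StationSet:
    """Load a station table from CSV or GeoJSON.

    ``format`` defaults to the file extension (.csv / .geojson / .json).
    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for duplicate ids or coordinates.
    """
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if format == "csv":
        df = pd.read_csv(path)
        return StationSet(_records_from_dataframe(df), crs_label=crs_label)
    if format == "geojson":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        rows = []
        for feat in doc.get("features", []):
            props = dict(feat["properties"])
            x, y = feat["geometry"]["coordinates"]
            props["easting"], props["northing"] = x, y
            rows.append(props)
        df = pd.DataFrame(rows, columns=CSV_COLUMNS)
        label = doc.get("crs_label", crs_label)
        return StationSet(_records_from_dataframe(df) if rows else (), crs_label=label)
    raise ValueError(f"unknown format {format!r}")


def write_stations(stations: StationSet, path: str | Path,
                   format: str | None = None) -> None:
    """Write a station table to CSV or GeoJSON; round-trips with :func:`load_stations`."""
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "csv"
    if format == "csv":
        stations.to_dataframe().to_csv(path, index=False)
        return
    if format == "geojson":
        features = []
        for r in stations:
            props = {c: getattr(r, c) for c in CSV_COLUMNS
                     if c not in ("easting", "northing")}
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.easting, r.northing]},
                "properties": props,
            })
        doc = {"type": "FeatureCollection", "crs_label": stations.crs_label,
               "features": features}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
        return
    raise ValueError(f"unknown format {format!r}")


def sabzevar_fixture() -> StationSet:
    """The packaged 48-station Sabzevar monitoring table, values as printed.

    Two rows carry documented inconsistencies of the source table itself and
    are flagged (not corrected) by :func:`validate_stations`: station 48's
    PM10 range (150-200) does not bracket its mean (102.50), and station 15's
    printed PM2.5/PM10 ratio (0.42) disagrees with the ratio of its printed
    means (0.46).
    """
    ref = resources.files("pmsurface.data") / "sabzevar_stations.csv"
    with resources.as_file(ref) as p:
        return load_stations(p, format="csv")
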