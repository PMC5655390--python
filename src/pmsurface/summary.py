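"""Descriptive statistics of a monitoring network against air-quality
standards: sample-weighted means, exceedance fractions, and PM2.5/PM10
ratio statistics.

Exceedance is evaluated over *station means* (one value per site), which is
the resolution at which campaign summary tables report data.  For the
Sabzevar network this reading reproduces both published percentages at once:
36/48 = 75.00% of stations exceed the 35 ug/m3 24-h PM2.5 threshold
(strict >), and 43/48 = 89.58% comply with the 154 ug/m3 24-h PM10 threshold
(strict <).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import DomainError, ValidationError
from .station_data import StationSet

__all__ = [
    "AirQualityStandard", "builtin_standards",
    "weighted_mean", "exceedance_fraction", "ratio_summary",
]


@dataclass(frozen=True)
class AirQualityStandard:
    """A regulatory concentration threshold (above the threshold violates)."""

    label: str
    pollutant: str
    threshold: float  # ug/m3
    averaging: str

    def __post_init__(self):
        if not self.threshold > 0:
            raise DomainError("threshold must be positive")


def builtin_standards() -> dict[str, AirQualityStandard]:
    """The packaged registry of Iran DOE and US EPA PM thresholds."""
    ref = resources.files("pmsurface.data") / "standards.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return {key: AirQualityStandard(**spec) for key, spec in raw.items()}


def weighted_mean(stations: StationSet, pollutant: str) -> float:
    """Sample-count-weighted mean concentration, sum(mean_i * n_i) / sum(n_i)."""
    if len(stations) == 0:
        raise ValidationError("empty station set")
    n = np.array([r.n_samples for r in stations], dtype=float)
    z = stations.values(pollutant)
    return float((z * n).sum() / n.sum())


def exceedance_fraction(stations: StationSet, pollutant: str, threshold: float,
                        comparator: str = "greater") -> float:
    """Percentage of stations whose mean is strictly above (``greater``) or
    strictly below (``less``) the threshold, rounded to 2 decimals.

    The complements of the strict comparisons use >= / <=, so
    ``greater`` at t plus the >=-complement ("not greater", i.e. ``<= t``)
    always sum to 100.
    """
    if not threshold > 0:
        raise DomainError("threshold must be positive")
    z = stations.values(pollutant)
    if comparator == "greater":
        frac = np.mean(z > threshold)
    elif comparator == "less":
        frac = np.mean(z < threshold)
    elif comparator == "greater_equal":
        frac = np.mean(z >= threshold)
    elif comparator == "less_equal":
        frac = np.mean(z <= threshold)
    else:
        raise ValueError(f"unknown comparator {comparator!r}")
    return round(float(100.0 * frac), 2)


def ratio_summary(stations: StationSet) -> dict:
    """Min / max / mean of the recomputed PM2.5/PM10 ratio across stations.

    Ratios are recomputed from the station means (not read from the printed
    ratio column); min and max are reported rounded to 2 decimals together
    with the station ids attaining them.
    """
    pm25 = stations.values("pm25")
    pm10 = stations.values("pm10")
    if np.any(pm10 <= 0):
        raise DomainError("PM10 mean must be positive at every station")
    ratios = pm25 / pm10
    ids = stations.station_ids
    return {
        "min": round(float(ratios.min()), 2),
        "max": round(float(ratios.max()), 2),
        "mean": float(ratios.mean()),
        "argmin_station": int(ids[ratios.argmin()]),
        "argmax_station": int(ids[ratios.argmax()]),
    }
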