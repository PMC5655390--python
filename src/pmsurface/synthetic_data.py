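"""Synthetic monitoring networks drawn from Gaussian random fields.

The generator emulates the statistical structure the interpolators assume:
station locations scattered uniformly over a rectangular domain and values
drawn from a stationary Gaussian random field with a known variogram
(nugget + structured covariance), optionally superposed on a linear drift
``a0 + ax*x + ay*y``.  Because the true variogram and drift are known,
variogram-fitting recovery, kriging unbiasedness, and the OK-vs-UK contrast
under drift are all directly checkable.

Simulation is by dense covariance factorization — exact and entirely
adequate for networks up to a few thousand stations.  A positive
``value_floor`` keeps simulated concentrations strictly positive so the
Box-Cox pipeline applies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import pdist, squareform

from .errors import DomainError, ValidationError
from .geostat import VariogramModel, variogram_eval
from .station_data import StationRecord, StationSet

__all__ = ["SimulationConfig", "simulate_grf", "truth_surface"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth for a simulated network.

    ``variogram=None`` with a drift gives a purely deterministic field;
    ``drift=None`` gives a stationary field.  ``value_floor`` is added to all
    values and must keep them positive.
    """

    n_stations: int = 100
    bbox: tuple[float, float, float, float] = (0.0, 10000.0, 0.0, 10000.0)  # metres
    variogram: VariogramModel | None = None
    drift: tuple[float, float, float] | None = None  # (a0, ax, ay)
    value_floor: float = 50.0  # ug/m3 offset keeping concentrations positive
    seed: int = 0

    def __post_init__(self):
        if self.n_stations < 3:
            raise DomainError("n_stations must be >= 3")
        min_e, max_e, min_n, max_n = self.bbox
        if not (max_e > min_e and max_n > min_n):
            raise DomainError(f"degenerate bbox {self.bbox}")


def _drift_at(config: SimulationConfig, xy: np.ndarray) -> np.ndarray:
    if config.drift is None:
        return np.zeros(xy.shape[0])
    a0, ax, ay = config.drift
    return a0 + ax * xy[:, 0] + ay * xy[:, 1]


def _covariance(model: VariogramModel, xy: np.ndarray) -> np.ndarray:
    # C(h) = sill - gamma(h) for h > 0; C(0) = sill (nugget + partial sill)
    h = squareform(pdist(xy))
    cov = model.sill - variogram_eval(model, h)
    np.fill_diagonal(cov, model.sill)
    return cov


def simulate_grf(config: SimulationConfig) -> StationSet:
    """Draw one synthetic network; identical seeds give identical output.

    The random-field covariance is validity-checked (smallest eigenvalue
    >= -1e-8 * trace; hole-effect/J-Bessel variograms are not positive
    definite at every parameter combination in 2-D) and factorized by
    eigendecomposition, so marginally semi-definite models remain usable.
    """
    rng = np.random.default_rng(config.seed)
    min_e, max_e, min_n, max_n = config.bbox
    xy = np.empty((config.n_stations, 2))
    seen: set[tuple[float, float]] = set()
    filled = 0
    while filled < config.n_stations:
        cand = rng.uniform((min_e, min_n), (max_e, max_n))
        key = (cand[0], cand[1])
        if key in seen:  # duplicates are astronomically unlikely but rejected
            continue
        seen.add(key)
        xy[filled] = cand
        filled += 1

    values = np.full(config.n_stations, float(config.value_floor))
    values += _drift_at(config, xy)
    if config.variogram is not None:
        cov = _covariance(config.variogram, xy)
        eigvals, eigvecs = linalg.eigh(cov)
        if eigvals[0] < -1e-8 * np.trace(cov):
            raise ValidationError(
                f"variogram {config.variogram.kind} with these parameters is not a "
                f"valid 2-D covariance (min eigenvalue {eigvals[0]:.3e})")
        factor = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
        values += factor @ rng.standard_normal(config.n_stations)

    if np.any(values <= 0):
        raise ValidationError(
            "simulated values are not all positive; raise value_floor "
            f"(min simulated value {values.min():.3f})")

    records = tuple(
        StationRecord(
            station_id=i + 1, name=f"synthetic-{i + 1}",
            easting=float(xy[i, 0]), northing=float(xy[i, 1]),
            n_samples=1, fabric="Synthetic",
            pm25_mean=float(values[i]), pm25_se=0.0,
            pm25_min=float(values[i]), pm25_max=float(values[i]),
            pm10_mean=float(values[i]), pm10_se=0.0,
            pm10_min=float(values[i]), pm10_max=float(values[i]),
            ratio=1.0,
        )
        for i in range(config.n_stations)
    )
    return StationSet(records, crs_label="synthetic planar metres")


def truth_surface(config: SimulationConfig, targets) -> np.ndarray:
    """Deterministic truth at ``targets`` for drift-only configurations.

    Only defined when the field has no stochastic component (``variogram``
    unset): the truth is then ``value_floor + drift`` exactly, which lets
    tests check exact recovery of a noiseless plane.
    """
    if config.variogram is not None:
        raise ValidationError(
            "truth_surface is defined only for drift-only (noiseless) configs")
    targets = np.atleast_2d(np.asarray(targets, float))
    return config.value_floor + _drift_at(config, targets)
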