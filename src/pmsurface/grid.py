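"""Regular prediction rasters and ESRI ASCII grid I/O.

A :class:`PredictionGrid` is a lower-left-corner-referenced regular raster of
cell-center concentration predictions, matching the ESRI ASCII grid
convention (rows written north-to-south) so surfaces interchange cleanly
with GIS tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DomainError, ValidationError
from .evaluation import MethodSpec, _fold_predictor
from .station_data import StationSet
from .transform import TransformSpec

__all__ = ["PredictionGrid", "make_grid", "predict_surface",
           "write_ascii_grid", "read_ascii_grid"]

#: Default cell size (metres) and bounding-box padding for city-scale maps.
DEFAULT_CELL_SIZE = 100.0
DEFAULT_PADDING = 500.0


@dataclass(frozen=True)
class PredictionGrid:
    """A regular raster of predictions over a bounding box.

    ``values`` is a (n_rows, n_cols) array in *map orientation* (row 0 is the
    northernmost row) or ``None`` for an empty grid awaiting prediction.
    """

    origin: tuple[float, float]  # (easting, northing) of the lower-left corner
    cell_size: float
    n_cols: int
    n_rows: int
    values: np.ndarray | None = None
    nodata: float = -9999.0

    def __post_init__(self):
        if not self.cell_size > 0:
            raise DomainError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise DomainError("grid must have at least one row and column")
        if self.values is not None and self.values.shape != (self.n_rows, self.n_cols):
            raise ValidationError(
                f"values shape {self.values.shape} != ({self.n_rows}, {self.n_cols})")

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) cell-center coordinates, row-major from the
        northernmost row (matching the ``values`` layout)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows)[::-1] + 0.5) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, points) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        x0, y0 = self.origin
        x1 = x0 + self.n_cols * self.cell_size
        y1 = y0 + self.n_rows * self.cell_size
        return ((points[:, 0] >= x0) & (points[:, 0] <= x1)
                & (points[:, 1] >= y0) & (points[:, 1] <= y1))


def make_grid(bbox: tuple[float, float, float, float],
              cell_size: float = DEFAULT_CELL_SIZE) -> PredictionGrid:
    """Empty grid covering ``bbox`` = (min_e, max_e, min_n, max_n).

    Column/row counts are ``ceil(extent / cell_size)`` so the grid always
    covers the box fully.
    """
    min_e, max_e, min_n, max_n = bbox
    if not (max_e > min_e and max_n > min_n):
        raise DomainError(f"degenerate or inverted bbox {bbox}")
    if not cell_size > 0:
        raise DomainError("cell_size must be positive")
    n_cols = math.ceil((max_e - min_e) / cell_size)
    n_rows = math.ceil((max_n - min_n) / cell_size)
    return PredictionGrid(origin=(min_e, min_n), cell_size=cell_size,
                          n_cols=n_cols, n_rows=n_rows)


def station_grid(stations: StationSet, cell_size: float = DEFAULT_CELL_SIZE,
                 padding: float = DEFAULT_PADDING) -> PredictionGrid:
    """Grid over the station bounding box padded by ``padding`` metres."""
    min_e, max_e, min_n, max_n = stations.bbox()
    return make_grid((min_e - padding, max_e + padding,
                      min_n - padding, max_n + padding), cell_size)


def predict_surface(stations: StationSet, pollutant: str, method: MethodSpec,
                    transform: TransformSpec, grid: PredictionGrid) -> PredictionGrid:
    """Fill ``grid`` with back-transformed predictions at every cell center.

    The interpolator is fitted once on all stations (Box-Cox scale) and
    evaluated at the cell centers; deterministic given its inputs.
    """
    locations, observed = stations.pollutant_data(pollutant)
    t_obs = transform.forward(observed)
    predictor = _fold_predictor(method, locations, t_obs)
    centers = grid.cell_centers()
    # _fold_predictor returns scalars; evaluate in one vectorized pass instead
    # for the common method types, falling back to per-cell calls.
    from .geostat import (KrigingConfig, empirical_semivariogram, fit_variogram,
                          kriging_predict)
    from .interp_deterministic import IDWConfig, RBFKernel, idw_predict, rbf_fit, rbf_predict
    from .evaluation import KrigingSpec

    if isinstance(method, IDWConfig):
        t_pred = idw_predict(locations, t_obs, centers, method)
    elif isinstance(method, RBFKernel):
        t_pred = rbf_predict(rbf_fit(locations, t_obs, method), centers)
    elif isinstance(method, KrigingSpec):
        emp = empirical_semivariogram(locations, t_obs, n_lags=method.n_lags)
        model = fit_variogram(emp, method.kind)
        cfg = KrigingConfig(variogram=model, mode=method.mode,
                            drift_order=method.drift_order)
        t_pred, _ = kriging_predict(locations, t_obs, centers, cfg)
    else:
        t_pred = np.array([predictor(locations, t_obs, c[None, :]) for c in centers])
    values = transform.inverse(t_pred).reshape(grid.n_rows, grid.n_cols)
    return replace(grid, values=values)


def write_ascii_grid(grid: PredictionGrid, path: str | Path) -> None:
    """Write a filled grid as an ESRI ASCII raster (6 header lines + rows
    north-to-south); nodata cells serialize as the sentinel token."""
    if grid.values is None:
        raise ValidationError("cannot write an unfilled grid")
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> PredictionGrid:
    """Round-trip reader for :func:`write_ascii_grid`."""
    with open(path, encoding="utf-8") as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    grid = PredictionGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]), n_rows=int(header["nrows"]),
        values=values, nodata=header["nodata_value"],
    )
    return grid
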