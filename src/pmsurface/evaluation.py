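"""Leave-one-out cross-validation of interpolators and the four error
statistics used to rank them.

Every interpolator is scored the same way: for each station i the method is
fitted (on the Box-Cox scale) to the other N-1 stations, predicts at s_i, the
prediction is back-transformed, and the paired (predicted I_i, observed O_i)
series is summarised by

    MAPE = 100/N * sum |(I_i - O_i) / O_i|        (percent)
    RMSE = sqrt( sum (I_i - O_i)^2 / N )
    MBE  = sum (I_i - O_i) / N
    MAE  = sum |I_i - O_i| / N

Metrics are reported on the concentration scale (primary, used for ranking)
and on the transformed scale.  For kriging methods the variogram is fitted
once on the full transformed dataset and reused across folds, mirroring
standard GIS cross-validation behaviour; per-fold refitting is available via
``KrigingSpec(refit_per_fold=True)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import DomainError, PMSurfaceError, ValidationError
from .geostat import (KrigingConfig, VariogramModel, empirical_semivariogram,
                      fit_variogram, kriging_predict)
from .interp_deterministic import IDWConfig, RBFKernel, rbf_fit, rbf_predict, idw_predict
from .station_data import StationSet
from .transform import TransformSpec

__all__ = [
    "KrigingSpec", "MethodSpec", "CVResult",
    "method_label", "method_family", "loocv", "metrics", "compare_models",
    "default_model_grid", "METRIC_NAMES",
]

METRIC_NAMES = ("mape", "rmse", "mbe", "mae")


@dataclass(frozen=True)
class KrigingSpec:
    """Kriging method spec for cross-validation: variogram model kind plus
    OK/UK mode.  The variogram itself is estimated from the data."""

    kind: str = "gaussian"
    mode: str = "ordinary"
    drift_order: int = 1
    n_lags: int = 12
    refit_per_fold: bool = False


MethodSpec = Union[IDWConfig, RBFKernel, KrigingSpec]


def method_label(method: MethodSpec) -> str:
    if isinstance(method, IDWConfig):
        p = method.power
        return f"IDW power {int(p) if float(p).is_integer() else p}"
    if isinstance(method, RBFKernel):
        return f"RBF {method.kind.replace('_', ' ')}"
    if isinstance(method, KrigingSpec):
        tag = "OK" if method.mode == "ordinary" else "UK"
        return f"{tag} {method.kind.replace('_', ' ')}"
    raise TypeError(f"unknown method spec {method!r}")


def method_family(method: MethodSpec) -> str:
    if isinstance(method, (IDWConfig, RBFKernel)):
        return "deterministic"
    if isinstance(method, KrigingSpec):
        return "geostatistics"
    raise TypeError(f"unknown method spec {method!r}")


@dataclass(frozen=True)
class CVResult:
    """Paired observed/predicted series from leave-one-out cross-validation.

    ``observed``/``predicted`` are on the concentration scale;
    ``transformed_observed``/``transformed_predicted`` on the Box-Cox scale.
    """

    station_ids: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    method_label: str
    transformed_observed: np.ndarray | None = None
    transformed_predicted: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.station_ids)
        if len(self.observed) != n or len(self.predicted) != n:
            raise ValidationError("observed/predicted/station_ids lengths differ")
        if len(np.unique(self.station_ids)) != n:
            raise ValidationError("every station must be predicted exactly once")

    def sorted_by_id(self) -> "CVResult":
        order = np.argsort(self.station_ids)
        pick = lambda a: None if a is None else np.asarray(a)[order]
        return CVResult(np.asarray(self.station_ids)[order], pick(self.observed),
                        pick(self.predicted), self.method_label,
                        pick(self.transformed_observed), pick(self.transformed_predicted))


def _fold_predictor(method: MethodSpec, full_locations, full_values):
    """Return f(train_locs, train_vals, target) -> scalar prediction.

    For kriging specs without per-fold refitting the variogram is fitted here,
    once, on the full transformed dataset.
    """
    if isinstance(method, IDWConfig):
        return lambda L, z, t: idw_predict(L, z, t, method)[0]
    if isinstance(method, RBFKernel):
        return lambda L, z, t: rbf_predict(rbf_fit(L, z, method), t)[0]
    if isinstance(method, KrigingSpec):
        shared_model: VariogramModel | None = None
        if not method.refit_per_fold:
            emp = empirical_semivariogram(full_locations, full_values, n_lags=method.n_lags)
            shared_model = fit_variogram(emp, method.kind)

        def predict(L, z, t):
            model = shared_model
            if model is None:
                model = fit_variogram(
                    empirical_semivariogram(L, z, n_lags=method.n_lags), method.kind)
            cfg = KrigingConfig(variogram=model, mode=method.mode,
                                drift_order=method.drift_order)
            return kriging_predict(L, z, t, cfg)[0][0]

        return predict
    raise TypeError(f"unknown method spec {method!r}")


def loocv(stations: StationSet, pollutant: str, method: MethodSpec,
          transform: TransformSpec) -> CVResult:
    """Leave-one-out cross-validation of ``method`` on one pollutant.

    Fitting happens on the Box-Cox scale; predictions are back-transformed to
    concentrations.  Deterministic given its inputs.
    """
    if len(stations) < 3:
        raise ValidationError("LOOCV requires at least 3 stations")
    locations, observed = stations.pollutant_data(pollutant)
    t_obs = transform.forward(observed)
    predictor = _fold_predictor(method, locations, t_obs)
    n = len(observed)
    t_pred = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            t_pred[i] = predictor(locations[mask], t_obs[mask], locations[i:i + 1])
        except PMSurfaceError as exc:
            raise type(exc)(
                f"{method_label(method)} failed on fold for station "
                f"{stations.records[i].station_id}: {exc}") from exc
    return CVResult(
        station_ids=stations.station_ids,
        observed=observed,
        predicted=transform.inverse(t_pred),
        transformed_observed=t_obs,
        transformed_predicted=t_pred,
        method_label=method_label(method),
    )


def metrics(cv: CVResult, scale: str = "concentration") -> dict[str, float]:
    """MAPE/RMSE/MBE/MAE for one CV run, on the requested scale."""
    if scale == "concentration":
        obs, pred = np.asarray(cv.observed), np.asarray(cv.predicted)
    elif scale == "transformed":
        if cv.transformed_observed is None or cv.transformed_predicted is None:
            raise ValidationError("CVResult carries no transformed-scale pairs")
        obs = np.asarray(cv.transformed_observed)
        pred = np.asarray(cv.transformed_predicted)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    zero = np.flatnonzero(obs == 0)
    if zero.size:
        raise DomainError(
            f"MAPE undefined: observed value is 0 at station {cv.station_ids[zero[0]]}")
    err = pred - obs
    return {
        "mape": float(100.0 * np.mean(np.abs(err / obs))),
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "mbe": float(np.mean(err)),
        "mae": float(np.mean(np.abs(err))),
    }


def default_model_grid() -> list[MethodSpec]:
    """The 11-method comparison grid: RBF (completely regularized spline),
    IDW powers 1 and 2, and OK/UK under each of the four variogram models."""
    grid: list[MethodSpec] = [
        RBFKernel("completely_regularized_spline"),
        IDWConfig(power=1.0),
        IDWConfig(power=2.0),
    ]
    for mode in ("ordinary", "universal"):
        for kind in ("stable", "hole_effect", "j_bessel", "gaussian"):
            grid.append(KrigingSpec(kind=kind, mode=mode))
    return grid


def compare_models(stations: StationSet, pollutant: str,
                   model_grid: Sequence[MethodSpec],
                   transform: TransformSpec) -> pd.DataFrame:
    """LOOCV every method in ``model_grid``; one row per method per scale.

    Columns: pollutant, family, function, scale, mape, rmse, mbe, mae and
    ``rank_mape`` (ranking by concentration-scale MAPE, 1 = best).
    """
    rows = []
    for method in model_grid:
        cv = loocv(stations, pollutant, method, transform)
        for scale in ("concentration", "transformed"):
            rows.append({
                "pollutant": pollutant,
                "family": method_family(method),
                "function": method_label(method),
                "scale": scale,
                **metrics(cv, scale),
            })
    table = pd.DataFrame(rows)
    conc = table[table["scale"] == "concentration"]
    ranks = conc["mape"].rank(method="min").astype(int)
    table["rank_mape"] = table["function"].map(dict(zip(conc["function"], ranks)))
    return table
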