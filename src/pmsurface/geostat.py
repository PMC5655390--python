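"""Geostatistical interpolation: semivariograms and ordinary/universal kriging.

The empirical semivariogram is the Matheron estimator

    gamma_hat(h) = 1/(2 N(h)) * sum_{|s_i - s_j| in bin(h)} (z_i - z_j)**2,

to which one of four parametric models is fitted by weighted least squares:
``gaussian``, ``stable`` (power exponent omega in (0, 2]), ``hole_effect``
(damped sine) and ``j_bessel`` (J0).  The gaussian/stable models use the
practical-range convention (factor 3 in the exponent), matching common GIS
software.

Ordinary kriging (OK) predicts a weighted sum of the data with weights
solving the variogram system under the unbiasedness constraint
``sum(lambda) = 1``; universal kriging (UK) augments the system with a
low-order polynomial drift basis (order 0: constant — identical to OK;
order 1: {1, x, y}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg, optimize, special
from scipy.spatial.distance import cdist, pdist, squareform

from .errors import DomainError, FitError, SingularSystemError, ValidationError

__all__ = [
    "EmpiricalVariogram", "VariogramModel", "KrigingConfig", "VARIOGRAM_KINDS",
    "empirical_semivariogram", "variogram_eval", "fit_variogram", "kriging_predict",
]

VARIOGRAM_KINDS = ("stable", "hole_effect", "j_bessel", "gaussian")


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned Matheron semivariance estimates with pair counts per lag."""

    lag_centers: np.ndarray
    semivariances: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self):
        lc = np.asarray(self.lag_centers, float)
        if lc.size and np.any(np.diff(lc) <= 0):
            raise ValidationError("lag centers must be strictly increasing")
        if np.any(np.asarray(self.semivariances) < 0):
            raise ValidationError("semivariances must be nonnegative")
        if np.any(np.asarray(self.pair_counts) < 1):
            raise ValidationError("retained bins must contain at least one pair")


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariance gamma(h): nugget + partial sill + range (+ shape).

    ``shape`` is the stable model's exponent omega in (0, 2] and is ignored by
    the other kinds.  gamma(0) is defined as 0; the nugget appears only in the
    limit h -> 0+.
    """

    kind: Literal[VARIOGRAM_KINDS]
    nugget: float
    partial_sill: float
    range_: float
    shape: float = 1.5

    def __post_init__(self):
        if self.kind not in VARIOGRAM_KINDS:
            raise DomainError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or not self.partial_sill > 0 or not self.range_ > 0:
            raise DomainError("require nugget >= 0, partial_sill > 0, range > 0")
        if self.kind == "stable" and not (0 < self.shape <= 2):
            raise DomainError("stable exponent must lie in (0, 2]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill


def variogram_eval(model: VariogramModel, h) -> np.ndarray:
    """Evaluate gamma(h) elementwise; gamma(0) = 0 exactly."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise DomainError("lag distances must be nonnegative")
    c0, c, a = model.nugget, model.partial_sill, model.range_
    if model.kind == "gaussian":
        g = 1.0 - np.exp(-3.0 * (h / a) ** 2)
    elif model.kind == "stable":
        g = 1.0 - np.exp(-3.0 * (h / a) ** model.shape)
    elif model.kind == "hole_effect":
        x = 2.0 * np.pi * h / a
        with np.errstate(invalid="ignore", divide="ignore"):
            g = 1.0 - np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
    else:  # j_bessel
        g = 1.0 - special.j0(2.0 * np.pi * h / a)
    out = c0 + c * g
    return np.where(h == 0, 0.0, out)


def empirical_semivariogram(locations, values, n_lags: int = 12,
                            max_dist: float | None = None) -> EmpiricalVariogram:
    """Matheron estimator on uniform-width lag bins; empty bins are dropped.

    ``max_dist`` defaults to half the maximum pairwise distance.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    if locations.shape[0] < 2:
        raise ValidationError("semivariogram needs at least 2 stations")
    d = pdist(locations)
    if max_dist is None:
        max_dist = 0.5 * d.max()
    if not max_dist > 0:
        raise DomainError("max_dist must be positive")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    keep = d <= max_dist
    if not keep.any():
        raise ValidationError("all station pairs lie beyond max_dist")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    which = np.clip(np.digitize(d[keep], edges) - 1, 0, n_lags - 1)
    centers, gammas, counts = [], [], []
    dk, sk = d[keep], sq[keep]
    for b in range(n_lags):
        m = which == b
        if not m.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(sk[m].mean())
        counts.append(int(m.sum()))
    return EmpiricalVariogram(np.array(centers), np.array(gammas), np.array(counts))


def fit_variogram(emp: EmpiricalVariogram, kind: str) -> VariogramModel:
    """Weighted least squares fit of a parametric model to ``emp``.

    Residuals are weighted by sqrt(N(h)) so the objective is
    sum N(h) * (gamma_hat - gamma)^2; parameters are bound-constrained
    (nugget >= 0, partial sill > 0, range > 0, stable exponent in (0, 2]).
    """
    h = np.asarray(emp.lag_centers, float)
    g = np.asarray(emp.semivariances, float)
    w = np.sqrt(np.asarray(emp.pair_counts, float))
    if h.size < 3:
        raise ValidationError("variogram fitting needs at least 3 lag bins")

    has_shape = kind == "stable"
    sill0 = max(g.max(), 1e-12)
    x0 = [min(g[0], 0.5 * sill0), max(sill0 - min(g[0], 0.5 * sill0), 1e-10), h.max()]
    lo = [0.0, 1e-12, 1e-12 * max(h.max(), 1.0)]
    hi = [2.0 * sill0 + 1e-12, 10.0 * sill0, 100.0 * h.max()]
    if has_shape:
        x0.append(1.5); lo.append(1e-3); hi.append(2.0)
    # keep the start strictly inside the box (degenerate, e.g. constant, data
    # can otherwise push it out)
    x0 = np.clip(x0, np.asarray(lo) + 1e-15, np.asarray(hi) - 1e-15)

    def residuals(p):
        model = VariogramModel(kind, nugget=p[0], partial_sill=p[1], range_=p[2],
                               shape=p[3] if has_shape else 1.5)
        return w * (variogram_eval(model, h) - g)

    res = optimize.least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    best = VariogramModel(kind, nugget=float(res.x[0]), partial_sill=float(res.x[1]),
                          range_=float(res.x[2]),
                          shape=float(res.x[3]) if has_shape else 1.5)
    if not res.success:
        raise FitError(f"variogram fit for kind={kind!r} did not converge: {res.message}",
                       best_so_far=best, diagnostics={"cost": res.cost, "status": res.status})
    return best


@dataclass(frozen=True)
class KrigingConfig:
    """Kriging mode (ordinary or universal), drift order, and variogram."""

    variogram: VariogramModel
    mode: Literal["ordinary", "universal"] = "ordinary"
    drift_order: int = 1  # universal only; 0 reproduces ordinary kriging

    def __post_init__(self):
        if self.mode not in ("ordinary", "universal"):
            raise DomainError(f"unknown kriging mode {self.mode!r}")
        if self.drift_order not in (0, 1):
            raise DomainError("drift_order must be 0 or 1")


def _drift_basis(xy: np.ndarray, order: int, mean: np.ndarray, scale: float) -> np.ndarray:
    cols = [np.ones(xy.shape[0])]
    if order >= 1:
        std = (xy - mean) / scale  # centring keeps the system well-conditioned
        cols += [std[:, 0], std[:, 1]]
    return np.column_stack(cols)


def kriging_predict(locations, values, targets,
                    config: KrigingConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary/universal kriging predictions and kriging variances.

    Solves, per target s0, the augmented system

        [Gamma, F; F^T, 0] [lambda; m] = [gamma(., s0); f(s0)]

    where ``F`` is the unbiasedness/drift basis (a single constant column for
    OK, {1, x, y} for UK with first-order drift).  With zero nugget the
    prediction at a data site reproduces the observation exactly.  On a
    singular matrix one jitter retry (1e-10 * trace on the diagonal) is
    attempted with a warning before raising.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = locations.shape[0]
    if n < 3:
        raise ValidationError("kriging requires at least 3 stations")
    model = config.variogram
    order = config.drift_order if config.mode == "universal" else 0
    mean = locations.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((locations - mean) ** 2, axis=1)))) or 1.0

    gamma_dd = variogram_eval(model, squareform(pdist(locations)))
    f = _drift_basis(locations, order, mean, scale)
    p = f.shape[1]
    a = np.zeros((n + p, n + p))
    a[:n, :n] = gamma_dd
    a[:n, n:] = f
    a[n:, :n] = f.T

    d_dt = cdist(locations, targets)
    # target side uses the h -> 0+ limit (the nugget) for coincident pairs:
    # with a nugget the field is noisy at microscale and kriging filters it,
    # so a data-site prediction need not reproduce the observation; with
    # nugget = 0 exact interpolation is recovered
    gamma_dt = np.where(d_dt == 0.0, model.nugget, variogram_eval(model, d_dt))
    ft = _drift_basis(targets, order, mean, scale)
    rhs = np.vstack([gamma_dt, ft.T])

    try:
        sol = linalg.solve(a, rhs)
    except linalg.LinAlgError:
        warnings.warn("singular kriging matrix; retrying with diagonal jitter",
                      RuntimeWarning, stacklevel=2)
        a_j = a + 1e-10 * np.trace(a[:n, :n]) / max(n, 1) * np.eye(n + p)
        try:
            sol = linalg.solve(a_j, rhs)
        except linalg.LinAlgError as exc:
            raise SingularSystemError(
                "kriging system singular even after jitter; check for "
                "near-duplicate stations or a degenerate drift basis"
            ) from exc
    lam = sol[:n, :]
    preds = lam.T @ values
    # kriging variance: lambda^T gamma0 + mu^T f0
    var = np.einsum("ij,ij->j", sol, rhs)
    var = np.where(var < 0, np.where(var > -1e-8 * max(model.sill, 1.0), 0.0, var), var)
    if np.any(var < 0):
        warnings.warn("negative kriging variance encountered; check variogram validity",
                      RuntimeWarning, stacklevel=2)
    return preds, var
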