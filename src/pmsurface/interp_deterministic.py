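"""Deterministic exact interpolators: inverse-distance weighting and radial
basis functions.

IDW predicts a weighted mean of the observed values with weights ``1/d**p``,
so its predictions always stay inside the observed data range and it returns
the station value exactly at zero distance.

The RBF family interpolates with a weighted sum of radially symmetric basis
functions plus a constant bias,

    Zhat(s0) = sum_i w_i * phi(|s_i - s0|) + w_{n+1},

with the weights solved from the augmented linear system that forces the
surface through every observation.  Five kernels are provided: thin-plate
spline, multiquadric, inverse multiquadric, completely regularized spline,
and spline with tension.  Unlike IDW, an RBF surface may overshoot the
observed minimum/maximum between stations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg, special
from scipy.spatial.distance import cdist

from .errors import DomainError, SingularSystemError, ValidationError

__all__ = [
    "IDWConfig", "idw_predict",
    "RBFKernel", "RBFModel", "RBF_KINDS", "rbf_kernel_eval", "rbf_fit", "rbf_predict",
    "EULER_GAMMA",
]

#: Euler-Mascheroni constant as used in the spline kernels.
EULER_GAMMA = 0.577215

RBF_KINDS = (
    "thin_plate",
    "multiquadric",
    "inverse_multiquadric",
    "completely_regularized_spline",
    "tension_spline",
)


# ---------------------------------------------------------------------------
# Inverse-distance weighting


@dataclass(frozen=True)
class IDWConfig:
    """IDW settings: distance power ``p`` and the search neighbourhood.

    ``n_neighbors=None`` means the global neighbourhood (all stations), which
    is the default for networks of a few dozen sites.
    """

    power: float = 1.0
    n_neighbors: int | None = None

    def __post_init__(self):
        if not self.power > 0:
            raise DomainError(f"IDW power must be positive, got {self.power}")
        if self.n_neighbors is not None and self.n_neighbors < 1:
            raise DomainError("n_neighbors must be >= 1")


def idw_predict(locations, values, targets, config: IDWConfig = IDWConfig()) -> np.ndarray:
    """Inverse-distance-weighted prediction at ``targets``.

    A target coinciding with a station returns that station's value exactly.
    Predictions are convex combinations of the data, hence bounded by the
    observed min/max.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if locations.shape[0] == 0:
        raise ValidationError("IDW requires at least one station")
    d = cdist(targets, locations)
    k = config.n_neighbors
    if k is not None:
        k = min(k, locations.shape[0])
        # mask all but the k nearest stations per target
        idx = np.argpartition(d, k - 1, axis=1)[:, k:]
        mask = np.zeros_like(d, dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        d = np.where(mask, np.inf, d)
    out = np.empty(targets.shape[0])
    for j in range(targets.shape[0]):
        dj = d[j]
        hit = np.flatnonzero(dj == 0.0)
        if hit.size:
            out[j] = values[hit[0]]
            continue
        w = dj ** -config.power  # inf distances (masked) get weight 0
        w[~np.isfinite(dj)] = 0.0
        sw = w.sum()
        if sw == 0:
            raise ValidationError(f"empty IDW neighbourhood for target {j}")
        out[j] = (w @ values) / sw
    return out


# ---------------------------------------------------------------------------
# Radial basis functions


@dataclass(frozen=True)
class RBFKernel:
    """A radial kernel ``phi(r)`` with shape/tension parameter ``sigma``.

    ``sigma`` acts on distances measured in internally standardized
    coordinates (see :func:`rbf_fit`), so it is scale-free with respect to the
    CRS units.  ``sigma=None`` asks :func:`rbf_fit` to select it by
    leave-one-out cross-validation (Rippa's closed form), mirroring how GIS
    packages tune the RBF parameter; a fixed value pins the kernel exactly.
    """

    kind: Literal[RBF_KINDS]
    sigma: float | None = None

    def __post_init__(self):
        if self.kind not in RBF_KINDS:
            raise DomainError(f"unknown RBF kernel {self.kind!r}; options: {RBF_KINDS}")
        if self.sigma is not None and not self.sigma > 0:
            raise DomainError(f"sigma must be positive, got {self.sigma}")


def rbf_kernel_eval(kernel: RBFKernel, r) -> np.ndarray:
    """Evaluate the radial basis ``phi(r)`` elementwise for ``r >= 0``.

    The two spline kernels built from E1 (exponential integral) and K0
    (modified Bessel) have removable singularities at r = 0; the analytic
    limit phi(0) = 0 is applied there, as for the thin-plate spline.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise DomainError("kernel distances must be nonnegative")
    if kernel.sigma is None:
        raise DomainError("kernel sigma is unset; fit first or give an explicit sigma")
    s = kernel.sigma
    kind = kernel.kind
    if kind == "multiquadric":
        return np.sqrt(r * r + s * s)
    if kind == "inverse_multiquadric":
        return 1.0 / np.sqrt(r * r + s * s)
    pos = r > 0
    out = np.zeros_like(r)
    rp = r[pos]
    if kind == "thin_plate":
        x = s * rp
        out[pos] = x * x * np.log(x)
    elif kind == "completely_regularized_spline":
        u = (s * rp / 2.0) ** 2
        out[pos] = np.log(u) + special.exp1(u) + EULER_GAMMA
    elif kind == "tension_spline":
        x = s * rp
        out[pos] = np.log(x / 2.0) + special.k0(x) + EULER_GAMMA
    return out


@dataclass(frozen=True)
class RBFModel:
    """A fitted RBF interpolant (kernel, centers, solved weights and bias).

    ``center_mean``/``center_scale`` record the internal isotropic coordinate
    standardization applied before kernel evaluation; predictions are
    expressed in the original coordinates and are invariant to it.
    """

    kernel: RBFKernel
    centers: np.ndarray        # (n, 2), original coordinates
    weights: np.ndarray        # (n,)
    bias: float
    center_mean: np.ndarray    # (2,)
    center_scale: float

    def _standardize(self, xy: np.ndarray) -> np.ndarray:
        return (xy - self.center_mean) / self.center_scale


def _standardization(locations: np.ndarray) -> tuple[np.ndarray, float]:
    mean = locations.mean(axis=0)
    # isotropic scale: RMS distance from the centroid (preserves radiality)
    rms = np.sqrt(np.mean(np.sum((locations - mean) ** 2, axis=1)))
    return mean, (rms if rms > 0 else 1.0)


#: Candidate sigmas (standardized-coordinate units) for automatic selection.
SIGMA_GRID = np.logspace(-2, 1.5, 15)


def _assemble(kernel: RBFKernel, d: np.ndarray, values: np.ndarray):
    n = d.shape[0]
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = rbf_kernel_eval(kernel, d)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    return a, np.concatenate([values, [0.0]])


def _select_sigma(kind: str, d: np.ndarray, values: np.ndarray) -> float:
    """Pick sigma minimizing the leave-one-out RMSE via Rippa's closed form.

    For the interpolation system A c = z the LOO prediction error at site i is
    c_i / (A^-1)_ii, so the whole LOO curve costs one inverse per candidate.
    """
    best_sigma, best_score = None, np.inf
    for sigma in SIGMA_GRID:
        a, b = _assemble(RBFKernel(kind, sigma), d, values)
        try:
            inv = linalg.inv(a)
        except linalg.LinAlgError:
            continue
        diag = np.diag(inv)[: len(values)]
        if np.any(np.abs(diag) < 1e-300):
            continue
        loo = (inv @ b)[: len(values)] / diag
        score = float(np.sqrt(np.mean(loo ** 2)))
        if np.isfinite(score) and score < best_score:
            best_sigma, best_score = float(sigma), score
    if best_sigma is None:
        raise SingularSystemError(
            f"no usable sigma found for kernel {kind!r}; give one explicitly")
    return best_sigma


def rbf_fit(locations, values, kernel: RBFKernel) -> RBFModel:
    """Solve the augmented RBF system ``[Phi, 1; 1^T, 0] [w; b] = [z; 0]``.

    Coordinates are standardized (zero centroid, unit RMS radius) before the
    kernel is evaluated so that sigma is scale-free and the E1/K0 kernels stay
    in a well-conditioned argument range regardless of the CRS units.  With
    ``kernel.sigma=None`` the shape parameter is first selected by
    leave-one-out cross-validation on the training data.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    n = locations.shape[0]
    if n < 2:
        raise ValidationError("RBF fit requires at least 2 stations")
    mean, scale = _standardization(locations)
    std = (locations - mean) / scale
    d = cdist(std, std)
    if np.any(d[~np.eye(n, dtype=bool)] == 0.0):
        i, j = np.argwhere((d == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValidationError(f"duplicate centers at rows {i} and {j}")
    if kernel.sigma is None:
        kernel = RBFKernel(kernel.kind, _select_sigma(kernel.kind, d, values))
    a, b = _assemble(kernel, d, values)
    try:
        lu = linalg.lu_factor(a)
        sol = linalg.lu_solve(lu, b)
        # a few steps of iterative refinement: spline systems are often
        # ill-conditioned and plain LU leaves residuals above the exactness bar
        for _ in range(3):
            r = b - a @ sol
            if np.linalg.norm(r) <= 1e-10 * max(1.0, np.linalg.norm(b)):
                break
            sol = sol + linalg.lu_solve(lu, r)
    except linalg.LinAlgError as exc:
        raise SingularSystemError(
            f"singular RBF system for kernel {kernel.kind} (sigma={kernel.sigma}); "
            "try a different sigma"
        ) from exc
    # the meaningful exactness check: the surface must reproduce the training
    # values (spline weights may legitimately be huge and mutually cancelling,
    # so a raw residual-norm bound would reject valid ill-conditioned solves)
    err = np.max(np.abs(a[:n, :] @ sol - values))
    if not err <= 1e-6 * max(1.0, np.max(np.abs(values))):
        raise SingularSystemError(
            f"RBF surface fails to interpolate the data (max error {err:.3e}); "
            f"adjust sigma (currently {kernel.sigma})"
        )
    return RBFModel(kernel=kernel, centers=locations, weights=sol[:n], bias=float(sol[n]),
                    center_mean=mean, center_scale=scale)


def rbf_predict(model: RBFModel, targets) -> np.ndarray:
    """Evaluate the fitted RBF surface at ``targets``."""
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    d = cdist(model._standardize(targets), model._standardize(model.centers))
    return rbf_kernel_eval(model.kernel, d) @ model.weights + model.bias
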