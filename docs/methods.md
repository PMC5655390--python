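# Methods

This note documents the statistical models implemented in `pmsurface`, the
parameter choices that matter, and what the synthetic-data tests do and do
not establish.

## Data model

A monitoring network is a table of stations with planar metric coordinates
(UTM metres; all distances are Euclidean — no geodesic computation) and
per-pollutant summaries of a sampling campaign: mean, standard error,
observed min–max, and the per-station sample count. The packaged Sabzevar
network has 48 stations whose per-station counts sum to 246 samples over a
9-month campaign.

Loading is strict about structural invariants (unique ids, pairwise-distinct
coordinates, positive sample counts) but deliberately lenient about
data-quality issues inside a row: source tables are loaded verbatim and
`validate_stations` *flags* inconsistencies instead of rejecting them. The
packaged table carries two such flags, preserved as printed: station 48's
PM10 mean (102.50) sits outside its own printed range (150–200), and station
15's printed PM2.5/PM10 ratio (0.42) disagrees with the ratio of its printed
means (107.69/234.62 → 0.46). No silent corrections are applied.

## Box-Cox normalization

Station-mean concentrations are strongly right-skewed. Every interpolator is
therefore fitted on the transformed scale `y = (x^λ − 1)/λ` (`ln x` at
λ = 0) and predictions are back-transformed before concentration-scale
scoring. The powers are fixed per pollutant — λ = 0.6 (PM2.5) and λ = 0.1
(PM10) — rather than re-estimated; a maximum-likelihood estimator
(`estimate_lambda`) is provided for other datasets but is not used on the
reproduction path. The forward/inverse pair is exact to ~1e-10 relative
error for the powers in practical use; strongly negative powers with large
arguments make the inverse ill-conditioned in float64 (1 + λy approaches an
underflowing x^λ), which is a property of the arithmetic, not the code.

An RBF or kriging fold prediction can in principle leave the domain of the
inverse transform (1 + λy ≤ 0); this raises a domain error rather than being
clipped, because a silent clip would bias the error statistics.

## Interpolators

**IDW.** Prediction is the 1/dᵖ-weighted mean of the data; an exact
coordinate hit returns that station's value. Predictions are convex
combinations, hence bounded by the observed min/max. The neighbourhood
default is global (all stations): at network sizes of a few dozen a search
radius adds variance without benefit. k-nearest restriction is available.

**RBF.** Five radial kernels; the completely regularized spline is
`φ(r) = ln(u) + E₁(u) + C_E` with `u = (σr/2)²`, and the tension spline is
`φ(r) = ln(σr/2) + K₀(σr) + C_E`, both with the analytic limit φ(0) = 0.
`C_E` is the Euler constant carried at the conventional 6-digit truncation
0.577215, so the φ → 0 limit holds to ~6.6e-7; the constant offset is
absorbed by the solved bias. Coordinates are standardized internally (zero
centroid, unit RMS radius) before kernel evaluation so that σ is scale-free
and the E₁/K₀ arguments stay in range at any CRS unit; predictions are
invariant to this standardization.

The weights solve the augmented system `[Φ, 1; 1ᵀ, 0]·[ω; ω_{n+1}] = [z; 0]`
by LU with a few steps of iterative refinement. Spline systems can be very
ill-conditioned, with legitimately huge mutually-cancelling weights; the
fitted model is therefore accepted or rejected on the check that matters —
reproduction of the training values to 1e-6 relative — rather than on a raw
residual norm, which for such systems sits at the backward-stability limit.

With `sigma=None` (the default) the shape parameter is selected by
minimizing the leave-one-out RMSE on the training data, computed cheaply via
Rippa's closed form `eᵢ = cᵢ/(A⁻¹)ᵢᵢ` over a fixed log-spaced grid
(1e-2 … 10^1.5 in standardized units). This mirrors how GIS packages tune
the RBF parameter and removes the need for a per-dataset manual choice; a
fixed σ = 1 was rejected because it leaves the completely regularized spline
nearly degenerate on the packaged network (fold predictions overshooting the
Box-Cox domain).

**Kriging.** The empirical semivariogram is the Matheron estimator on 12
uniform lag bins up to half the maximum pairwise distance (empty bins
dropped). Parametric models are fitted by N(h)-weighted least squares with
bound constraints; the four forms are

| model | γ(h) − c₀, as a fraction of c |
|---|---|
| gaussian | 1 − exp(−3h²/a²) |
| stable | 1 − exp(−3(h/a)^ω), ω ∈ (0, 2] |
| hole effect | 1 − sin(2πh/a)/(2πh/a) |
| J-Bessel | 1 − J₀(2πh/a) |

with the practical-range factor 3 for gaussian/stable, matching common GIS
conventions; γ(0) = 0 exactly and the nugget c₀ appears as the h → 0⁺ jump.
The functional forms are isolated in `variogram_eval` so alternates can be
swapped.

Ordinary kriging solves the augmented variogram system per target under
`Σλ = 1`; universal kriging augments it with drift columns ({1, x, y} at the
default first order — the minimal non-trivial drift; order 0 reproduces OK
exactly). On the right-hand side a coincident target-data pair uses the
h → 0⁺ limit (the nugget): with a nugget the field is treated as noisy at
microscale and kriging filters it, so data-site predictions are inexact;
with c₀ = 0 exact interpolation is recovered. Kriging variances are reported
per target, with values in (−1e-8·sill, 0) clamped to zero. A singular
system triggers one diagonal-jitter retry (1e-10 × mean diagonal) with a
warning before raising.

In cross-validation the variogram is fitted once on the full transformed
dataset and reused across folds, mirroring standard GIS cross-validation;
`refit_per_fold=True` refits on each training subset instead.

## Cross-validation and scoring

The evaluation design is leave-one-out: each station is predicted from a
model configured on the other N−1 (on the Box-Cox scale), and the
back-transformed prediction is paired with the observation. Four statistics
summarize the fold errors: MAPE (percent), RMSE, MBE and MAE, reported on
both the concentration scale and the transformed scale. Concentration-scale
MAPE is the ranking criterion for "best method". The identities
|MBE| ≤ MAE ≤ RMSE hold for every run, with MAE = RMSE exactly when all
residual magnitudes are equal; MAPE is invariant to rescaling both series by
a positive constant.

The default comparison grid has 11 rows: RBF (completely regularized
spline), IDW powers 1 and 2, and OK/UK under each of the four variogram
models.

## Exceedance summaries

Exceedance is computed over the 48 *station means* — the resolution at which
campaign tables report data, and the only one auditable without the raw
246-sample series. "Exceeds" is strict (>), "complies" is strict (<); under
this reading the packaged network gives exactly 75.00% of stations above the
35 μg/m³ 24-h PM2.5 standard (36/48) and 89.58% below the 154 μg/m³ 24-h
PM10 standard (43/48). Ratio statistics are recomputed from the means, not
read from the printed ratio column. The network-level means are
sample-count-weighted.

## Prediction grids

Surfaces are cell-center predictions on a lower-left-referenced regular
raster, written in the ESRI ASCII grid convention (rows north to south) for
clean GIS interchange. The default is a 100 m cell over the station bounding
box padded by 500 m — appropriate for a city extent of a few kilometres. No
masking polygon is applied; predictions cover the full bounding box.

## Synthetic data

`simulate_grf` draws station locations uniformly over a rectangle and values
from a stationary Gaussian random field whose covariance is
`C(h) = sill − γ(h)` for the configured variogram (nugget as white noise),
optionally plus a deterministic linear drift, plus a positive floor so the
Box-Cox pipeline applies. Simulation is exact dense eigendecomposition —
appropriate up to a few thousand stations — and covariance validity is
checked numerically (smallest eigenvalue ≥ −1e-8 × trace), since
hole-effect/J-Bessel models are not positive definite at every parameter
combination in 2-D. Identical seeds give identical networks.

The generator emulates the stationarity/drift assumptions of the
interpolators; it does *not* emulate temporal sampling structure,
measurement error per visit, heteroskedastic station variances, urban
source geometry, or anisotropy. Passing recovery tests therefore establishes
the estimators' correctness under their own assumptions, not their adequacy
for any particular real network.

Recovery checks (seeded, run in the test suite): the gaussian range
(truth 2000 m, nugget 0.1, partial sill 1.0) is recovered within ±30%
averaged over 20 seeds at n = 200; universal kriging beats ordinary kriging
in LOOCV RMSE on a majority of 20 strongly drifted fields (drift spanning
~8 sill units across a 10 km domain, n = 80, a size chosen to keep the whole
suite fast while leaving the contrast unambiguous); a noiseless plane is
recovered by UK to ≤ 1e-6; and on a pure-nugget field LOOCV RMSE approaches
the field standard deviation (±20%) — no method can beat white noise.

## Known limitations

* The variogram parameterizations of proprietary GIS software are not fully
  specified; fitted kriging rows can differ numerically from tables produced
  with such software even when the workflow matches. On the packaged network
  the OK hole-effect/J-Bessel rows score within ~0.3 MAPE points of IDW
  power 1 for PM10, so the method ranking there is not robust at that margin.
* Transformed-scale RMSE/MBE/MAE magnitudes depend on any additional
  rescaling applied before scoring; published tables that do not state their
  scale cannot be matched digit-for-digit.
* Anisotropy, local search neighbourhoods for kriging, barriers, and
  conditional simulation are out of scope.
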