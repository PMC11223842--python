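# Methods

## The calibration problem

A DIA identification engine scores candidate peptide-spectrum matches partly
by how far a peptide's measured retention time (RT) falls from its estimated
RT. The estimate comes from the spectral library, whose RT or iRT values live
on a different scale than the current run's chromatography, so a run-specific
mapping from library scale to measured scale must be fitted first. The data
available for that fit are the (library RT/iRT, measured RT) pairs of
already-identified precursors, and they have three defining properties:

1. the true relation is monotone non-decreasing but usually nonlinear;
2. true points are dense mid-gradient and sparse at both ends of elution;
3. a substantial fraction of the pairs are false matches — uniform clutter
   that can reach 75% of all points when calibration runs on unvalidated
   first-pass identifications.

`calibrt` treats calibration as robust monotone curve fitting under exactly
these conditions.

## The pipeline

**1. Gridding and frequency counting.** The point cloud is binned on an
equal-width `grid_size x grid_size` grid (default 100) spanning the data
range on each axis; bins are half-open with a closed top edge, the standard
histogram convention. Each occupied row and each occupied column then
contributes its highest-count cell (union of row and column maxima; ties go
to the lowest index). This non-maximal suppression caps the surviving cell
count at `2 x grid_size` regardless of the raw data size, which is what makes
the rest of the pipeline run in constant time with respect to n.

**2. Maximum-weight ascending path.** The retained cells become nodes of a
DAG. A directed edge connects cell u to cell v whenever v is at least as
large as u in both grid indices (and differs), so any path is monotone on
both axes; all comparable pairs are edges, not just neighbours. The edge
weight is `freq(u) * freq(v) / dist(u, v)` with distance measured in
grid-index units, making the search invariant to axis scales. The node set of
the maximum-weight-sum path — found by an O(K^2) dynamic program over the
(ix, iy)-sorted nodes — is kept for fitting. High-frequency, tightly spaced
cells (the signal ridge) dominate this objective; isolated noise cells
contribute little weight and monotonicity excludes most of them outright.
Ties prefer the longer path, then the lexicographically smallest index
sequence, so the result is deterministic.

**3. Span filtering (optional, off by default).** Because true points thin
out at the elution ends, a path node separated from its inner neighbour by
more than `threshold` (default 10%) of the full range in either dimension is
likely noise. When enabled, such end nodes are trimmed iteratively from both
ends, never from the interior, down to a floor of two nodes. It stays off by
default because with in-range noise all points deserve equal consideration;
it earns its keep when noise extends beyond the true library-RT range (the
1.2x scenario in the benchmark), where an end spur would otherwise bend the
extrapolation.

**4. LOESS with linear end extrapolation.** A local-linear (degree 1)
tricube-weighted LOESS is fitted through the surviving cells' centre
coordinates, with each cell's frequency as a regression weight and no
robustness iterations (outliers were removed upstream). The smoothing
fraction is 0.3 with a floor of two points per window. Duplicate x positions
are collapsed to their frequency-weighted mean. Beyond the fitted range the
curve continues linearly through the end anchors; the end slope is the secant
between the anchor and the knot nearest to 10% inside the fitted x-range,
which is robust to single-knot jitter. Predictions between knots are linear
interpolations of the fitted values. The LOESS is written in-house because
the widely used `lowess` routines accept no per-observation weights; at unit
weights it agrees with `statsmodels.nonparametric.lowess` (it=0) to within
1e-12, which the test suite asserts.

The fitted curve is not explicitly projected to be monotone: monotonicity is
imposed by the path selection, and on the benchmark scenarios the smoothed
curve inherits it. A cumulative-max post-process would be easy to add but is
deliberately not applied by default.

**Degenerate inputs.** Below `min_points` pairs (default 5), or when either
axis has zero range, the calibrator falls back to an ordinary least-squares
line (a constant at zero x-range), flags the model metadata, and warns. A
calibrator embedded in an iterative identification loop must produce some
mapping for a tiny first-pass peptide set rather than fail.

The core pipeline contains no randomness: identical input and configuration
give bit-identical models.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `grid_size` | 100 | cells/axis | resolution of the density summary; 25–50 is too coarse to separate ridge from clutter at small n, 200 fragments the ridge when points are few |
| `span.enabled` | off | — | end-outlier trimming; enable when noise can exceed the library-RT range |
| `span.threshold` | 0.10 | fraction of range | allowable end gap, both dimensions |
| `loess_frac` | 0.3 | fraction of knots | LOESS window; smaller tracks sharp curvature closer at the cost of noise sensitivity |
| `min_points` | 5 | pairs | below this the OLS fallback is used |

## The synthetic benchmark

Real calibration inputs are emulated, not replayed: the generator produces a
monotone ground-truth curve of one of five archetypes — linear, distortion at
the start of elution (slope ramps from 0 over the first 15% of the x-range),
distortion at the end (mirrored), exponential (`expm1`-shaped), and S-type
(logistic with argument spanning ±5) — over a library scale of [0, 100] and a
measured scale of roughly [5, 125] minutes. x values are drawn from a
truncated normal centred mid-range with sigma a quarter of the range
(centre-dense, end-sparse, as in real elution profiles), and y receives
Gaussian jitter with sigma 0.5% of the y-range. A scenario subsamples the
2500 ground-truth points at a sampling rate in {0.01, 0.1, 0.3, 0.5} and adds
`round(f/(1-f) * n_signal)` uniform noise points so that noise makes up
fraction f in {0.01, 0.05, 0.35, 0.75} of the total; noise stays inside the
signal bounding box unless `noise_x_limit_factor > 1` stretches the upper x
limit (1.2 in the out-of-range scenario).

Fit quality is the mean relative deviation (MRD): the mean over *signal*
points of |predicted − measured| divided by the signal measured-RT range.
Range normalisation (rather than per-point division by the measured value)
keeps the metric well-defined near zero RT and weighs the whole gradient
equally.

Three generic calibrators serve as baselines, each ending in the same LOESS:
raw LOESS on all points; quantile trimming (drop points whose absolute
residual from a preliminary least-squares line exceeds the 95th percentile)
then LOESS; and RANSAC with a linear base model (scikit-learn defaults,
including the adaptive MAD-of-y inlier threshold, fixed seed) then LOESS on
the inliers. The RANSAC threshold choice matters: the library default
degrades gracefully into raw LOESS as noise grows, which is the documented,
out-of-the-box behaviour a practitioner would get; a hand-tuned narrow band
around the dominant trend would instead make RANSAC a near-oracle on linear
data and an unrepresentative baseline.

**What the generator does not emulate:** heteroscedastic RT error, locally
clustered (non-uniform) false matches, interference-driven correlations
between noise and signal density, and real chromatographic drift shapes
outside the five archetypes. Passing benchmarks therefore demonstrate noise
tolerance under idealised clutter, not performance on any particular
instrument's data.

## Numerical choices

- Binning: `numpy.histogram2d` over [min, max] per axis; the retained-cell
  set is invariant to separate increasing affine rescalings of either axis.
- Path DP ties are resolved (weight, then node count, then lexicographic) to
  make output deterministic; the brute-force enumeration oracle in the test
  suite agrees with the DP on random instances.
- LOESS windows with all-identical x collapse to the weighted mean; a window
  whose tricube weights vanish at the boundary falls back to its two nearest
  points.
- Problem sizes in the test and benchmark runs (2500 ground-truth points, 10
  to 25 seeds per scenario) are the package's chosen study conditions; the
  full factorial (5 curves x 4 rates x 4 noise levels) runs in seconds
  because the pipeline's cost after binning is bounded by the grid size.

## Known limitations

- The fitted curve can dip non-monotonically between knots in principle; no
  isotonic projection is applied.
- Cell centres, not member-point means, represent retained cells; the
  quantisation error is bounded by one cell and is visible as the ~0.5-unit
  tolerance in the clean-line end-to-end test.
- The span filter trims only path *ends*; a wide interior gap (e.g. a
  segmented gradient) is never filtered.
- With fewer than ~10 signal points the grid pipeline is formally applicable
  but the OLS fallback (min_points=5) and single-cell rows make the result
  effectively linear.
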