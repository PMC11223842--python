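"""Synthetic calibration scenarios, the MRD metric, and baseline calibrators.

Real calibration inputs are the (library iRT, measured RT) pairs of
precursors identified in a DIA run: a monotone curve whose shape depends on
the chromatographic gradient, sampled densely mid-gradient and sparsely at
the ends, contaminated by false matches that scatter uniformly over the data
range.  This module emulates those inputs with five parametric monotone
archetypes -- linear, distortion at the start of elution, distortion at the
end, exponential, and S-shaped -- combined with uniform random subsampling
and an FDR-style noise injection: a scenario at noise fraction f has
``round(f / (1 - f) * n_signal)`` uniform noise points so that noise makes up
fraction f of the total.  Noise stays inside the signal bounding box unless
``noise_x_limit_factor > 1`` stretches the upper x limit, which is the case
span filtering exists for.

Fitting quality is scored by the mean relative deviation (MRD): the mean over
*signal* points of |predicted - measured| normalised by the signal measured-RT
range.  Three generic calibrators serve as baselines: plain LOESS, LOESS
after quantile-based residual trimming, and LOESS after RANSAC inlier
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .calibrator import CalibConfig, fit_calibration
from .data_io import CalibrationPoints
from .exceptions import DegenerateScenarioError
from .loess_fit import CalibrationModel, fit_loess

CURVE_TYPES = ("linear", "distortion_begin", "distortion_end", "exponential", "s_type")
SAMPLING_RATES = (0.01, 0.1, 0.3, 0.5)
NOISE_FRACTIONS = (0.01, 0.05, 0.35, 0.75)
BASELINE_METHODS = ("raw_loess", "quantile_loess", "ransac_loess")

# Ground-truth curve family: x plays the role of library iRT over [0, 100],
# y the measured RT in minutes over roughly [5, 125].
X_RANGE = (0.0, 100.0)
_LINEAR_SLOPE = 1.2
_LINEAR_INTERCEPT = 5.0
_DISTORTION_WINDOW = 0.15  # fraction of the x-range that flattens
_EXP_RATE = 3.0  # exponent over the unit interval
_LOGISTIC_STEEPNESS = 10.0  # logistic argument spans +-steepness/2
_JITTER_SD_FRACTION = 0.005  # measurement jitter, fraction of the y-range

# Baseline parameters (module constants; generic textbook choices).
QUANTILE_KEEP = 95.0  # residual percentile kept by quantile trimming
RANSAC_SEED = 0  # RANSAC inlier threshold: scikit-learn's MAD-of-y default


def _curve_y(curve_type: str, x: np.ndarray, x_range) -> np.ndarray:
    """Noise-free monotone non-decreasing archetype evaluated at x."""
    lo, hi = x_range
    span = hi - lo
    u = (x - lo) / span
    if curve_type == "linear":
        return _LINEAR_SLOPE * x + _LINEAR_INTERCEPT
    if curve_type == "distortion_begin":
        # slope ramps linearly from 0 to nominal over the first window
        w = _DISTORTION_WINDOW
        y = np.where(u < w, u**2 / (2 * w), u - w / 2)
        return _LINEAR_INTERCEPT + _LINEAR_SLOPE * span * y
    if curve_type == "distortion_end":
        w = _DISTORTION_WINDOW
        v = 1.0 - u
        y = np.where(v < w, v**2 / (2 * w), v - w / 2)
        return _LINEAR_INTERCEPT + _LINEAR_SLOPE * span * ((1 - w / 2) - y)
    if curve_type == "exponential":
        scale = _LINEAR_SLOPE * span
        return _LINEAR_INTERCEPT + scale * (np.expm1(_EXP_RATE * u) / np.expm1(_EXP_RATE))
    if curve_type == "s_type":
        scale = _LINEAR_SLOPE * span
        z = _LOGISTIC_STEEPNESS * (u - 0.5)
        lo_v, hi_v = (
            1 / (1 + np.exp(_LOGISTIC_STEEPNESS / 2)),
            1 / (1 + np.exp(-_LOGISTIC_STEEPNESS / 2)),
        )
        return _LINEAR_INTERCEPT + scale * (1 / (1 + np.exp(-z)) - lo_v) / (hi_v - lo_v)
    raise ValueError(f"unknown curve type {curve_type!r}; choose from {CURVE_TYPES}")


def generate_curve(
    curve_type: str,
    n: int,
    x_range=X_RANGE,
    seed: int | None = None,
    jitter_sd_fraction: float = _JITTER_SD_FRACTION,
) -> CalibrationPoints:
    """Ground-truth points on one archetype, centre-dense in x.

    x is drawn from a truncated normal centred mid-range with sigma equal to
    a quarter of the range (dense centre, sparse ends, as in real elution
    profiles); y gets Gaussian jitter with sigma ``jitter_sd_fraction`` of
    the y-range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = x_range
    mid, sigma = 0.5 * (lo + hi), 0.25 * (hi - lo)
    x = stats.truncnorm.rvs(
        (lo - mid) / sigma, (hi - mid) / sigma, loc=mid, scale=sigma, size=n, random_state=rng
    )
    y = _curve_y(curve_type, x, x_range)
    y_span = _curve_y(curve_type, np.array([hi]), x_range)[0] - _curve_y(
        curve_type, np.array([lo]), x_range
    )[0]
    if jitter_sd_fraction > 0:
        y = y + rng.normal(0.0, jitter_sd_fraction * y_span, size=n)
    return CalibrationPoints(x, y)


def subsample_and_add_noise(
    points: CalibrationPoints,
    sampling_rate: float,
    noise_fraction: float,
    noise_x_limit_factor: float = 1.0,
    seed: int | None = None,
) -> tuple[CalibrationPoints, np.ndarray]:
    """Subsample the ground truth and mix in uniform noise.

    Returns the combined points (signal first) and a boolean signal mask.
    Noise x and y are drawn independently and uniformly over the sampled
    signal's range; ``noise_x_limit_factor`` > 1 raises the upper noise x
    limit to ``factor * max(signal x)`` to emulate out-of-range library
    entries.
    """
    if not 0.0 < sampling_rate <= 0.5:
        raise ValueError("sampling_rate must be in (0, 0.5]")
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    if noise_x_limit_factor < 1.0:
        raise ValueError("noise_x_limit_factor must be >= 1")
    rng = np.random.default_rng(seed)
    n_signal = round(sampling_rate * points.n)
    if n_signal < 1:
        raise DegenerateScenarioError(
            f"sampling rate {sampling_rate} of {points.n} points leaves no signal"
        )
    idx = rng.choice(points.n, size=n_signal, replace=False)
    sx, sy = points.library_rt[idx], points.measured_rt[idx]
    n_noise = round(noise_fraction / (1.0 - noise_fraction) * n_signal)
    x_hi = noise_x_limit_factor * sx.max() if noise_x_limit_factor > 1 else sx.max()
    nx = rng.uniform(sx.min(), x_hi, size=n_noise)
    ny = rng.uniform(sy.min(), sy.max(), size=n_noise)
    combined = CalibrationPoints(np.concatenate([sx, nx]), np.concatenate([sy, ny]))
    is_signal = np.zeros(combined.n, dtype=bool)
    is_signal[:n_signal] = True
    return combined, is_signal


def mrd(predicted_rt, measured_rt, is_signal) -> float:
    """Mean relative deviation over signal points.

    mean(|predicted - measured|) / (max - min) of the signal measured RTs;
    noise points never contribute.
    """
    predicted = np.asarray(predicted_rt, dtype=float)
    measured = np.asarray(measured_rt, dtype=float)
    mask = np.asarray(is_signal, dtype=bool)
    if predicted.shape != measured.shape or predicted.shape != mask.shape:
        raise ValueError("predicted, measured and is_signal must share one length")
    if not mask.any():
        raise ValueError("MRD needs at least one signal point")
    span = measured[mask].max() - measured[mask].min()
    if span <= 0:
        raise ValueError("signal measured-RT range must be positive")
    return float(np.mean(np.abs(predicted[mask] - measured[mask])) / span)


def baseline_fit(
    method: str, points: CalibrationPoints, config: CalibConfig | None = None
) -> CalibrationModel:
    """Fit one of the generic reference calibrators.

    raw_loess: LOESS on every point.  quantile_loess: drop points whose
    absolute residual from a preliminary least-squares line exceeds the 95th
    percentile, then LOESS.  ransac_loess: RANSAC with a linear base model
    (scikit-learn's adaptive MAD inlier threshold, fixed seed), then LOESS
    on the inliers.
    """
    config = config or CalibConfig()
    x, y = points.library_rt, points.measured_rt
    if method == "raw_loess":
        keep = np.ones(points.n, dtype=bool)
    elif method == "quantile_loess":
        slope, intercept = np.polyfit(x, y, 1)
        resid = np.abs(y - (slope * x + intercept))
        keep = resid <= np.percentile(resid, QUANTILE_KEEP)
    elif method == "ransac_loess":
        ransac = RANSACRegressor(LinearRegression(), random_state=RANSAC_SEED)
        ransac.fit(x.reshape(-1, 1), y)
        keep = ransac.inlier_mask_
    else:
        raise ValueError(f"unknown baseline {method!r}; choose from {BASELINE_METHODS}")
    if keep.sum() < 2:
        keep = np.ones(points.n, dtype=bool)
    return fit_loess(np.column_stack([x[keep], y[keep]]), frac=config.loess_frac)


@dataclass(frozen=True)
class BenchScenario:
    """One synthetic data set specification."""

    curve_type: str
    sampling_rate: float
    noise_fraction: float
    n_truth: int = 2500
    noise_x_limit_factor: float = 1.0
    seed: int = 0

    def realise(self) -> tuple[CalibrationPoints, np.ndarray]:
        truth = generate_curve(self.curve_type, self.n_truth, seed=self.seed)
        return subsample_and_add_noise(
            truth,
            self.sampling_rate,
            self.noise_fraction,
            self.noise_x_limit_factor,
            seed=self.seed + 1,
        )


def evaluate_method(
    method: str, scenario: BenchScenario, config: CalibConfig | None = None
) -> float:
    """Realise a scenario, fit one method, and return its MRD."""
    config = config or CalibConfig()
    points, is_signal = scenario.realise()
    if method == "calib_rt":
        model = fit_calibration(points, config)
    else:
        model = baseline_fit(method, points, config)
    return mrd(model.predict(points.library_rt), points.measured_rt, is_signal)


def run_experiment_matrix(
    curve_types=CURVE_TYPES,
    sampling_rates=SAMPLING_RATES,
    noise_fractions=NOISE_FRACTIONS,
    methods=("calib_rt",) + BASELINE_METHODS,
    n_seeds: int = 1,
    n_truth: int = 2500,
    base_seed: int = 0,
    config: CalibConfig | None = None,
    out_tsv=None,
) -> pd.DataFrame:
    """Full factorial benchmark; tidy per-seed MRD table.

    Seeds are derived deterministically from ``base_seed``.  When ``out_tsv``
    is given the table is also written as TSV.
    """
    rows = []
    for curve_type in curve_types:
        for sampling_rate in sampling_rates:
            for noise_fraction in noise_fractions:
                for rep in range(n_seeds):
                    curve_tag = CURVE_TYPES.index(curve_type) if curve_type in CURVE_TYPES else 0
                    seed = (base_seed * 1_000_003 + rep * 7919 + curve_tag * 971) % 2**31
                    scenario = BenchScenario(
                        curve_type=curve_type,
                        sampling_rate=sampling_rate,
                        noise_fraction=noise_fraction,
                        n_truth=n_truth,
                        seed=seed,
                    )
                    for method in methods:
                        rows.append(
                            {
                                "method": method,
                                "curve_type": curve_type,
                                "sampling_rate": sampling_rate,
                                "noise_fraction": noise_fraction,
                                "seed": seed,
                                "mrd": evaluate_method(method, scenario, config),
                            }
                        )
    table = pd.DataFrame(
        rows,
        columns=["method", "curve_type", "sampling_rate", "noise_fraction", "seed", "mrd"],
    )
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    return table


def summarize_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Median MRD per (method, curve, sampling rate, noise fraction) cell."""
    if table.empty:
        return table
    return (
        table.groupby(["method", "curve_type", "sampling_rate", "noise_fraction"])["mrd"]
        .median()
        .reset_index(name="median_mrd")
    )
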