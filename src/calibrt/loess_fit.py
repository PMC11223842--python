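"""LOESS fit through the surviving path nodes, with linear end extrapolation.

The smoother is the classical local-linear LOESS: for each knot, the nearest
``frac`` fraction of points (at least two) is weighted by the tricube kernel
of scaled distance and a degree-1 weighted least-squares line is evaluated at
the knot.  Cell frequencies multiply the kernel weights so that a cell
summarising many raw points pulls harder than a singleton.  No robustness
iterations are run -- outliers are removed upstream by the path search.

Beyond the fitted x-range the curve continues as straight lines through the
end anchors, with slopes taken as the secant over the outermost 10% of the
fitted range.  A hand-rolled smoother is used because the usual lowess
routines accept no per-observation weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

DEFAULT_LOESS_FRAC = 0.3
_SLOPE_WINDOW = 0.10  # fraction of the fitted x-range used for end slopes


@dataclass
class CalibrationModel:
    """A fitted calibration curve, callable on library RT/iRT values.

    Inside ``[knots_x[0], knots_x[-1]]`` predictions linearly interpolate the
    fitted knot values; outside, they follow the end-anchor extrapolation
    lines, which pass through the anchors exactly (continuity).
    """

    knots_x: np.ndarray
    knots_y: np.ndarray
    left_slope: float
    right_slope: float
    loess_frac: float = DEFAULT_LOESS_FRAC
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.knots_x = np.asarray(self.knots_x, dtype=float)
        self.knots_y = np.asarray(self.knots_y, dtype=float)
        if self.knots_x.size == 0 or self.knots_x.shape != self.knots_y.shape:
            raise ValueError("knots_x and knots_y must be equal-length and non-empty")
        if self.knots_x.size > 1 and not (np.diff(self.knots_x) > 0).all():
            raise ValueError("knots_x must be strictly increasing")

    @property
    def left_anchor(self) -> tuple[float, float]:
        return float(self.knots_x[0]), float(self.knots_y[0])

    @property
    def right_anchor(self) -> tuple[float, float]:
        return float(self.knots_x[-1]), float(self.knots_y[-1])

    def predict(self, x) -> np.ndarray:
        """Evaluate the calibration curve at library RT/iRT values ``x``."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        y = np.interp(x, self.knots_x, self.knots_y)
        (xl, yl), (xr, yr) = self.left_anchor, self.right_anchor
        below, above = x < xl, x > xr
        y[below] = yl + self.left_slope * (x[below] - xl)
        y[above] = yr + self.right_slope * (x[above] - xr)
        return y[0] if scalar else y

    __call__ = predict

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "knots_x": self.knots_x.tolist(),
            "knots_y": self.knots_y.tolist(),
            "left_slope": self.left_slope,
            "right_slope": self.right_slope,
            "loess_frac": self.loess_frac,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CalibrationModel":
        return cls(
            knots_x=np.asarray(payload["knots_x"], dtype=float),
            knots_y=np.asarray(payload["knots_y"], dtype=float),
            left_slope=float(payload["left_slope"]),
            right_slope=float(payload["right_slope"]),
            loess_frac=float(payload.get("loess_frac", DEFAULT_LOESS_FRAC)),
            metadata=dict(payload.get("metadata", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))


def _dedupe(x, y, w):
    """Collapse duplicate x values to their weight-averaged y."""
    order = np.argsort(x, kind="stable")
    x, y, w = x[order], y[order], w[order]
    ux, start = np.unique(x, return_index=True)
    if ux.size == x.size:
        return x, y, w
    bounds = np.append(start, x.size)
    ys = np.array(
        [np.average(y[a:b], weights=w[a:b]) for a, b in zip(bounds, bounds[1:])]
    )
    ws = np.array([w[a:b].sum() for a, b in zip(bounds, bounds[1:])])
    return ux, ys, ws


def _tricube(u: np.ndarray) -> np.ndarray:
    out = np.clip(1.0 - np.clip(u, 0.0, 1.0) ** 3, 0.0, None) ** 3
    return out


def _local_linear(x, y, w, x0: float, window: int) -> float:
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:window]
    xs, ys, ws, ds = x[idx], y[idx], w[idx], d[idx]
    dmax = ds.max()
    kern = np.ones_like(ds) if dmax == 0 else _tricube(ds / dmax)
    wt = kern * ws
    if (wt > 0).sum() < 2:  # tricube zeroes the window boundary; keep 2 closest
        wt = ws.copy()
    t = xs - x0
    sw, swt = wt.sum(), (wt * t).sum()
    swtt, swy, swty = (wt * t * t).sum(), (wt * ys).sum(), (wt * t * ys).sum()
    denom = sw * swtt - swt**2
    if denom <= 1e-12 * max(sw * swtt, 1e-300):  # collinear in x: weighted mean
        return swy / sw
    # intercept of the weighted degree-1 fit at t = 0
    return (swtt * swy - swt * swty) / denom


def fit_loess(path_points, weights=None, frac: float = DEFAULT_LOESS_FRAC) -> CalibrationModel:
    """Fit the calibration curve through (x, y) points with positive weights.

    Requires at least two distinct x values (degenerate inputs are handled
    by the calibrator's linear fallback, not here).
    """
    pts = np.asarray(path_points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    x, y, w = _dedupe(x, y, w)
    if x.size < 2:
        raise ValueError("need >= 2 distinct x values to fit a curve")
    window = max(2, int(np.ceil(frac * x.size)))
    fitted = np.array([_local_linear(x, y, w, xi, window) for xi in x])
    left_slope = _end_slope(x, fitted, side="left")
    right_slope = _end_slope(x, fitted, side="right")
    return CalibrationModel(
        knots_x=x,
        knots_y=fitted,
        left_slope=left_slope,
        right_slope=right_slope,
        loess_frac=frac,
    )


def _end_slope(x: np.ndarray, y: np.ndarray, side: str) -> float:
    """Secant slope through an end anchor and the knot ~10% inside the range."""
    span = x[-1] - x[0]
    if side == "left":
        target = x[0] + _SLOPE_WINDOW * span
        j = int(np.argmin(np.abs(x[1:] - target))) + 1
        return (y[j] - y[0]) / (x[j] - x[0])
    target = x[-1] - _SLOPE_WINDOW * span
    j = int(np.argmin(np.abs(x[:-1] - target)))
    return (y[-1] - y[j]) / (x[-1] - x[j])
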