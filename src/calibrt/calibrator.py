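"""End-to-end calibration pipeline.

``fit_calibration`` composes the four stages -- grid counting, non-maximal
suppression, maximum-weight monotone path search, optional span filtering --
and fits the LOESS curve through the surviving cells.  The result converts
any spectral-library RT/iRT into an estimated measured RT.  The pipeline is
fully deterministic: identical input and configuration give bit-identical
models, which matters when the calibrator runs inside an iterative
identification engine.

Inputs below the workflow's assumptions (fewer than ``min_points`` pairs, or
zero range on either axis) fall back to an ordinary least-squares line,
flagged in the model metadata, rather than failing: a first identification
pass may legitimately supply a handful of peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import CalibrationPoints
from .exceptions import DegenerateRangeError
from .grid_select import DEFAULT_GRID_SIZE, GridSpec, grid_count, nonmax_suppress
from .loess_fit import DEFAULT_LOESS_FRAC, CalibrationModel, fit_loess
from .path_graph import PathNode, max_weight_path
from .span_filter import SpanConfig, filter_span

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibConfig:
    """Tunable knobs of the pipeline; defaults follow the published method."""

    grid_size: int = DEFAULT_GRID_SIZE
    span: SpanConfig = field(default_factory=SpanConfig)
    loess_frac: float = DEFAULT_LOESS_FRAC
    min_points: int = 5

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


def _linear_fallback(points: CalibrationPoints, reason: str) -> CalibrationModel:
    x, y = points.library_rt, points.measured_rt
    logger.warning("falling back to a least-squares line (%s)", reason)
    if x.min() == x.max():
        mean_y = float(y.mean())
        model = CalibrationModel(
            knots_x=np.array([x[0]]), knots_y=np.array([mean_y]),
            left_slope=0.0, right_slope=0.0,
        )
    else:
        slope, intercept = np.polyfit(x, y, 1)
        kx = np.array([x.min(), x.max()])
        model = CalibrationModel(
            knots_x=kx, knots_y=slope * kx + intercept,
            left_slope=float(slope), right_slope=float(slope),
        )
    model.metadata.update({"method": "linear_fallback", "fallback_reason": reason})
    return model


def fit_calibration(points: CalibrationPoints, config: CalibConfig | None = None) -> CalibrationModel:
    """Fit the full calibration curve on paired (library, measured) RTs."""
    config = config or CalibConfig()
    if points.n < config.min_points:
        return _linear_fallback(points, f"n={points.n} below min_points={config.min_points}")
    try:
        spec = GridSpec.from_points(points, config.grid_size)
    except DegenerateRangeError as err:
        return _linear_fallback(points, str(err))

    summary = nonmax_suppress(grid_count(points, spec))
    nodes = [
        PathNode(ix, iy, *summary.cell_center(ix, iy), freq=int(summary.counts[iy, ix]))
        for ix, iy in summary.retained
    ]
    path = max_weight_path(nodes)
    x_range = float(points.library_rt.max() - points.library_rt.min())
    y_range = float(points.measured_rt.max() - points.measured_rt.min())
    filtered = filter_span(path, config.span, x_range, y_range)
    logger.info(
        "calibration stages: %d points -> %d retained cells -> %d path nodes -> %d after span filter",
        points.n, len(nodes), len(path), len(filtered),
    )

    xs = {node.x for node in filtered.nodes}
    if len(xs) < 2:
        return _linear_fallback(points, "fewer than 2 distinct path x positions")
    model = fit_loess(
        [(node.x, node.y) for node in filtered.nodes],
        weights=[node.freq for node in filtered.nodes],
        frac=config.loess_frac,
    )
    model.metadata.update(
        {
            "method": "calib_rt",
            "grid_size": config.grid_size,
            "span_enabled": config.span.enabled,
            "span_threshold": config.span.threshold,
            "loess_frac": config.loess_frac,
            "stage_counts": {
                "points": points.n,
                "retained_cells": len(nodes),
                "path_nodes": len(path),
                "filtered_nodes": len(filtered),
            },
        }
    )
    return model


def transform(model: CalibrationModel, library_rt) -> np.ndarray:
    """Convert library RT/iRT values to estimated measured RTs."""
    return model.predict(np.asarray(library_rt, dtype=float))


def fit(
    library_rt,
    measured_rt,
    grid_size: int = DEFAULT_GRID_SIZE,
    span_filter_enabled: bool = False,
    span_threshold: float = 0.10,
    loess_frac: float = DEFAULT_LOESS_FRAC,
    min_points: int = 5,
) -> CalibrationModel:
    """Convenience wrapper: fit from two vectors with keyword configuration."""
    points = CalibrationPoints(np.asarray(library_rt, float), np.asarray(measured_rt, float))
    config = CalibConfig(
        grid_size=grid_size,
        span=SpanConfig(enabled=span_filter_enabled, threshold=span_threshold),
        loess_frac=loess_frac,
        min_points=min_points,
    )
    return fit_calibration(points, config)
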