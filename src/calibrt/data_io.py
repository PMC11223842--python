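"""Paired retention-time tables.

A calibration data set is a list of (library RT or iRT, measured RT) pairs,
one per identified precursor.  The library value is dimensionless (iRT) or in
minutes; the measured value is in minutes.  Every module downstream works on
the :class:`CalibrationPoints` container defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_LIBRARY_COLUMN = "library_rt"
DEFAULT_MEASURED_COLUMN = "measured_rt"


@dataclass(frozen=True)
class CalibrationPoints:
    """Paired (library RT/iRT, measured RT) observations.

    Parameters
    ----------
    library_rt
        Spectral-library RT or iRT per precursor.
    measured_rt
        Measured RT in minutes, same length as ``library_rt``.

    Both vectors must be finite and non-empty; duplicate pairs are kept
    because cell frequencies drive the calibration algorithm.
    """

    library_rt: np.ndarray
    measured_rt: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.library_rt, dtype=float)
        y = np.asarray(self.measured_rt, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("library_rt and measured_rt must be equal-length 1-D vectors")
        if x.size == 0:
            raise EmptyInputError("no calibration points provided")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("calibration points must be finite")
        object.__setattr__(self, "library_rt", x)
        object.__setattr__(self, "measured_rt", y)

    @property
    def n(self) -> int:
        return int(self.library_rt.size)


def read_pairs(
    path,
    library_column: str = DEFAULT_LIBRARY_COLUMN,
    measured_column: str = DEFAULT_MEASURED_COLUMN,
    delimiter: str = "\t",
) -> CalibrationPoints:
    """Read paired RT values from a delimited text file.

    Non-numeric or non-finite rows are dropped (the count is logged).
    Raises :class:`SchemaError` when a named column is absent and
    :class:`EmptyInputError` when no valid row remains.
    """
    frame = pd.read_csv(path, sep=delimiter)
    for column in (library_column, measured_column):
        if column not in frame.columns:
            raise SchemaError(
                f"column {column!r} not found; available columns: {list(frame.columns)}"
            )
    x = pd.to_numeric(frame[library_column], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(frame[measured_column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d non-finite/malformed rows from %s", dropped, path)
    if not keep.any():
        raise EmptyInputError(f"no valid (library, measured) pairs in {path}")
    return CalibrationPoints(x[keep], y[keep])


def write_predictions(path, library_rt, predicted_rt, delimiter: str = "\t") -> int:
    """Write a two-column predictions table; returns the number of data rows."""
    x = np.asarray(library_rt, dtype=float)
    y = np.asarray(predicted_rt, dtype=float)
    if x.shape != y.shape:
        raise ValueError("library_rt and predicted_rt must have equal length")
    frame = pd.DataFrame({"library_rt": x, "predicted_rt": y})
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.12g")
    return len(frame)
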