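"""Pixel-ratio to dose-ratio calibration.

A film-measured relative dose ratio is regressed on the EPID pixel-value
ratio (A/B x 100) over the abutment lattice, giving a straight line whose
slope converts *changes* in pixel ratio into fractional dose changes.
Only the slope is ever applied downstream: gantry-angle corrections are
differences against the 0 deg reference, so the intercept cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import FitError, ValidationError

__all__ = [
    "CalibrationPair",
    "DoseConversion",
    "fit_conversion",
    "ratio_delta_to_dose_delta",
]


@dataclass(frozen=True)
class CalibrationPair:
    """One (EPID pixel ratio, film dose ratio) observation.

    ``pixel_ratio`` lives on the ~100 scale (A/B x 100); ``dose_ratio`` is
    the film-derived abutment dose over the neighbouring open-field dose,
    a dimensionless fraction near 1.
    """

    pixel_ratio: float
    dose_ratio: float

    def __post_init__(self) -> None:
        if not (
            np.isfinite(self.pixel_ratio)
            and np.isfinite(self.dose_ratio)
            and self.pixel_ratio > 0
            and self.dose_ratio > 0
        ):
            raise ValidationError("calibration pair must be finite and positive")


@dataclass(frozen=True)
class DoseConversion:
    """Fitted linear conversion: dose_ratio = slope * pixel_ratio + intercept."""

    slope: float
    intercept: float
    r: float
    p_value: float | None = None
    slope_stderr: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValidationError("slope must be finite")
        if not -1.0 <= self.r <= 1.0:
            raise ValidationError("correlation must lie in [-1, 1]")


def _as_xy(pairs: Iterable[CalibrationPair | Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for p in pairs:
        if isinstance(p, CalibrationPair):
            xs.append(p.pixel_ratio)
            ys.append(p.dose_ratio)
        else:
            x, y = p
            xs.append(float(x))
            ys.append(float(y))
    return np.asarray(xs), np.asarray(ys)


def fit_conversion(pairs: Iterable[CalibrationPair | Sequence[float]]) -> DoseConversion:
    """Ordinary least squares of dose ratio on pixel ratio.

    Requires at least three pairs with non-degenerate pixel-ratio spread;
    reports the Pearson correlation of the same pairs (and its two-sided
    p-value).  Exact on collinear input to machine precision.
    """
    x, y = _as_xy(pairs)
    if x.size < 3:
        raise ValidationError("need at least three calibration pairs")
    if np.allclose(x, x[0]):
        raise FitError("pixel ratios are all equal; slope is undefined")
    res = stats.linregress(x, y)
    return DoseConversion(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(np.clip(res.rvalue, -1.0, 1.0)),
        p_value=float(res.pvalue),
        slope_stderr=float(res.stderr),
    )


def ratio_delta_to_dose_delta(conv: DoseConversion, delta_ratio: float) -> float:
    """Map a pixel-ratio change to a fractional dose change.

    Returns ``slope * delta_ratio`` (x100 gives percent).  The intercept
    never enters: corrections are relative changes against a reference.
    """
    return conv.slope * delta_ratio
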