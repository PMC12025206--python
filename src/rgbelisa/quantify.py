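"""Concentration read-out from calibrated RGBscores.

Inverts a fitted calibration curve for unknown samples, estimates the
detection limit from blank replicates (k-sigma convention, k = 3 by
default), and reports the Pearson correlation against a reference method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibrate import CalibrationModel
from .regression import RegressionFit


class NonInvertibleError(ValueError):
    """The calibration curve cannot be inverted at the requested score."""


@dataclass(frozen=True)
class QuantResult:
    """One quantified sample.

    Scores outside the calibrated score interval are clamped to the nearest
    calibrated concentration endpoint (``clamped`` set, ``in_range``
    cleared) rather than extrapolated: outside the fitted range the curve
    flattens and small score noise maps to large concentration error.
    """

    score: float
    concentration: float
    in_range: bool
    clamped: bool


def _invert_fit(fit: RegressionFit, score: float) -> float:
    if fit.kind == "linear":
        if fit.a == 0:
            raise NonInvertibleError("linear calibration has zero slope")
        return (score - fit.b) / fit.a
    if fit.kind == "logarithmic":
        if fit.a == 0:
            raise NonInvertibleError("logarithmic calibration has zero slope")
        return math.exp((score - fit.c) / fit.a) - fit.b
    if fit.kind == "logistic4":
        if fit.a == 0 or fit.c == 0:
            raise NonInvertibleError("logistic calibration is flat")
        if score == fit.d:
            raise NonInvertibleError("score sits on the logistic asymptote d")
        arg = (fit.a / (score - fit.d) - 1.0) / fit.b
        if arg <= 0:
            raise NonInvertibleError(
                f"score {score} is outside the logistic branch (argument {arg} <= 0)"
            )
        return -math.log(arg) / fit.c
    raise NonInvertibleError(f"unknown model kind {fit.kind!r}")


def invert_calibration(model: CalibrationModel, score: float) -> QuantResult:
    """Map one RGBscore to a concentration through the calibration curve."""
    if not model.fit.converged:
        raise NonInvertibleError("calibration fit did not converge")
    score = float(score)
    lo, hi = model.score_range
    clo, chi = model.concentration_range
    if lo <= score <= hi:
        conc = _invert_fit(model.fit, score)
        return QuantResult(score=score, concentration=float(conc), in_range=True, clamped=False)
    # clamp to the concentration endpoint whose fitted score is nearest
    y_lo, y_hi = model.fit.predict(np.array([clo, chi]))
    conc = clo if abs(score - y_lo) <= abs(score - y_hi) else chi
    return QuantResult(score=score, concentration=float(conc), in_range=False, clamped=True)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson method-comparison summary (reference vs image-based)."""

    n: int
    x_values: tuple
    y_values: tuple
    x_bar: float
    y_bar: float
    r: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "x_values": list(self.x_values),
            "y_values": list(self.y_values),
            "x_bar": self.x_bar,
            "y_bar": self.y_bar,
            "r": self.r,
        }


def pearson_correlation(x, y) -> CorrelationReport:
    """Pearson product-moment correlation between paired concentration
    estimates (reference method x, image-based method y)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("correlation needs at least two pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationReport(
        n=int(x.size),
        x_values=tuple(x.tolist()),
        y_values=tuple(y.tolist()),
        x_bar=float(x.mean()),
        y_bar=float(y.mean()),
        r=r,
    )


def detection_limit(model: CalibrationModel, blank_scores, k: float = 3.0) -> float:
    """k-sigma detection limit anchored at the blank.

    The blank mean score is shifted by k standard deviations in the
    direction of increasing concentration and both scores are pushed through
    the inverse calibration; the LOD is the separation of the two
    concentrations.  For a linear calibration this reduces to the closed
    form k*sd/|slope|.
    """
    blank_scores = np.asarray(blank_scores, dtype=np.float64)
    if blank_scores.ndim != 1 or blank_scores.size < 3:
        raise ValueError("need at least 3 blank replicate scores")
    mean_b = float(blank_scores.mean())
    sd_b = float(blank_scores.std(ddof=1))
    if sd_b == 0.0:
        warnings.warn("blank replicates are identical; detection limit is 0", stacklevel=2)
        return 0.0

    clo, chi = model.concentration_range
    x0 = _invert_fit(model.fit, mean_b)
    delta = max((chi - clo) * 1e-6, 1e-12)
    slope = (float(model.fit.predict(x0 + delta)) - float(model.fit.predict(x0))) / delta
    if slope == 0.0:
        raise NonInvertibleError("calibration curve is flat at the blank level")
    sign = 1.0 if slope > 0 else -1.0
    x_lod = _invert_fit(model.fit, mean_b + sign * k * sd_b)
    return abs(x_lod - x0)
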