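"""RGBscore computation and brute-force weight calibration.

The RGBscore of a region of interest is the pixel mean of a weighted channel
sum, ``mean(alpha*R + beta*G + gamma*B)``.  Calibration enumerates every
weight triple on a grid (default -1..1 in steps of 0.05, i.e. 41^3 - 1
triples with the all-zero triple excluded), scores the calibration series
under each triple, fits the requested regression models, and keeps, per
model, the triple with the highest coefficient of determination.

Because the score is linear in the channels, the per-triple score of a
region reduces to a dot product with its channel means, so the whole grid is
evaluated as one matrix product and the model fits run batched over all
triples (see :mod:`rgbelisa.regression`).  The winning triple per model is
then re-scored on the raw pixel arrays and re-fit, so the reported
parameters are exactly those a naive per-triple enumeration would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regression import MODEL_KINDS, RegressionFit, fit_batch, fit_model
from .roi import RoiSelection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightTriple:
    """Channel weights (alpha, beta, gamma) of the RGBscore."""

    alpha: float
    beta: float
    gamma: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def __iter__(self):
        return iter((self.alpha, self.beta, self.gamma))


def rgbscore(roi, weights) -> float:
    """Pixel mean of alpha*R + beta*G + gamma*B over a region of interest.

    ``roi`` is a :class:`RoiSelection` or an (R, G, B) triple of equal-shape
    arrays; ``weights`` is a :class:`WeightTriple` or any 3-sequence.
    """
    if isinstance(roi, RoiSelection):
        R, G, B = roi.R, roi.G, roi.B
    else:
        R, G, B = (np.asarray(ch, dtype=np.float64) for ch in roi)
    if not (R.shape == G.shape == B.shape) or R.size == 0:
        raise ValueError("R, G, B must be nonempty arrays of identical shape")
    alpha, beta, gamma = weights
    return float(np.mean(alpha * R + beta * G + gamma * B))


@dataclass
class ConcentrationSeries:
    """Per-level calibration inputs: concentrations with channel data.

    ``channel_means`` is an (L, 3) array of per-level ROI channel means,
    sufficient for the grid search (the score is linear in the channels).
    When the original ROIs are kept, winning triples are re-scored on the
    raw pixel arrays.
    """

    concentrations: np.ndarray
    channel_means: np.ndarray
    rois: list | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=np.float64)
        self.channel_means = np.asarray(self.channel_means, dtype=np.float64)
        if self.concentrations.ndim != 1:
            raise ValueError("concentrations must be 1-D")
        if self.channel_means.shape != (self.concentrations.size, 3):
            raise ValueError("channel_means must be (n_levels, 3)")
        if (self.concentrations < 0).any():
            raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_rois(cls, pairs: Sequence[tuple[float, RoiSelection]]) -> "ConcentrationSeries":
        concs = [c for c, _ in pairs]
        rois = [r for _, r in pairs]
        means = np.array([r.channel_means for r in rois])
        return cls(np.array(concs), means, rois=rois)

    @classmethod
    def from_means(cls, pairs: Sequence[tuple[float, Sequence[float]]]) -> "ConcentrationSeries":
        concs = [c for c, _ in pairs]
        means = np.array([list(m) for _, m in pairs])
        return cls(np.array(concs), means)

    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)

    def scores_for(self, weights) -> np.ndarray:
        """Per-level RGBscores under one weight triple."""
        if self.rois is not None:
            return np.array([rgbscore(r, weights) for r in self.rois])
        w = np.asarray(list(weights), dtype=np.float64)
        return self.channel_means @ w


@dataclass
class CalibrationModel:
    """A winning weight triple with its fitted regression model."""

    weights: WeightTriple
    fit: RegressionFit
    scores: list  # [(concentration, rgbscore), ...]
    metadata: dict = field(default_factory=dict)

    @property
    def concentration_range(self) -> tuple[float, float]:
        concs = [c for c, _ in self.scores]
        return (min(concs), max(concs))

    @property
    def score_range(self) -> tuple[float, float]:
        """Score interval covered by the fitted curve over the calibrated
        concentration range (the invertible interval for quantification)."""
        lo, hi = self.concentration_range
        y = self.fit.predict(np.array([lo, hi]))
        return (float(min(y)), float(max(y)))

    def to_dict(self) -> dict:
        return {
            "weights": [self.weights.alpha, self.weights.beta, self.weights.gamma],
            "fit": self.fit.to_dict(),
            "scores": [[float(c), float(s)] for c, s in self.scores],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            weights=WeightTriple(*d["weights"]),
            fit=RegressionFit.from_dict(d["fit"]),
            scores=[(c, s) for c, s in d["scores"]],
            metadata=d.get("metadata", {}),
        )


@dataclass
class GridSearchResult:
    """Per-model winners plus the overall selected calibration."""

    per_model: dict
    best_kind: str

    @property
    def best(self) -> CalibrationModel:
        return self.per_model[self.best_kind]

    def table(self) -> list[dict]:
        """Rows shaped like the published per-model summary:
        model | alpha | beta | gamma | R^2."""
        return [
            {
                "model": kind,
                "alpha": m.weights.alpha,
                "beta": m.weights.beta,
                "gamma": m.weights.gamma,
                "r_squared": m.fit.r_squared,
            }
            for kind, m in self.per_model.items()
        ]


def weight_grid(step: float = 0.05, lo: float = -1.0, hi: float = 1.0) -> np.ndarray:
    """All weight triples k*step on [lo, hi]^3 except (0, 0, 0), in
    lexicographic (alpha-major) order.

    Grid values are integer multiples of the step so repeated addition
    cannot drift.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lo >= hi:
        raise ValueError("grid range must satisfy lo < hi")
    n_steps = (hi - lo) / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must divide the grid range evenly")
    k_lo = round(lo / step)
    if abs(k_lo * step - lo) > 1e-9:
        raise ValueError("grid bounds must be integer multiples of the step")
    ks = np.arange(k_lo, k_lo + round(n_steps) + 1)
    vals = ks * step
    m = vals.size
    A = np.repeat(vals, m * m)
    B = np.tile(np.repeat(vals, m), m)
    C = np.tile(vals, m * m)
    W = np.column_stack([A, B, C])
    nonzero = ~(
        (np.repeat(ks, m * m) == 0)
        & (np.tile(np.repeat(ks, m), m) == 0)
        & (np.tile(ks, m * m) == 0)
    )
    return W[nonzero]


def coefficient_grid_search(
    series: ConcentrationSeries,
    models: Sequence[str] = MODEL_KINDS,
    step: float = 0.05,
    grid_range: tuple[float, float] = (-1.0, 1.0),
    tie_round: int = 6,
    select_round: int = 3,
) -> GridSearchResult:
    """Brute-force search for the best weight triple under each model.

    Per model, triples are ranked by R^2 rounded to ``tie_round`` decimals;
    ties go to the lexicographically smallest (alpha, beta, gamma).  The
    overall winner is the per-model winner with the highest R^2 rounded to
    ``select_round`` decimals, ties resolved toward the model with fewer
    parameters (linear, then logarithmic, then logistic4): R^2 differences
    below that rounding are not meaningful on a handful of calibration
    levels, and the four-parameter logistic can approximate any near-affine
    or near-logarithmic series arbitrarily well, so raw maximization would
    never prefer a simpler curve.
    """
    models = tuple(models)
    if not models:
        raise ValueError("at least one regression model must be requested")
    for kind in models:
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
    if series.n_distinct() < 3:
        raise ValueError("calibration needs at least 3 distinct concentration levels")

    x = series.concentrations
    W = weight_grid(step, *grid_range)
    S = W @ series.channel_means.T  # (n_triples, n_levels)
    logger.info("grid search: %d triples x %d levels, models=%s", W.shape[0], x.size, models)

    per_model: dict[str, CalibrationModel] = {}
    for kind in models:
        r2 = fit_batch(kind, x, S)
        r2 = np.where(np.isnan(r2), -np.inf, r2)
        rounded = np.round(r2, tie_round)
        idx = int(np.argmax(rounded))  # first max = lexicographically smallest triple
        w = WeightTriple(*(float(v) for v in W[idx]))
        scores = series.scores_for(w)
        fit = fit_model(kind, x, scores)
        logger.info("  %s winner (%.3f, %.3f, %.3f) R^2=%.6f",
                    kind, w.alpha, w.beta, w.gamma, fit.r_squared)
        per_model[kind] = CalibrationModel(
            weights=w,
            fit=fit,
            scores=list(zip(x.tolist(), scores.tolist())),
            metadata={
                "grid_step": step,
                "grid_range": list(grid_range),
                "n_triples": int(W.shape[0]),
                "tie_round": tie_round,
                "tie_break": "R^2 rounded, lexicographically smallest triple",
            },
        )

    best_kind = None
    best_rounded = -np.inf
    for kind in MODEL_KINDS:  # canonical parsimony order
        if kind not in per_model:
            continue
        rounded = round(per_model[kind].fit.r_squared, select_round)
        if rounded > best_rounded:
            best_rounded = rounded
            best_kind = kind
    return GridSearchResult(per_model=per_model, best_kind=best_kind)
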