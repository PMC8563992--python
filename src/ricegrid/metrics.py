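"""Stand-uniformity index, detection scores and location-error statistics.

The heterogeneity index of a stand is the coefficient of variation of the
occupied (Voronoi cell) areas x_1..x_n:

    CV = sigma / xbar,   sigma = sqrt( sum (x_i - xbar)^2 / n )

with the population divisor n.  CV is 0 for a perfect lattice and ~0.5 for a
completely random layout; the uniformity index is its reciprocal, with the
perfectly uniform case (CV = 0) reported as a distinguished flag rather than
infinity.

Detection quality uses the confusion counts of point matching, with the
convention TN = 0 (there is no meaningful "true negative" location):

    precision = TP/(TP+FP)      recall = TP/(TP+FN)
    accuracy  = (TP+FN)/(TP+FP+TN+FN)      F1 = harmonic mean

Note the accuracy formula is deliberately nonstandard (numerator TP+FN); it
is implemented exactly as defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .detection import ClusterSet
from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedMetricError,
    UnitMismatchError,
)

__all__ = [
    "AreaSample",
    "HeterogeneityResult",
    "ConfusionCounts",
    "DetectionEval",
    "MatchResult",
    "LocationErrorSummary",
    "GammaFit",
    "PERFECTLY_UNIFORM",
    "heterogeneity_cv",
    "uniformity_index",
    "match_positions",
    "detection_scores",
    "location_errors",
    "fit_gamma",
    "relative_error",
    "round_half_up",
]


class _PerfectlyUniform:
    """Sentinel for CV = 0: uniformity has no finite value."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PERFECTLY_UNIFORM"


PERFECTLY_UNIFORM = _PerfectlyUniform()


@dataclass(frozen=True)
class AreaSample:
    """Positive cell areas entering the heterogeneity index."""

    areas: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.areas, dtype=float).ravel()
        object.__setattr__(self, "areas", a)

    @property
    def n(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class HeterogeneityResult:
    mean: float
    sigma: float
    cv: float
    n: int

    @property
    def perfectly_uniform(self) -> bool:
        return self.cv == 0.0

    @property
    def uniformity(self):
        return uniformity_index(self)


def heterogeneity_cv(sample: AreaSample | np.ndarray) -> HeterogeneityResult:
    """Coefficient of variation of cell areas (population sigma, divisor n)."""
    areas = sample.areas if isinstance(sample, AreaSample) else np.asarray(sample, dtype=float)
    areas = areas.ravel()
    if len(areas) == 0:
        raise InvalidInputError("empty area sample")
    mean = float(areas.mean())
    if mean <= 0:
        raise InvalidInputError("mean area must be positive")
    sigma = float(np.sqrt(np.mean((areas - mean) ** 2)))
    return HeterogeneityResult(mean=mean, sigma=sigma, cv=sigma / mean, n=len(areas))


def uniformity_index(result: HeterogeneityResult | float):
    """Reciprocal CV; returns the PERFECTLY_UNIFORM sentinel when CV = 0."""
    cv = result.cv if isinstance(result, HeterogeneityResult) else float(result)
    if cv < 0:
        raise InvalidInputError("cv must be non-negative")
    if cv == 0.0:
        return PERFECTLY_UNIFORM
    return 1.0 / cv


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise InvalidInputError("confusion counts must be non-negative")


@dataclass(frozen=True)
class DetectionEval:
    precision: float
    accuracy: float
    recall: float
    f1: float


@dataclass(frozen=True)
class MatchResult:
    """One-to-one nearest matching of detected to true positions."""

    pairs: tuple[tuple[int, int, float], ...]  # (detected_idx, truth_idx, distance)
    counts: ConfusionCounts
    units: str = "px"


def _positions(obj) -> tuple[np.ndarray, str | None]:
    if isinstance(obj, ClusterSet):
        return obj.positions, obj.units
    return np.asarray(obj, dtype=float).reshape(-1, 2), None


def match_positions(detected, truth, max_dist: float) -> MatchResult:
    """Greedy globally-nearest one-to-one matching under a distance gate.

    Candidate pairs within ``max_dist`` are accepted in order of increasing
    distance (ties broken by lowest detected, then truth index); each point
    participates in at most one pair.  TP = matched pairs, FP = unmatched
    detections, FN = unmatched truths, TN = 0 by convention.
    """
    if max_dist <= 0:
        raise InvalidParameterError("max_dist must be positive")
    det, u1 = _positions(detected)
    tru, u2 = _positions(truth)
    if u1 is not None and u2 is not None and u1 != u2:
        raise UnitMismatchError(f"detected in {u1!r} but truth in {u2!r}")
    units = u1 or u2 or "px"

    pairs: list[tuple[int, int, float]] = []
    if len(det) and len(tru):
        d = cdist(det, tru)
        di, tj = np.nonzero(d <= max_dist)
        order = np.lexsort((tj, di, d[di, tj]))
        used_d = np.zeros(len(det), dtype=bool)
        used_t = np.zeros(len(tru), dtype=bool)
        for k in order:
            i, j = int(di[k]), int(tj[k])
            if not used_d[i] and not used_t[j]:
                used_d[i] = used_t[j] = True
                pairs.append((i, j, float(d[i, j])))
    counts = ConfusionCounts(
        TP=len(pairs), FP=len(det) - len(pairs), FN=len(tru) - len(pairs), TN=0
    )
    return MatchResult(pairs=tuple(pairs), counts=counts, units=units)


def detection_scores(counts: ConfusionCounts) -> DetectionEval:
    """Precision, accuracy, recall and F1 from confusion counts (TN = 0 convention)."""
    tp, fp, fn, tn = counts.TP, counts.FP, counts.FN, counts.TN
    if tp + fp == 0:
        raise UndefinedMetricError("precision")
    if tp + fn == 0:
        raise UndefinedMetricError("recall")
    if tp + fp + tn + fn == 0:
        raise UndefinedMetricError("accuracy")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    accuracy = (tp + fn) / (tp + fp + tn + fn)
    if precision + recall == 0:
        raise UndefinedMetricError("f1")
    f1 = 2 * precision * recall / (precision + recall)
    return DetectionEval(precision=precision, accuracy=accuracy, recall=recall, f1=f1)


@dataclass(frozen=True)
class LocationErrorSummary:
    """Distances between matched detected/true positions, in centimetres."""

    errors: np.ndarray
    mean_error: float | None

    @property
    def n(self) -> int:
        return len(self.errors)


def location_errors(match: MatchResult, gsd: float) -> LocationErrorSummary:
    """Matched pixel distances converted to ground centimetres by the image scale."""
    if gsd <= 0:
        raise InvalidParameterError("gsd must be positive")
    errs = np.array([p[2] for p in match.pairs], dtype=float) * gsd
    mean = float(errs.mean()) if len(errs) else None
    return LocationErrorSummary(errors=errs, mean_error=mean)


@dataclass(frozen=True)
class GammaFit:
    shape: float
    scale: float
    mean: float  # shape * scale
    sample_mean: float


def fit_gamma(errors) -> GammaFit:
    """Maximum-likelihood gamma fit (location fixed at zero) to error distances."""
    errs = np.asarray(errors, dtype=float).ravel()
    if len(errs) < 10:
        raise InsufficientDataError("gamma fit needs at least 10 observations")
    if np.any(errs <= 0):
        raise InvalidInputError("gamma support requires strictly positive values")
    if np.ptp(errs) == 0:
        raise DegenerateDataError("zero-variance sample: gamma shape diverges")
    shape, _, scale = stats.gamma.fit(errs, floc=0)
    return GammaFit(
        shape=float(shape),
        scale=float(scale),
        mean=float(shape * scale),
        sample_mean=float(errs.mean()),
    )


def relative_error(a: float, b: float) -> float:
    """|a - b| / |b|, the agreement measure between two index estimates."""
    if b == 0:
        raise InvalidParameterError("reference value must be non-zero")
    return abs(a - b) / abs(b)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding used when comparing against reported tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
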