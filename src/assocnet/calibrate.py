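"""Benchmark calibration of raw evidence scores into confidences.

Raw evidence scores (e.g. aggregated text-mining support for a directed
regulatory pair) are unitless; to become confidence scores they are
benchmarked against a gold standard of known interactions.  The pipeline:

1. **label** scored predictions against the gold standard — pairs in the
   positive set are positives; a seeded sample of scored non-positive pairs
   (``negative_ratio`` per positive) serves as negatives; the rest stay
   unknown and are excluded from fitting;
2. **sliding-window precision** — sort by raw score descending and record,
   for each window of labelled predictions, the fraction of positives at
   the window's median raw score;
3. **isotonic fit** — pool-adjacent-violators least-squares regression of
   precision on raw score, yielding a monotone non-decreasing calibration
   curve;
4. **apply** — linear interpolation between curve knots, clamped to the
   end values, mapping every raw score (labelled or not) to a confidence
   in [0, 1].

One curve is fitted per benchmark category (regulation, upregulation,
downregulation, transcriptional regulation, phosphorylation) and applied
to extracted relations of all action types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .network import ActionType, RegulatoryEdge

GOLD_CATEGORIES = (
    "regulation",
    "upregulation",
    "downregulation",
    "transcriptional regulation",
    "phosphorylation",
)


@dataclass
class GoldStandard:
    """Known positive directed pairs within a gene universe."""

    category: str
    positives: frozenset[tuple[str, str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in GOLD_CATEGORIES:
            raise InvalidParameterError(
                f"category must be one of {GOLD_CATEGORIES}, got {self.category!r}"
            )
        self.positives = frozenset(tuple(p) for p in self.positives)
        self.universe = frozenset(self.universe)
        for a, b in self.positives:
            if a == b:
                raise InvalidInputError(f"gold standard contains self-pair {a!r}")
            if a not in self.universe or b not in self.universe:
                raise InvalidInputError(f"gold pair ({a}, {b}) outside the universe")


@dataclass
class ScoredPrediction:
    """A directed pair with a raw evidence score and a benchmark label."""

    source: str
    target: str
    raw: float
    label: str = "unknown"
    action_type: ActionType = ActionType.REGULATION
    sign: str = "unspecified"

    def __post_init__(self) -> None:
        if not np.isfinite(self.raw):
            raise InvalidInputError("raw score must be finite")
        if self.label not in ("positive", "negative", "unknown"):
            raise InvalidInputError(f"invalid label {self.label!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class CalibrationCurve:
    """Monotone map raw score → confidence, as knots + values."""

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knots.size == 0:
            raise InvalidInputError("calibration curve needs at least one knot")
        if self.knots.size != self.values.size:
            raise InvalidInputError("knots and values must have equal length")
        if (np.diff(self.knots) <= 0).any():
            raise InvalidInputError("knots must be strictly ascending")
        if (np.diff(self.values) < -1e-12).any():
            raise InvalidInputError("curve values must be non-decreasing")
        if (self.values < 0).any() or (self.values > 1).any():
            raise InvalidInputError("curve values must lie in [0, 1]")


def label_predictions(
    predictions: Sequence[ScoredPrediction],
    gold: GoldStandard,
    negative_ratio: float = 10.0,
    seed: int = 0,
) -> list[ScoredPrediction]:
    """Label predictions against a gold standard.

    Predictions whose ordered pair is in ``gold.positives`` are labelled
    positive.  Negatives are a seeded uniform sample (without replacement)
    of the *scored* non-positive pairs, ``negative_ratio`` per positive;
    remaining predictions stay unknown.  Raises when the candidate pool is
    too small for the requested number of negatives.
    """
    if negative_ratio < 0:
        raise InvalidParameterError("negative_ratio must be >= 0")
    for pred in predictions:
        if pred.source not in gold.universe or pred.target not in gold.universe:
            raise InvalidInputError(
                f"prediction pair {pred.pair} outside the gold universe"
            )
    labelled = [replace(p) for p in predictions]
    pos_idx = [i for i, p in enumerate(labelled) if p.pair in gold.positives]
    candidate_idx = [i for i, p in enumerate(labelled) if p.pair not in gold.positives]
    n_neg = int(round(negative_ratio * len(pos_idx)))
    if n_neg > len(candidate_idx):
        raise InvalidParameterError(
            f"universe of scored non-positive pairs too small: need {n_neg} negatives, "
            f"have {len(candidate_idx)} candidates"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(candidate_idx), size=n_neg, replace=False) if n_neg else []
    for i in pos_idx:
        labelled[i].label = "positive"
    for j in neg_idx:
        labelled[candidate_idx[int(j)]].label = "negative"
    return labelled


def sliding_window_precision(
    labelled: Sequence[ScoredPrediction],
    window: int = 100,
    step: int = 50,
) -> list[tuple[float, float]]:
    """Precision in sliding windows over the labelled predictions.

    Sorted by raw score descending, each window of ``window`` labelled
    predictions (advancing by ``step``) yields one point: (median raw score
    of the window, fraction of positives).  A window wider than the data
    collapses to a single whole-set point.  Points are returned in
    ascending raw-score order.
    """
    if window < 2:
        raise InvalidParameterError("window must be >= 2")
    if step < 1:
        raise InvalidParameterError("step must be >= 1")
    used = [p for p in labelled if p.label != "unknown"]
    if not used:
        raise InvalidInputError("no labelled predictions to benchmark")
    used.sort(key=lambda p: (-p.raw, p.source, p.target))
    raws = np.array([p.raw for p in used])
    hits = np.array([p.label == "positive" for p in used], dtype=float)
    n = len(used)
    points: list[tuple[float, float]] = []
    if window > n:
        points.append((float(np.median(raws)), float(hits.mean())))
    else:
        for start in range(0, n - window + 1, step):
            sl = slice(start, start + window)
            points.append((float(np.median(raws[sl])), float(hits[sl].mean())))
    points.sort(key=lambda t: t[0])
    return points


def _pava(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares isotonic regression (pool adjacent violators)."""
    n = y.size
    means = list(y.astype(float))
    weights = list(w.astype(float))
    counts = [1] * n
    i = 0
    while i < len(means) - 1:
        if means[i] > means[i + 1] + 1e-15:
            total_w = weights[i] + weights[i + 1]
            merged = (means[i] * weights[i] + means[i + 1] * weights[i + 1]) / total_w
            means[i : i + 2] = [merged]
            weights[i : i + 2] = [total_w]
            counts[i : i + 2] = [counts[i] + counts[i + 1]]
            if i > 0:
                i -= 1
        else:
            i += 1
    out = np.empty(n)
    pos = 0
    for mean, count in zip(means, counts):
        out[pos : pos + count] = mean
        pos += count
    return out


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Isotonic least-squares fit of precision vs raw score.

    Points are sorted by raw score; duplicate raw values are merged by
    averaging their precisions before the pool-adjacent-violators pass.
    """
    if not points:
        raise InvalidInputError("need at least one precision point")
    pts = sorted((float(x), float(y)) for x, y in points)
    knots: list[float] = []
    ys: list[float] = []
    ws: list[float] = []
    for x, y in pts:
        if knots and x == knots[-1]:
            ws[-1] += 1.0
            ys[-1] += (y - ys[-1]) / ws[-1]
        else:
            knots.append(x)
            ys.append(y)
            ws.append(1.0)
    fitted = _pava(np.array(ys), np.array(ws))
    fitted = np.clip(fitted, 0.0, 1.0)
    return CalibrationCurve(np.array(knots), fitted)


def apply_calibration(curve: CalibrationCurve, raw) -> np.ndarray | float:
    """Interpolate the curve at raw score(s), clamped to the end values."""
    result = np.interp(np.asarray(raw, dtype=float), curve.knots, curve.values)
    if np.ndim(raw) == 0:
        return float(result)
    return result


def calibrate_category(
    predictions: Sequence[ScoredPrediction],
    gold: GoldStandard,
    negative_ratio: float = 10.0,
    window: int = 100,
    step: int = 50,
    seed: int = 0,
) -> tuple[CalibrationCurve, list[RegulatoryEdge]]:
    """Full pipeline: label → window precision → isotonic fit → apply.

    Returns the fitted curve (reusable across action types) and one
    calibrated regulatory edge per prediction; unknown-labelled predictions
    are excluded from fitting but still receive calibrated confidences.
    Confidences of exactly 0 are nudged to a tiny positive floor so every
    edge keeps the at-least-one-direction-positive invariant.
    """
    labelled = label_predictions(predictions, gold, negative_ratio, seed)
    points = sliding_window_precision(labelled, window, step)
    curve = fit_calibration(points)
    edges = []
    for pred in predictions:
        conf = float(apply_calibration(curve, pred.raw))
        edges.append(
            RegulatoryEdge(
                pred.source,
                pred.target,
                pred.action_type,
                pred.sign,
                confidence_forward=max(conf, 1e-9),
            )
        )
    return curve, edges
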