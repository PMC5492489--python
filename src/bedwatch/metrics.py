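"""Event matching, confusion accounting and evaluation metrics.

Per event type the engine's detections are matched one-to-one against the
manually recorded (actual) events within a frame tolerance; unmatched
detections are false positives and unmatched actual events false negatives.
True-negative counts are evaluation *opportunities* without an event and
must be supplied by the caller (they come from the recording protocol, not
from the frames).

Metrics are the usual confusion-based proportions — accuracy, precision,
sensitivity, specificity — reported as percentages rounded half-up to two
decimals, with the false positive/negative rates defined as the exact
complements of specificity and sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .classify import FrameClassification
from .io import EventRecord, EventType, FrameLabel, Location, Posture


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]


def pct(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Exact rational percentage rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    q = Decimal(1).scaleb(-ndigits)
    value = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


def metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, sensitivity, specificity, FPR and FNR (percent).

    Ratios whose denominator is zero are returned as ``None``.  The false
    positive/negative rates are computed as 100 minus the rounded
    specificity/sensitivity, so the complement identities hold exactly.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    accuracy = pct(c.tp + c.tn, c.total)
    precision = pct(c.tp, c.tp + c.fp) if c.tp + c.fp else None
    sensitivity = pct(c.tp, c.tp + c.fn) if c.tp + c.fn else None
    specificity = pct(c.tn, c.tn + c.fp) if c.tn + c.fp else None
    fpr = round(100.0 - specificity, 2) if specificity is not None else None
    fnr = round(100.0 - sensitivity, 2) if sensitivity is not None else None
    return MetricSet(accuracy, precision, sensitivity, specificity, fpr, fnr)


def match_events(
    actual: Sequence[EventRecord],
    detected: Sequence[EventRecord],
    tolerance: int = 15,
    negatives: Union[int, Mapping[EventType, int]] = 0,
) -> Dict[EventType, ConfusionCounts]:
    """Greedy one-to-one matching of detections to actual events per type.

    Events match when they share a type and their frame indices differ by
    at most ``tolerance`` frames.  ``negatives`` supplies the per-type count
    of non-event opportunities (the TN column).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")

    def tn_for(t: EventType) -> int:
        if isinstance(negatives, Mapping):
            return int(negatives.get(t, 0))
        return int(negatives)

    types = {e.type for e in actual} | {e.type for e in detected}
    if isinstance(negatives, Mapping):
        types |= set(negatives)
    out: Dict[EventType, ConfusionCounts] = {}
    for t in types:
        act = sorted((e.frame_index for e in actual if e.type is t))
        det = sorted((e.frame_index for e in detected if e.type is t))
        used = [False] * len(det)
        tp = 0
        for a in act:
            for j, d in enumerate(det):
                if not used[j] and abs(d - a) <= tolerance:
                    used[j] = True
                    tp += 1
                    break
        out[t] = ConfusionCounts(
            tp=tp, fp=len(det) - tp, fn=len(act) - tp, tn=tn_for(t)
        )
    return out


# -- frame-level classification accounting ------------------------------


@dataclass(frozen=True)
class ClassificationReport:
    location_matrix: np.ndarray  # rows: truth, cols: predicted (class order)
    posture_matrix: np.ndarray
    location_classes: Tuple[str, ...]
    posture_classes: Tuple[str, ...]
    n: int
    location_rate: float  # percent, 2 decimals
    posture_rate: float
    joint_rate: float     # both location and posture correct


def classification_report(
    pred: Sequence[FrameClassification], truth: Sequence[FrameLabel]
) -> ClassificationReport:
    """Confusion matrices and correct-recognition rates for aligned frames."""
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    if not pred:
        raise ValueError("empty inputs")
    loc_classes = [l.value for l in Location]
    pos_classes = [p.value for p in Posture]
    loc_m = np.zeros((len(loc_classes), len(loc_classes)), dtype=int)
    pos_m = np.zeros((len(pos_classes), len(pos_classes)), dtype=int)
    joint = 0
    for p, t in zip(pred, truth):
        if p.index != t.index:
            raise ValueError(f"index mismatch: predicted {p.index}, truth {t.index}")
        loc_m[loc_classes.index(t.location.value), loc_classes.index(p.location.value)] += 1
        pos_m[pos_classes.index(t.posture.value), pos_classes.index(p.posture.value)] += 1
        if p.location is t.location and p.posture is t.posture:
            joint += 1
    n = len(pred)
    return ClassificationReport(
        location_matrix=loc_m,
        posture_matrix=pos_m,
        location_classes=tuple(loc_classes),
        posture_classes=tuple(pos_classes),
        n=n,
        location_rate=pct(int(np.trace(loc_m)), n),
        posture_rate=pct(int(np.trace(pos_m)), n),
        joint_rate=pct(joint, n),
    )


def overall_rate(matrix: Sequence[Sequence[int]], ndigits: int = 2) -> float:
    """Diagonal fraction of a square confusion matrix, as a percentage."""
    m = np.asarray(matrix, dtype=int)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("confusion matrix must be square")
    return pct(int(np.trace(m)), int(m.sum()), ndigits)


def best_of_rate(
    correct_by_class: Mapping[str, Mapping[str, int]],
    total: int,
    ndigits: int = 2,
) -> float:
    """Combined recognition rate picking, per class, the best algorithm.

    ``correct_by_class`` maps algorithm name -> class name -> correct count;
    the best count per class is summed and divided by ``total``.
    """
    classes = set()
    for counts in correct_by_class.values():
        classes |= set(counts)
    best_sum = sum(
        max(counts.get(c, 0) for counts in correct_by_class.values())
        for c in sorted(classes)
    )
    return pct(best_sum, total, ndigits)
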