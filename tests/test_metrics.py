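"""Event matching, metric arithmetic and classification accounting."""

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from itertools import permutations

import numpy as np
import pytest

from bedwatch.classify import FrameClassification
from bedwatch.io import EventRecord, EventType, FrameLabel, Location, Posture
from bedwatch.metrics import (
    ConfusionCounts,
    best_of_rate,
    classification_report,
    match_events,
    metrics,
    overall_rate,
    pct,
)


class TestMetrics:
    def test_perfect_small_case(self):
        m = metrics(ConfusionCounts(tp=1, tn=1, fp=0, fn=0))
        assert (m.accuracy, m.precision, m.sensitivity, m.specificity) == (
            100.0,
            100.0,
            100.0,
            100.0,
        )
        assert (m.fpr, m.fnr) == (0.0, 0.0)

    def test_fall_style_counts(self):
        m = metrics(ConfusionCounts(tp=26, tn=117, fp=2, fn=0))
        assert m.accuracy == 98.62
        assert m.precision == 92.86
        assert m.sensitivity == 100.0
        assert m.specificity == 98.32
        assert m.fpr == 1.68
        assert m.fnr == 0.0

    def test_bed_exit_style_counts(self):
        m = metrics(ConfusionCounts(tp=22, tn=126, fp=1, fn=4))
        assert m.accuracy == 96.73
        assert m.sensitivity == 84.62
        assert m.precision == 95.65
        assert m.specificity == 99.21

    def test_zero_denominators_return_sentinel(self):
        m = metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.precision is None and m.sensitivity is None
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())

    def test_complement_identities_on_random_counts(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 200, size=4))
            if tp + fp + tn + fn == 0:
                continue
            m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            if m.specificity is not None:
                assert m.fpr == pytest.approx(100.0 - m.specificity, abs=1e-9)
            if m.sensitivity is not None:
                assert m.fnr == pytest.approx(100.0 - m.sensitivity, abs=1e-9)
            for v in (m.accuracy, m.precision, m.sensitivity, m.specificity, m.fpr, m.fnr):
                assert v is None or 0.0 <= v <= 100.0

    def test_matches_rational_arithmetic_oracle(self, rng):
        def oracle(num, den):
            frac = Fraction(num * 100, den)
            return float(
                (Decimal(frac.numerator) / Decimal(frac.denominator)).quantize(
                    Decimal("0.01"), rounding=ROUND_HALF_UP
                )
            )

        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 500, size=4))
            total = tp + fp + tn + fn
            if total == 0:
                continue
            m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert m.accuracy == oracle(tp + tn, total)
            if tp + fp:
                assert m.precision == oracle(tp, tp + fp)
            if tp + fn:
                assert m.sensitivity == oracle(tp, tp + fn)
            if tn + fp:
                assert m.specificity == oracle(tn, tn + fp)


def ev(t, i):
    return EventRecord(t, i)


class TestMatching:
    def test_identical_lists_all_true_positive(self):
        actual = [ev(EventType.FALL, 10), ev(EventType.FALL, 60), ev(EventType.BED_EXIT, 60)]
        counts = match_events(actual, list(actual), tolerance=15)
        assert counts[EventType.FALL] == ConfusionCounts(tp=2, fp=0, tn=0, fn=0)
        assert counts[EventType.BED_EXIT].tp == 1

    def test_offset_within_tolerance_matches(self):
        counts = match_events([ev(EventType.FALL, 100)], [ev(EventType.FALL, 103)], 15)
        assert counts[EventType.FALL].tp == 1
        counts = match_events([ev(EventType.FALL, 100)], [ev(EventType.FALL, 130)], 15)
        assert counts[EventType.FALL] == ConfusionCounts(tp=0, fp=1, tn=0, fn=1)

    def test_spurious_detection_counts_as_fp(self):
        counts = match_events([], [ev(EventType.AREA_EXIT, 7)], 15, negatives=9)
        assert counts[EventType.AREA_EXIT] == ConfusionCounts(tp=0, fp=1, tn=9, fn=0)

    def test_translation_invariance(self, rng):
        actual = [ev(EventType.FALL, int(i)) for i in sorted(rng.integers(0, 500, 8))]
        detected = [ev(EventType.FALL, int(i)) for i in sorted(rng.integers(0, 500, 8))]
        base = match_events(actual, detected, 15)
        shifted = match_events(
            [ev(e.type, e.frame_index + 1000) for e in actual],
            [ev(e.type, e.frame_index + 1000) for e in detected],
            15,
        )
        assert base == shifted

    def test_greedy_matches_exhaustive_bipartite_oracle(self, rng):
        # optimal one-to-one matching found by trying every assignment
        def oracle_tp(act, det, tol):
            best = 0
            for perm in permutations(range(len(det))):
                tp = 0
                for i, a in enumerate(act):
                    if i < len(perm) and abs(det[perm[i]] - a) <= tol:
                        tp += 1
                best = max(best, tp)
            return best

        for _ in range(40):
            act = sorted(int(v) for v in rng.integers(0, 60, size=rng.integers(0, 5)))
            det = sorted(int(v) for v in rng.integers(0, 60, size=rng.integers(0, 5)))
            n = max(len(act), len(det))
            act_p, det_p = act + [10**6] * (n - len(act)), det + [-(10**6)] * (n - len(det))
            counts = match_events(
                [ev(EventType.FALL, i) for i in act],
                [ev(EventType.FALL, i) for i in det],
                tolerance=10,
            )
            got_tp = counts.get(EventType.FALL, ConfusionCounts()).tp
            assert got_tp == oracle_tp(act_p, det_p, 10)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_events([], [], tolerance=-1)


class TestClassificationReport:
    def test_identical_predictions_are_perfect(self):
        truth = [
            FrameLabel(i, Location.FLOOR, Posture.STANDING) for i in range(20)
        ]
        pred = [FrameClassification(i, Location.FLOOR, Posture.STANDING) for i in range(20)]
        report = classification_report(pred, truth)
        assert report.location_rate == 100.0
        assert report.joint_rate == 100.0
        assert np.trace(report.location_matrix) == 20

    def test_mixed_predictions_counted_per_class(self):
        truth = [
            FrameLabel(0, Location.BED, Posture.LAYING),
            FrameLabel(1, Location.BED, Posture.LAYING),
            FrameLabel(2, Location.FLOOR, Posture.SITTING),
            FrameLabel(3, Location.NONE, Posture.NONE),
        ]
        pred = [
            FrameClassification(0, Location.BED, Posture.LAYING),
            FrameClassification(1, Location.BEDRAIL, Posture.LAYING),
            FrameClassification(2, Location.FLOOR, Posture.LAYING),
            FrameClassification(3, Location.NONE, Posture.NONE),
        ]
        report = classification_report(pred, truth)
        assert report.location_rate == 75.0
        assert report.posture_rate == 75.0
        assert report.joint_rate == 50.0

    def test_overall_rate_of_diagonal_matrix(self):
        assert overall_rate([[3, 0], [0, 1]]) == 100.0
        assert overall_rate([[3, 1], [0, 0]]) == 75.0

    def test_best_of_rate_picks_max_per_class(self):
        counts = {
            "a": {"x": 10, "y": 0},
            "b": {"x": 5, "y": 8},
        }
        assert best_of_rate(counts, total=20) == 90.0  # (10 + 8) / 20


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=300, derandomize=True)
    @given(
        tp=st.integers(0, 10**6),
        fp=st.integers(0, 10**6),
        tn=st.integers(0, 10**6),
        fn=st.integers(0, 10**6),
    )
    def test_metric_identities_property(tp, fp, tn, fn):
        """FPR and FNR are exact complements of specificity and sensitivity
        for every realizable confusion vector."""
        if tp + fp + tn + fn == 0:
            return
        m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        if m.specificity is not None:
            assert m.fpr == pytest.approx(100.0 - m.specificity, abs=1e-9)
            assert 0.0 <= m.fpr <= 100.0
        if m.sensitivity is not None:
            assert m.fnr == pytest.approx(100.0 - m.sensitivity, abs=1e-9)
            assert 0.0 <= m.fnr <= 100.0

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_pct_rounds_half_up():
    assert pct(1, 8) == 12.5
    assert pct(1, 3) == 33.33
    assert pct(5, 8, 1) == 62.5
    assert pct(1, 800) == 0.13  # 0.125 rounds up
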