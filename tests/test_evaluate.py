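"""Confusion metrics, alarm rates, event matching and the persistence filter."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from falldetect import (
    AlarmEvent,
    ConfusionMatrix,
    StatusLabel,
    UndefinedMetricError,
    UndefinedRateError,
    alarm_rates,
    class_metrics,
    coma_persistence_filter,
    confusion_matrix,
    event_report,
    f1,
    windows_to_alarms,
)

FALL, STUMBLE, COMA = StatusLabel.FALL, StatusLabel.STUMBLE, StatusLabel.COMA


class TestConfusionMatrix:
    def test_equal_sequences_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 2, 1])
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag([1, 2, 2, 1]))

    def test_single_disagreeing_pair(self):
        cm = confusion_matrix([0], [1])
        assert cm.counts[0, 1] == 1 and cm.total == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 4, 1000)
        pred = rng.integers(0, 4, 1000)
        cm = confusion_matrix(truth, pred)
        for i in range(4):
            for j in range(4):
                assert cm.counts[i, j] == int(
                    sum(1 for t, p in zip(truth, pred) if t == i and p == j)
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 0]]))


class TestClassMetrics:
    def test_worked_safe_row_recall(self):
        # five predicted columns for the safe row of a row-normalized display
        row = [23292, 8, 8, 89, 1278]
        counts = np.zeros((5, 5), dtype=int)
        counts[0] = row
        counts[1, 1] = counts[2, 2] = counts[3, 3] = counts[4, 4] = 1
        cm = ConfusionMatrix(counts)
        assert round(cm.row_recall(0), 2) == 0.94

    def test_perfect_diagonal_all_ones(self):
        cm = confusion_matrix([0, 1, 2, 3], [0, 1, 2, 3])
        for c in range(4):
            m = class_metrics(cm, c)
            assert (m.accuracy, m.precision, m.recall, m.specificity, m.f1) \
                == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_matches_per_pair_tally_oracle(self):
        rng = np.random.default_rng(1)
        truth = rng.integers(0, 4, 400)
        pred = rng.integers(0, 4, 400)
        cm = confusion_matrix(truth, pred)
        for cls in range(4):
            tp = sum(1 for t, p in zip(truth, pred) if t == cls and p == cls)
            fp = sum(1 for t, p in zip(truth, pred) if t != cls and p == cls)
            fn = sum(1 for t, p in zip(truth, pred) if t == cls and p != cls)
            tn = len(truth) - tp - fp - fn
            m = class_metrics(cm, cls)
            assert m.accuracy == pytest.approx((tp + tn) / len(truth))
            assert m.precision == pytest.approx(tp / (tp + fp))
            assert m.recall == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))

    def test_empty_matrix_undefined(self):
        with pytest.raises(UndefinedMetricError):
            class_metrics(confusion_matrix([], []), 0)


class TestF1:
    @pytest.mark.parametrize(
        "p,r,expected",
        [(0.9518, 0.9443, 0.948), (0.0769, 0.0193, 0.031)],
    )
    def test_printed_values(self, p, r, expected):
        assert round(f1(p, r), 3) == expected

    @given(st.floats(min_value=0, max_value=1))
    def test_equal_arguments_identity(self, p):
        assert f1(p, p) == pytest.approx(p)

    def test_zero_when_both_zero(self):
        assert f1(0.0, 0.0) == 0.0


class TestAlarmRates:
    @pytest.mark.parametrize(
        "correct,alarms,expected",
        [((177), 200, (0.885, 0.115)), (10, 10, (1.0, 0.0)), (0, 10, (0.0, 1.0))],
    )
    def test_known_splits(self, correct, alarms, expected):
        assert alarm_rates(correct, alarms) == pytest.approx(expected)

    @given(st.integers(0, 500), st.integers(1, 500))
    def test_rates_sum_to_one(self, correct, alarms):
        correct = min(correct, alarms)
        acc, false = alarm_rates(correct, alarms)
        assert acc + false == pytest.approx(1.0)

    def test_zero_alarms_is_undefined_not_zero(self):
        with pytest.raises(UndefinedRateError):
            alarm_rates(0, 0)

    def test_more_correct_than_alarms_rejected(self):
        with pytest.raises(ValueError):
            alarm_rates(5, 4)


class TestWindowsToAlarms:
    def test_all_safe_yields_nothing(self):
        assert windows_to_alarms([0, 0, 0], [0.0, 1.0, 2.0]) == []

    def test_fall_run_becomes_one_event(self):
        events = windows_to_alarms([0, 1, 1, 0], [0.0, 1.0, 2.0, 3.0])
        assert events == [AlarmEvent(FALL, 1.0, 2.0)]

    def test_nearby_same_type_runs_merge(self):
        labels = [1, 0, 1, 0, 0, 0, 1]
        times = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = windows_to_alarms(labels, times, merge_gap=2.0)
        assert events == [AlarmEvent(FALL, 0.0, 2.0), AlarmEvent(FALL, 6.0, 6.0)]

    def test_type_change_splits_runs(self):
        events = windows_to_alarms([1, 2, 2, 3], [0.0, 1.0, 2.0, 3.0])
        assert [e.type for e in events] == [FALL, STUMBLE, COMA]

    def test_matches_run_length_encoding_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            labels = rng.integers(0, 4, 40)
            times = np.arange(40) * 10.0  # gaps too large to merge
            events = windows_to_alarms(labels, times, merge_gap=2.0)
            runs = [(int(k), len(list(g)))
                    for k, g in itertools.groupby(labels)]
            expected = [r for r in runs if r[0] != 0]
            assert len(events) == len(expected)
            assert [int(e.type) for e in events] == [r[0] for r in expected]


def _brute_force_max_matches(truths, alarms, tol):
    """Maximum same-type one-to-one overlap matching by exhaustive search."""

    def overlaps(t, a):
        return a.start <= t.end + tol and a.end >= t.start - tol

    best = 0
    for perm in itertools.permutations(range(len(alarms)),
                                       min(len(alarms), len(truths))):
        used = sum(
            1 for t, ai in zip(truths, perm)
            if alarms[ai].type == t.type and overlaps(t, alarms[ai])
        )
        best = max(best, used)
    # permutations assign alarms to truths in truth order; also try truth subsets
    for k in range(len(truths)):
        for sub in itertools.combinations(range(len(truths)), k + 1):
            subset = [truths[i] for i in sub]
            for perm in itertools.permutations(range(len(alarms)),
                                               min(len(alarms), len(subset))):
                used = sum(
                    1 for t, ai in zip(subset, perm)
                    if alarms[ai].type == t.type and overlaps(t, alarms[ai])
                )
                best = max(best, used)
    return best


class TestEventReport:
    def test_matched_plus_unmatched_false_alarms(self):
        truths = [AlarmEvent(FALL, 10.0 * i, 10.0 * i + 2) for i in range(10)]
        alarms = [AlarmEvent(FALL, 10.0 * i + 0.5, 10.0 * i + 1.5)
                  for i in range(10)]
        alarms += [AlarmEvent(FALL, 500.0 + i, 500.5 + i) for i in range(3)]
        rep = event_report(truths, alarms)
        stats = rep.stats(FALL)
        assert stats.sensitivity == 100.0
        assert stats.n_false_alarms == 3

    def test_no_alarms(self):
        truths = [AlarmEvent(COMA, 0.0, 30.0)]
        rep = event_report(truths, [])
        assert rep.stats(COMA).sensitivity == 0.0
        assert rep.stats(COMA).n_false_alarms == 0

    def test_cross_type_alarm_is_miss_plus_false_alarm(self):
        truths = [AlarmEvent(FALL, 0.0, 2.0)]
        alarms = [AlarmEvent(STUMBLE, 0.5, 1.5)]
        rep = event_report(truths, alarms)
        assert rep.stats(FALL).n_accurate == 0
        assert rep.stats(STUMBLE).n_false_alarms == 1
        assert rep.event_confusion[(FALL, STUMBLE)] == 1

    def test_matches_exhaustive_matching_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            truths = []
            t = 0.0
            for _ in range(rng.integers(1, 5)):
                t += rng.uniform(1, 15)
                typ = StatusLabel(int(rng.integers(1, 4)))
                truths.append(AlarmEvent(typ, t, t + rng.uniform(0.5, 6)))
                t = truths[-1].end
            alarms = []
            for _ in range(rng.integers(0, 5)):
                start = rng.uniform(0, t + 5)
                typ = StatusLabel(int(rng.integers(1, 4)))
                alarms.append(AlarmEvent(typ, start, start + rng.uniform(0.5, 8)))
            alarms.sort(key=lambda e: e.start)
            rep = event_report(truths, alarms, tolerance=1.0)
            got = sum(s.n_accurate for s in rep.per_type.values())
            assert got == _brute_force_max_matches(truths, alarms, 1.0)
            fa = sum(s.n_false_alarms for s in rep.per_type.values())
            assert fa == len(alarms) - got

    def test_permutation_invariance_and_false_alarm_increment(self):
        truths = [AlarmEvent(FALL, 0.0, 2.0), AlarmEvent(STUMBLE, 10.0, 12.0)]
        alarms = [AlarmEvent(FALL, 0.5, 1.0), AlarmEvent(STUMBLE, 11.0, 11.5)]
        base = event_report(truths, alarms)
        shuffled = event_report(truths, alarms[::-1])
        assert base.stats(FALL).n_accurate == shuffled.stats(FALL).n_accurate
        extra = alarms + [AlarmEvent(COMA, 100.0, 130.0)]
        rep = event_report(truths, extra)
        assert rep.stats(COMA).n_false_alarms == \
            base.stats(COMA).n_false_alarms + 1
        for typ in (FALL, STUMBLE):
            assert rep.stats(typ).n_false_alarms == base.stats(typ).n_false_alarms


class TestComaPersistenceFilter:
    def test_thirty_consecutive_comas_confirm(self):
        labels = [3] * 30
        out = coma_persistence_filter(labels, horizon=30, min_fraction=1.0)
        assert out[-1] == 3
        assert np.all(out[:-1] == 0)  # earlier ones lack a full trailing window

    def test_interleaved_safe_demotes(self):
        labels = ([3] * 10 + [0] + [3] * 19) * 2
        out = coma_persistence_filter(labels, horizon=30, min_fraction=1.0)
        assert np.all(np.asarray(out) != 3)

    def test_all_safe_unchanged(self):
        labels = np.zeros(50, dtype=int)
        assert np.array_equal(coma_persistence_filter(labels), labels)

    def test_never_adds_coma_and_is_monotone(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, 200)
        out = coma_persistence_filter(labels, horizon=10, min_fraction=0.8)
        coma_in = set(np.flatnonzero(labels == 3))
        coma_out = set(np.flatnonzero(out == 3))
        assert coma_out <= coma_in
        # non-coma labels pass through untouched
        keep = labels != 3
        assert np.array_equal(out[keep], labels[keep])
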