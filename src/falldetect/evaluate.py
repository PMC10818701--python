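"""Two-level evaluation of accident detectors.

Level 1 — per-time-unit: a k x k confusion matrix over the status classes
and one-vs-rest accuracy, precision, recall, specificity and F1 per class.

Level 2 — event-level: runs of identical non-safe labels become alarm
events; each ground-truth event is *accurately detected* when at least one
same-type alarm overlaps it (within a tolerance), matched greedily
one-to-one in time order; unmatched alarms are false alarms of their
emitted type.  Sensitivity is 100 * accurate / targets.  Alarm-centric
accuracy-rate / false-detection-rate avoid the dominance of the safe class.

A persistence filter for coma demotes isolated coma labels: prolonged
genuine unconsciousness yields a steady series of coma decisions, whereas a
resting person produces occasional safe labels from small unavoidable
movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import StatusLabel

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "AlarmEvent",
    "EventTypeStats",
    "EventReport",
    "UndefinedMetricError",
    "UndefinedRateError",
    "confusion_matrix",
    "class_metrics",
    "f1",
    "alarm_rates",
    "windows_to_alarms",
    "event_report",
    "coma_persistence_filter",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric is undefined for the given counts (e.g. empty matrix)."""


class UndefinedRateError(ZeroDivisionError):
    """Alarm rates are undefined when no alarms were generated."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0):
            raise ValueError("confusion matrix counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_recall(self, cls: int) -> float:
        """Row-normalized recall: diagonal count over the true-class row sum.

        This is the per-class 'accuracy percentage' of a row-normalized
        confusion display.
        """
        row = self.counts[int(cls)]
        if row.sum() == 0:
            raise UndefinedMetricError(f"no true instances of class {cls}")
        return float(row[int(cls)] / row.sum())


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class, all in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float


def confusion_matrix(truth, pred, n_classes: int = 4) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape:
        raise ValueError(
            f"truth and pred lengths differ: {truth.shape} vs {pred.shape}"
        )
    if truth.size and (truth.min() < 0 or truth.max() >= n_classes or
                       pred.min() < 0 or pred.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    counts = np.bincount(
        truth * n_classes + pred, minlength=n_classes * n_classes
    ).reshape(n_classes, n_classes)
    return ConfusionMatrix(counts)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix, cls: int | StatusLabel) -> ClassMetrics:
    """One-vs-rest TP/FP/FN/TN metrics for ``cls`` from a confusion matrix.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); specificity = TN/(TN+FP); F1 = harmonic mean of
    precision and recall.  Ratios with a zero denominator are reported as 0.
    """
    cls = int(cls)
    c = cm.counts
    total = cm.total
    if total == 0:
        raise UndefinedMetricError("metrics are undefined for an empty matrix")
    tp = int(c[cls, cls])
    fp = int(c[:, cls].sum() - tp)
    fn = int(c[cls, :].sum() - tp)
    tn = total - tp - fp - fn

    def ratio(num, den):
        return float(num / den) if den else 0.0

    p = ratio(tp, tp + fp)
    r = ratio(tp, tp + fn)
    return ClassMetrics(
        accuracy=ratio(tp + tn, total),
        precision=p,
        recall=r,
        specificity=ratio(tn, tn + fp),
        f1=f1(p, r),
    )


def alarm_rates(n_correct: int, n_alarms: int) -> tuple[float, float]:
    """(accuracy rate, false detection rate) over generated alarms.

    accuracy rate = correct detections / alarms generated; false detection
    rate = incorrect detections / alarms generated; they sum to 1.  Raises
    :class:`UndefinedRateError` when no alarms exist (distinct from 0).
    """
    if n_correct > n_alarms:
        raise ValueError("n_correct cannot exceed n_alarms")
    if n_alarms == 0:
        raise UndefinedRateError("rates are undefined when no alarms were generated")
    return n_correct / n_alarms, (n_alarms - n_correct) / n_alarms


@dataclass(frozen=True)
class AlarmEvent:
    """A detected or ground-truth accident event (non-safe) in time."""

    type: StatusLabel
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.type == StatusLabel.SAFE:
            raise ValueError("an AlarmEvent cannot be of type safe")
        if self.start > self.end:
            raise ValueError("event start must be <= end")


def windows_to_alarms(labels, times, merge_gap: float = 2.0) -> list[AlarmEvent]:
    """Collapse a per-window label sequence into alarm events.

    Maximal runs of identical non-safe labels become one event spanning the
    centre times of their first and last windows; consecutive runs of the
    same type separated by at most ``merge_gap`` seconds are merged.
    """
    labels = np.asarray(labels, dtype=np.int64)
    times = np.asarray(times, dtype=float)
    if labels.shape != times.shape:
        raise ValueError("labels and times must have equal length")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    events: list[AlarmEvent] = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == int(StatusLabel.SAFE):
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        ev = AlarmEvent(StatusLabel(int(labels[i])), float(times[i]), float(times[j]))
        if (events and events[-1].type == ev.type
                and ev.start - events[-1].end <= merge_gap):
            events[-1] = AlarmEvent(ev.type, events[-1].start, ev.end)
        else:
            events.append(ev)
        i = j + 1
    return events


@dataclass
class EventTypeStats:
    n_targets: int = 0
    n_accurate: int = 0
    n_false_alarms: int = 0

    @property
    def sensitivity(self) -> float:
        """Percentage of targets accurately detected; 0 when no targets."""
        if self.n_targets == 0:
            return 0.0
        return 100.0 * self.n_accurate / self.n_targets


@dataclass
class EventReport:
    """Per-type event tallies plus a truth-type x alarm-type overlap table."""

    per_type: dict[StatusLabel, EventTypeStats] = field(default_factory=dict)
    event_confusion: dict[tuple[StatusLabel, StatusLabel], int] = field(
        default_factory=dict
    )

    def stats(self, t: StatusLabel) -> EventTypeStats:
        return self.per_type.setdefault(StatusLabel(t), EventTypeStats())

    def merged(self, other: "EventReport") -> "EventReport":
        out = EventReport()
        for rep in (self, other):
            for t, s in rep.per_type.items():
                acc = out.stats(t)
                acc.n_targets += s.n_targets
                acc.n_accurate += s.n_accurate
                acc.n_false_alarms += s.n_false_alarms
            for k, v in rep.event_confusion.items():
                out.event_confusion[k] = out.event_confusion.get(k, 0) + v
        return out


def _overlaps(truth: AlarmEvent, alarm: AlarmEvent, tol: float) -> bool:
    return alarm.start <= truth.end + tol and alarm.end >= truth.start - tol


def _max_bipartite_matching(adj: list[list[int]], n_right: int) -> list[int]:
    """Kuhn's augmenting-path matching; returns right index per left, -1 if none."""
    match_left = [-1] * len(adj)
    match_right = [-1] * n_right

    def try_augment(u: int, seen: list[bool]) -> bool:
        for v in adj[u]:
            if seen[v]:
                continue
            seen[v] = True
            if match_right[v] < 0 or try_augment(match_right[v], seen):
                match_left[u] = v
                match_right[v] = u
                return True
        return False

    for u in range(len(adj)):
        try_augment(u, [False] * n_right)
    return match_left


def event_report(
    truth_events: list[AlarmEvent],
    alarms: list[AlarmEvent],
    tolerance: float = 2.0,
) -> EventReport:
    """Match alarms to ground-truth events and tally Table-style statistics.

    A truth event counts as accurately detected when an alarm of the same
    type overlaps it within +-``tolerance`` seconds; alarms are paired
    one-to-one with truth events by a maximum bipartite matching per type
    (so an alarm spanning two truth events is credited to exactly one, and
    the accurate-detection count does not depend on enumeration order).
    Every unmatched alarm is a false alarm of its emitted type — a
    cross-type detection (e.g. a stumble alarm during a true fall) is a
    miss for the truth type and a false alarm of the alarm type; such
    overlaps are additionally tallied in ``event_confusion``.
    """
    truth_events = sorted(truth_events, key=lambda e: (e.start, e.end))
    alarms = sorted(alarms, key=lambda e: (e.start, e.end))
    report = EventReport()
    for t in truth_events:
        report.stats(t.type).n_targets += 1
    matched = [False] * len(alarms)
    by_type: dict[StatusLabel, tuple[list[int], list[int]]] = {}
    for ti, t in enumerate(truth_events):
        by_type.setdefault(t.type, ([], []))[0].append(ti)
    for ai, a in enumerate(alarms):
        by_type.setdefault(a.type, ([], []))[1].append(ai)
    for typ, (t_idx, a_idx) in by_type.items():
        if not t_idx or not a_idx:
            continue
        adj = [
            [j for j, ai in enumerate(a_idx)
             if _overlaps(truth_events[ti], alarms[ai], tolerance)]
            for ti in t_idx
        ]
        match_t = _max_bipartite_matching(adj, len(a_idx))
        for row, j in enumerate(match_t):
            if j >= 0:
                matched[a_idx[j]] = True
                report.stats(typ).n_accurate += 1
    for i, a in enumerate(alarms):
        if not matched[i]:
            report.stats(a.type).n_false_alarms += 1
        for t in truth_events:
            if _overlaps(t, a, tolerance):
                key = (t.type, a.type)
                report.event_confusion[key] = report.event_confusion.get(key, 0) + 1
    return report


def coma_persistence_filter(
    labels, horizon: int = 30, min_fraction: float = 0.9
):
    """Demote coma labels that are not persistent.

    A coma label at position i is confirmed only when at least
    ``min_fraction`` of the trailing ``horizon`` labels (inclusive of i) are
    coma; otherwise it is demoted to safe.  Early positions with fewer than
    ``horizon`` trailing labels cannot be confirmed.  Non-coma labels pass
    through unchanged, so the filter never *adds* coma alarms.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    labels = np.asarray(labels, dtype=np.int64)
    out = labels.copy()
    is_coma = (labels == int(StatusLabel.COMA)).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(is_coma)])
    for i in np.flatnonzero(is_coma):
        if i + 1 < horizon:
            out[i] = int(StatusLabel.SAFE)
            continue
        frac = (csum[i + 1] - csum[i + 1 - horizon]) / horizon
        if frac < min_fraction:
            out[i] = int(StatusLabel.SAFE)
    return out
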