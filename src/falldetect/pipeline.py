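"""End-to-end workflows: cohort simulation, training, detection, comparison.

`run_comparison` reproduces the study design at configurable scale: simulate
a cohort, split it 25/5 at participant level, calibrate the hierarchical
baseline on the training participants, train the GRU classifier on their
windows, then evaluate both detectors on the held-out participants at two
levels (per-window confusion metrics and event-level sensitivity /
false-alarm tallies).  A scenario-level probe additionally counts the
baseline's false alarms on even walking vs uneven ground vs motorcycle
riding, the environments reported to provoke them in the field.

The GRU here trains with inverse-frequency class weights and a window
stride of 2: the simulated cohort is ~90% safe samples, and accident
windows are a fraction of a percent of the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluate import (
    ClassMetrics,
    ConfusionMatrix,
    EventReport,
    class_metrics,
    coma_persistence_filter,
    confusion_matrix,
    event_report,
    windows_to_alarms,
)
from .features import (
    DEFAULT_CHANNELS,
    DEFAULT_LABEL_POS,
    DEFAULT_WINDOW_LEN,
    make_windows,
    window_labels,
    window_tensor,
)
from .gru import GruClassifier, GruConfig
from .hierarchical import HierarchicalDetector, ThresholdConfig
from .records import Dataset, Recording, StatusLabel, split_by_participant
from .simulate import ScenarioSpec, simulate_cohort, simulate_scenario

__all__ = ["ComparisonResult", "run_comparison", "detect_windows",
           "scenario_false_alarms", "format_metrics_table",
           "format_event_table"]

_EVENT_TYPES = (StatusLabel.FALL, StatusLabel.STUMBLE, StatusLabel.COMA)


@dataclass
class ComparisonResult:
    """Side-by-side evaluation of the GRU classifier and the baseline."""

    gru_cm: ConfusionMatrix
    her_cm: ConfusionMatrix
    gru_metrics: dict[StatusLabel, ClassMetrics]
    her_metrics: dict[StatusLabel, ClassMetrics]
    gru_events: EventReport
    her_events: EventReport
    threshold_config: ThresholdConfig
    gru_history: dict[str, list[float]]
    scenario_alarms: dict[str, int] = field(default_factory=dict)
    n_train_windows: int = 0
    n_test_windows: int = 0


def _window_positions(n: int, window_len: int, label_pos: int) -> np.ndarray:
    """0-based sample indices labelling each stride-1 window of a recording."""
    n_windows = n - window_len + 1
    return np.arange(n_windows) + label_pos - 1


def detect_windows(
    recording: Recording,
    detector: HierarchicalDetector,
    window_len: int = DEFAULT_WINDOW_LEN,
    label_pos: int = DEFAULT_LABEL_POS,
) -> np.ndarray:
    """Per-window labels from a per-sample detector, at the window label
    positions (stride 1), so threshold and sequence models are comparable."""
    sample_labels = detector.predict(recording)
    pos = _window_positions(len(recording), window_len, label_pos)
    return sample_labels[pos]


def scenario_false_alarms(
    detector: HierarchicalDetector,
    kinds=("walk_even", "walk_uneven", "motorcycle"),
    seeds=(101, 102, 103),
    duration: float = 120.0,
    merge_gap: float = 2.0,
) -> dict[str, int]:
    """Fall+stumble alarm-event counts per safe-only scenario kind.

    Every alarm on these scenarios is false by construction (all samples are
    labelled safe); counts are summed over the fixed seeds.
    """
    out: dict[str, int] = {}
    for kind in kinds:
        count = 0
        for seed in seeds:
            rec = simulate_scenario(ScenarioSpec(kind, duration=duration), seed)
            labels = detector.predict(rec)
            events = windows_to_alarms(labels, rec.t, merge_gap=merge_gap)
            count += sum(e.type in (StatusLabel.FALL, StatusLabel.STUMBLE)
                         for e in events)
        out[kind] = count
    return out


def run_comparison(
    n_participants: int = 30,
    n_train: int = 25,
    seed: int = 1,
    session_plan: list[ScenarioSpec] | None = None,
    gru_config: GruConfig | None = None,
    grid: dict | None = None,
    train_stride: int = 2,
    channels=DEFAULT_CHANNELS,
    window_len: int = DEFAULT_WINDOW_LEN,
    label_pos: int = DEFAULT_LABEL_POS,
    apply_coma_filter: bool = False,
    coma_horizon: int = 30,
    include_scenario_probe: bool = True,
    dataset: Dataset | None = None,
) -> ComparisonResult:
    """Run the full simulate/train/evaluate comparison at a fixed seed.

    Pass ``dataset`` to compare on pre-existing recordings instead of a
    freshly simulated cohort (the seed then governs only the split and
    the model initialization).
    """
    seed = int(seed) % (2 ** 31)
    cohort = dataset if dataset is not None else \
        simulate_cohort(n_participants, seed, session_plan)
    train_ds, test_ds = split_by_participant(cohort, n_train, seed)

    her = HierarchicalDetector(grid=grid).fit(train_ds)

    if gru_config is None:
        gru_config = GruConfig(seed=seed, epochs=8, batch_size=256,
                               class_weighting=True)
    train_windows = []
    for rec in train_ds.recordings:
        train_windows.extend(
            make_windows(rec, window_len, train_stride, label_pos, channels)
        )
    gru = GruClassifier(gru_config).fit(
        window_tensor(train_windows), window_labels(train_windows)
    )

    truth_all, gru_all, her_all = [], [], []
    gru_ev = EventReport()
    her_ev = EventReport()
    n_test_windows = 0
    for rec in test_ds.recordings:
        windows = make_windows(rec, window_len, 1, label_pos, channels)
        if not windows:
            continue
        n_test_windows += len(windows)
        truth = window_labels(windows)
        times = np.array([w.center_time for w in windows])
        gru_labels, _ = gru.predict(window_tensor(windows))
        her_labels = detect_windows(rec, her, window_len, label_pos)
        if apply_coma_filter:
            gru_labels = coma_persistence_filter(gru_labels, coma_horizon)
            her_labels = coma_persistence_filter(her_labels, coma_horizon)
        truth_all.append(truth)
        gru_all.append(gru_labels)
        her_all.append(her_labels)
        truth_events = windows_to_alarms(truth, times)
        gru_ev = gru_ev.merged(
            event_report(truth_events, windows_to_alarms(gru_labels, times))
        )
        her_ev = her_ev.merged(
            event_report(truth_events, windows_to_alarms(her_labels, times))
        )

    truth_cat = np.concatenate(truth_all)
    gru_cm = confusion_matrix(truth_cat, np.concatenate(gru_all))
    her_cm = confusion_matrix(truth_cat, np.concatenate(her_all))

    scen = {}
    if include_scenario_probe:
        scen = scenario_false_alarms(her)

    return ComparisonResult(
        gru_cm=gru_cm,
        her_cm=her_cm,
        gru_metrics={c: class_metrics(gru_cm, c) for c in StatusLabel},
        her_metrics={c: class_metrics(her_cm, c) for c in StatusLabel},
        gru_events=gru_ev,
        her_events=her_ev,
        threshold_config=her.config,
        gru_history=gru.history,
        scenario_alarms=scen,
        n_train_windows=len(train_windows),
        n_test_windows=n_test_windows,
    )


def format_metrics_table(metrics: dict[StatusLabel, ClassMetrics],
                         title: str) -> str:
    """Text table: per-class accuracy/precision/recall/specificity (%) and F1."""
    lines = [title,
             f"{'label':<10}{'accuracy':>10}{'precision':>11}{'recall':>9}"
             f"{'specificity':>13}{'F1':>8}"]
    for cls, m in metrics.items():
        lines.append(
            f"{cls.label_name:<10}{100 * m.accuracy:>9.2f}%"
            f"{100 * m.precision:>10.2f}%{100 * m.recall:>8.2f}%"
            f"{100 * m.specificity:>12.2f}%{m.f1:>8.3f}"
        )
    return "\n".join(lines)


def format_event_table(reports: dict[str, EventReport]) -> str:
    """Text table of per-type targets / accurate / sensitivity / false alarms."""
    lines = [f"{'model':<14}{'index':<28}" +
             "".join(f"{t.label_name:>9}" for t in _EVENT_TYPES)]
    for name, rep in reports.items():
        rows = [
            ("number of target events", lambda s: str(s.n_targets)),
            ("number of accurate detection", lambda s: str(s.n_accurate)),
            ("sensitivity (%)", lambda s: f"{s.sensitivity:.0f}%"),
            ("number of false alarms", lambda s: str(s.n_false_alarms)),
        ]
        for i, (label, fmt) in enumerate(rows):
            cells = "".join(f"{fmt(rep.stats(t)):>9}" for t in _EVENT_TYPES)
            lines.append(f"{name if i == 0 else '':<14}{label:<28}{cells}")
    return "\n".join(lines)
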