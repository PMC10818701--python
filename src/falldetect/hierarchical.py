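"""Hierarchical-threshold baseline detector (HER-S reconstruction).

The benchmark detector combines signal-vector-magnitude and vertical-axis
acceleration thresholds in a fixed decision hierarchy, evaluated per
sample:

1. *fall* — SVMa dips below a free-fall ceiling and, within a short
   horizon, spikes above an impact floor (or the vertical axis does) while
   posture (SVMo) changes by more than a floor;
2. *stumble* — an impact-level SVMa / vertical spike or a large one-step
   SVMa jump without the full fall signature;
3. *coma* — rolling SVMa standard deviation stays below a stillness
   ceiling for a minimum duration, gated on a non-upright posture;
4. *safe* otherwise.  Fall shadows stumble shadows coma.

The original system's threshold values are not published here, so they are
calibrated by exhaustive grid search maximizing macro-F1 on training data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .evaluate import class_metrics, confusion_matrix
from .features import svma, svmo
from .records import Dataset, Recording, StatusLabel, ValidationError

__all__ = ["ThresholdConfig", "DEFAULT_GRID", "HierarchicalDetector",
           "detect_hierarchical", "calibrate_thresholds"]


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds of the hierarchical detector (accelerations in g).

    ``theta_freefall`` — SVMa dip ceiling marking free fall;
    ``theta_impact`` — SVMa spike floor marking ground impact;
    ``theta_delta`` — one-step SVMa jump floor;
    ``theta_vert`` — vertical-axis |acceleration| floor (alternative impact
    evidence);
    ``stillness_sd`` / ``stillness_duration`` — rolling SVMa SD ceiling and
    window for the coma rule;
    ``posture_change`` — SVMo excursion (deg) required around an impact to
    call a fall rather than a step;
    ``posture_gate`` — minimum SVMo (deg, non-upright) for the coma rule;
    ``horizon`` — seconds within which dip and impact must co-occur.
    """

    theta_freefall: float = 0.6
    theta_impact: float = 2.0
    theta_delta: float = 1.0
    theta_vert: float = 1.8
    stillness_sd: float = 0.01
    stillness_duration: float = 5.0
    posture_change: float = 20.0
    posture_gate: float = 15.0
    horizon: float = 1.5
    vertical_axis: str = "az"

    def __post_init__(self) -> None:
        if not self.theta_freefall < 1.0 < self.theta_impact:
            raise ValueError(
                "need theta_freefall < 1 g < theta_impact "
                f"(got {self.theta_freefall}, {self.theta_impact})"
            )
        for name in ("stillness_duration", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: Default calibration grid (values in g / degrees).
DEFAULT_GRID: dict[str, list] = {
    "theta_freefall": [0.4, 0.6],
    "theta_impact": [1.6, 2.0, 2.5, 3.0],
    "theta_delta": [0.8, 1.2],
    "theta_vert": [1.6, 2.4],
    "stillness_sd": [0.008, 0.015, 0.03],
    "posture_change": [15.0, 30.0],
}


def _base_series(recording: Recording):
    s = svma(recording.ax, recording.ay, recording.az)
    d = np.zeros_like(s)
    if len(s) > 1:
        d[1:] = np.diff(s)
    o = svmo(recording.pitch, recording.roll)
    return s, d, o


def _rolling_sd(s: np.ndarray, w: int) -> np.ndarray:
    """Trailing-window standard deviation; inf where the window is incomplete."""
    if w <= 1:
        return np.zeros_like(s)
    c1 = np.concatenate([[0.0], np.cumsum(s)])
    c2 = np.concatenate([[0.0], np.cumsum(s * s)])
    out = np.full_like(s, np.inf)
    if len(s) >= w:
        tot = c1[w:] - c1[:-w]
        tot2 = c2[w:] - c2[:-w]
        var = np.maximum(tot2 / w - (tot / w) ** 2, 0.0)
        out[w - 1:] = np.sqrt(var)
    return out


def detect_hierarchical(
    recording: Recording,
    cfg: ThresholdConfig,
    _series=None,
) -> np.ndarray:
    """Per-sample status labels from the threshold hierarchy (int array)."""
    s, d, o = _series if _series is not None else _base_series(recording)
    dt = recording.sampling_interval
    n = len(s)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    w = max(int(round(cfg.horizon / dt)), 1)

    vert = np.abs(getattr(recording, cfg.vertical_axis))
    impact = (s > cfg.theta_impact) | (vert > cfg.theta_vert)
    dip = s < cfg.theta_freefall

    # dip seen in the trailing `horizon` samples (excluding the current one)
    dip_recent = np.zeros(n, dtype=bool)
    if n > 1:
        dip_recent[1:] = _trailing_any(dip[:-1], w)

    # posture excursion inside +-horizon of each sample
    o_max = maximum_filter1d(o, size=2 * w + 1, mode="nearest")
    o_min = minimum_filter1d(o, size=2 * w + 1, mode="nearest")
    posture_moved = (o_max - o_min) > cfg.posture_change

    fall = impact & dip_recent & posture_moved
    stumble = (impact | (d > cfg.theta_delta)) & ~fall

    sd_w = max(int(round(cfg.stillness_duration / dt)), 2)
    rolling = _rolling_sd(s, sd_w)
    coma = (rolling < cfg.stillness_sd) & (o > cfg.posture_gate)

    out = np.zeros(n, dtype=np.int64)
    out[coma] = int(StatusLabel.COMA)
    out[stumble] = int(StatusLabel.STUMBLE)
    out[fall] = int(StatusLabel.FALL)
    return out


def _trailing_any(x: np.ndarray, w: int) -> np.ndarray:
    """For each i: any(x[max(0, i-w+1) : i+1]) — vectorized via cumsum."""
    xi = x.astype(np.int64)
    c = np.concatenate([[0], np.cumsum(xi)])
    lo = np.maximum(np.arange(len(x)) - w + 1, 0)
    return (c[np.arange(1, len(x) + 1)] - c[lo]) > 0


class HierarchicalDetector:
    """Estimator-style wrapper: ``fit`` calibrates thresholds, ``predict``
    labels samples."""

    def __init__(self, config: ThresholdConfig | None = None,
                 grid: dict[str, list] | None = None):
        self.config = config
        self.grid = grid

    def fit(self, train: Dataset) -> "HierarchicalDetector":
        self.config = calibrate_thresholds(train, self.grid)
        return self

    def predict(self, recording: Recording) -> np.ndarray:
        if self.config is None:
            raise RuntimeError("detector has no thresholds; call fit() or "
                               "pass a ThresholdConfig")
        return detect_hierarchical(recording, self.config)


def _macro_f1(truth: np.ndarray, pred: np.ndarray, n_classes: int = 4) -> float:
    cm = confusion_matrix(truth, pred, n_classes)
    return float(np.mean([class_metrics(cm, c).f1 for c in range(n_classes)]))


def calibrate_thresholds(
    train: Dataset, grid: dict[str, list] | None = None
) -> ThresholdConfig:
    """Exhaustive grid search for the macro-F1-maximizing thresholds.

    Deterministic: ties break toward the first configuration in grid order
    (itertools.product over the grid dict in its key order).  Requires all
    four status classes in the training labels.
    """
    if grid is None:
        grid = DEFAULT_GRID
    present = set()
    for r in train.recordings:
        present.update(np.unique(r.labels).tolist())
    missing = [StatusLabel(c).label_name for c in range(4) if c not in present]
    if missing:
        raise ValidationError(
            f"calibration requires all four classes in training data; "
            f"missing: {', '.join(missing)}"
        )

    valid_names = {f.name for f in fields(ThresholdConfig)}
    unknown = set(grid) - valid_names
    if unknown:
        raise ValueError(f"unknown threshold parameters in grid: {sorted(unknown)}")

    series = [_base_series(r) for r in train.recordings]
    truth = np.concatenate([r.labels for r in train.recordings])

    names = list(grid)
    best_cfg = None
    best_score = -1.0
    base = ThresholdConfig()
    for values in itertools.product(*(grid[n] for n in names)):
        cfg = replace(base, **dict(zip(names, values)))
        pred = np.concatenate([
            detect_hierarchical(r, cfg, _series=ser)
            for r, ser in zip(train.recordings, series)
        ])
        score = _macro_f1(truth, pred)
        if score > best_score:
            best_score = score
            best_cfg = cfg
    return best_cfg
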