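"""Signal-vector-magnitude features and sliding-window segmentation.

SVMa, the Euclidean norm of the three acceleration axes, is ~1 g when the
body is stationary, dips toward 0 during free fall and spikes at ground
impact; its first difference (dSVMa) is large for abrupt movements; SVMo,
the norm of (pitch, roll), tracks posture change.  Recordings are cut into
2 s windows (20 samples at 10 Hz), advanced one sample at a time, each
labelled by the status of its 10th sample (1-based, i.e. the window centre).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .records import Recording, StatusLabel

__all__ = [
    "DEFAULT_CHANNELS",
    "svma",
    "delta_svma",
    "svmo",
    "feature_matrix",
    "Window",
    "make_windows",
    "window_tensor",
    "window_labels",
]

#: Per-timestep channel set fed to sequence classifiers (configurable).
DEFAULT_CHANNELS = ("ax", "ay", "az", "pitch", "roll", "svma", "delta_svma", "svmo")

DEFAULT_WINDOW_LEN = 20
DEFAULT_STRIDE = 1
DEFAULT_LABEL_POS = 10  # 1-based position of the labelling sample


def _check_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} requires finite inputs")


def svma(ax, ay, az):
    """Signal vector magnitude of acceleration: ||(ax, ay, az)||, in g."""
    ax, ay, az = np.asarray(ax, float), np.asarray(ay, float), np.asarray(az, float)
    _check_finite("svma", ax, ay, az)
    return np.sqrt(ax * ax + ay * ay + az * az)


def delta_svma(series):
    """First difference of an SVMa series: out[i] = series[i+1] - series[i].

    Output length is ``len(series) - 1``; an empty series is rejected.
    """
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("delta_svma requires a series of length >= 1")
    return np.diff(series)


def svmo(pitch, roll):
    """Signal vector magnitude of the rotation angles: ||(pitch, roll)||, deg."""
    pitch, roll = np.asarray(pitch, float), np.asarray(roll, float)
    _check_finite("svmo", pitch, roll)
    return np.hypot(pitch, roll)


def feature_matrix(recording: Recording, channels=DEFAULT_CHANNELS) -> np.ndarray:
    """Per-sample feature matrix (n_samples, n_channels) for a recording.

    ``delta_svma`` for the first sample of the recording is 0 (no preceding
    raw sample); inside the recording every window inherits the difference to
    the sample preceding it, so no window is discarded.
    """
    derived = {}
    s = None
    if "svma" in channels or "delta_svma" in channels:
        s = svma(recording.ax, recording.ay, recording.az)
        derived["svma"] = s
    if "delta_svma" in channels:
        d = np.zeros(len(recording))
        if len(recording) > 1:
            d[1:] = np.diff(s)
        derived["delta_svma"] = d
    if "svmo" in channels:
        derived["svmo"] = svmo(recording.pitch, recording.roll)
    cols = []
    for ch in channels:
        if ch in derived:
            cols.append(derived[ch])
        elif hasattr(recording, ch):
            cols.append(np.asarray(getattr(recording, ch), float))
        else:
            raise ValueError(f"unknown channel {ch!r}")
    return np.column_stack(cols) if cols else np.empty((len(recording), 0))


@dataclass(frozen=True)
class Window:
    """One fixed-length labelled window.

    ``features`` is a (window_len, n_channels) view; ``start`` is the 0-based
    index of the first sample in the parent recording; ``label`` is the status
    of the sample at the configured (1-based) label position.
    """

    features: np.ndarray
    label: StatusLabel
    participant_id: str
    start: int
    center_time: float


def make_windows(
    recording: Recording,
    window_len: int = DEFAULT_WINDOW_LEN,
    stride: int = DEFAULT_STRIDE,
    label_pos: int = DEFAULT_LABEL_POS,
    channels=DEFAULT_CHANNELS,
) -> list[Window]:
    """Segment one recording into labelled sliding windows.

    Window k (k = 0, 1, ...) covers samples ``k*stride .. k*stride+window_len-1``
    and is labelled by the status of sample ``k*stride + label_pos - 1``
    (``label_pos`` counts from 1: the default 10 labels a 20-sample window by
    its 10th sample).  Windows never cross recording boundaries; a recording
    shorter than ``window_len`` yields no windows.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 1 <= label_pos <= window_len:
        raise ValueError(
            f"label_pos must lie in [1, {window_len}] (1-based), got {label_pos}"
        )
    n = len(recording)
    if n < window_len:
        return []
    feats = feature_matrix(recording, channels)
    views = sliding_window_view(feats, window_len, axis=0)[::stride]  # (k, C, L)
    n_windows = views.shape[0]
    out = []
    for k in range(n_windows):
        start = k * stride
        li = start + label_pos - 1
        out.append(
            Window(
                features=views[k].T,
                label=StatusLabel(int(recording.labels[li])),
                participant_id=recording.participant_id,
                start=start,
                center_time=float(recording.t[li]),
            )
        )
    return out


def window_tensor(windows: list[Window]) -> np.ndarray:
    """Stack windows into an (n, window_len, n_channels) float array."""
    if not windows:
        raise ValueError("no windows to stack")
    return np.stack([w.features for w in windows]).astype(float)


def window_labels(windows: list[Window]) -> np.ndarray:
    return np.array([int(w.label) for w in windows], dtype=np.int64)
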