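"""Core data model and sensor-log I/O.

A worn IMU samples at 10 Hz and each record carries seven fields: date,
time, three acceleration axes (in g), and the pitch and roll angles (in
degrees).  Every record is additionally labelled with a worker status code:
0 = safe, 1 = fall, 2 = stumble, 3 = coma.  Recordings are per-participant,
strictly time-ordered on a fixed sampling grid.

Acceleration is expressed in units of g so that the stationary signal
magnitude is ~1, free fall dips toward 0 and ground impacts appear as
multiples of gravity, independent of the sensor's native scale.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "StatusLabel",
    "ImuSample",
    "PhaseSpan",
    "Recording",
    "Dataset",
    "SensorLogError",
    "ParseError",
    "ValidationError",
    "read_sensor_log",
    "write_sensor_log",
    "split_by_participant",
]

DEFAULT_SAMPLING_INTERVAL = 0.1
_DEFAULT_START = _dt.datetime(2024, 1, 1, 9, 0, 0)
_HEADER = ["date", "time", "ax", "ay", "az", "pitch", "roll", "label"]


class SensorLogError(Exception):
    """Base class for sensor-log problems."""


class ParseError(SensorLogError):
    """A row of a sensor log could not be parsed."""


class ValidationError(SensorLogError):
    """A structurally valid file or object violates a data-model invariant."""


class StatusLabel(IntEnum):
    """Worker status coding: 0 safe, 1 fall, 2 stumble, 3 coma."""

    SAFE = 0
    FALL = 1
    STUMBLE = 2
    COMA = 3

    @classmethod
    def from_code(cls, code: int) -> "StatusLabel":
        try:
            return cls(int(code))
        except ValueError:
            raise ValidationError(
                f"unknown status label code {code!r}; expected 0 (safe), "
                "1 (fall), 2 (stumble) or 3 (coma)"
            ) from None

    @property
    def label_name(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class ImuSample:
    """One 0.1 s sensor record: time, 3-axis acceleration (g), pitch/roll (deg)."""

    t: float
    ax: float
    ay: float
    az: float
    pitch: float
    roll: float


@dataclass(frozen=True)
class PhaseSpan:
    """Ground-truth span of one simulated motion phase (simulator sidecar).

    ``start``/``stop`` are sample indices (stop exclusive); purely metadata,
    never part of the CSV interchange format and never read by detectors.
    """

    name: str
    start: int
    stop: int
    label: StatusLabel
    scenario: str = ""


@dataclass
class Recording:
    """Time-ordered labelled IMU stream of one participant.

    Channels are stored as flat arrays for efficiency; :meth:`sample` exposes
    the per-record :class:`ImuSample` view.  ``annotations`` are free-text
    notes keyed by sample index and are ignored by every computation.
    """

    participant_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    labels: np.ndarray
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL
    start_datetime: _dt.datetime = _DEFAULT_START
    annotations: dict[int, str] = field(default_factory=dict)
    phases: list[PhaseSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "ax", "ay", "az", "pitch", "roll"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = len(self.t)
        for name in ("ax", "ay", "az", "pitch", "roll"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"channel {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if len(self.labels) != n:
            raise ValidationError(
                f"labels have length {len(self.labels)}, expected {n}"
            )
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise ValidationError(
                    f"timestamps are not strictly increasing at sample {bad}"
                )
            if np.any(np.abs(dt - self.sampling_interval) > 1e-6):
                bad = int(np.argmax(np.abs(dt - self.sampling_interval) > 1e-6)) + 1
                raise ValidationError(
                    f"timestamp gap at sample {bad} is {dt[bad - 1]:.6f} s, "
                    f"expected the {self.sampling_interval} s sampling grid"
                )
        if n and (np.any(np.abs(self.pitch) > 90 + 1e-9) or
                  np.any(np.abs(self.roll) > 180 + 1e-9)):
            raise ValidationError("pitch must lie in [-90, 90] and roll in [-180, 180]")
        bad = ~np.isin(self.labels, [s.value for s in StatusLabel])
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise ValidationError(
                f"unknown status label code {self.labels[idx]} at sample {idx}"
            )

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, i: int) -> ImuSample:
        return ImuSample(
            t=float(self.t[i]), ax=float(self.ax[i]), ay=float(self.ay[i]),
            az=float(self.az[i]), pitch=float(self.pitch[i]), roll=float(self.roll[i]),
        )

    def __iter__(self) -> Iterator[ImuSample]:
        return (self.sample(i) for i in range(len(self)))

    @property
    def status_labels(self) -> list[StatusLabel]:
        return [StatusLabel(int(c)) for c in self.labels]

    @classmethod
    def from_samples(
        cls,
        participant_id: str,
        samples: Sequence[ImuSample],
        labels: Sequence[int | StatusLabel],
        **kwargs,
    ) -> "Recording":
        return cls(
            participant_id=participant_id,
            t=[s.t for s in samples],
            ax=[s.ax for s in samples],
            ay=[s.ay for s in samples],
            az=[s.az for s in samples],
            pitch=[s.pitch for s in samples],
            roll=[s.roll for s in samples],
            labels=[int(l) for l in labels],
            **kwargs,
        )


@dataclass
class Dataset:
    """A cohort of recordings with a shared sampling interval."""

    recordings: list[Recording]
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            raise ValidationError("participant_ids must be unique within a Dataset")

    @property
    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.recordings]

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def n_samples(self) -> int:
        return sum(len(r) for r in self.recordings)


def _format_time(start: _dt.datetime, seconds: float) -> tuple[str, str]:
    stamp = start + _dt.timedelta(seconds=float(seconds))
    return stamp.strftime("%Y-%m-%d"), f"{stamp:%H:%M:%S}.{stamp.microsecond // 100000}"


def write_sensor_log(recording: Recording, path) -> None:
    """Serialize a recording as the CSV interchange format.

    Header ``date,time,ax,ay,az,pitch,roll,label[,annotation]``; acceleration
    written with 5 decimals (round-trip error < 1e-4 g), angles with 3.
    """
    has_notes = bool(recording.annotations)
    header = _HEADER + (["annotation"] if has_notes else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(len(recording)):
            date, time = _format_time(recording.start_datetime, recording.t[i])
            row = [
                date, time,
                f"{recording.ax[i]:.5f}", f"{recording.ay[i]:.5f}",
                f"{recording.az[i]:.5f}",
                f"{recording.pitch[i]:.3f}", f"{recording.roll[i]:.3f}",
                str(int(recording.labels[i])),
            ]
            if has_notes:
                row.append(recording.annotations.get(i, ""))
            writer.writerow(row)


def read_sensor_log(
    path,
    participant_id: str | None = None,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    assume_safe: bool = False,
) -> Recording:
    """Read a CSV sensor log into a :class:`Recording`.

    Parameters
    ----------
    path
        CSV file with header ``date,time,ax,ay,az,pitch,roll,label`` and an
        optional trailing ``annotation`` column.
    assume_safe
        Admit unlabelled field logs (no ``label`` column) by filling safe(0).

    Raises
    ------
    ParseError
        Malformed row, with the 1-based line number.
    ValidationError
        Non-monotone / off-grid timestamps or an unknown label code.
    """
    path = str(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row") from None
        header = [h.strip() for h in header]
        has_label = "label" in header
        if header[:7] != _HEADER[:7]:
            raise ParseError(
                f"{path}: unexpected header {header!r}; expected columns "
                f"{_HEADER[:7]} [+ label[, annotation]]"
            )
        if not has_label and not assume_safe:
            raise ParseError(
                f"{path}: missing mandatory 'label' column "
                "(pass assume_safe=True for unlabelled field logs)"
            )
        has_notes = "annotation" in header
        n_req = 7 + int(has_label)

        t, ax, ay, az, pitch, roll, labels = [], [], [], [], [], [], []
        annotations: dict[int, str] = {}
        start: _dt.datetime | None = None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < n_req:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_req} fields, got {len(row)}"
                )
            try:
                stamp = _parse_stamp(row[0], row[1])
                vals = [float(v) for v in row[2:7]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if start is None:
                start = stamp
            t.append((stamp - start).total_seconds())
            ax.append(vals[0]); ay.append(vals[1]); az.append(vals[2])
            pitch.append(vals[3]); roll.append(vals[4])
            if has_label:
                try:
                    code = int(row[7])
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: label {row[7]!r} is not an integer"
                    ) from None
                try:
                    labels.append(int(StatusLabel.from_code(code)))
                except ValidationError as exc:
                    raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            else:
                labels.append(int(StatusLabel.SAFE))
            if has_notes and len(row) > n_req and row[n_req].strip():
                annotations[len(t) - 1] = row[n_req].strip()

    return Recording(
        participant_id=participant_id or _stem(path),
        t=t, ax=ax, ay=ay, az=az, pitch=pitch, roll=roll, labels=labels,
        sampling_interval=sampling_interval,
        start_datetime=start or _DEFAULT_START,
        annotations=annotations,
    )


def _parse_stamp(date: str, time: str) -> _dt.datetime:
    time = time.strip()
    fmt = "%H:%M:%S.%f" if "." in time else "%H:%M:%S"
    return _dt.datetime.combine(
        _dt.datetime.strptime(date.strip(), "%Y-%m-%d").date(),
        _dt.datetime.strptime(time, fmt).time(),
    )


def _stem(path: str) -> str:
    import os

    return os.path.splitext(os.path.basename(path))[0]


def split_by_participant(
    dataset: Dataset, n_train: int, seed: int
) -> tuple[Dataset, Dataset]:
    """Random disjoint participant-level train/test split.

    Splitting at recording level guarantees no sliding window ever straddles
    the train/test boundary.  Reproducible for a fixed seed.
    """
    n = len(dataset.recordings)
    if not 0 < n_train < n:
        raise ValueError(
            f"n_train must be in (0, {n}) for {n} participants, got {n_train}"
        )
    order = np.random.default_rng(seed).permutation(n)
    train_idx = set(order[:n_train].tolist())
    train = [r for i, r in enumerate(dataset.recordings) if i in train_idx]
    test = [r for i, r in enumerate(dataset.recordings) if i not in train_idx]
    return (
        Dataset(train, dataset.sampling_interval),
        Dataset(test, dataset.sampling_interval),
    )
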