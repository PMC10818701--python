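"""Synthetic IMU scenario simulator.

The study's raw sensor data were destroyed under its IRB consent, so this
module emulates the data-collection protocol: walking on even and uneven
ground, stairs, slopes and gravel, riding a motorcycle over bumps, falls
from height (dropped weighted doll), directional stumbles onto a padded
floor, progressive and abrupt comas, and free seated rest.

Each scenario is an ordered list of motion *phases*.  A phase prescribes a
target SVMa level (with oscillation, noise, and impulsive spikes where the
surface warrants them) and a target posture; pitch and roll relax toward the
posture target through a mean-reverting (Ornstein-Uhlenbeck style) drift so
that SVMo carries posture signal.  The acceleration vector is the phase's
SVMa magnitude pointed along the gravity direction implied by the current
pitch/roll, so the generated ``svma(ax, ay, az)`` reproduces the phase
profile exactly.

Signal morphology follows the field descriptions: falls and stumbles open
with a dip of SVMa toward zero (free fall), then an abrupt peak at ground
impact; a true stumble's labelled span lasts only 2-3 s and is followed by
walking-like recovery, while a fall from height leaves the subject lying
still; a resting person fidgets slightly every few seconds whereas a comatose
one does not.  All magnitudes are engineering defaults chosen for class
separability (the source protocol reports none) and are overridable per
phase.

Every simulate call attaches its realized phase plan (:class:`PhaseSpan`
list) to the returned :class:`Recording` as machine-readable ground truth;
the plan is test/oracle metadata, not part of the CSV interchange format.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .records import (
    DEFAULT_SAMPLING_INTERVAL,
    Dataset,
    PhaseSpan,
    Recording,
    StatusLabel,
)

__all__ = [
    "PhaseProfile",
    "ScenarioSpec",
    "SCENARIO_KINDS",
    "DEFAULT_SCENARIO_DURATION",
    "simulate_scenario",
    "simulate_fall",
    "simulate_stumble",
    "simulate_cohort",
    "simulate_participant",
    "default_session_plan",
]


@dataclass(frozen=True)
class PhaseProfile:
    """One motion phase: SVMa shape, posture target and status label.

    ``svma_mean`` in g; if ``mean_range`` is set the level is drawn from it
    when the phase is instantiated (e.g. impact peaks).  ``duration_range``
    in seconds; a scenario's designated *fill* phase absorbs the remaining
    scenario duration instead.  ``spike_range``/``spike_spacing`` put
    impulsive SVMa excursions (in g / seconds apart) on top of the base
    signal — the signature of uneven surfaces, stairs and speed bumps.
    ``fidget`` = (spacing_lo, spacing_hi, amp_lo, amp_hi) adds the small
    occasional movements of a resting-but-awake person.
    """

    name: str
    duration_range: tuple[float, float]
    svma_mean: float
    svma_sd: float
    label: StatusLabel
    mean_range: tuple[float, float] | None = None
    osc_amp: float = 0.0
    osc_freq: float = 2.0
    spike_range: tuple[float, float] | None = None
    spike_spacing: tuple[float, float] | None = None
    spike_width: tuple[int, int] = (1, 2)
    fidget: tuple[float, float, float, float] | None = None
    pitch_target: float = 0.0
    roll_target: float = 0.0
    ou_rate: float = 1.5
    orientation_drift_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.svma_mean < 0:
            raise ValueError("svma_mean must be >= 0")
        if self.duration_range[0] > self.duration_range[1]:
            raise ValueError("duration_range min must be <= max")


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario request: kind, total duration (s) and phase overrides.

    ``params`` maps phase names to field overrides (e.g.
    ``{"freefall": {"svma_sd": 0.0}}``) and may carry the scenario-level
    key ``magnitude_scale`` (multiplies oscillation amplitudes and spike
    magnitudes; used for per-participant jitter).
    """

    kind: str
    duration: float | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scenario catalogue

_WALK = dict(svma_mean=1.0, svma_sd=0.03, osc_amp=0.3, osc_freq=2.0,
             pitch_target=5.0, orientation_drift_sd=2.0)

_STUMBLE_POSTURE = {
    "fwd": (60.0, 0.0),
    "rear": (-60.0, 0.0),
    "left": (10.0, -60.0),
    "right": (10.0, 60.0),
}

SAFE, FALL, STUMBLE, COMA = (StatusLabel.SAFE, StatusLabel.FALL,
                             StatusLabel.STUMBLE, StatusLabel.COMA)

#: Default scenario durations in seconds.  The default session plan below
#: sums to 550 s = 5500 samples per participant at 10 Hz.
DEFAULT_SCENARIO_DURATION = {
    "walk_even": 50.0,
    "walk_uneven": 50.0,
    "stairs": 35.0,
    "slope": 35.0,
    "gravel": 90.0,
    "motorcycle": 50.0,
    "rest": 100.0,
    "fall_height": 11.0,
    "stumble_fwd": 9.0,
    "stumble_left": 9.0,
    "stumble_right": 9.0,
    "stumble_rear": 9.0,
    "coma_progressive": 45.0,
    "coma_abrupt": 37.0,
}


def _phases_for(kind: str) -> list[PhaseProfile]:
    """Ordered phase list for a scenario kind; the last phase is the fill."""
    if kind == "walk_even":
        return [PhaseProfile("walk", (0, 0), label=SAFE, **_WALK)]
    if kind == "walk_uneven":
        return [PhaseProfile("walk_uneven", (0, 0), label=SAFE,
                             spike_range=(1.5, 2.5), spike_spacing=(0.5, 2.0),
                             **{**_WALK, "orientation_drift_sd": 4.0})]
    if kind == "gravel":
        return [PhaseProfile("gravel", (0, 0), label=SAFE,
                             spike_range=(1.5, 2.5), spike_spacing=(0.6, 2.0),
                             **{**_WALK, "orientation_drift_sd": 4.0})]
    if kind == "slope":
        return [PhaseProfile("slope", (0, 0), label=SAFE,
                             spike_range=(1.5, 2.0), spike_spacing=(1.0, 2.5),
                             **{**_WALK, "pitch_target": 12.0,
                                "orientation_drift_sd": 3.0})]
    if kind == "stairs":
        return [PhaseProfile("stairs", (0, 0), label=SAFE,
                             spike_range=(1.8, 2.2), spike_spacing=(0.5, 0.5),
                             **_WALK)]
    if kind == "motorcycle":
        return [PhaseProfile("motorcycle", (0, 0), svma_mean=1.0, svma_sd=0.12,
                             label=SAFE, spike_range=(2.5, 3.5),
                             spike_spacing=(1.0, 4.0), pitch_target=15.0,
                             orientation_drift_sd=2.0)]
    if kind == "rest":
        return [PhaseProfile("rest_sit", (0, 0), svma_mean=1.0, svma_sd=0.02,
                             label=SAFE, fidget=(5.0, 15.0, 0.1, 0.4),
                             pitch_target=25.0, ou_rate=1.0,
                             orientation_drift_sd=1.0)]
    if kind == "fall_height":
        return [
            PhaseProfile("sway", (2.0, 3.0), svma_mean=1.0, svma_sd=0.05,
                         osc_amp=0.15, osc_freq=1.0, label=SAFE,
                         pitch_target=5.0, orientation_drift_sd=2.0),
            PhaseProfile("freefall", (0.3, 0.8), svma_mean=0.15, svma_sd=0.03,
                         label=FALL, pitch_target=85.0, ou_rate=2.5,
                         orientation_drift_sd=2.0),
            PhaseProfile("impact", (0.1, 0.2), svma_mean=5.0, svma_sd=0.3,
                         mean_range=(4.0, 6.0), label=FALL, pitch_target=85.0,
                         ou_rate=8.0, orientation_drift_sd=5.0),
            PhaseProfile("still_lying", (0, 0), svma_mean=1.0, svma_sd=0.012,
                         label=SAFE, pitch_target=85.0, ou_rate=2.0,
                         orientation_drift_sd=0.3),
        ]
    if kind.startswith("stumble_"):
        direction = kind.split("_", 1)[1]
        if direction not in _STUMBLE_POSTURE:
            raise ValueError(f"unknown stumble direction {direction!r}")
        p_t, r_t = _STUMBLE_POSTURE[direction]
        return [
            PhaseProfile("walk", (2.0, 3.0), label=SAFE, **_WALK),
            PhaseProfile("dip", (0.2, 0.4), svma_mean=0.5, svma_sd=0.05,
                         label=STUMBLE, pitch_target=p_t, roll_target=r_t,
                         ou_rate=3.0, orientation_drift_sd=2.0),
            PhaseProfile("impact", (0.1, 0.2), svma_mean=2.7, svma_sd=0.2,
                         mean_range=(2.0, 3.5), label=STUMBLE,
                         pitch_target=p_t, roll_target=r_t, ou_rate=8.0,
                         orientation_drift_sd=4.0),
            # duration set at instantiation so the labelled span totals 2-3 s
            PhaseProfile("unsteady", (1.6, 2.5), svma_mean=1.0, svma_sd=0.2,
                         osc_amp=0.2, osc_freq=1.5, label=STUMBLE,
                         pitch_target=p_t / 2, roll_target=r_t / 2,
                         ou_rate=1.0, orientation_drift_sd=3.0),
            PhaseProfile("recover_walk", (0, 0), svma_mean=1.0, svma_sd=0.05,
                         osc_amp=0.25, osc_freq=2.0, label=SAFE,
                         pitch_target=5.0, ou_rate=1.5,
                         orientation_drift_sd=2.0),
        ]
    if kind == "coma_progressive":
        return [
            PhaseProfile("rest", (5.0, 8.0), svma_mean=1.0, svma_sd=0.02,
                         label=SAFE, fidget=(5.0, 15.0, 0.1, 0.4),
                         pitch_target=25.0, ou_rate=1.0),
            PhaseProfile("sit_down", (0.8, 1.2), svma_mean=1.45, svma_sd=0.1,
                         mean_range=(1.3, 1.6), label=SAFE, pitch_target=40.0,
                         ou_rate=3.0, orientation_drift_sd=2.0),
            PhaseProfile("still_coma", (0, 0), svma_mean=1.0, svma_sd=0.004,
                         label=COMA, pitch_target=40.0, ou_rate=1.0,
                         orientation_drift_sd=0.05),
        ]
    if kind == "coma_abrupt":
        return [
            PhaseProfile("stand", (3.0, 5.0), svma_mean=1.0, svma_sd=0.03,
                         osc_amp=0.05, osc_freq=1.0, label=SAFE,
                         pitch_target=2.0),
            PhaseProfile("collapse_drop", (0.2, 0.4), svma_mean=0.3,
                         svma_sd=0.05, label=COMA, pitch_target=80.0,
                         ou_rate=3.0, orientation_drift_sd=2.0),
            PhaseProfile("collapse_impact", (0.1, 0.2), svma_mean=3.0,
                         svma_sd=0.2, mean_range=(2.5, 3.5), label=COMA,
                         pitch_target=80.0, ou_rate=8.0,
                         orientation_drift_sd=4.0),
            PhaseProfile("still_coma", (0, 0), svma_mean=1.0, svma_sd=0.004,
                         label=COMA, pitch_target=80.0, ou_rate=2.0,
                         orientation_drift_sd=0.05),
        ]
    raise ValueError(f"unknown scenario kind {kind!r}")


SCENARIO_KINDS = tuple(DEFAULT_SCENARIO_DURATION)


# ---------------------------------------------------------------------------
# Generation

def _instantiate_phases(
    spec: ScenarioSpec, rng: np.random.Generator, dt: float
) -> list[tuple[PhaseProfile, int]]:
    """Draw phase durations/levels and allocate sample counts for a scenario."""
    duration = spec.duration
    if duration is None:
        if spec.kind not in DEFAULT_SCENARIO_DURATION:
            raise ValueError(f"unknown scenario kind {spec.kind!r}")
        duration = DEFAULT_SCENARIO_DURATION[spec.kind]
    n_total = int(round(duration / dt))
    if n_total < 1:
        raise ValueError(f"scenario duration {duration} s too short")
    profiles = _phases_for(spec.kind)
    scale = float(spec.params.get("magnitude_scale", 1.0))

    merged = []
    for p in profiles:
        over = spec.params.get(p.name, {})
        if over:
            p = replace(p, **over)
        merged.append(p)

    # stumble: draw the total labelled span first (2-3 s) so that
    # dip + impact + unsteady realizes it exactly in samples.
    span_budget = None
    if spec.kind.startswith("stumble_"):
        span_budget = int(round(rng.uniform(2.2, 2.8) / dt))

    out: list[tuple[PhaseProfile, int]] = []
    used = 0
    for i, p in enumerate(merged):
        if p.mean_range is not None:
            p = replace(p, svma_mean=float(rng.uniform(*p.mean_range)))
        if scale != 1.0:
            p = replace(
                p,
                osc_amp=p.osc_amp * scale,
                spike_range=tuple(scale * np.asarray(p.spike_range))
                if p.spike_range else None,
            )
        if i == len(merged) - 1:  # fill phase
            n = n_total - used
            if n < 1:
                raise ValueError(
                    f"scenario {spec.kind!r}: duration {duration} s leaves no "
                    "room for its final phase"
                )
        elif p.name == "unsteady" and span_budget is not None:
            already = sum(m for q, m in out if q.label == STUMBLE)
            n = max(1, span_budget - already)
        else:
            lo, hi = p.duration_range
            n = max(1, int(round(rng.uniform(lo, hi) / dt)))
        out.append((p, n))
        used += n
    return out


def _phase_magnitude(p: PhaseProfile, n: int, t0: float,
                     rng: np.random.Generator, dt: float) -> np.ndarray:
    t = t0 + dt * np.arange(n)
    m = np.full(n, p.svma_mean)
    if p.osc_amp:
        phase0 = rng.uniform(0, 2 * np.pi)
        m += p.osc_amp * np.sin(2 * np.pi * p.osc_freq * t + phase0)
    m += rng.normal(0.0, p.svma_sd, n)
    if p.spike_range is not None and p.spike_spacing is not None:
        pos = rng.uniform(*p.spike_spacing)
        while pos < n * dt:
            i = int(pos / dt)
            w = int(rng.integers(p.spike_width[0], p.spike_width[1] + 1))
            m[i:i + w] = rng.uniform(*p.spike_range)
            pos += rng.uniform(*p.spike_spacing)
    if p.fidget is not None:
        sp_lo, sp_hi, amp_lo, amp_hi = p.fidget
        pos = rng.uniform(sp_lo, sp_hi)
        while pos < n * dt:
            i = int(pos / dt)
            w = int(rng.integers(2, 5))
            m[i:i + w] += rng.uniform(amp_lo, amp_hi)
            pos += rng.uniform(sp_lo, sp_hi)
    return np.clip(m, 0.02, None)


def _ou_track(target: float, rate: float, drift_sd: float, n: int,
              prev: float, rng: np.random.Generator, dt: float) -> np.ndarray:
    """Mean-reverting first-order track toward ``target`` starting at ``prev``."""
    a = min(rate * dt, 1.0)
    x = a * target + drift_sd * np.sqrt(dt) * rng.standard_normal(n)
    # y[k] = (1 - a) * y[k-1] + x[k]
    y, _ = lfilter([1.0], [1.0, -(1.0 - a)], x, zi=[(1.0 - a) * prev])
    return y


def _generate(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    dt: float,
    pitch0: float | None = None,
    roll0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[PhaseSpan]]:
    phases = _instantiate_phases(spec, rng, dt)
    mags, pitches, rolls, labels = [], [], [], []
    spans = []
    pitch_prev = phases[0][0].pitch_target if pitch0 is None else pitch0
    roll_prev = phases[0][0].roll_target if roll0 is None else roll0
    idx = 0
    for p, n in phases:
        mags.append(_phase_magnitude(p, n, idx * dt, rng, dt))
        pt = _ou_track(p.pitch_target, p.ou_rate, p.orientation_drift_sd,
                       n, pitch_prev, rng, dt)
        rl = _ou_track(p.roll_target, p.ou_rate, p.orientation_drift_sd,
                       n, roll_prev, rng, dt)
        pitch_prev, roll_prev = pt[-1], rl[-1]
        pitches.append(pt)
        rolls.append(rl)
        labels.append(np.full(n, int(p.label), dtype=np.int64))
        spans.append(PhaseSpan(p.name, idx, idx + n, p.label, spec.kind))
        idx += n
    return (np.concatenate(mags), np.concatenate(pitches),
            np.concatenate(rolls), np.concatenate(labels), spans)


def _assemble(participant_id: str, m, pitch, roll, labels, spans, dt) -> Recording:
    pitch = np.clip(pitch, -90.0, 90.0)
    roll = np.clip(roll, -180.0, 180.0)
    p = np.deg2rad(pitch)
    r = np.deg2rad(roll)
    # gravity direction in the body frame for the given pitch/roll
    ax = -m * np.sin(p)
    ay = m * np.cos(p) * np.sin(r)
    az = m * np.cos(p) * np.cos(r)
    n = len(m)
    return Recording(
        participant_id=participant_id,
        t=dt * np.arange(n), ax=ax, ay=ay, az=az,
        pitch=pitch, roll=roll, labels=labels,
        sampling_interval=dt, phases=list(spans),
    )


def simulate_scenario(
    spec: ScenarioSpec,
    rng_seed: int,
    participant_id: str = "sim",
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
) -> Recording:
    """Generate one labelled scenario recording (deterministic per seed).

    The returned recording carries the realized phase plan in
    ``recording.phases``.
    """
    rng = np.random.default_rng(rng_seed)
    m, pitch, roll, labels, spans = _generate(spec, rng, sampling_interval)
    return _assemble(participant_id, m, pitch, roll, labels, spans,
                     sampling_interval)


def simulate_fall(params: dict | None = None, rng_seed: int = 0,
                  duration: float | None = None) -> Recording:
    """Fall-from-height recording: sway, free-fall dip, impact peak, stillness."""
    return simulate_scenario(
        ScenarioSpec("fall_height", duration=duration, params=params or {}),
        rng_seed,
    )


def simulate_stumble(direction: str = "fwd", rng_seed: int = 0,
                     params: dict | None = None,
                     duration: float | None = None) -> Recording:
    """Directional stumble: dip + smaller impact, 2-3 s labelled span, recovery."""
    return simulate_scenario(
        ScenarioSpec(f"stumble_{direction}", duration=duration,
                     params=params or {}),
        rng_seed,
    )


def default_session_plan() -> list[ScenarioSpec]:
    """The per-participant session emulating the collection protocol.

    Walking tasks, gravel trail (1.5 min), motorcycle ride, two falls from
    height, four directional stumbles, progressive and abrupt comas (still
    span >= 30 s) and 100 s of free rest; 550 s total = 5500 samples at 10 Hz.
    """
    kinds = [
        "walk_even", "walk_uneven", "stairs", "slope", "gravel", "motorcycle",
        "fall_height", "fall_height",
        "stumble_fwd", "stumble_left", "stumble_right", "stumble_rear",
        "coma_progressive", "coma_abrupt", "rest",
    ]
    return [ScenarioSpec(k) for k in kinds]


def simulate_participant(
    participant_index: int,
    rng_seed: int,
    session_plan: list[ScenarioSpec] | None = None,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
) -> Recording:
    """One participant's full session; deterministic in (index, master seed).

    Per-participant jitter scales oscillation amplitudes and surface-spike
    magnitudes by a factor drawn in [0.9, 1.1].
    """
    if session_plan is None:
        session_plan = default_session_plan()
    if not session_plan:
        raise ValueError("session_plan must contain at least one scenario")
    ss = np.random.SeedSequence(entropy=rng_seed, spawn_key=(participant_index,))
    rng = np.random.default_rng(ss)
    scale = float(rng.uniform(0.9, 1.1))

    mags, pitches, rolls, labels, spans = [], [], [], [], []
    offset = 0
    pitch_prev = roll_prev = None
    for spec in session_plan:
        params = dict(spec.params)
        params.setdefault("magnitude_scale", scale)
        spec_j = dataclasses.replace(spec, params=params)
        m, pt, rl, lb, sp = _generate(spec_j, rng, sampling_interval,
                                      pitch0=pitch_prev, roll0=roll_prev)
        pitch_prev, roll_prev = None, None  # restart posture at next scenario
        mags.append(m); pitches.append(pt); rolls.append(rl); labels.append(lb)
        spans.extend(
            PhaseSpan(s.name, s.start + offset, s.stop + offset, s.label,
                      s.scenario)
            for s in sp
        )
        offset += len(m)
    return _assemble(
        f"P{participant_index:02d}",
        np.concatenate(mags), np.concatenate(pitches), np.concatenate(rolls),
        np.concatenate(labels), spans, sampling_interval,
    )


def simulate_cohort(
    n_participants: int,
    rng_seed: int,
    session_plan: list[ScenarioSpec] | None = None,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
) -> Dataset:
    """Simulate a cohort: one session recording per participant.

    The default 30-participant cohort on the default plan yields 165,000
    samples (30 x 5500), mirroring the scale of the emulated collection.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    recs = [
        simulate_participant(i, rng_seed, session_plan, sampling_interval)
        for i in range(n_participants)
    ]
    return Dataset(recs, sampling_interval)
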