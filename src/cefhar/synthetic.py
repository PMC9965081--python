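"""Synthetic wrist-accelerometer datasets replicating the collection protocol.

The study dataset this package targets is private, so the generator emulates its
structure: 8 subjects, 250-frame samples at 15 fps, 6 single-activity and 12
two-activity scripts, 10 repetitions each (1440 recordings, 180 per subject).
Activities occur at varying onsets inside each recording; every other frame is
the no-movement background.

Signals are built from a gravity-orientation model.  Each posture (standing,
seated, lying, bent-over) corresponds to a unit gravity direction in the sensor
frame; a transition activity is a smooth reorientation ramp between its start
and end posture plus an activity-specific transient bump, and walking is a
quasi-periodic oscillation (~2 Hz step frequency with a first harmonic) around
the standing orientation.  Background adds Gaussian noise and a small slow
orientation wobble so "no movement" is never exactly constant.  Motif shapes,
the orientation table, and duration ranges are documented package constants
chosen so classes are separable and transitions are brief relative to the
recording; they make no claim to biomechanical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import (
    ACTIVITY_NAMES,
    AccelSample,
    ActivityCatalog,
    Dataset,
    canonical_catalog,
)

__all__ = [
    "GeneratorConfig",
    "ActivityScript",
    "SubjectParams",
    "MotifParams",
    "TABLE_SCRIPTS",
    "ORIENTATIONS",
    "activity_motif",
    "generate_sample",
    "generate_dataset",
    "subject_label",
]

# --- posture gravity directions (unit vectors, sensor frame, units of g) -----
_STANDING = np.array([0.0, 0.0, 1.0])
_SEATED = np.array([0.6, 0.0, 0.8])
_LYING = np.array([1.0, 0.0, 0.0])

#: start / end posture per transition activity; walking and picking return to
#: their start posture (picking via a bent-over excursion).
ORIENTATIONS: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "get-up": (_LYING, _STANDING),
    "laying": (_STANDING, _LYING),
    "stand-up": (_SEATED, _STANDING),
    "sitting": (_STANDING, _SEATED),
    "picking": (_STANDING, _STANDING),
    "walking": (_STANDING, _STANDING),
}

# picking's mid-motif bent-over excursion target
_BENT = np.array([0.15, 0.75, 0.64])


@dataclass(frozen=True)
class MotifParams:
    """Per-activity motif constants.

    duration_range
        admissible segment lengths in frames (half-open low/high for the RNG).
    bump_amplitude, bump_freq_hz
        transient jerk superposed on the reorientation ramp; the envelope
        vanishes at the segment endpoints so motifs join the background
        continuously.
    bump_axes
        unit-less per-axis weights of the bump.
    """

    duration_range: tuple[int, int]
    bump_amplitude: float
    bump_freq_hz: float
    bump_axes: tuple[float, float, float]


# Transitions last 15-45 frames (1-3 s at 15 fps); walking 45-120 frames.
# Bump frequency/axis signatures are distinct per class so that activities
# sharing an orientation delta (or its reverse) remain separable.
DEFAULT_MOTIFS: dict[str, MotifParams] = {
    "get-up": MotifParams((20, 45), 0.35, 1.2, (0.2, 0.9, 0.4)),
    "laying": MotifParams((20, 45), 0.30, 0.8, (0.7, 0.3, 0.6)),
    "stand-up": MotifParams((15, 35), 0.30, 1.6, (0.3, 0.8, 0.5)),
    "sitting": MotifParams((15, 35), 0.25, 1.0, (0.8, 0.2, 0.5)),
    "picking": MotifParams((15, 40), 0.40, 1.8, (0.4, 0.6, 0.7)),
    "walking": MotifParams((45, 120), 0.25, 2.0, (1.0, 0.35, 0.5)),
}


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject scales applied to every motif of that subject."""

    amp_scale: float = 1.0
    freq_scale: float = 1.0
    dur_scale: float = 1.0


@dataclass(frozen=True)
class ActivityScript:
    """An ordered list of 1 or 2 non-background activities to perform."""

    activities: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.activities) <= 2:
            raise ValueError("a script holds 1 or 2 activities")
        for a in self.activities:
            if a == "background" or a not in ORIENTATIONS:
                raise ValueError(f"invalid script activity {a!r}")

    @property
    def name(self) -> str:
        return "—".join(self.activities)  # em-dash, matching protocol naming


#: The 18 protocol scripts: 6 singles plus the 12 ordered pairs of the study grid.
TABLE_SCRIPTS: tuple[ActivityScript, ...] = tuple(
    ActivityScript(tuple(acts))
    for acts in [
        ("get-up",),
        ("laying",),
        ("stand-up",),
        ("picking",),
        ("sitting",),
        ("walking",),
        ("walking", "picking"),
        ("walking", "sitting"),
        ("stand-up", "walking"),
        ("sitting", "laying"),
        ("get-up", "stand-up"),
        ("picking", "walking"),
        ("get-up", "laying"),
        ("laying", "get-up"),
        ("stand-up", "picking"),
        ("stand-up", "sitting"),
        ("picking", "sitting"),
        ("sitting", "stand-up"),
    ]
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Protocol + signal-model parameters; defaults replicate the study grid."""

    n_subjects: int = 8
    reps: int = 10
    sample_length: int = 250
    fps: float = 15.0
    noise_sd: float = 0.03  # g, white per-axis sensor noise
    wobble_amplitude: float = 0.004  # g, slow background orientation wobble
    wobble_freq_hz: float = 0.1
    walk_amplitude: float = 0.25  # g, anterior-axis stride oscillation
    walk_freq_hz: float = 2.0  # base step frequency before subject scaling
    min_gap: int = 5  # frames of background between two segments
    edge_margin: int = 3  # background frames guaranteed at either end
    amp_scale_range: tuple[float, float] = (0.8, 1.2)
    freq_scale_range: tuple[float, float] = (0.85, 1.15)
    dur_scale_range: tuple[float, float] = (0.85, 1.15)
    motifs: dict[str, MotifParams] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.sample_length < 1:
            raise ValueError("sample_length must be positive")
        for name, m in self.motifs.items():
            lo, hi = m.duration_range
            if not 1 <= lo <= hi:
                raise ValueError(f"{name}: invalid duration range {m.duration_range}")
        # the longest admissible realization of any protocol script must fit
        def worst_case(script: "ActivityScript") -> int:
            need = sum(
                int(np.ceil(self.motifs[a].duration_range[1] * self.dur_scale_range[1]))
                for a in script.activities
            )
            if len(script.activities) == 2:
                need += self.min_gap
            return need + 2 * self.edge_margin

        worst = max(worst_case(s) for s in TABLE_SCRIPTS)
        if self.sample_length < worst:
            raise ValueError(
                f"sample_length {self.sample_length} cannot fit the longest "
                f"admissible script realization (needs {worst} frames)"
            )


def subject_label(i: int) -> str:
    """Subject identifiers a, b, c, ... matching the protocol table."""
    if i < 26:
        return chr(ord("a") + i)
    return f"s{i}"


def _smoothstep(tau: np.ndarray) -> np.ndarray:
    return tau * tau * (3.0 - 2.0 * tau)


def _onoff_envelope(duration: int, ramp: int) -> np.ndarray:
    """Trapezoidal envelope: 0 at the segment endpoints, 1 in the interior.

    The ramps are brief (a fraction of a second) so labelled frames carry
    activity-level signal almost everywhere — the label sequence and the
    signal energy stay coupled — while the segment still joins the
    surrounding background continuously.
    """
    t = np.arange(duration, dtype=float)
    if duration == 1:
        return np.zeros(1)
    r = max(1, min(ramp, (duration - 1) // 2))
    return np.clip(np.minimum(t, duration - 1 - t) / r, 0.0, 1.0)


def activity_motif(
    activity: str,
    duration: int,
    subject_params: SubjectParams,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
    start_orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free-baseline motif plus sensor noise: a ``(duration, 3)`` signal in g.

    Transition activities ramp smoothly between their configured start and end
    gravity orientations with a vanishing-endpoint transient bump; walking is a
    quasi-periodic oscillation around the standing orientation with a first
    harmonic.  ``start_orientation`` lets callers splice motifs continuously
    into an ongoing recording; the default is the activity's table start.
    """
    if activity == "background":
        raise ValueError(
            "background is the generator's default state, not a motif"
        )
    if activity not in ORIENTATIONS:
        raise ValueError(f"unknown activity {activity!r}")
    if duration < 1:
        raise ValueError("duration must be >= 1")
    config = config or GeneratorConfig()
    mp = config.motifs[activity]
    start, end = ORIENTATIONS[activity]
    if start_orientation is not None:
        start = np.asarray(start_orientation, dtype=float)
        if activity in ("picking", "walking"):
            end = start  # excursion activities return to where they began
    t = np.arange(duration, dtype=float)
    tau = t / (duration - 1) if duration > 1 else np.ones(1)
    sig = np.empty((duration, 3))

    if activity == "walking":
        f = config.walk_freq_hz * subject_params.freq_scale
        amp = config.walk_amplitude * subject_params.amp_scale
        phase = rng.uniform(0, 2 * np.pi)
        osc = amp * np.sin(2 * np.pi * f * t / config.fps + phase)
        harm = 0.4 * amp * np.sin(4 * np.pi * f * t / config.fps + 2 * phase)
        env = _onoff_envelope(duration, ramp=5)  # ~1 step of gait spin-up
        sig[:] = start[None, :]
        axes = np.asarray(mp.bump_axes)
        sig += env[:, None] * (osc + harm)[:, None] * axes[None, :]
    else:
        ramp = start[None, :] + _smoothstep(tau)[:, None] * (end - start)[None, :]
        if activity == "picking":
            # out-and-back excursion toward the bent-over posture
            ramp = ramp + np.sin(np.pi * tau)[:, None] * (_BENT - start)[None, :]
        f = mp.bump_freq_hz * subject_params.freq_scale
        amp = mp.bump_amplitude * subject_params.amp_scale
        phase = rng.uniform(0, 2 * np.pi)
        env = _onoff_envelope(duration, ramp=3)
        bump = amp * env * np.sin(2 * np.pi * f * t / config.fps + phase)
        sig = ramp + bump[:, None] * np.asarray(mp.bump_axes)[None, :]

    sig += rng.normal(0.0, config.noise_sd, size=sig.shape)
    return sig


def _background(
    n: int,
    orientation: np.ndarray,
    rng: np.random.Generator,
    config: GeneratorConfig,
    t0: int,
    wobble_phase: np.ndarray,
) -> np.ndarray:
    """Stationary posture: gravity + slow wobble + white noise."""
    t = np.arange(t0, t0 + n, dtype=float)
    arg = 2 * np.pi * config.wobble_freq_hz * t[:, None] / config.fps + wobble_phase
    sig = orientation[None, :] + config.wobble_amplitude * np.sin(arg)
    sig += rng.normal(0.0, config.noise_sd, size=(n, 3))
    return sig


def _draw_duration(
    mp: MotifParams, subject: SubjectParams, rng: np.random.Generator
) -> int:
    lo, hi = mp.duration_range
    d = int(round(rng.integers(lo, hi + 1) * subject.dur_scale))
    return max(1, d)


def generate_sample(
    config: GeneratorConfig,
    script: ActivityScript,
    subject_id: str,
    rng: np.random.Generator,
    subject_params: SubjectParams | None = None,
    sample_id: str | None = None,
) -> AccelSample:
    """One scripted recording: background everywhere except the script's segments.

    Segment durations are drawn from each activity's configured range (scaled by
    the subject), onsets uniformly subject to fit, ordering, and a minimum
    background gap.  Orientation is continuous across segment boundaries: the
    recording opens in the first activity's start posture, and each segment
    starts from whatever posture the previous one left behind.
    """
    T = config.sample_length
    sp = subject_params or SubjectParams()
    catalog = canonical_catalog()

    durations = [_draw_duration(config.motifs[a], sp, rng) for a in script.activities]
    total = sum(durations)
    free = T - total - 2 * config.edge_margin
    if len(durations) == 2:
        free -= config.min_gap
    if free < 0:
        raise ValueError(
            f"script {script.name!r} with durations {durations} cannot fit in "
            f"{T} frames"
        )
    # distribute the free background frames over the 2 or 3 gaps
    n_gaps = len(durations) + 1
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1))
    slack = np.diff(np.concatenate(([0], cuts, [free])))
    onsets = []
    pos = config.edge_margin + int(slack[0])
    for i, d in enumerate(durations):
        onsets.append(pos)
        pos += d
        if i + 1 < len(durations):
            pos += config.min_gap + int(slack[i + 1])

    frames = np.empty((T, 3))
    labels = np.zeros(T, dtype=np.int64)
    wobble_phase = rng.uniform(0, 2 * np.pi, size=3)
    orientation = ORIENTATIONS[script.activities[0]][0]
    cursor = 0
    for act, onset, dur in zip(script.activities, onsets, durations):
        if onset > cursor:
            frames[cursor:onset] = _background(
                onset - cursor, orientation, rng, config, cursor, wobble_phase
            )
        frames[onset : onset + dur] = activity_motif(
            act, dur, sp, rng, config, start_orientation=orientation
        )
        labels[onset : onset + dur] = catalog.index_of(act)
        if act in ("picking", "walking"):
            pass  # returns to the posture it started from
        else:
            orientation = ORIENTATIONS[act][1]
        cursor = onset + dur
    if cursor < T:
        frames[cursor:] = _background(
            T - cursor, orientation, rng, config, cursor, wobble_phase
        )

    return AccelSample(
        frames=frames,
        labels=labels,
        subject_id=subject_id,
        sample_id=sample_id or f"{subject_id}-{script.name}",
        fps=config.fps,
    )


def _subject_params(config: GeneratorConfig, subject_index: int) -> SubjectParams:
    ss = np.random.SeedSequence((config.seed, 0x5B, subject_index))
    r = np.random.default_rng(ss)
    return SubjectParams(
        amp_scale=r.uniform(*config.amp_scale_range),
        freq_scale=r.uniform(*config.freq_scale_range),
        dur_scale=r.uniform(*config.dur_scale_range),
    )


def generate_dataset(config: GeneratorConfig | None = None) -> Dataset:
    """The full protocol grid: every subject x 18 scripts x ``reps`` repetitions.

    Each sample draws from an independent random stream keyed by
    ``(seed, subject, script, rep)``, so datasets are reproducible and
    order-independent; subject scale parameters are drawn once per subject.
    """
    config = config or GeneratorConfig()
    samples = []
    for si in range(config.n_subjects):
        sid = subject_label(si)
        sp = _subject_params(config, si)
        for ci, script in enumerate(TABLE_SCRIPTS):
            for rep in range(config.reps):
                ss = np.random.SeedSequence((config.seed, 1, si, ci, rep))
                rng = np.random.default_rng(ss)
                samples.append(
                    generate_sample(
                        config,
                        script,
                        sid,
                        rng,
                        subject_params=sp,
                        sample_id=f"{sid}-{script.name}-r{rep:02d}",
                    )
                )
    return Dataset(samples=samples, catalog=canonical_catalog())
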