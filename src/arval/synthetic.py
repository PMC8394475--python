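"""Synthetic paired recordings of the validation protocol.

The generator emulates the study setup: a subject wearing a phone-holding
headset performs, per trial, a synchronization movement (five head nods)
followed by scripted exercises (squats, side-steps, step-ups) or about a
minute of free play.  The noise-free head trajectory ("ground truth") is
built from smooth raised-cosine motion primitives and then degraded twice:

* into a *reference* recording — dense sampling (default 120 Hz) with
  sub-millimetre white position noise, in the lab frame;
* into a *training-game* (TG) recording — sparse sampling (default
  30 Hz), started with a lag relative to the reference, expressed in the
  TG's own world frame (rotated/offset from the lab frame), with larger
  white noise on positions and rotations and an optional linear drift.

Every quantity the downstream pipeline estimates (lag, frame alignment,
per-rep amplitudes) is therefore known exactly, which is what makes the
analysis testable without the original laboratory recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .trajectory_io import (
    CHANNELS,
    POSITION_CHANNELS,
    ROTATION_CHANNELS,
    PoseTrack,
    euler_to_matrix,
    matrix_to_euler,
)

#: reference stature (mm) at which the configured absolute displacements apply
REFERENCE_HEIGHT = 1750.0

#: scripted protocol of the first trial
TRIAL1_PROTOCOL: tuple[str, ...] = (
    ("nod",)
    + ("squat",) * 3
    + ("side_step_right",) * 3
    + ("step_up",) * 3
    + ("side_step_left",) * 3
)

#: trial 2: nods, then randomized free play for about a minute
TRIAL2_PROTOCOL: tuple[str, ...] = ("nod", "free_play")

# segment durations (s)
_DUR = {
    "nod": 5.0,
    "squat": 3.0,
    "side_step_right": 2.5,
    "side_step_left": 2.5,
    "step_up": 3.5,
}
_REST = 1.0
_LEAD = 2.0
_TAIL = 2.0

#: coupled translation accompanying the nods (mm), so that positional
#: cross-correlation can also lock onto the synchronization movement
NOD_COUPLING_MM = 20.0


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    height: float  # mm
    seed: int

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValidationError("height must be positive")


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated trial.

    Displacement defaults are values at the reference stature (1750 mm)
    and scale linearly with subject height; each repetition additionally
    receives a small seeded multiplicative jitter (``rep_jitter_frac``),
    mimicking natural rep-to-rep variability.

    The TG position error has two parts: white per-frame jitter
    (``tg_noise_sd``) and a slow wander of the world-frame anchor
    (``tg_wander_sd``, an Ornstein-Uhlenbeck process with correlation
    time ``tg_wander_tau``).  The split matters: per-frame trajectory
    error is governed by the total sd, while per-rep amplitude error is
    governed mostly by the slow part, exactly the asymmetry real
    inertial-plus-vision trackers show.
    """

    protocol: Sequence[str] = TRIAL1_PROTOCOL
    squat_depth_frac: float = 0.20  # fraction of height
    step_height: float = 200.0  # mm at reference stature
    sidestep_width: float = 300.0  # mm at reference stature
    nod_amplitude: float = 20.0  # deg
    ref_rate: float = 120.0  # Hz
    tg_rate: float = 30.0  # Hz
    ref_noise_sd: float = 0.5  # mm
    tg_noise_sd: float = 5.0  # mm, white per-frame jitter
    tg_wander_sd: float = 22.0  # mm, slow tracking error (OU process)
    tg_wander_tau: float = 2.0  # s, correlation time of the wander
    tg_rot_noise_sd: float = 0.75  # deg
    injected_lag: float = 0.5  # s, positive = TG behind reference
    frame_rotation: tuple[float, float, float] = (0.0, 0.0, 90.0)  # deg about lab axes
    frame_offset: tuple[float, float, float] = (250.0, -150.0, 80.0)  # mm
    drift_rate: float = 0.0  # mm/s on each position axis
    rep_jitter_frac: float = 0.10
    free_play_duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_rate <= 0 or self.tg_rate <= 0:
            raise ValidationError("sampling rates must be positive")
        for name in ("ref_noise_sd", "tg_noise_sd", "tg_wander_sd", "tg_rot_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.protocol:
            raise ValidationError("protocol must be non-empty")
        if not 0 <= self.rep_jitter_frac < 0.5:
            raise ValidationError("rep_jitter_frac must be in [0, 0.5)")
        if not 0 < self.squat_depth_frac < 1:
            raise ValidationError("squat_depth_frac must be in (0, 1)")


@dataclass(frozen=True)
class Segment:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"segment {self.label!r} has end <= start")


@dataclass(frozen=True)
class RepTruth:
    """Ground-truth repetition: label, interval and true amplitude (mm)."""

    exercise: str
    start: float
    end: float
    axis: str
    amplitude: float


@dataclass(frozen=True)
class _Pulse:
    channel: str
    t0: float
    t1: float
    amplitude: float
    shape: str  # cosine | plateau | nod


def _pulse_values(pulse: _Pulse, t: np.ndarray, sorted_t: bool = False) -> np.ndarray:
    out = np.zeros_like(t)
    if sorted_t:
        lo = int(np.searchsorted(t, pulse.t0, side="left"))
        hi = int(np.searchsorted(t, pulse.t1, side="right"))
        m = slice(lo, hi)
    else:
        m = (t >= pulse.t0) & (t <= pulse.t1)
    um = (t[m] - pulse.t0) / (pulse.t1 - pulse.t0)
    a = pulse.amplitude
    if pulse.shape == "cosine":
        out[m] = a * 0.5 * (1.0 - np.cos(2.0 * np.pi * um))
    elif pulse.shape == "plateau":
        r = 0.3
        v = np.empty_like(um)
        rise = um < r
        hold = (um >= r) & (um <= 1.0 - r)
        fall = um > 1.0 - r
        v[rise] = 0.5 * (1.0 - np.cos(np.pi * um[rise] / r))
        v[hold] = 1.0
        v[fall] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - um[fall]) / r))
        out[m] = a * v
    elif pulse.shape == "nod":
        window = 0.5 * (1.0 - np.cos(2.0 * np.pi * um))
        out[m] = a * np.sin(2.0 * np.pi * 5.0 * um) * window
    else:  # pragma: no cover
        raise ValueError(f"unknown pulse shape {pulse.shape!r}")
    return out


@dataclass
class GroundTruth:
    """Noise-free head trajectory in the lab frame plus its annotation.

    The trajectory is stored analytically (a sum of pulses over constant
    baselines) and can be evaluated at arbitrary times; outside the
    recording the pose is held at its boundary value.
    """

    profile: SubjectProfile
    config: GeneratorConfig
    duration: float
    segments: list[Segment]
    reps: list[RepTruth]
    pulses: list[_Pulse]
    baseline: dict[str, float]
    _track: PoseTrack | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        segs = sorted(self.segments, key=lambda s: s.start)
        tol = 1e-9
        if segs:
            if abs(segs[0].start) > tol or abs(segs[-1].end - self.duration) > tol:
                raise ValidationError("segments do not tile the recording")
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end - tol:
                    raise ValidationError(
                        f"segments {a.label!r} and {b.label!r} overlap"
                    )
                if b.start > a.end + tol:
                    raise ValidationError("segments leave a gap in the recording")
        self.segments = segs

    def eval_channels(self, t: np.ndarray) -> dict[str, np.ndarray]:
        tc = np.clip(np.asarray(t, dtype=float), 0.0, self.duration)
        sorted_t = tc.ndim == 1 and bool(np.all(np.diff(tc) >= 0))
        out = {name: np.full(tc.shape, self.baseline.get(name, 0.0)) for name in CHANNELS}
        for pulse in self.pulses:
            if pulse.amplitude == 0.0:
                continue
            out[pulse.channel] = out[pulse.channel] + _pulse_values(pulse, tc, sorted_t)
        return out

    @property
    def track(self) -> PoseTrack:
        """The ground truth sampled at the reference rate (noise-free)."""
        if self._track is None:
            rate = self.config.ref_rate
            n = int(round(self.duration * rate))
            t = np.arange(n) / rate
            self._track = PoseTrack.from_channels(
                t, self.eval_channels(t), device="truth", nominal_rate=rate
            )
        return self._track

    def exercise_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label not in ("rest", "nod")]


def generate_subject(seed: int, subject_id: str | None = None) -> SubjectProfile:
    """Draw a subject whose stature follows the study population.

    Height ~ Normal(1750 mm, 100 mm) truncated to [1400, 2100] mm by
    rejection; reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    while True:
        h = rng.normal(1750.0, 100.0)
        if 1400.0 <= h <= 2100.0:
            break
    return SubjectProfile(
        subject_id=subject_id if subject_id is not None else f"S{seed}",
        height=float(h),
        seed=int(seed),
    )


_EXERCISE_BUILD: dict[str, tuple[str, str, float]] = {
    # label -> (channel, shape, sign)
    "squat": ("pos_longitudinal", "cosine", -1.0),
    "step_up": ("pos_longitudinal", "plateau", +1.0),
    "side_step_right": ("pos_transversal", "cosine", +1.0),
    "side_step_left": ("pos_transversal", "cosine", -1.0),
}


def _nominal_displacement(label: str, profile: SubjectProfile, config: GeneratorConfig) -> float:
    scale = profile.height / REFERENCE_HEIGHT
    if label == "squat":
        return config.squat_depth_frac * profile.height
    if label == "step_up":
        return config.step_height * scale
    if label in ("side_step_right", "side_step_left"):
        return config.sidestep_width * scale
    raise ValidationError(f"unknown exercise label {label!r}")


def _expand_protocol(config: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    out: list[str] = []
    choices = ("squat", "side_step_right", "step_up", "side_step_left")
    for label in config.protocol:
        if label == "free_play":
            elapsed = 0.0
            while elapsed < config.free_play_duration:
                ex = choices[rng.integers(len(choices))]
                out.append(ex)
                elapsed += _DUR[ex] + _REST
        else:
            out.append(label)
    return out


def generate_ground_truth(profile: SubjectProfile, config: GeneratorConfig) -> GroundTruth:
    """Lay the protocol out on a timeline of smooth motion primitives.

    Squats are raised-cosine dips on the longitudinal axis, step-ups
    rise-hold-fall plateaus, side-steps out-and-back raised-cosine
    excursions on the transversal axis (one repetition per excursion), and
    the nod block is five flexion oscillations with a +/-20 mm coupled
    sagittal/longitudinal translation.  Rest gaps separate all segments,
    so segments tile the recording exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
    labels = _expand_protocol(config, rng)
    if not labels:
        raise ValidationError("expanded protocol is empty")

    segments: list[Segment] = []
    reps: list[RepTruth] = []
    pulses: list[_Pulse] = []
    baseline = {name: 0.0 for name in CHANNELS}
    baseline["pos_longitudinal"] = 0.94 * profile.height

    t = 0.0

    def add_rest(dur: float) -> None:
        nonlocal t
        segments.append(Segment("rest", t, t + dur))
        t += dur

    add_rest(_LEAD)
    for i, label in enumerate(labels):
        dur = _DUR[label]
        seg = Segment(label, t, t + dur)
        segments.append(seg)
        if label == "nod":
            # coupled translation scales with the nod amplitude (1 mm per deg
            # at the default 20 deg), so a zero-amplitude nod is truly static
            coupling = NOD_COUPLING_MM * config.nod_amplitude / 20.0
            pulses.append(_Pulse("rot_flexion", t, t + dur, config.nod_amplitude, "nod"))
            pulses.append(_Pulse("pos_sagittal", t, t + dur, coupling, "nod"))
            pulses.append(_Pulse("pos_longitudinal", t, t + dur, -coupling, "nod"))
        else:
            channel, shape, sign = _EXERCISE_BUILD[label]
            amp = _nominal_displacement(label, profile, config)
            if config.rep_jitter_frac > 0:
                factor = 1.0 + config.rep_jitter_frac * rng.standard_normal()
                amp *= max(factor, 0.5)
            pulses.append(_Pulse(channel, t, t + dur, sign * amp, shape))
            if label in ("squat", "step_up"):
                # squatting/stepping tips the head forward; gives the sagittal
                # axis real signal so frame registration is well conditioned
                pulses.append(_Pulse("pos_sagittal", t, t + dur, 0.3 * amp, "cosine"))
            exercise = "side_step" if label.startswith("side_step") else label
            axis = channel.removeprefix("pos_")
            reps.append(RepTruth(exercise, t, t + dur, axis, float(amp)))
        t += dur
        add_rest(_REST if i < len(labels) - 1 else _TAIL)

    return GroundTruth(
        profile=profile,
        config=config,
        duration=t,
        segments=segments,
        reps=reps,
        pulses=pulses,
        baseline=baseline,
    )


def _noise_rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, stream]))


def _ou_process(
    rng: np.random.Generator, n: int, dt: float, sd: float, tau: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path: sd ``sd``, corr. time ``tau``.

    Models the slow wander of the TG's world-frame anchor (feature-point
    relocalization and IMU integration error) as a Gaussian process with
    exponential autocorrelation.
    """
    from scipy.signal import lfilter

    a = math.exp(-dt / tau)
    e = rng.standard_normal(n) * (sd * math.sqrt(1.0 - a * a))
    e[0] = rng.standard_normal() * sd  # stationary start
    return lfilter([1.0], [1.0, -a], e)


def degrade_to_reference(truth: GroundTruth, config: GeneratorConfig | None = None) -> PoseTrack:
    """Sample the truth at the reference rate with white position noise.

    The reference system resolves markers to well under a millimetre, so
    the default noise is sub-millimetre and rotations are left noise-free.
    """
    config = config or truth.config
    n = int(round(truth.duration * config.ref_rate))
    t = np.arange(n) / config.ref_rate
    channels = truth.eval_channels(t)
    if config.ref_noise_sd > 0:
        rng = _noise_rng(config, 1)
        for name in POSITION_CHANNELS:
            channels[name] = channels[name] + rng.normal(0.0, config.ref_noise_sd, n)
    return PoseTrack.from_channels(
        t, channels, device="reference", nominal_rate=config.ref_rate
    )


def degrade_to_tg(truth: GroundTruth, config: GeneratorConfig | None = None) -> PoseTrack:
    """Produce the training-game stream from the same truth.

    The TG starts ``injected_lag`` seconds after (positive) or before the
    reference clock, reports in its own world frame (``frame_rotation``
    about the lab axes followed by ``frame_offset``), samples at
    ``tg_rate`` and adds white noise on positions and rotations, the slow
    positional wander, plus an optional linear drift.
    """
    config = config or truth.config
    n = int(round(truth.duration * config.tg_rate))
    t = np.arange(n) / config.tg_rate
    channels = truth.eval_channels(t - config.injected_lag if config.injected_lag else t)

    rotate = any(abs(a) > 0 for a in config.frame_rotation)
    if rotate:
        r_frame = Rotation.from_euler("xyz", config.frame_rotation, degrees=True)
        pos = np.stack([channels[c] for c in POSITION_CHANNELS], axis=1)
        pos = pos @ r_frame.as_matrix().T
        for i, c in enumerate(POSITION_CHANNELS):
            channels[c] = pos[:, i]
        r_dev = euler_to_matrix(
            channels["rot_rotation"], channels["rot_flexion"], channels["rot_lateral_flexion"]
        )
        rot, flex, latflex = matrix_to_euler(r_frame * r_dev)
        channels["rot_rotation"], channels["rot_flexion"], channels["rot_lateral_flexion"] = (
            rot,
            flex,
            latflex,
        )
    if any(abs(o) > 0 for o in config.frame_offset):
        for c, off in zip(POSITION_CHANNELS, config.frame_offset):
            channels[c] = channels[c] + off
    if config.drift_rate:
        for c in POSITION_CHANNELS:
            channels[c] = channels[c] + config.drift_rate * t
    if config.tg_noise_sd > 0 or config.tg_rot_noise_sd > 0:
        rng = _noise_rng(config, 2)
        for c in POSITION_CHANNELS:
            channels[c] = channels[c] + rng.normal(0.0, config.tg_noise_sd, n)
        for c in ROTATION_CHANNELS:
            channels[c] = channels[c] + rng.normal(0.0, config.tg_rot_noise_sd, n)
    if config.tg_wander_sd > 0:
        rng = _noise_rng(config, 3)
        dt = 1.0 / config.tg_rate
        for c in POSITION_CHANNELS:
            channels[c] = channels[c] + _ou_process(
                rng, n, dt, config.tg_wander_sd, config.tg_wander_tau
            )
    return PoseTrack.from_channels(t, channels, device="tg", nominal_rate=config.tg_rate)


def generate_trial(
    profile: SubjectProfile, config: GeneratorConfig
) -> tuple[GroundTruth, PoseTrack, PoseTrack]:
    """Convenience wrapper: truth plus both degraded recordings."""
    truth = generate_ground_truth(profile, config)
    return truth, degrade_to_reference(truth, config), degrade_to_tg(truth, config)
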