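"""Repetition segmentation, amplitudes and exercise recognition.

Each exercise has a primary anatomical axis — the axis with the largest
excursion: transversal for the side-step, longitudinal for the squat and
the step-up.  A repetition's amplitude is the max-minus-min of the
primary-axis channel inside the repetition interval, with each extremum
found independently of when it occurs, so the measure is invariant to
time reversal or any reordering of samples.

Recognition mirrors how the training game itself classifies movement:
displacement thresholds scaled to the individual user's height, with the
sign of the longitudinal excursion separating squats (down) from
step-ups (up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ValidationError
from .trajectory_io import PoseTrack

EXERCISES = ("squat", "side_step", "step_up")

_PRIMARY_AXIS = {
    "side_step": "transversal",
    "squat": "longitudinal",
    "step_up": "longitudinal",
}


def primary_axis(exercise: str) -> str:
    """Primary movement axis of an exercise label."""
    try:
        return _PRIMARY_AXIS[exercise]
    except KeyError:
        raise ValidationError(f"unknown exercise {exercise!r}") from None


@dataclass(frozen=True)
class ExerciseRep:
    """One detected repetition of an exercise."""

    exercise: str
    start: float
    end: float
    axis: str
    amplitude: float
    source: str = "tg"  # tg | reference

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValidationError(f"unknown exercise {self.exercise!r}")
        if self.end <= self.start:
            raise ValidationError("rep interval has end <= start")
        if self.axis != primary_axis(self.exercise):
            raise ValidationError(
                f"axis {self.axis!r} does not match primary axis of {self.exercise!r}"
            )
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass
class ThresholdSet:
    """Height-scaled recognition thresholds (fractions of user height).

    Defaults leave at least a factor-of-two margin below the default
    synthetic displacements (squat 0.20 x height, step-up ~0.11 x height,
    side-step ~0.17 x height).
    """

    squat_frac: float = 0.10
    step_up_frac: float = 0.07
    side_step_frac: float = 0.10
    min_rep_duration: float = 0.8  # s

    def __post_init__(self) -> None:
        for name in ("squat_frac", "step_up_frac", "side_step_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.min_rep_duration <= 0:
            raise ValidationError("min_rep_duration must be positive")

    def threshold_mm(self, exercise: str, height: float) -> float:
        frac = {
            "squat": self.squat_frac,
            "step_up": self.step_up_frac,
            "side_step": self.side_step_frac,
        }[exercise]
        return frac * height


@dataclass
class PairedAmplitudes:
    """TG and reference amplitudes matched repetition-by-repetition."""

    exercises: list[str] = field(default_factory=list)
    tg_amplitude: list[float] = field(default_factory=list)
    ref_amplitude: list[float] = field(default_factory=list)
    intervals: list[tuple[float, float]] = field(default_factory=list)
    unmatched_tg: list[ExerciseRep] = field(default_factory=list)
    unmatched_ref: list[ExerciseRep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.exercises)

    def for_exercise(self, exercise: str) -> tuple[np.ndarray, np.ndarray]:
        mask = [e == exercise for e in self.exercises]
        tg = np.asarray(self.tg_amplitude, dtype=float)[mask]
        ref = np.asarray(self.ref_amplitude, dtype=float)[mask]
        return tg, ref

    def extend(self, other: "PairedAmplitudes") -> None:
        self.exercises.extend(other.exercises)
        self.tg_amplitude.extend(other.tg_amplitude)
        self.ref_amplitude.extend(other.ref_amplitude)
        self.intervals.extend(other.intervals)
        self.unmatched_tg.extend(other.unmatched_tg)
        self.unmatched_ref.extend(other.unmatched_ref)


def rep_amplitude(track: PoseTrack, interval: tuple[float, float], axis: str) -> float:
    """Max-minus-min of the axis channel inside the interval (mm)."""
    start, end = interval
    if end <= start:
        raise ValidationError("empty interval")
    if start < track.time[0] - 1e-9 or end > track.time[-1] + 1e-9:
        raise ValidationError("interval outside the track span")
    mask = (track.time >= start) & (track.time <= end)
    values = track.channel(f"pos_{axis}")[mask]
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValidationError("no samples inside the interval")
    return float(values.max() - values.min())


def recognize_exercise(
    track: PoseTrack,
    interval: tuple[float, float],
    height: float,
    thresholds: ThresholdSet | None = None,
) -> str | None:
    """Classify the movement inside ``interval`` by height-scaled thresholds.

    Signed excursions are measured from the track-median baseline:
    downward longitudinal -> squat, upward longitudinal -> step-up,
    absolute transversal -> side-step.  If several thresholds fire, the
    largest threshold-normalized excursion wins (deterministic
    tie-break); returns ``None`` when no threshold is reached.
    """
    if height <= 0:
        raise ValidationError("height must be positive")
    thresholds = thresholds or ThresholdSet()
    start, end = interval
    mask = (track.time >= start) & (track.time <= end)
    if not mask.any():
        return None
    long_ch = track.channel("pos_longitudinal")
    trans_ch = track.channel("pos_transversal")
    base_long = float(np.nanmedian(long_ch))
    base_trans = float(np.nanmedian(trans_ch))
    seg_long = long_ch[mask]
    seg_trans = trans_ch[mask]
    excursions = {
        "squat": base_long - float(np.nanmin(seg_long)),
        "step_up": float(np.nanmax(seg_long)) - base_long,
        "side_step": float(np.nanmax(np.abs(seg_trans - base_trans))),
    }
    scores = {
        ex: excursions[ex] / thresholds.threshold_mm(ex, height)
        for ex in EXERCISES
        if excursions[ex] >= thresholds.threshold_mm(ex, height)
    }
    if not scores:
        return None
    return max(scores, key=scores.get)


def segment_repetitions(
    track: PoseTrack,
    protocol_segments: pd.DataFrame | None = None,
    *,
    height: float | None = None,
    thresholds: ThresholdSet | None = None,
    source: str = "tg",
    boundary_frac: float = 0.02,
) -> list[ExerciseRep]:
    """Detect repetition intervals and compute their amplitudes.

    With ``protocol_segments`` (a table with ``label``, ``start_s``,
    ``end_s``; the generator's ground-truth sidecar) the intervals are
    taken from the labels.  Without labels, excursion peaks on each
    exercise's primary axis are detected with prominence at least the
    height-scaled threshold and minimum separation ``min_rep_duration``;
    each peak's interval extends outward to the surrounding crossings of
    ``boundary_frac`` times the threshold, i.e. back to near-baseline, so
    the max-min amplitude covers the whole excursion.
    """
    reps: list[ExerciseRep] = []
    if protocol_segments is not None:
        for _, row in protocol_segments.iterrows():
            label = str(row["label"])
            if label.startswith("side_step"):
                exercise = "side_step"
            elif label in ("squat", "step_up"):
                exercise = label
            else:
                continue
            start, end = float(row["start_s"]), float(row["end_s"])
            if start < track.time[0] - 1e-9 or end > track.time[-1] + 1e-9:
                continue  # rep not fully covered by the (cropped) track
            axis = primary_axis(exercise)
            amp = rep_amplitude(track, (start, end), axis)
            reps.append(ExerciseRep(exercise, start, end, axis, amp, source))
        return sorted(reps, key=lambda r: r.start)

    if height is None:
        raise ValidationError("label-free segmentation needs the subject height")
    thresholds = thresholds or ThresholdSet()
    rate = track.nominal_rate or 1.0 / float(np.median(np.diff(track.time)))
    distance = max(1, int(round(thresholds.min_rep_duration * rate)))

    detector_signals = {
        "squat": np.nanmedian(track.channel("pos_longitudinal"))
        - track.channel("pos_longitudinal"),
        "step_up": track.channel("pos_longitudinal")
        - np.nanmedian(track.channel("pos_longitudinal")),
        "side_step": np.abs(
            track.channel("pos_transversal") - np.nanmedian(track.channel("pos_transversal"))
        ),
    }
    for exercise, sig in detector_signals.items():
        thr = thresholds.threshold_mm(exercise, height)
        clean = np.nan_to_num(sig, nan=0.0)
        peaks, _ = find_peaks(clean, prominence=thr, distance=distance)
        boundary = boundary_frac * thr
        for p in peaks:
            if clean[p] < thr:
                continue
            # extend to (and include) the surrounding near-baseline crossings
            lo = p
            while lo > 0 and clean[lo] > boundary:
                lo -= 1
            hi = p
            while hi < clean.size - 1 and clean[hi] > boundary:
                hi += 1
            interval = (float(track.time[lo]), float(track.time[hi]))
            if interval[1] <= interval[0]:
                continue
            label = recognize_exercise(track, interval, height, thresholds)
            if label != exercise:
                continue  # e.g. a squat's rebound seen by the step-up detector
            axis = primary_axis(exercise)
            amp = rep_amplitude(track, interval, axis)
            reps.append(ExerciseRep(exercise, *interval, axis, amp, source))
    return sorted(reps, key=lambda r: r.start)


def _overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def pair_amplitudes(
    tg_reps: Sequence[ExerciseRep], ref_reps: Sequence[ExerciseRep]
) -> PairedAmplitudes:
    """Greedily match TG and reference reps by maximal interval overlap.

    Matching is restricted to reps of the same exercise; every rep is
    matched at most once and unmatched reps are reported separately.
    """
    out = PairedAmplitudes()
    used_tg: set[int] = set()
    used_ref: set[int] = set()
    candidates = []
    for i, tr in enumerate(tg_reps):
        for j, rr in enumerate(ref_reps):
            if tr.exercise != rr.exercise:
                continue
            ov = _overlap(tr.interval, rr.interval)
            if ov > 0:
                candidates.append((ov, i, j))
    for ov, i, j in sorted(candidates, key=lambda c: (-c[0], c[1], c[2])):
        if i in used_tg or j in used_ref:
            continue
        used_tg.add(i)
        used_ref.add(j)
        tr, rr = tg_reps[i], ref_reps[j]
        out.exercises.append(tr.exercise)
        out.tg_amplitude.append(tr.amplitude)
        out.ref_amplitude.append(rr.amplitude)
        out.intervals.append(
            (min(tr.start, rr.start), max(tr.end, rr.end))
        )
    out.unmatched_tg = [r for i, r in enumerate(tg_reps) if i not in used_tg]
    out.unmatched_ref = [r for j, r in enumerate(ref_reps) if j not in used_ref]
    # keep chronological order for reporting
    order = np.argsort([iv[0] for iv in out.intervals]) if out.intervals else []
    out.exercises = [out.exercises[k] for k in order]
    out.tg_amplitude = [out.tg_amplitude[k] for k in order]
    out.ref_amplitude = [out.ref_amplitude[k] for k in order]
    out.intervals = [out.intervals[k] for k in order]
    return out


def write_reps_csv(reps: Iterable[ExerciseRep], path: str | Path) -> None:
    """Rep table: ``exercise,source,start_s,end_s,axis,amplitude_mm``."""
    rows = [
        {
            "exercise": r.exercise,
            "source": r.source,
            "start_s": r.start,
            "end_s": r.end,
            "axis": r.axis,
            "amplitude_mm": r.amplitude,
        }
        for r in reps
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.17g")
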