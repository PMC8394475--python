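"""Repetition segmentation, amplitude extraction, recognition, pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import linear_sum_assignment

from arval.errors import ValidationError
from arval.exercise import (
    ExerciseRep,
    ThresholdSet,
    pair_amplitudes,
    primary_axis,
    recognize_exercise,
    rep_amplitude,
    segment_repetitions,
)
from arval.synthetic import generate_ground_truth, generate_subject
from arval.trajectory_io import CHANNELS, PoseTrack

from conftest import identity_generator


def flat_track(n=120, rate=30.0, **channels_override):
    t = np.arange(n) / rate
    channels = {name: np.zeros(n) for name in CHANNELS}
    channels.update(channels_override)
    return PoseTrack.from_channels(t, channels, nominal_rate=rate)


class TestPrimaryAxis:
    @pytest.mark.parametrize(
        "exercise,axis",
        [("side_step", "transversal"), ("squat", "longitudinal"), ("step_up", "longitudinal")],
    )
    def test_axis_mapping(self, exercise, axis):
        assert primary_axis(exercise) == axis

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            primary_axis("lunge")


class TestRepAmplitude:
    def test_constant_channel_zero(self):
        track = flat_track()
        assert rep_amplitude(track, (0.0, 1.0), "longitudinal") == 0.0

    def test_ramp_full_range(self):
        n = 120
        ramp = np.linspace(0.0, 350.0, n)
        track = flat_track(n, pos_longitudinal=ramp)
        assert rep_amplitude(track, (0.0, track.time[-1]), "longitudinal") == pytest.approx(350.0)

    def test_time_reversal_invariant(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=90) * 50
        fwd = flat_track(90, pos_transversal=values)
        rev = flat_track(90, pos_transversal=values[::-1])
        iv = (0.0, fwd.time[-1])
        assert rep_amplitude(fwd, iv, "transversal") == rep_amplitude(rev, iv, "transversal")

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    def test_equals_range_of_values(self, values):
        arr = np.array(values)
        track = flat_track(len(arr), pos_longitudinal=arr)
        amp = rep_amplitude(track, (0.0, track.time[-1]), "longitudinal")
        assert amp == pytest.approx(np.max(arr) - np.min(arr))

    def test_empty_interval_rejected(self):
        with pytest.raises(ValidationError):
            rep_amplitude(flat_track(), (1.0, 1.0), "longitudinal")


class TestRecognizeExercise:
    def _dip_track(self, depth, sign=-1.0):
        n = 150
        t = np.arange(n) / 30.0
        pulse = np.zeros(n)
        m = (t >= 1.0) & (t <= 3.0)
        u = (t[m] - 1.0) / 2.0
        pulse[m] = sign * depth * 0.5 * (1 - np.cos(2 * np.pi * u))
        return flat_track(n, pos_longitudinal=1650.0 + pulse)

    def test_downward_dip_is_squat(self):
        track = self._dip_track(0.2 * 1750.0)
        assert recognize_exercise(track, (0.5, 3.5), 1750.0) == "squat"

    def test_upward_excursion_is_step_up(self):
        track = self._dip_track(200.0, sign=+1.0)
        assert recognize_exercise(track, (0.5, 3.5), 1750.0) == "step_up"

    def test_lateral_excursion_is_side_step(self):
        n = 150
        t = np.arange(n) / 30.0
        lat = np.zeros(n)
        m = (t >= 1.0) & (t <= 3.0)
        lat[m] = 300.0 * 0.5 * (1 - np.cos(2 * np.pi * (t[m] - 1.0) / 2.0))
        track = flat_track(n, pos_transversal=lat)
        assert recognize_exercise(track, (0.5, 3.5), 1750.0) == "side_step"

    def test_static_segment_is_none(self):
        assert recognize_exercise(flat_track(), (0.0, 1.0), 1750.0) is None

    @pytest.mark.parametrize("seed", range(0, 100, 1))
    def test_generator_segments_reproduce_labels(self, seed):
        """Across 100 seeds, every generated rep is recognized as its label."""
        profile = generate_subject(seed)
        truth = generate_ground_truth(profile, identity_generator(seed=seed))
        track = truth.track
        for rep in truth.reps:
            assert (
                recognize_exercise(track, (rep.start, rep.end), profile.height)
                == rep.exercise
            )


class TestSegmentRepetitions:
    def test_labelled_trial1_counts(self, clean_trial):
        truth, ref, _ = clean_trial
        segments = pd.DataFrame(
            [{"label": s.label, "start_s": s.start, "end_s": s.end} for s in truth.segments]
        )
        reps = segment_repetitions(ref, segments, source="reference")
        counts = {e: sum(r.exercise == e for r in reps) for e in ("squat", "side_step", "step_up")}
        assert counts == {"squat": 3, "side_step": 6, "step_up": 3}

    def test_detection_matches_labels_on_clean_data(self, clean_trial):
        truth, ref, _ = clean_trial
        reps = segment_repetitions(ref, height=truth.profile.height, source="reference")
        counts = {e: sum(r.exercise == e for r in reps) for e in ("squat", "side_step", "step_up")}
        assert counts == {"squat": 3, "side_step": 6, "step_up": 3}
        # detected amplitudes recover the configured displacements
        for rep in reps:
            true = [
                r.amplitude
                for r in truth.reps
                if r.exercise == rep.exercise and r.start <= (rep.start + rep.end) / 2 <= r.end
            ]
            assert len(true) == 1
            assert rep.amplitude == pytest.approx(true[0], rel=0.02)

    def test_constant_track_empty(self):
        assert segment_repetitions(flat_track(), height=1750.0) == []

    def test_noise_below_threshold_no_false_positives(self):
        """Monte-Carlo false-positive check: white noise well below the
        height-scaled thresholds must never produce a repetition."""
        rng = np.random.default_rng(99)
        n_detect = 0
        for _ in range(50):
            n = 900
            track = flat_track(
                n,
                pos_longitudinal=rng.normal(0, 20.0, n),
                pos_transversal=rng.normal(0, 20.0, n),
            )
            n_detect += len(segment_repetitions(track, height=1750.0))
        assert n_detect == 0


def make_rep(exercise, start, end, amp, source="tg"):
    return ExerciseRep(exercise, start, end, primary_axis(exercise), amp, source)


class TestPairAmplitudes:
    def test_identical_lists_fully_matched(self):
        reps = [make_rep("squat", i * 4.0, i * 4.0 + 3.0, 350.0) for i in range(3)]
        refs = [make_rep("squat", i * 4.0, i * 4.0 + 3.0, 350.0, "reference") for i in range(3)]
        paired = pair_amplitudes(reps, refs)
        assert len(paired) == 3
        assert paired.tg_amplitude == paired.ref_amplitude
        assert not paired.unmatched_tg and not paired.unmatched_ref

    def test_missing_tg_rep_reported_unmatched(self):
        tg = [make_rep("squat", 0.0, 3.0, 350.0)]
        ref = [
            make_rep("squat", 0.0, 3.0, 352.0, "reference"),
            make_rep("squat", 4.0, 7.0, 340.0, "reference"),
        ]
        paired = pair_amplitudes(tg, ref)
        assert len(paired) == 1
        assert len(paired.unmatched_ref) == 1
        assert paired.unmatched_ref[0].start == 4.0

    def test_exercise_labels_never_cross_matched(self):
        tg = [make_rep("squat", 0.0, 3.0, 350.0)]
        ref = [make_rep("step_up", 0.0, 3.0, 200.0, "reference")]
        paired = pair_amplitudes(tg, ref)
        assert len(paired) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_jittered_matching_equals_optimal_assignment(self, seed):
        """Greedy overlap matching equals the Hungarian-optimal assignment
        for realistically jittered intervals."""
        rng = np.random.default_rng(seed)
        starts = np.arange(6) * 4.0
        tg = [
            make_rep(
                "squat", s + rng.uniform(-0.2, 0.2), s + 3.0 + rng.uniform(-0.2, 0.2), 300.0 + i
            )
            for i, s in enumerate(starts)
        ]
        ref = [
            make_rep(
                "squat",
                s + rng.uniform(-0.2, 0.2),
                s + 3.0 + rng.uniform(-0.2, 0.2),
                300.5 + i,
                "reference",
            )
            for i, s in enumerate(starts)
        ]
        paired = pair_amplitudes(tg, ref)
        overlap = np.zeros((6, 6))
        for i, a in enumerate(tg):
            for j, b in enumerate(ref):
                overlap[i, j] = max(0.0, min(a.end, b.end) - max(a.start, b.start))
        rows, cols = linear_sum_assignment(-overlap)
        optimal = {(i, j) for i, j in zip(rows, cols)}
        # recover greedy matching from the (distinct) amplitudes
        greedy = {
            (int(a - 300.0), int(b - 300.5))
            for a, b in zip(paired.tg_amplitude, paired.ref_amplitude)
        }
        assert len(paired) == 6
        assert greedy == optimal
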