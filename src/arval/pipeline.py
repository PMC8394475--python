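"""End-to-end validation runs and the report bundle.

A *run* processes a set of trials — synthetic (generated on the fly from
a :class:`~arval.synthetic.GeneratorConfig`) or file-based — through the
full chain: lag estimation on the nod movement, lag correction, overlap
cropping onto the common 30 Hz grid, frame alignment, pooled per-frame
trajectory differences, repetition segmentation and amplitude pairing
(scripted trials only), and the per-exercise agreement battery.

The study layout mirrors the validation protocol: every subject performs
a scripted trial (trial 1: nods, 3 squats, 3 side-steps right, 3
step-ups, 3 side-steps left) and a free-play trial (trial 2: nods plus
about a minute of randomized exercises).  Free play contributes to the
trajectory metrics but not to amplitude pairing, since amplitudes are
defined against the scripted protocol.  Trials can be flagged corrupt;
they are skipped and counted as excluded, and every reported statistic
carries the number of trials that actually entered it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .agreement import AmplitudeAgreement, TrajectoryAgreement, amplitude_agreement
from .errors import ArvalError, ValidationError
from .exercise import (
    EXERCISES,
    PairedAmplitudes,
    ThresholdSet,
    pair_amplitudes,
    segment_repetitions,
)
from .synchronization import (
    DEFAULT_SEARCH_WINDOW,
    DEFAULT_SYNC_CHANNEL,
    FrameAlignment,
    SyncResult,
    align_frames,
    estimate_lag,
    overlap_crop,
    shift_time,
)
from .trajectory_io import (
    CHANNELS,
    PoseTrack,
    read_pose_csv,
    read_segments_csv,
    write_pose_csv,
    write_segments_csv,
)

logger = logging.getLogger("arval")

__version__ = "0.1.0"


@dataclass
class TrialFiles:
    """One file-based trial: pose CSVs plus an optional segment sidecar."""

    subject_id: str
    trial: int
    tg_csv: str
    ref_csv: str
    segments_csv: str | None = None
    height: float | None = None


@dataclass
class RunConfig:
    """Configuration of a validation run."""

    mode: str = "synthetic"  # synthetic | files
    n_subjects: int = 30
    generator: synthetic.GeneratorConfig = field(default_factory=synthetic.GeneratorConfig)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    sync_channel: str = DEFAULT_SYNC_CHANNEL
    sync_window: float = DEFAULT_SEARCH_WINDOW
    seed: int = 0
    include_trial2: bool = True
    pool_trial2_trajectories: bool = True
    use_labels: bool = True
    corrupt_trials: tuple[tuple[int, int], ...] = ()  # (subject index from 0, trial 1|2)
    trials: list[TrialFiles] = field(default_factory=list)  # files mode

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "synthetic" and self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.mode == "files" and not self.trials:
            raise ValidationError("files mode needs at least one trial entry")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = synthetic.GeneratorConfig(**raw.pop("generator", {}))
        thr = ThresholdSet(**raw.pop("thresholds", {}))
        trials = [TrialFiles(**t) for t in raw.pop("trials", [])]
        corrupt = tuple(tuple(c) for c in raw.pop("corrupt_trials", []))
        return cls(generator=gen, thresholds=thr, trials=trials, corrupt_trials=corrupt, **raw)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "mode": self.mode,
                "n_subjects": self.n_subjects,
                "generator": asdict(self.generator) | {"protocol": list(self.generator.protocol)},
                "thresholds": asdict(self.thresholds),
                "sync_channel": self.sync_channel,
                "sync_window": self.sync_window,
                "seed": self.seed,
                "include_trial2": self.include_trial2,
                "pool_trial2_trajectories": self.pool_trial2_trajectories,
                "use_labels": self.use_labels,
                "corrupt_trials": list(map(list, self.corrupt_trials)),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TrialOutcome:
    subject_id: str
    trial: int
    excluded: bool = False
    exclusion_reason: str | None = None
    sync: SyncResult | None = None
    alignment: FrameAlignment | None = None
    n_frames: int = 0
    channel_mad: dict[str, float] = field(default_factory=dict)
    abs_diffs: dict[str, np.ndarray] | None = None
    paired: PairedAmplitudes | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "subject_id": self.subject_id,
            "trial": self.trial,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "sync": self.sync.to_dict() if self.sync else None,
            "alignment": self.alignment.to_dict() if self.alignment else None,
            "n_frames": self.n_frames,
            "channel_mad": self.channel_mad,
            "warnings": self.warnings,
        }


@dataclass
class AgreementReport:
    """Everything a validation run computes, ready for serialization."""

    version: str
    seed: int
    config_digest: str
    n_trials_total: int
    n_trials_analyzed: int
    n_trials_excluded: int
    trajectory: list[TrajectoryAgreement]
    trajectory_trial1_only: list[TrajectoryAgreement]
    amplitudes: dict[str, AmplitudeAgreement]
    rep_counts: dict[str, int]
    n_unmatched_reps: int
    trials: list[TrialOutcome]
    warnings: list[str] = field(default_factory=list)
    bland_altman_data: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_digest": self.config_digest,
            "n_trials_total": self.n_trials_total,
            "n_trials_analyzed": self.n_trials_analyzed,
            "n_trials_excluded": self.n_trials_excluded,
            "trajectory": [t.to_dict() for t in self.trajectory],
            "trajectory_trial1_only": [t.to_dict() for t in self.trajectory_trial1_only],
            "amplitudes": {k: v.to_dict() for k, v in self.amplitudes.items()},
            "rep_counts": self.rep_counts,
            "n_unmatched_reps": self.n_unmatched_reps,
            "trials": [t.to_dict() for t in self.trials],
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, allow_nan=True)


def process_trial(
    tg: PoseTrack,
    ref: PoseTrack,
    segments: pd.DataFrame | None,
    height: float | None,
    config: RunConfig,
    subject_id: str,
    trial: int,
    pair_reps: bool = True,
) -> TrialOutcome:
    """Run one trial through sync, alignment and per-frame differencing."""
    outcome = TrialOutcome(subject_id=subject_id, trial=trial)
    stage = "estimate_lag"
    try:
        import warnings as _warnings

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            sync = estimate_lag(tg, ref, config.sync_channel, config.sync_window)
            stage = "overlap_crop"
            tg_c, ref_c = overlap_crop(shift_time(tg, -sync.lag), ref)
            stage = "align_frames"
            tg_a, alignment = align_frames(tg_c, ref_c)
            stage = "trajectory_metrics"
            diffs = {
                name: np.abs(tg_a.channel(name) - ref_c.channel(name)) for name in CHANNELS
            }
            paired = None
            if pair_reps:
                stage = "segmentation"
                if segments is not None and config.use_labels:
                    tg_reps = segment_repetitions(tg_a, segments, source="tg")
                    ref_reps = segment_repetitions(ref_c, segments, source="reference")
                else:
                    if height is None:
                        raise ValidationError("label-free segmentation needs subject height")
                    tg_reps = segment_repetitions(
                        tg_a, height=height, thresholds=config.thresholds, source="tg"
                    )
                    ref_reps = segment_repetitions(
                        ref_c, height=height, thresholds=config.thresholds, source="reference"
                    )
                stage = "pair_amplitudes"
                paired = pair_amplitudes(tg_reps, ref_reps)
        outcome.warnings = [str(w.message) for w in caught]
    except ArvalError as exc:
        raise ArvalError(f"{subject_id} trial {trial}, stage {stage}: {exc}") from exc
    outcome.sync = sync
    outcome.alignment = alignment
    outcome.n_frames = len(tg_a)
    outcome.channel_mad = {name: float(d.mean()) for name, d in diffs.items()}
    outcome.abs_diffs = diffs
    outcome.paired = paired
    logger.info(
        "%s trial %d: lag=%.4fs peak_corr=%.3f frames=%d",
        subject_id,
        trial,
        sync.lag,
        sync.peak_corr,
        len(tg_a),
    )
    return outcome


def _subject_seeds(seed: int, n_subjects: int) -> np.ndarray:
    # three independent 31-bit streams per subject: profile, trial 1, trial 2
    return np.random.SeedSequence(seed).generate_state(3 * n_subjects) % (2**31)


def _iter_synthetic_trials(config: RunConfig):
    seeds = _subject_seeds(config.seed, config.n_subjects)
    for i in range(config.n_subjects):
        profile = synthetic.generate_subject(int(seeds[3 * i]), f"S{i + 1:02d}")
        trial_specs = [(1, synthetic.TRIAL1_PROTOCOL, int(seeds[3 * i + 1]))]
        if config.include_trial2:
            trial_specs.append((2, synthetic.TRIAL2_PROTOCOL, int(seeds[3 * i + 2])))
        for trial, protocol, tseed in trial_specs:
            gen = replace(config.generator, protocol=protocol, seed=tseed)
            yield i, profile, trial, gen


def _segments_frame(truth: synthetic.GroundTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"segment": i, "label": s.label, "start_s": s.start, "end_s": s.end}
            for i, s in enumerate(truth.segments)
        ]
    )


def run_validation(config: RunConfig, outdir: str | Path | None = None) -> AgreementReport:
    """Execute the full validation run and (optionally) write the bundle."""
    outcomes: list[TrialOutcome] = []
    report_warnings: list[str] = []

    if config.mode == "synthetic":
        for i, profile, trial, gen in _iter_synthetic_trials(config):
            if (i, trial) in set(map(tuple, config.corrupt_trials)):
                outcomes.append(
                    TrialOutcome(
                        subject_id=profile.subject_id,
                        trial=trial,
                        excluded=True,
                        exclusion_reason="data corruption (flagged)",
                    )
                )
                logger.warning("%s trial %d excluded: flagged corrupt", profile.subject_id, trial)
                continue
            truth, ref, tg = (
                lambda t: (t, synthetic.degrade_to_reference(t, gen), synthetic.degrade_to_tg(t, gen))
            )(synthetic.generate_ground_truth(profile, gen))
            segments = _segments_frame(truth)
            try:
                outcome = process_trial(
                    tg,
                    ref,
                    segments,
                    profile.height,
                    config,
                    profile.subject_id,
                    trial,
                    pair_reps=(trial == 1),
                )
            except ArvalError as exc:
                outcomes.append(
                    TrialOutcome(
                        subject_id=profile.subject_id,
                        trial=trial,
                        excluded=True,
                        exclusion_reason=str(exc),
                    )
                )
                report_warnings.append(f"excluded {profile.subject_id} trial {trial}: {exc}")
                continue
            outcomes.append(outcome)
    else:
        for tf in config.trials:
            key = (tf.subject_id, tf.trial)
            tg = read_pose_csv(tf.tg_csv, device="tg", nominal_rate=config.generator.tg_rate)
            ref = read_pose_csv(
                tf.ref_csv, device="reference", nominal_rate=config.generator.ref_rate
            )
            segments = read_segments_csv(tf.segments_csv) if tf.segments_csv else None
            try:
                outcome = process_trial(
                    tg,
                    ref,
                    segments,
                    tf.height,
                    config,
                    tf.subject_id,
                    tf.trial,
                    pair_reps=(tf.trial == 1),
                )
            except ArvalError as exc:
                outcomes.append(
                    TrialOutcome(
                        subject_id=tf.subject_id,
                        trial=tf.trial,
                        excluded=True,
                        exclusion_reason=str(exc),
                    )
                )
                report_warnings.append(f"excluded {key}: {exc}")
                continue
            outcomes.append(outcome)

    analyzed = [o for o in outcomes if not o.excluded]
    for o in analyzed:
        report_warnings.extend(f"{o.subject_id} trial {o.trial}: {w}" for w in o.warnings)

    def pooled(trial_filter) -> list[TrajectoryAgreement]:
        rows = []
        sel = [o for o in analyzed if trial_filter(o)]
        for name in CHANNELS:
            if sel:
                d = np.concatenate([o.abs_diffs[name] for o in sel])
                sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
                rows.append(
                    TrajectoryAgreement(
                        channel=name,
                        mad_mean=float(d.mean()),
                        mad_sd=sd,
                        rmse=float(np.sqrt(np.mean(d**2))),
                        n_frames=int(d.size),
                        n_trials=len(sel),
                    )
                )
            else:
                rows.append(TrajectoryAgreement(name, 0.0, 0.0, 0.0, 0, 0))
        return rows

    trajectory = pooled(
        (lambda o: True) if config.pool_trial2_trajectories else (lambda o: o.trial == 1)
    )
    trajectory_t1 = pooled(lambda o: o.trial == 1)

    pooled_pairs = PairedAmplitudes()
    for o in analyzed:
        if o.paired is not None:
            pooled_pairs.extend(o.paired)

    amplitudes: dict[str, AmplitudeAgreement] = {}
    rep_counts: dict[str, int] = {}
    ba_data: dict[str, dict[str, list[float]]] = {}
    for exercise in EXERCISES:
        tg_amp, ref_amp = pooled_pairs.for_exercise(exercise)
        rep_counts[exercise] = int(tg_amp.size)
        if tg_amp.size >= 5 and np.ptp(tg_amp) > 0 and np.ptp(ref_amp) > 0:
            amplitudes[exercise] = amplitude_agreement(
                exercise, tg_amp, ref_amp, ks_seed=config.seed % (2**31)
            )
            ba_data[exercise] = {
                "mean_mm": ((tg_amp + ref_amp) / 2.0).tolist(),
                "diff_mm": (tg_amp - ref_amp).tolist(),
            }

    report = AgreementReport(
        version=__version__,
        seed=config.seed,
        config_digest=config.digest(),
        n_trials_total=len(outcomes),
        n_trials_analyzed=len(analyzed),
        n_trials_excluded=len(outcomes) - len(analyzed),
        trajectory=trajectory,
        trajectory_trial1_only=trajectory_t1,
        amplitudes=amplitudes,
        rep_counts=rep_counts,
        n_unmatched_reps=len(pooled_pairs.unmatched_tg) + len(pooled_pairs.unmatched_ref),
        trials=outcomes,
        warnings=report_warnings,
        bland_altman_data=ba_data,
    )
    if outdir is not None:
        write_report_bundle(report, outdir)
    return report


def write_report_bundle(report: AgreementReport, outdir: str | Path) -> None:
    """Write report.json plus the position/rotation/amplitude CSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())

    pos = [t for t in report.trajectory if t.channel.startswith("pos_")]
    rot = [t for t in report.trajectory if t.channel.startswith("rot_")]
    pd.DataFrame([t.to_dict() for t in pos]).to_csv(outdir / "table3_positions.csv", index=False)
    pd.DataFrame([t.to_dict() for t in rot]).to_csv(outdir / "table4_rotations.csv", index=False)
    pd.DataFrame([a.to_dict() for a in report.amplitudes.values()]).to_csv(
        outdir / "table5_amplitudes.csv", index=False
    )
    for exercise, data in report.bland_altman_data.items():
        agg = report.amplitudes[exercise]
        lines = [
            f"# exercise: {exercise}",
            f"# ba_median_mm: {agg.ba_median:.6g}",
            f"# ba_loa_low_mm: {agg.ba_loa_low:.6g}",
            f"# ba_loa_high_mm: {agg.ba_loa_high:.6g}",
            "mean_mm,diff_mm",
        ]
        lines += [f"{m:.6g},{d:.6g}" for m, d in zip(data["mean_mm"], data["diff_mm"])]
        (outdir / f"bland_altman_{exercise}.csv").write_text("\n".join(lines) + "\n")


def make_study(config: RunConfig, outdir: str | Path) -> list[TrialFiles]:
    """Materialize the synthetic study as CSV files plus sidecars.

    Writes, per subject, the trial-1 and trial-2 recording pairs
    (reference and TG pose CSVs) and the ground-truth segment sidecars,
    plus a ``study.json`` manifest.
    """
    if config.mode != "synthetic":
        raise ValidationError("make_study requires synthetic mode")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    written: list[TrialFiles] = []
    for i, profile, trial, gen in _iter_synthetic_trials(config):
        truth, ref, tg = (
            lambda t: (t, synthetic.degrade_to_reference(t, gen), synthetic.degrade_to_tg(t, gen))
        )(synthetic.generate_ground_truth(profile, gen))
        stem = f"{profile.subject_id}_trial{trial}"
        ref_path = outdir / f"{stem}_ref.csv"
        tg_path = outdir / f"{stem}_tg.csv"
        seg_path = outdir / f"{stem}_segments.csv"
        write_pose_csv(ref, ref_path)
        write_pose_csv(tg, tg_path)
        write_segments_csv(truth.segments, seg_path)
        tf = TrialFiles(
            subject_id=profile.subject_id,
            trial=trial,
            tg_csv=str(tg_path),
            ref_csv=str(ref_path),
            segments_csv=str(seg_path),
            height=profile.height,
        )
        written.append(tf)
        manifest.append(
            asdict(tf)
            | {
                "height_mm": profile.height,
                "generator_seed": gen.seed,
                "duration_s": truth.duration,
            }
        )
    (outdir / "study.json").write_text(
        json.dumps({"seed": config.seed, "trials": manifest}, sort_keys=True, indent=2)
    )
    return written
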