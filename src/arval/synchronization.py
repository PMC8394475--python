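"""Temporal and spatial registration of the two pose streams.

The two systems share no clock and no world frame.  Registration happens
in three steps: the lag between the streams is estimated by normalized
cross-correlation on the synchronization movement (five head nods,
default channel ``rot_flexion``); both streams are cropped and resampled
onto a common grid at the coarser (TG) rate; and the TG's world frame is
mapped onto the lab frame by the signed axis permutation that maximizes
the summed per-axis correlation, plus a static per-axis offset.

The frame search is restricted to signed permutations rather than free
rotations because the TG's inertial unit gravity-aligns its vertical
axis: the frames can differ only by a horizontal relabelling (plus
translation).  A free-rotation Procrustes variant is available through
``align_frames(..., free_rotation=True)`` for data that violate that
assumption.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.spatial.transform import Rotation

from .errors import AmbiguousAlignmentError, SyncError, ValidationError
from .trajectory_io import (
    CHANNELS,
    POSITION_CHANNELS,
    ROTATION_CHANNELS,
    PoseTrack,
    euler_to_matrix,
    matrix_to_euler,
)

#: default correlation channel: the nod lives in the flexion channel
DEFAULT_SYNC_CHANNEL = "rot_flexion"
#: fallback if the rotation channel carries no signal
FALLBACK_SYNC_CHANNEL = "pos_longitudinal"
#: operators start the two systems within seconds of each other
DEFAULT_SEARCH_WINDOW = 3.0


@dataclass
class SyncResult:
    """Estimated lag (s, positive = TG behind reference) and diagnostics."""

    lag: float
    peak_corr: float
    channel: str
    search_window: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if abs(self.lag) > self.search_window + 1e-9:
            raise ValidationError("lag outside the search window")

    def to_dict(self) -> dict:
        return {
            "lag_s": self.lag,
            "peak_corr": self.peak_corr,
            "channel": self.channel,
            "search_window_s": self.search_window,
            "low_confidence": self.low_confidence,
        }


@dataclass
class FrameAlignment:
    """Signed axis permutation (ref <- tg) and static offset per axis (mm)."""

    axis_map: np.ndarray  # (3, 3) with entries in {-1, 0, 1}
    static_offset: np.ndarray  # (3,) mm, added after mapping

    def __post_init__(self) -> None:
        m = np.asarray(self.axis_map, dtype=int)
        if m.shape != (3, 3) or not np.isin(m, (-1, 0, 1)).all():
            raise ValidationError("axis_map must be a 3x3 signed permutation matrix")
        if not ((np.abs(m).sum(axis=0) == 1).all() and (np.abs(m).sum(axis=1) == 1).all()):
            raise ValidationError("axis_map must have exactly one nonzero per row/column")
        self.axis_map = m
        self.static_offset = np.asarray(self.static_offset, dtype=float)

    @property
    def is_identity(self) -> bool:
        return bool((self.axis_map == np.eye(3, dtype=int)).all())

    def to_dict(self) -> dict:
        return {
            "axis_map": self.axis_map.tolist(),
            "static_offset_mm": self.static_offset.tolist(),
        }


def shift_time(track: PoseTrack, delta: float) -> PoseTrack:
    """Return the track with ``delta`` added to all timestamps."""
    if delta == 0.0:
        return track
    return track.replace(time=track.time + delta)


def resample(track: PoseTrack, target_times: np.ndarray) -> PoseTrack:
    """Linearly interpolate all channels at ``target_times``.

    Angle channels are interpolated on unwrapped values so a wrap-around
    never produces a spurious mid-way angle.  Extrapolation is refused.
    """
    target_times = np.asarray(target_times, dtype=float)
    if target_times.size and (
        target_times[0] < track.time[0] - 1e-9 or target_times[-1] > track.time[-1] + 1e-9
    ):
        raise ValidationError(
            f"target times [{target_times[0]:g}, {target_times[-1]:g}] extend beyond "
            f"track span [{track.time[0]:g}, {track.time[-1]:g}]"
        )
    channels = {}
    for name in CHANNELS:
        values = track.channel(name)
        if name in ROTATION_CHANNELS:
            values = np.unwrap(values, period=360.0)
        channels[name] = np.interp(target_times, track.time, values)
    rate = (
        1.0 / float(np.median(np.diff(target_times))) if target_times.size >= 2 else None
    )
    return PoseTrack.from_channels(
        target_times,
        channels,
        device=track.device,
        nominal_rate=rate,
    )


def _uniform_grid_values(track: PoseTrack, channel: str, dt: float) -> tuple[np.ndarray, float]:
    """Channel resampled onto a uniform grid at ``dt`` over the track span."""
    n = int(np.floor((track.time[-1] - track.time[0]) / dt)) + 1
    grid = track.time[0] + np.arange(n) * dt
    values = np.interp(grid, track.time, track.channel(channel))
    return values, float(track.time[0])


def estimate_lag(
    tg: PoseTrack,
    ref: PoseTrack,
    channel: str = DEFAULT_SYNC_CHANNEL,
    search_window: float = DEFAULT_SEARCH_WINDOW,
) -> SyncResult:
    """Lag of the TG stream behind the reference by cross-correlation.

    Both streams are resampled to the TG rate, mean-removed, and the
    normalized cross-correlation is maximized over lags within
    ``+/-search_window`` seconds; the peak is refined to sub-sample
    precision by parabolic interpolation.  A peak correlation below 0.5
    flags the result as low-confidence.
    """
    rate = tg.nominal_rate or 1.0 / float(np.median(np.diff(tg.time)))
    dt = 1.0 / rate
    y, t0_tg = _uniform_grid_values(tg, channel, dt)
    x, t0_ref = _uniform_grid_values(ref, channel, dt)
    if np.ptp(y) == 0.0 or np.ptp(x) == 0.0:
        raise SyncError(f"channel {channel!r} has zero variance; lag undefined")
    y = y - y.mean()
    x = x - x.mean()

    c = sp_signal.correlate(y, x, mode="full", method="auto")
    lags = sp_signal.correlation_lags(y.size, x.size, mode="full")
    norm = np.sqrt(np.sum(x * x) * np.sum(y * y))
    c = c / norm
    lag_seconds = lags * dt + (t0_tg - t0_ref)

    in_window = np.abs(lag_seconds) <= search_window
    if not in_window.any():
        raise SyncError("no lags inside the search window")
    idx = np.flatnonzero(in_window)
    i = idx[np.argmax(c[idx])]

    # parabolic sub-sample refinement around the discrete peak
    delta = 0.0
    if 0 < i < c.size - 1:
        denom = c[i - 1] - 2.0 * c[i] + c[i + 1]
        if denom < 0:
            delta = 0.5 * (c[i - 1] - c[i + 1]) / denom
            # guard against numerically meaningless refinements
            if abs(delta) < 1e-6 or abs(delta) > 0.5:
                delta = 0.0
    lag = float(np.clip(lag_seconds[i] + delta * dt, -search_window, search_window))
    peak = float(c[i])

    low = peak < 0.5
    if low:
        warnings.warn(
            f"lag estimate has low confidence (peak correlation {peak:.2f} < 0.5)"
        )
    return SyncResult(
        lag=lag,
        peak_corr=peak,
        channel=channel,
        search_window=search_window,
        low_confidence=low,
    )


def overlap_crop(tg: PoseTrack, ref: PoseTrack) -> tuple[PoseTrack, PoseTrack]:
    """Crop both (lag-corrected) tracks to their common span on the TG grid."""
    t0 = max(tg.time[0], ref.time[0])
    t1 = min(tg.time[-1], ref.time[-1])
    if t1 <= t0:
        raise ValidationError("tracks have no temporal overlap")
    keep = (tg.time >= t0 - 1e-12) & (tg.time <= t1 + 1e-12)
    times = tg.time[keep]
    if times.size == 0:
        raise ValidationError("tracks have no temporal overlap")
    tg_c = resample(tg, times)
    ref_c = resample(ref, times)
    return tg_c, ref_c


def signed_permutations() -> list[np.ndarray]:
    """All 48 signed 3x3 permutation matrices (proper and improper)."""
    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for row, (col, s) in enumerate(zip(perm, signs)):
                m[row, col] = s
            out.append(m)
    return out


def apply_axis_map(track: PoseTrack, axis_map: np.ndarray, offset=(0.0, 0.0, 0.0)) -> PoseTrack:
    """Map position channels through a signed permutation (+ offset).

    Rotation channels are re-expressed in the mapped frame when the map is
    a proper rotation; for improper maps (reflections) orientation has no
    consistent image and the channels are left untouched.
    """
    m = np.asarray(axis_map, dtype=int)
    offset = np.asarray(offset, dtype=float)
    pos = track.positions() @ m.T + offset
    channels = dict(track.channels())
    for i, c in enumerate(POSITION_CHANNELS):
        channels[c] = pos[:, i]
    if round(float(np.linalg.det(m))) == 1 and not (m == np.eye(3, dtype=int)).all():
        r_map = Rotation.from_matrix(m.astype(float))
        r_dev = euler_to_matrix(
            channels["rot_rotation"], channels["rot_flexion"], channels["rot_lateral_flexion"]
        )
        rot, flex, latflex = matrix_to_euler(r_map * r_dev)
        channels["rot_rotation"], channels["rot_flexion"], channels["rot_lateral_flexion"] = (
            rot,
            flex,
            latflex,
        )
    return track.replace(**channels)


def align_frames(
    tg: PoseTrack,
    ref: PoseTrack,
    ambiguity_margin: float = 0.01,
    free_rotation: bool = False,
) -> tuple[PoseTrack, FrameAlignment]:
    """Register the TG world frame to the lab frame.

    Chooses the signed axis permutation maximizing the summed per-axis
    Pearson correlation between mapped TG and reference positions, then
    removes the per-axis mean difference.  Raises
    :class:`AmbiguousAlignmentError` when the runner-up scores within
    ``ambiguity_margin`` (relative) of the winner.

    With ``free_rotation=True`` the permutation is replaced by the full
    Procrustes (Kabsch) rotation between the mean-centred point clouds;
    the result is still reported through ``axis_map`` rounded to the
    nearest signed permutation, with the exact rotation applied.
    """
    if len(tg) != len(ref):
        raise ValidationError("tracks must be on a common grid (run overlap_crop first)")
    p_tg = tg.positions()
    p_ref = ref.positions()

    if free_rotation:
        a = p_tg - p_tg.mean(axis=0)
        b = p_ref - p_ref.mean(axis=0)
        h = a.T @ b
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        mapped = p_tg @ r.T
        offset = (p_ref - mapped).mean(axis=0)
        m_near = _nearest_signed_permutation(r)
        aligned = tg.replace(
            **{
                c: (mapped[:, i] + offset[i])
                for i, c in enumerate(POSITION_CHANNELS)
            }
        )
        return aligned, FrameAlignment(axis_map=m_near, static_offset=offset)

    # correlation matrix C[i, j] = corr(ref axis i, tg axis j)
    c = np.zeros((3, 3))
    ref_sd = p_ref.std(axis=0)
    tg_sd = p_tg.std(axis=0)
    ref_c = p_ref - p_ref.mean(axis=0)
    tg_c = p_tg - p_tg.mean(axis=0)
    for i in range(3):
        for j in range(3):
            if ref_sd[i] == 0.0 or tg_sd[j] == 0.0:
                continue
            c[i, j] = float(ref_c[:, i] @ tg_c[:, j]) / (len(tg) * ref_sd[i] * tg_sd[j])

    candidates = signed_permutations()
    scores = np.array([float(np.sum(m * c)) for m in candidates])
    order = np.argsort(scores)[::-1]
    best, second = scores[order[0]], scores[order[1]]
    if best <= 0 or (best - second) < ambiguity_margin * abs(best):
        raise AmbiguousAlignmentError(
            f"frame alignment ambiguous: best score {best:.4f}, runner-up {second:.4f}",
            candidates=[candidates[order[0]], candidates[order[1]]],
        )
    m = candidates[order[0]]
    mapped = p_tg @ m.T
    offset = (p_ref - mapped).mean(axis=0)
    aligned = apply_axis_map(tg, m, offset)
    return aligned, FrameAlignment(axis_map=m, static_offset=offset)


def _nearest_signed_permutation(r: np.ndarray) -> np.ndarray:
    m = np.zeros((3, 3), dtype=int)
    used = set()
    for i in range(3):
        j = int(np.argmax([abs(r[i, k]) if k not in used else -1 for k in range(3)]))
        used.add(j)
        m[i, j] = 1 if r[i, j] >= 0 else -1
    return m
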