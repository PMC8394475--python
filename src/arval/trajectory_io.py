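"""Trajectory containers and file I/O.

The package works with two recordings of the same head-mounted display
(HMD): a smartphone training game (TG) that logs its own pose at ~30 Hz,
and an optoelectronic reference system that records four reflective
markers on the HMD at 120 Hz.  Both are reduced to a :class:`PoseTrack`:
three position channels on the anatomical axes (sagittal = front-back,
transversal = side-to-side, longitudinal = vertical) in millimetres and
three orientation channels (flexion, lateral flexion, rotation) in
degrees.

Coordinates are lab-frame and right-handed with the longitudinal axis
along gravity.  Euler decomposition is intrinsic
rotation(longitudinal) -> flexion(transversal) -> lateral flexion(sagittal),
i.e. scipy's ``"ZYX"`` with x=sagittal, y=transversal, z=longitudinal.
The same convention is used by the generator and the analysis, so the
channels are mutually consistent even though the convention itself is a
package choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import FormatError, ValidationError

POSITION_CHANNELS = ("pos_sagittal", "pos_transversal", "pos_longitudinal")
ROTATION_CHANNELS = ("rot_flexion", "rot_lateral_flexion", "rot_rotation")
CHANNELS = POSITION_CHANNELS + ROTATION_CHANNELS

#: intrinsic Euler sequence: rotation (z, longitudinal), flexion (y,
#: transversal), lateral flexion (x, sagittal)
EULER_SEQ = "ZYX"

# CSV dialect: column name -> PoseTrack channel
POSE_CSV_COLUMNS = {
    "time_s": "time",
    "pos_sag_mm": "pos_sagittal",
    "pos_trans_mm": "pos_transversal",
    "pos_long_mm": "pos_longitudinal",
    "rot_flex_deg": "rot_flexion",
    "rot_latflex_deg": "rot_lateral_flexion",
    "rot_rot_deg": "rot_rotation",
}


def euler_to_matrix(rot_deg: np.ndarray, flex_deg: np.ndarray, latflex_deg: np.ndarray) -> Rotation:
    """Compose orientation(s) from the three rotation channels."""
    angles = np.stack(np.broadcast_arrays(rot_deg, flex_deg, latflex_deg), axis=-1)
    return Rotation.from_euler(EULER_SEQ, angles, degrees=True)


def matrix_to_euler(rot: Rotation) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose orientation(s) into (rotation, flexion, lateral flexion) deg."""
    ang = rot.as_euler(EULER_SEQ, degrees=True)
    ang = np.atleast_2d(ang)
    return ang[..., 0], ang[..., 1], ang[..., 2]


@dataclass
class PoseTrack:
    """One device's pose series: positions in mm, rotations in deg.

    ``gap_mask`` marks frames where the pose could not be reconstructed
    (e.g. <3 visible markers); gap frames carry NaN channel values and are
    excluded from downstream metrics.
    """

    time: np.ndarray
    pos_sagittal: np.ndarray
    pos_transversal: np.ndarray
    pos_longitudinal: np.ndarray
    rot_flexion: np.ndarray
    rot_lateral_flexion: np.ndarray
    rot_rotation: np.ndarray
    device: str = "tg"
    nominal_rate: float | None = None
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.time.size
        for name in CHANNELS:
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"channel {name!r} has length {getattr(self, name).size}, expected {n}"
                )
        if n >= 2:
            dt = np.diff(self.time)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"time is not strictly increasing at row {int(bad[0]) + 1}"
                )
            if self.nominal_rate is not None:
                med = float(np.median(dt))
                expected = 1.0 / self.nominal_rate
                if not (0.8 * expected <= med <= 1.2 * expected):
                    raise ValidationError(
                        f"median sampling interval {med:.6g}s deviates >20% from "
                        f"nominal 1/{self.nominal_rate:g}s"
                    )
        if self.gap_mask is not None:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.size != n:
                raise ValidationError("gap_mask length mismatch")

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0]) if len(self) else 0.0

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)

    def positions(self) -> np.ndarray:
        """(n, 3) array ordered (sagittal, transversal, longitudinal)."""
        return np.stack([self.channel(c) for c in POSITION_CHANNELS], axis=1)

    def channels(self) -> dict[str, np.ndarray]:
        return {name: self.channel(name) for name in CHANNELS}

    def replace(self, **kwargs) -> "PoseTrack":
        return replace(self, **kwargs)

    @classmethod
    def from_channels(
        cls,
        time: np.ndarray,
        channels: Mapping[str, np.ndarray],
        device: str = "tg",
        nominal_rate: float | None = None,
        gap_mask: np.ndarray | None = None,
    ) -> "PoseTrack":
        return cls(
            time=time,
            device=device,
            nominal_rate=nominal_rate,
            gap_mask=gap_mask,
            **{name: channels[name] for name in CHANNELS},
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time}
        for col, name in POSE_CSV_COLUMNS.items():
            if name != "time":
                data[col] = self.channel(name)
        return pd.DataFrame(data)


@dataclass
class MarkerTrack:
    """Raw reference-system form: four labelled markers in the lab frame.

    ``markers`` maps label -> (n, 3) position array in mm; occluded frames
    are NaN and mirrored in ``gap_masks``.
    """

    time: np.ndarray
    markers: dict[str, np.ndarray]
    nominal_rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if len(self.markers) != 4:
            raise ValidationError(f"expected exactly 4 markers, got {len(self.markers)}")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        for label, arr in self.markers.items():
            if arr.shape != (self.time.size, 3):
                raise ValidationError(f"marker {label!r} shape {arr.shape} != (n, 3)")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.markers)

    def gap_masks(self) -> dict[str, np.ndarray]:
        return {k: np.isnan(v).any(axis=1) for k, v in self.markers.items()}


@dataclass
class HmdMarkerModel:
    """Local marker coordinates (mm) on the HMD, centroid at the origin.

    The default is a 100 x 60 mm rectangle in the device's
    transversal-longitudinal plane, matching a phone-on-headset footprint.
    A coplanar model is acceptable: the rigid fit resolves the out-of-plane
    direction through the proper-rotation constraint of the Kabsch
    solution.
    """

    local: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "LFHD": np.array([0.0, -50.0, 30.0]),
            "RFHD": np.array([0.0, 50.0, 30.0]),
            "LBHD": np.array([0.0, -50.0, -30.0]),
            "RBHD": np.array([0.0, 50.0, -30.0]),
        }
    )

    def __post_init__(self) -> None:
        self.local = {k: np.asarray(v, dtype=float) for k, v in self.local.items()}
        if len(self.local) < 3:
            raise ValidationError("marker model needs at least 3 markers")
        pts = np.stack(list(self.local.values()))
        centered = pts - pts.mean(axis=0)
        labels = list(self.local)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                d = np.linalg.norm(pts[i] - pts[j])
                if d <= 10.0:
                    raise ValidationError(
                        f"markers {labels[i]!r}/{labels[j]!r} only {d:.1f} mm apart"
                    )
        if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
            raise ValidationError("marker model is collinear")


# -----------------------------------------------------------------------------
# CSV I/O
# -----------------------------------------------------------------------------

def read_pose_csv(path: str | Path, device: str = "tg", nominal_rate: float | None = None) -> PoseTrack:
    """Read a pose CSV in the package dialect.

    Strict: a missing column or a malformed numeric field raises
    :class:`FormatError`; non-monotone time raises :class:`ValidationError`
    naming the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    numeric = {}
    for col in POSE_CSV_COLUMNS:
        try:
            # numpy's parser round-trips "%.17g" output bit-exactly
            numeric[col] = df[col].to_numpy().astype(float)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path.name}: malformed numeric value in column {col!r}: {exc}")
    channels = {POSE_CSV_COLUMNS[c]: v for c, v in numeric.items() if POSE_CSV_COLUMNS[c] != "time"}
    return PoseTrack.from_channels(
        numeric["time_s"], channels, device=device, nominal_rate=nominal_rate
    )


def write_pose_csv(track: PoseTrack, path: str | Path) -> None:
    """Write a :class:`PoseTrack` at full float precision ('.' decimal)."""
    if len(track) == 0:
        raise ValidationError("refusing to write an empty track")
    track.to_frame().to_csv(Path(path), index=False, float_format="%.17g")


def read_marker_csv(path: str | Path, nominal_rate: float | None = None) -> MarkerTrack:
    """Read the marker CSV dialect ``time_s,<label>_x_mm,<label>_y_mm,<label>_z_mm`` x4."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError(f"{path.name}: missing column(s) time_s")
    labels = []
    for col in df.columns:
        if col.endswith("_x_mm"):
            labels.append(col[: -len("_x_mm")])
    markers = {}
    for label in labels:
        cols = [f"{label}_{ax}_mm" for ax in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
        markers[label] = df[cols].to_numpy(dtype=float)
    return MarkerTrack(df["time_s"].to_numpy(dtype=float), markers, nominal_rate=nominal_rate)


def write_marker_csv(track: MarkerTrack, path: str | Path) -> None:
    data = {"time_s": track.time}
    for label, arr in track.markers.items():
        for i, ax in enumerate("xyz"):
            data[f"{label}_{ax}_mm"] = arr[:, i]
    pd.DataFrame(data).to_csv(Path(path), index=False, float_format="%.17g")


# -----------------------------------------------------------------------------
# Marker -> pose reconstruction
# -----------------------------------------------------------------------------

def _kabsch(model: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||observed_centered - R model_centered||."""
    mc = model - model.mean(axis=0)
    oc = observed - observed.mean(axis=0)
    h = mc.T @ oc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def pose_from_markers(markers: MarkerTrack, model: HmdMarkerModel | None = None) -> PoseTrack:
    """Reconstruct the HMD pose from the four labelled markers.

    Per frame the position is the centroid of the visible markers and the
    orientation is a least-squares rigid (Kabsch) fit of the marker model
    to the observations.  Frames with fewer than three visible markers, or
    with a degenerate (collinear) visible set, become gaps.
    """
    if model is None:
        model = HmdMarkerModel()
    n = markers.time.size
    labels = [lab for lab in markers.labels if lab in model.local]
    if len(labels) < 3:
        raise ValidationError("fewer than 3 marker labels shared with the model")
    obs = np.stack([markers.markers[lab] for lab in labels], axis=1)  # (n, m, 3)
    local = np.stack([model.local[lab] for lab in labels])  # (m, 3)

    pos = np.full((n, 3), np.nan)
    eul = np.full((n, 3), np.nan)  # rotation, flexion, lateral flexion
    gap = np.zeros(n, dtype=bool)
    for i in range(n):
        visible = ~np.isnan(obs[i]).any(axis=1)
        if visible.sum() < 3:
            gap[i] = True
            continue
        pts = obs[i, visible]
        loc = local[visible]
        centered = loc - loc.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
            gap[i] = True
            continue
        r = _kabsch(loc, pts)
        pos[i] = pts.mean(axis=0)
        rot, flex, latflex = matrix_to_euler(Rotation.from_matrix(r))
        eul[i] = [rot[0], flex[0], latflex[0]]

    return PoseTrack(
        time=markers.time,
        pos_sagittal=pos[:, 0],
        pos_transversal=pos[:, 1],
        pos_longitudinal=pos[:, 2],
        rot_flexion=eul[:, 1],
        rot_lateral_flexion=eul[:, 2],
        rot_rotation=eul[:, 0],
        device="reference",
        nominal_rate=markers.nominal_rate,
        gap_mask=gap,
    )


def interpolate_gaps(track: PoseTrack, max_gap: float) -> PoseTrack:
    """Fill gaps up to ``max_gap`` seconds by linear interpolation.

    Longer gaps (and gaps touching the track ends) stay flagged and NaN so
    downstream metrics can exclude them.
    """
    if track.gap_mask is None or not track.gap_mask.any():
        return track
    gap = track.gap_mask.copy()
    if gap.all():
        warnings.warn("track consists entirely of gaps; nothing to interpolate")
        return track
    valid = ~gap
    t = track.time
    # contiguous gap runs
    idx = np.nonzero(gap)[0]
    runs: list[tuple[int, int]] = []
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))

    new_channels = {name: track.channel(name).copy() for name in CHANNELS}
    new_gap = gap.copy()
    for lo, hi in runs:
        if lo == 0 or hi == len(track) - 1:
            continue  # no bracketing samples
        span = t[hi + 1] - t[lo - 1]
        if span > max_gap:
            continue
        sl = slice(lo, hi + 1)
        for name in CHANNELS:
            ch = new_channels[name]
            ch[sl] = np.interp(t[sl], t[valid], ch[valid])
        new_gap[sl] = False
    return track.replace(gap_mask=new_gap, **new_channels)


def write_segments_csv(segments: Iterable, path: str | Path) -> None:
    """Ground-truth sidecar: ``segment,label,start_s,end_s`` per row."""
    rows = [
        {"segment": i, "label": seg.label, "start_s": seg.start, "end_s": seg.end}
        for i, seg in enumerate(segments)
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.17g")


def read_segments_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in ("label", "start_s", "end_s") if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {', '.join(missing)}")
    return df
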