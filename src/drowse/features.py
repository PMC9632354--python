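"""Per-frame eye/mouth geometry and windowed blink/yawn frequencies.

Landmark conventions: the 6-point eye has corners p1, p6 and vertical lid
pairs (p2, p3), (p4, p5); the 8-point mouth has corners M1, M5 and vertical
lip pairs (M2, M8), (M3, M7), (M4, M6).  Every ratio feature is invariant
under translation, rotation and uniform scaling of the landmark set; the
mouth-area proxy S_mp is translation-invariant only, being a product of
coordinate differences.

All primitives broadcast over leading axes, so a whole session can be
processed as one ``(n, 6, 2)`` / ``(n, 8, 2)`` array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError
from . import headpose as _hp
from .synth import Session, binarize_kss, EXCLUDED, FATIGUE

__all__ = [
    "EyeCalibration",
    "FeatureFrame",
    "WindowStats",
    "FEATURE_ORDER",
    "eav",
    "eoa",
    "s_ar",
    "mav",
    "moa",
    "s_mp",
    "lid_distance",
    "is_eye_closed",
    "blink_frequency",
    "yawn_frequency",
    "yawn_flags",
    "scalarize",
    "calibrate_eye",
    "extract_features",
]

#: Fixed column order of the 11-dimensional feature vector.
FEATURE_ORDER = (
    "eav",
    "mav",
    "s_ar",
    "s_mp",
    "pitch",
    "yaw",
    "roll",
    "eoa",
    "moa",
    "f_blink",
    "f_yawn",
)


@dataclass(frozen=True)
class EyeCalibration:
    """Fully-open eye geometry of one subject.

    ``a_max`` is the maximum canthus (corner-to-corner) distance, ``b_max``
    the maximum eyelid-pair distance; ``baseline_open`` is the calibrated
    fully-open lid gap used by the closure test (defaults to ``b_max``).
    """

    a_max: float
    b_max: float
    baseline_open: float | None = None

    def __post_init__(self) -> None:
        if self.a_max <= 0 or self.b_max <= 0:
            raise ValueError("calibration axes must be positive")
        if self.baseline_open is None:
            object.__setattr__(self, "baseline_open", self.b_max)
        elif self.baseline_open <= 0:
            raise ValueError("baseline_open must be positive")


@dataclass(frozen=True)
class FeatureFrame:
    """The per-frame feature vector before scalarization."""

    eav: tuple[float, float]
    eoa: float
    s_ar: float
    mav: tuple[float, float, float]
    moa: float
    s_mp: float
    pitch: float
    yaw: float
    roll: float


@dataclass(frozen=True)
class WindowStats:
    """Windowed event-frequency features (fractions of frames)."""

    f_blink: float
    f_yawn: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("window must contain at least one frame")
        if not (0.0 <= self.f_blink <= 1.0 and 0.0 <= self.f_yawn <= 1.0):
            raise ValueError("frequencies must lie in [0, 1]")


def _dist(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    return np.linalg.norm(p - q, axis=-1)


def _check_pts(pts, k: int, name: str) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.shape[-2:] != (k, 2):
        raise ValueError(f"{name} must have shape (..., {k}, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def eav(eye_pts) -> np.ndarray:
    """Eye aspect vector: vertical lid gaps over the canthus distance.

    Returns ``(..., 2)``: (|p5 - p4| / |p6 - p1|, |p2 - p3| / |p6 - p1|).
    """
    pts = _check_pts(eye_pts, 6, "eye_pts")
    width = _dist(pts[..., 5, :], pts[..., 0, :])
    if np.any(width <= 0):
        raise DegenerateGeometryError("eye corners coincide")
    v1 = _dist(pts[..., 4, :], pts[..., 3, :])
    v2 = _dist(pts[..., 1, :], pts[..., 2, :])
    return np.stack([v1 / width, v2 / width], axis=-1)


def _opening_angle(apex, corner_a, corner_b, what: str) -> np.ndarray:
    """arcsin(perpendicular distance of apex to the corner line / |apex - corner_a|)."""
    line = corner_b - corner_a
    norm = np.linalg.norm(line, axis=-1)
    if np.any(norm <= 0):
        raise DegenerateGeometryError(f"{what} corners coincide")
    rel = apex - corner_a
    hyp = np.linalg.norm(rel, axis=-1)
    if np.any(hyp <= 0):
        raise DegenerateGeometryError(f"{what} apex coincides with a corner")
    cross = np.abs(rel[..., 0] * line[..., 1] - rel[..., 1] * line[..., 0])
    perp = cross / norm
    ratio = np.clip(perp / hyp, 0.0, 1.0)
    return np.arcsin(ratio)


def eoa(eye_pts) -> np.ndarray:
    """Eye opening angle in radians, in [0, pi/2].

    Angle at the eye corner p1 subtended by the upper-lid point p2 above
    the corner line p1-p6.
    """
    pts = _check_pts(eye_pts, 6, "eye_pts")
    return _opening_angle(pts[..., 1, :], pts[..., 0, :], pts[..., 5, :], "eye")


def s_ar(eye_pts, calib: EyeCalibration) -> np.ndarray:
    """Eye closure area ratio: the eye outline is fitted by an ellipse whose
    axes are the canthus distance and the mean lid gap, and the instantaneous
    ellipse area is referenced to the calibrated fully-open one (pi cancels).
    """
    pts = _check_pts(eye_pts, 6, "eye_pts")
    a_now = _dist(pts[..., 5, :], pts[..., 0, :])
    b_now = lid_distance(pts)
    return (a_now * b_now) / (calib.a_max * calib.b_max)


def mav(mouth_pts) -> np.ndarray:
    """Mouth aspect vector ``(..., 3)``: the three vertical lip gaps
    (|M4 - M6|, |M3 - M7|, |M2 - M8|) over the corner distance |M5 - M1|."""
    pts = _check_pts(mouth_pts, 8, "mouth_pts")
    width = _dist(pts[..., 4, :], pts[..., 0, :])
    if np.any(width <= 0):
        raise DegenerateGeometryError("mouth corners coincide")
    v1 = _dist(pts[..., 3, :], pts[..., 5, :])  # M4-M6
    v2 = _dist(pts[..., 2, :], pts[..., 6, :])  # M3-M7
    v3 = _dist(pts[..., 1, :], pts[..., 7, :])  # M2-M8
    return np.stack([v1 / width, v2 / width, v3 / width], axis=-1)


def moa(mouth_pts) -> np.ndarray:
    """Mouth opening angle in radians: as :func:`eoa`, with the mid-upper-lip
    point M3 against the corner line M1-M5."""
    pts = _check_pts(mouth_pts, 8, "mouth_pts")
    return _opening_angle(pts[..., 2, :], pts[..., 0, :], pts[..., 4, :], "mouth")


def s_mp(mouth_pts) -> np.ndarray:
    """Mouth opening area proxy |x_M8 - x_M1| * |y_M7 - y_M3|, pixels squared."""
    pts = _check_pts(mouth_pts, 8, "mouth_pts")
    return np.abs(pts[..., 7, 0] - pts[..., 0, 0]) * np.abs(
        pts[..., 6, 1] - pts[..., 2, 1]
    )


def lid_distance(eye_pts) -> np.ndarray:
    """Mean of the two vertical lid-pair gaps."""
    pts = _check_pts(eye_pts, 6, "eye_pts")
    return 0.5 * (
        _dist(pts[..., 1, :], pts[..., 2, :]) + _dist(pts[..., 4, :], pts[..., 3, :])
    )


def is_eye_closed(eye_pts, calib: EyeCalibration, threshold: float = 0.2) -> np.ndarray:
    """Per-frame closure test: mean lid gap below ``threshold`` of the
    calibrated fully-open gap (the P80 convention from the PERCLOS
    literature, with its default 20%)."""
    if calib is None:
        raise ValueError("eye calibration required for the closure test")
    return lid_distance(eye_pts) < threshold * calib.baseline_open


def blink_frequency(closed_flags) -> float:
    """Fraction of closed-eye frames in the window."""
    flags = np.asarray(closed_flags)
    if flags.size == 0:
        raise ValueError("blink_frequency needs a non-empty window")
    return float(np.mean(flags.astype(bool)))


def yawn_flags(
    mav_mid, fps: float, threshold: float = 0.6, min_duration: float = 3.0
) -> np.ndarray:
    """Mark frames that belong to a yawn.

    A frame yawns iff it lies in a contiguous run where the midline mouth
    aspect (|M3 - M7| / |M5 - M1|) exceeds ``threshold`` for at least
    ``min_duration`` seconds — the duration gate is what separates ~4 s
    yawns from sub-second speech peaks.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    x = np.asarray(mav_mid, dtype=float)
    if x.size == 0:
        raise ValueError("yawn detection needs a non-empty window")
    above = x > threshold
    flags = np.zeros_like(above)
    min_frames = int(np.ceil(min_duration * fps))
    # run-length scan over the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_frames:
            flags[start:end] = True
    return flags


def yawn_frequency(
    mav_mid, fps: float, threshold: float = 0.6, min_duration: float = 3.0
) -> float:
    """Fraction of yawning frames in the window (see :func:`yawn_flags`)."""
    flags = yawn_flags(mav_mid, fps, threshold, min_duration)
    return float(np.mean(flags))


def scalarize(frame: FeatureFrame, window: WindowStats) -> np.ndarray:
    """Collapse a FeatureFrame plus window stats into the fixed 11-vector.

    EAV and MAV enter as the mean of their components; the order is
    :data:`FEATURE_ORDER`.
    """
    vec = np.array(
        [
            float(np.mean(frame.eav)),
            float(np.mean(frame.mav)),
            frame.s_ar,
            frame.s_mp,
            frame.pitch,
            frame.yaw,
            frame.roll,
            frame.eoa,
            frame.moa,
            window.f_blink,
            window.f_yawn,
        ]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite components")
    return vec


def calibrate_eye(eye_pts) -> EyeCalibration:
    """Calibrate fully-open eye geometry from a stream: the maxima of the
    canthus distance and of the mean lid gap over all frames."""
    pts = _check_pts(eye_pts, 6, "eye_pts")
    a_max = float(np.max(_dist(pts[..., 5, :], pts[..., 0, :])))
    b_max = float(np.max(lid_distance(pts)))
    if a_max <= 0 or b_max <= 0:
        raise DegenerateGeometryError("cannot calibrate a fully-closed stream")
    return EyeCalibration(a_max=a_max, b_max=b_max)


def _trailing_fraction(flags: np.ndarray, window_frames: int) -> np.ndarray:
    """Trailing-window mean of a boolean series; the window grows from the
    series start until `window_frames` history is available."""
    x = flags.astype(float)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window_frames, 0)
    return (cs[idx] - cs[lo]) / (idx - lo)


def extract_features(
    session: Session,
    calib: EyeCalibration | None = None,
    *,
    window_seconds: float = 60.0,
    closure_threshold: float = 0.2,
    yawn_threshold: float = 0.6,
    yawn_min_duration: float = 3.0,
    estimate_pose: bool = True,
    cam=None,
    face_model=None,
) -> pd.DataFrame:
    """Turn a landmark session into the 11-feature table.

    One row per frame with columns ``t``, the 11 features of
    :data:`FEATURE_ORDER` (EAV/MAV already scalarized) and a binary
    ``label`` (1 = fatigue) derived from the per-frame KSS score; frames
    whose KSS falls in the excluded band are dropped.  Blink and yawn
    frequencies use a trailing window of ``window_seconds``.  Head pose is
    recovered from the 5-point set by the batch PnP solver unless
    ``estimate_pose`` is False (then angles are zero).
    """
    if calib is None:
        calib = calibrate_eye(session.eye_pts)

    eav_v = eav(session.eye_pts)
    mav_v = mav(session.mouth_pts)
    df = pd.DataFrame({"t": session.t})
    df["eav"] = eav_v.mean(axis=-1)
    df["mav"] = mav_v.mean(axis=-1)
    df["s_ar"] = s_ar(session.eye_pts, calib)
    df["s_mp"] = s_mp(session.mouth_pts)

    if estimate_pose:
        R, _, _ = _hp.solve_pose_batch(session.pose_pts, face_model, cam)
        from scipy.spatial.transform import Rotation

        angles = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
        df["pitch"], df["yaw"], df["roll"] = angles[:, 0], angles[:, 1], angles[:, 2]
    else:
        df["pitch"] = df["yaw"] = df["roll"] = 0.0

    df["eoa"] = eoa(session.eye_pts)
    df["moa"] = moa(session.mouth_pts)

    w = max(int(round(window_seconds * session.fps)), 1)
    closed = is_eye_closed(session.eye_pts, calib, closure_threshold)
    df["f_blink"] = _trailing_fraction(closed, w)
    yawning = yawn_flags(mav_v[..., 1], session.fps, yawn_threshold, yawn_min_duration)
    df["f_yawn"] = _trailing_fraction(yawning, w)

    binary = np.array([binarize_kss(k) for k in session.kss])
    df["label"] = (binary == FATIGUE).astype(int)
    keep = binary != EXCLUDED
    df = df.loc[keep].reset_index(drop=True)
    return df[["t", *FEATURE_ORDER, "label"]]
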