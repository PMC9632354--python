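"""Head-pose recovery from five 2D face landmarks.

The driver's head is treated as a rigid body observed by a fixed pinhole
camera.  Five canonical points (eye centres, nose tip, mouth corners) of a
generic 3D face model are matched to their detected 2D image positions and
the rotation/translation minimising mean squared reprojection error is
found by damped Gauss-Newton, initialised from a scaled-orthographic depth
estimate.  The rotation is then reported as intrinsic pitch-yaw-roll Euler
angles in degrees, the representation used downstream to flag nods (pitch
excursions) and tilts (roll excursions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, NoConvergenceError

__all__ = [
    "CameraIntrinsics",
    "Face3DModel",
    "EulerAngles",
    "PoseResult",
    "default_intrinsics",
    "default_face_model",
    "project_points",
    "solve_pose",
    "solve_pose_batch",
    "rotation_to_euler",
    "euler_to_rotation",
    "is_abnormal_posture",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole camera: focal lengths and principal point, in pixels."""

    fx: float = 600.0
    fy: float = 600.0
    cx: float = 320.0
    cy: float = 240.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


#: Generic adult face, millimetres, roughly centred between the eyes.
#: Interocular distance 65 mm; the nose tip protrudes towards the camera.
_DEFAULT_MODEL_POINTS = np.array(
    [
        [-32.5, 30.0, -25.0],  # left eye centre
        [32.5, 30.0, -25.0],  # right eye centre
        [0.0, 0.0, 10.0],  # nose tip
        [-25.0, -35.0, -15.0],  # left mouth corner
        [25.0, -35.0, -15.0],  # right mouth corner
    ]
)

_MODEL_POINT_NAMES = (
    "left_eye",
    "right_eye",
    "nose_tip",
    "left_mouth",
    "right_mouth",
)


@dataclass(frozen=True)
class Face3DModel:
    """Five named 3D reference points of a generic face, millimetres."""

    points: np.ndarray = field(default_factory=lambda: _DEFAULT_MODEL_POINTS.copy())
    names: tuple = _MODEL_POINT_NAMES

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (5, 3):
            raise ValueError("face model needs exactly five 3D points")
        centred = pts - pts.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError("3D model points are collinear")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic x-y-z (pitch, yaw, roll) decomposition, degrees."""

    pitch: float
    yaw: float
    roll: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pitch, self.yaw, self.roll])


@dataclass(frozen=True)
class PoseResult:
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,) millimetres
    residual: float  # RMS reprojection error, pixels
    n_iter: int

    @property
    def euler(self) -> EulerAngles:
        return rotation_to_euler(self.rotation)


def default_intrinsics() -> CameraIntrinsics:
    return CameraIntrinsics()


def default_face_model() -> Face3DModel:
    return Face3DModel()


def project_points(
    points3d: np.ndarray,
    rotation: np.ndarray,
    translation: np.ndarray,
    cam: CameraIntrinsics,
) -> np.ndarray:
    """Project model points through the pinhole camera.

    Broadcasts over leading axes: ``rotation`` may be ``(..., 3, 3)`` and
    ``translation`` ``(..., 3)``, giving ``(..., k, 2)`` pixel coordinates.
    """
    pts = np.asarray(points3d, dtype=float)
    camera_pts = pts @ np.swapaxes(rotation, -1, -2) + translation[..., None, :]
    z = camera_pts[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cam.fx * camera_pts[..., 0] / z + cam.cx
        v = cam.fy * camera_pts[..., 1] / z + cam.cy
    return np.stack([u, v], axis=-1)


def _check_points2d(points2d: np.ndarray) -> np.ndarray:
    pts = np.asarray(points2d, dtype=float)
    if pts.shape[-2:] != (5, 2):
        raise ValueError(f"expected (..., 5, 2) image points, got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("image points must be finite")
    centred = pts - pts.mean(axis=-2, keepdims=True)
    s = np.linalg.svd(centred, compute_uv=False)
    if np.any(s[..., 1] < 1e-9 * np.maximum(s[..., 0], 1.0)):
        raise DegenerateGeometryError("2D correspondences are collinear")
    return pts


def _residuals(params: np.ndarray, pts2d, model_pts, cam) -> np.ndarray:
    rot = Rotation.from_rotvec(params[..., :3].reshape(-1, 3)).as_matrix()
    rot = rot.reshape(params.shape[:-1] + (3, 3))
    proj = project_points(model_pts, rot, params[..., 3:], cam)
    return (proj - pts2d).reshape(params.shape[:-1] + (10,))


def _initial_params(pts2d: np.ndarray, model: Face3DModel, cam: CameraIntrinsics):
    """Scaled-orthographic bootstrap: depth from the 2D/3D spread ratio."""
    spread3d = np.linalg.norm(
        model.points - model.points.mean(axis=0), axis=-1
    ).mean()
    centred = pts2d - pts2d.mean(axis=-2, keepdims=True)
    spread2d = np.linalg.norm(centred, axis=-1).mean(axis=-1)
    f = 0.5 * (cam.fx + cam.fy)
    z0 = f * spread3d / np.maximum(spread2d, 1e-9)
    mean2d = pts2d.mean(axis=-2)
    t0 = np.stack(
        [
            (mean2d[..., 0] - cam.cx) / cam.fx * z0,
            (mean2d[..., 1] - cam.cy) / cam.fy * z0,
            z0,
        ],
        axis=-1,
    )
    params = np.zeros(pts2d.shape[:-2] + (6,))
    params[..., 3:] = t0
    return params


# Finite-difference steps: radians for the rotation vector, mm for translation.
_FD_STEPS = np.array([1e-5, 1e-5, 1e-5, 1e-2, 1e-2, 1e-2])


def solve_pose_batch(
    points2d: np.ndarray,
    model: Face3DModel | None = None,
    cam: CameraIntrinsics | None = None,
    *,
    max_iter: int = 30,
    step_tol: float = 1e-10,
    residual_tol: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve many poses at once by vectorised damped Gauss-Newton.

    Parameters
    ----------
    points2d
        ``(n, 5, 2)`` detected pixel positions, in the model's point order.
    residual_tol
        RMS reprojection error (pixels) above which the fit is declared
        non-convergent.

    Returns
    -------
    rotations ``(n, 3, 3)``, translations ``(n, 3)``, rms residuals ``(n,)``.
    """
    model = model or default_face_model()
    cam = cam or default_intrinsics()
    pts2d = _check_points2d(points2d)
    squeeze = pts2d.ndim == 2
    if squeeze:
        pts2d = pts2d[None]

    params = _initial_params(pts2d, model, cam)
    lam = 1e-6
    for it in range(max_iter):
        r = _residuals(params, pts2d, model.points, cam)  # (n, 10)
        # central-difference Jacobian, batched over poses
        J = np.empty(params.shape[:-1] + (10, 6))
        for j in range(6):
            dp = np.zeros(6)
            dp[j] = _FD_STEPS[j]
            rp = _residuals(params + dp, pts2d, model.points, cam)
            rm = _residuals(params - dp, pts2d, model.points, cam)
            J[..., :, j] = (rp - rm) / (2.0 * _FD_STEPS[j])
        JtJ = np.einsum("...ij,...ik->...jk", J, J)
        JtJ += lam * np.eye(6)
        g = np.einsum("...ij,...i->...j", J, r)
        try:
            delta = np.linalg.solve(JtJ, -g[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by lam
            raise DegenerateGeometryError("normal equations singular") from exc
        params = params + delta
        if np.max(np.abs(delta)) < step_tol:
            break

    r = _residuals(params, pts2d, model.points, cam)
    rms = np.sqrt(np.mean(r**2, axis=-1))
    if np.any(rms > residual_tol) or not np.all(np.isfinite(rms)):
        raise NoConvergenceError(
            f"pose solver residual {np.nanmax(rms):.2f} px exceeds "
            f"tolerance {residual_tol} px after {max_iter} iterations"
        )
    rot = Rotation.from_rotvec(params[..., :3].reshape(-1, 3)).as_matrix()
    rot = rot.reshape(params.shape[:-1] + (3, 3))
    t = params[..., 3:]
    if squeeze:
        return rot[0], t[0], rms[0]
    return rot, t, rms


def solve_pose(
    points2d: np.ndarray,
    model: Face3DModel | None = None,
    cam: CameraIntrinsics | None = None,
    **kwargs,
) -> PoseResult:
    """Recover rotation and translation from five 2D-3D correspondences."""
    rot, t, rms = solve_pose_batch(np.asarray(points2d, dtype=float), model, cam, **kwargs)
    return PoseResult(rotation=rot, translation=t, residual=float(rms), n_iter=-1)


def rotation_to_euler(R: np.ndarray, *, tol: float = 1e-6) -> EulerAngles:
    """Decompose a rotation matrix into intrinsic pitch-yaw-roll, degrees.

    Gimbal lock (|yaw| = 90 deg) is resolved by assigning the whole residual
    twist to pitch and setting roll to zero, which is what scipy's Euler
    decomposition does for a degenerate middle axis.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.all(np.isfinite(R)):
        raise ValueError("rotation matrix must be finite")
    if np.max(np.abs(R @ R.T - np.eye(3))) > tol or abs(np.linalg.det(R) - 1.0) > tol:
        raise ValueError("input is not a proper rotation matrix")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns at gimbal lock
        pitch, yaw, roll = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
    return EulerAngles(pitch=float(pitch), yaw=float(yaw), roll=float(roll))


def euler_to_rotation(angles) -> np.ndarray:
    """Inverse of :func:`rotation_to_euler`; accepts EulerAngles or a triple.

    Batched input of shape ``(n, 3)`` yields ``(n, 3, 3)``.
    """
    if isinstance(angles, EulerAngles):
        angles = angles.as_array()
    arr = np.asarray(angles, dtype=float)
    return Rotation.from_euler("XYZ", arr, degrees=True).as_matrix()


def is_abnormal_posture(
    pitch: float, roll: float, *, nod_threshold: float = 20.0, tilt_threshold: float = 20.0
) -> bool:
    """Flag a nod (large pitch) or tilt (large roll), thresholds in degrees."""
    return bool(np.abs(pitch) > nod_threshold) or bool(np.abs(roll) > tilt_threshold)
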