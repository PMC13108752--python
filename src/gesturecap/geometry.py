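"""Pinhole camera model, triangulation and rigid registration.

The world frame is the reference camera's frame (right-handed, z forward,
millimetres): the reference camera has identity rotation and zero
translation, and every other camera's extrinsics are expressed relative to
it.  Distortion follows the 5-coefficient radial-tangential model
(k1, k2, p1, p2, k3) used by checkerboard calibration tooling.

Triangulation is linear DLT on undistorted normalized coordinates: the
homogeneous system is solved in least squares via the smallest eigenvector
of :math:`A^T A`, batched over observations.  A midpoint method is provided
as an independent cross-check.  Rigid registration is the SVD (Kabsch)
solution with reflection correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .errors import (
    BehindCameraError,
    DegenerateFitError,
    DegenerateGeometryError,
    FormatError,
    GeometryError,
)

__all__ = [
    "CameraParams",
    "RigidTransform",
    "project",
    "distort_normalized",
    "undistort_points",
    "triangulate_pair",
    "triangulate_batch",
    "midpoint_triangulate",
    "reprojection_rms",
    "rigid_fit",
    "load_camera_params",
    "save_camera_params",
]

_ORTHO_TOL = 1e-9


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if R.shape != (3, 3):
        raise GeometryError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol * 100, rtol=0):
        raise GeometryError("rotation is not orthonormal")
    if np.linalg.det(R) < 0:
        raise GeometryError("rotation has determinant -1 (reflection)")


@dataclass(frozen=True)
class CameraParams:
    """Intrinsics, distortion and extrinsic pose of one pinhole camera.

    ``rotation``/``translation`` map world coordinates into the camera
    frame: x_cam = R x_world + t.  A reference camera has R = I, t = 0.
    """

    camera_id: str
    fx: float
    fy: float
    cx: float
    cy: float
    dist: np.ndarray  # (k1, k2, p1, p2, k3)
    rotation: np.ndarray
    translation: np.ndarray
    width: int = 1920
    height: int = 1080

    def __post_init__(self) -> None:
        object.__setattr__(self, "dist", np.asarray(self.dist, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )
        if self.fx <= 0 or self.fy <= 0:
            raise GeometryError("focal lengths must be positive")
        if self.dist.shape != (5,):
            raise GeometryError("dist must have 5 coefficients (k1,k2,p1,p2,k3)")
        _check_rotation(self.rotation)

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates: -R^T t."""
        return -self.rotation.T @ self.translation

    def to_camera_frame(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation


def distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply radial-tangential distortion to normalized coordinates."""
    xy = np.asarray(xy, dtype=float)
    k1, k2, p1, p2, k3 = dist
    x, y = xy[..., 0], xy[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.stack([xd, yd], axis=-1)


def project(points: np.ndarray, cam: CameraParams, *, strict: bool = True):
    """Project world points (mm) to pixel coordinates.

    Full model: world-to-camera transform, perspective divide, distortion,
    intrinsic mapping.  With ``strict`` (default) any non-positive camera
    depth raises :class:`BehindCameraError`; with ``strict=False`` a
    validity mask is returned alongside the pixels and behind-camera points
    yield NaN.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pc = cam.to_camera_frame(pts.reshape(-1, 3))
    z = pc[:, 2]
    ok = z > 0
    if strict and not np.all(ok):
        raise BehindCameraError(
            f"{int((~ok).sum())} point(s) at or behind camera {cam.camera_id}"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = pc[:, :2] / z[:, None]
    xy_d = distort_normalized(xy, cam.dist)
    uv = np.empty_like(xy_d)
    uv[:, 0] = cam.fx * xy_d[:, 0] + cam.cx
    uv[:, 1] = cam.fy * xy_d[:, 1] + cam.cy
    uv[~ok] = np.nan
    if strict:
        return uv[0] if single else uv.reshape(pts.shape[:-1] + (2,))
    return uv.reshape(pts.shape[:-1] + (2,)), ok.reshape(pts.shape[:-1])


def undistort_points(
    uv: np.ndarray, cam: CameraParams, *, max_iter: int = 20, tol: float = 1e-12
) -> np.ndarray:
    """Map pixels to undistorted normalized coordinates.

    The distortion model has no closed-form inverse; a fixed-point
    iteration (at most ``max_iter`` sweeps, stopping when the update falls
    below ``tol``) inverts it to well beyond measurement precision.
    """
    uv = np.asarray(uv, dtype=float)
    xd = np.stack(
        [(uv[..., 0] - cam.cx) / cam.fx, (uv[..., 1] - cam.cy) / cam.fy], axis=-1
    )
    k1, k2, p1, p2, k3 = cam.dist
    xy = xd.copy()
    for _ in range(max_iter):
        x, y = xy[..., 0], xy[..., 1]
        r2 = x * x + y * y
        radial = 1.0 + r2 * (k1 + r2 * (k2 + r2 * k3))
        dx = 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
        dy = p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
        new = np.stack(
            [(xd[..., 0] - dx) / radial, (xd[..., 1] - dy) / radial], axis=-1
        )
        delta = np.nanmax(np.abs(new - xy)) if new.size else 0.0
        xy = new
        if delta < tol:
            break
    return xy


def _normalized_projection_rows(cam: CameraParams) -> np.ndarray:
    """3x4 projection matrix [R | t] for undistorted normalized coords."""
    return np.hstack([cam.rotation, cam.translation.reshape(3, 1)])


def triangulate_batch(
    uv1: np.ndarray,
    uv2: np.ndarray,
    cam1: CameraParams,
    cam2: CameraParams,
    *,
    min_ray_angle_rad: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """DLT-triangulate many pixel observation pairs at once.

    Returns (points (..., 3) in the world frame, valid mask).  Pairs whose
    viewing rays are numerically parallel (angle below
    ``min_ray_angle_rad``) or whose homogeneous solution degenerates are
    flagged invalid rather than raising, so whole streams can be processed
    in one call.
    """
    c1, c2 = cam1.center, cam2.center
    baseline = np.linalg.norm(c1 - c2)
    if baseline < 1e-9:
        raise DegenerateGeometryError("camera centers coincide")
    x1 = undistort_points(uv1, cam1)
    x2 = undistort_points(uv2, cam2)
    P1 = _normalized_projection_rows(cam1)
    P2 = _normalized_projection_rows(cam2)
    shape = x1.shape[:-1]
    x1f = x1.reshape(-1, 2)
    x2f = x2.reshape(-1, 2)
    n = x1f.shape[0]
    A = np.empty((n, 4, 4))
    A[:, 0] = x1f[:, 0, None] * P1[2] - P1[0]
    A[:, 1] = x1f[:, 1, None] * P1[2] - P1[1]
    A[:, 2] = x2f[:, 0, None] * P2[2] - P2[0]
    A[:, 3] = x2f[:, 1, None] * P2[2] - P2[1]
    finite = np.all(np.isfinite(A.reshape(n, -1)), axis=1)
    A[~finite] = np.eye(4)
    # balance the homogeneous column (rotation entries are O(1), the
    # translation column O(baseline mm)) for well-conditioned normal
    # equations
    col_scale = max(
        1.0,
        float(np.linalg.norm(cam1.translation)),
        float(np.linalg.norm(cam2.translation)),
        baseline,
    )
    A[:, :, 3] /= col_scale

    AtA = np.einsum("nij,nik->njk", A, A)
    _, vecs = np.linalg.eigh(AtA)
    X = vecs[:, :, 0]  # smallest-eigenvalue eigenvector
    w = X[:, 3] / col_scale
    with np.errstate(divide="ignore", invalid="ignore"):
        pts = X[:, :3] / w[:, None]
    valid = finite & (np.abs(w) > 1e-15) & np.all(np.isfinite(pts), axis=1)

    # parallel-ray guard: angle between back-projected rays in world frame
    d1 = np.concatenate([x1f, np.ones((n, 1))], axis=1) @ cam1.rotation
    d2 = np.concatenate([x2f, np.ones((n, 1))], axis=1) @ cam2.rotation
    with np.errstate(invalid="ignore"):
        cosang = np.abs(
            np.sum(d1 * d2, axis=1)
            / (np.linalg.norm(d1, axis=1) * np.linalg.norm(d2, axis=1))
        )
    valid &= np.isfinite(cosang) & (np.arccos(np.clip(cosang, 0, 1)) > min_ray_angle_rad)
    pts[~valid] = np.nan
    return pts.reshape(shape + (3,)), valid.reshape(shape)


def triangulate_pair(
    obs1: Tuple[float, float, float],
    obs2: Tuple[float, float, float],
    cam1: CameraParams,
    cam2: CameraParams,
) -> Tuple[np.ndarray, float]:
    """Triangulate one observation pair; confidence is the pairwise minimum.

    Each observation is (u, v, confidence).  The fused confidence is the
    lower of the two: if a keypoint is poorly seen by either camera, the
    reconstructed 3D position cannot be trusted more than that view.
    """
    u1, v1, conf1 = obs1
    u2, v2, conf2 = obs2
    pts, valid = triangulate_batch(
        np.array([[u1, v1]]), np.array([[u2, v2]]), cam1, cam2
    )
    if not valid[0]:
        raise DegenerateGeometryError("rays are numerically parallel or invalid")
    return pts[0], float(min(conf1, conf2))


def midpoint_triangulate(
    uv1: np.ndarray, uv2: np.ndarray, cam1: CameraParams, cam2: CameraParams
) -> np.ndarray:
    """Midpoint-method triangulation (cross-check for the DLT route)."""
    x1 = undistort_points(np.asarray(uv1, dtype=float), cam1)
    x2 = undistort_points(np.asarray(uv2, dtype=float), cam2)
    shape = x1.shape[:-1]
    x1f, x2f = x1.reshape(-1, 2), x2.reshape(-1, 2)
    n = x1f.shape[0]
    d1 = np.concatenate([x1f, np.ones((n, 1))], axis=1) @ cam1.rotation
    d2 = np.concatenate([x2f, np.ones((n, 1))], axis=1) @ cam2.rotation
    d1 /= np.linalg.norm(d1, axis=1, keepdims=True)
    d2 /= np.linalg.norm(d2, axis=1, keepdims=True)
    c1, c2 = cam1.center, cam2.center
    b = c2 - c1
    d12 = np.sum(d1 * d2, axis=1)
    denom = 1.0 - d12**2
    t1 = (d1 @ b - d12 * (d2 @ b)) / denom
    t2 = (d12 * (d1 @ b) - (d2 @ b)) / denom
    p1 = c1 + t1[:, None] * d1
    p2 = c2 + t2[:, None] * d2
    return (0.5 * (p1 + p2)).reshape(shape + (3,))


def reprojection_rms(
    points: np.ndarray, obs: np.ndarray, cam: CameraParams
) -> float:
    """Root-mean-square pixel residual between projections and observations.

    The standard calibration quality metric: project each 3D point, take
    the Euclidean pixel residual to its observation, and return the RMS.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    ob = np.asarray(obs, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise GeometryError("reprojection_rms needs at least one point")
    if pts.shape[0] != ob.shape[0]:
        raise GeometryError("points and observations differ in length")
    proj = project(pts, cam)
    res = proj - ob
    return float(np.sqrt(np.mean(np.sum(res * res, axis=1))))


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Similarity map x -> R (s x) + t with det(R) = +1, s > 0 (default 1)."""

    R: np.ndarray
    t: np.ndarray
    s: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))
        _check_rotation(self.R)
        if self.s <= 0:
            raise GeometryError("scale must be positive")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (self.s * pts) @ self.R.T + self.t

    def inverse(self) -> "RigidTransform":
        Rinv = self.R.T
        return RigidTransform(Rinv, -(Rinv @ self.t) / self.s, 1.0 / self.s)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the map equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.R @ other.R,
            self.s * (self.R @ other.t) + self.t,
            self.s * other.s,
        )

    def to_json(self) -> dict:
        return {"R": self.R.ravel().tolist(), "t": self.t.tolist(), "s": self.s}

    @classmethod
    def from_json(cls, raw: dict) -> "RigidTransform":
        return cls(
            np.asarray(raw["R"], dtype=float).reshape(3, 3),
            np.asarray(raw["t"], dtype=float),
            float(raw.get("s", 1.0)),
        )


def rigid_fit(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid registration (Kabsch) of paired point sets.

    Finds R, t minimizing sum ||R p_i + t - q_i||^2 with det(R) = +1; the
    reflection case is corrected by flipping the sign of the smallest
    singular direction.  Scale is fixed to 1 — uniform scaling, where
    needed, is estimated upstream from an external length measurement.
    """
    P = np.asarray(P, dtype=float).reshape(-1, 3)
    Q = np.asarray(Q, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape:
        raise DegenerateFitError("point sets differ in shape")
    n = P.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need at least 3 correspondences, got {n}")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    sv_p = np.linalg.svd(P0, compute_uv=False)
    if sv_p[1] <= max(1e-9, 1e-12 * sv_p[0]):
        raise DegenerateFitError("points are (near-)collinear; rotation unidentifiable")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t, 1.0)


# ---------------------------------------------------------------------------
# Camera parameter files
# ---------------------------------------------------------------------------


def save_camera_params(cam: CameraParams, path: Union[str, Path]) -> None:
    raw = {
        "camera_id": cam.camera_id,
        "fx": cam.fx,
        "fy": cam.fy,
        "cx": cam.cx,
        "cy": cam.cy,
        "dist": cam.dist.tolist(),
        "R": cam.rotation.ravel().tolist(),
        "t": cam.translation.tolist(),
        "width": cam.width,
        "height": cam.height,
    }
    Path(path).write_text(json.dumps(raw, indent=1))


def load_camera_params(path: Union[str, Path]) -> CameraParams:
    """Load and validate a camera parameter JSON file."""
    try:
        raw = json.loads(Path(path).read_text())
        return CameraParams(
            camera_id=str(raw["camera_id"]),
            fx=float(raw["fx"]),
            fy=float(raw["fy"]),
            cx=float(raw["cx"]),
            cy=float(raw["cy"]),
            dist=np.asarray(raw["dist"], dtype=float),
            rotation=np.asarray(raw["R"], dtype=float).reshape(3, 3),
            translation=np.asarray(raw["t"], dtype=float),
            width=int(raw.get("width", 1920)),
            height=int(raw.get("height", 1080)),
        )
    except GeometryError:
        raise
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"bad camera parameter file {path}: {exc}") from exc
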