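"""Synthetic gesture-session generator.

Emulates the study design that the analysis pipeline expects as input:
10 participants x 8 sequences recorded by an optical motion-capture system
at 100 fps and three 1920x1080 @ 30 fps video cameras (one frontal, two
diagonal), with 13 upper-body target keypoints.

Each session bundle contains

* ground-truth skeletal motion (smooth sums of random harmonics driving a
  shoulder-elbow-wrist-fingertip chain with per-participant constant bone
  lengths, plus near-rigid torso/face sway),
* a MoCap-like reference: the truth upsampled to 100 fps, displaced by a
  fixed per-keypoint outward marker offset (the anatomical marker-vs-
  keypoint mismatch, a systematic bias that rigid alignment cannot fully
  remove), with persistent track-loss dropout,
* per-camera 2D detections: projections with Gaussian pixel noise,
  occlusion-aware confidences (occlusion is tested geometrically against a
  torso capsule so low confidence correlates with pose) and random
  dropout,
* depth-degraded monocular 3D streams: the truth in the frontal camera's
  frame, multiplied by a hidden scale, with large smoothly-varying
  depth-axis noise.

All randomness derives from ``(seed, participant, sequence, substream)``
integer keys, so adding a camera or method never perturbs other draws and
identical configurations reproduce byte-identical exports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .errors import FormatError
from .geometry import CameraParams, RigidTransform, project, save_camera_params
from .keypoints import (
    SessionMeta,
    Stream2D,
    Stream3D,
    TARGET_NAMES,
    write_stream,
)

__all__ = [
    "SimulationConfig",
    "SessionBundle",
    "build_cameras",
    "generate_motion",
    "render_observations",
    "generate_bundle",
    "generate_study",
    "iter_study",
    "export_study",
    "MONO_METHODS",
]

# canonical column indices (see keypoints.TARGET_KEYPOINTS)
I_SHO_R, I_SHO_L = 0, 1
I_ELB_R, I_ELB_L = 2, 3
I_WRI_R, I_WRI_L = 4, 5
I_THU_R, I_THU_L = 6, 7
I_MID_R, I_MID_L = 8, 9
I_CHE_R, I_CHE_L = 10, 11
I_CHIN = 12

# substream codes for named random substreams
_SUB_BODY = 1
_SUB_MOTION = 2
_SUB_MOCAP = 3
_SUB_CAM = 10  # + camera index
_SUB_MONO = 50  # + mono method index

MONO_METHODS = ("mono_a", "mono_b")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults reproduce the emulated study: 10 participants x 8 sequences
    of 60 s, three cameras, 30 fps video against a 100 fps reference, a
    0.3-confidence validity threshold downstream, 5-s margins, and an
    elbow-shoulder length drawn per participant from U(260, 320) mm which
    doubles as the tape-measured segment length used for monocular
    scaling.
    """

    n_participants: int = 10
    n_sequences: int = 8
    n_cameras: int = 3
    duration_s: float = 60.0
    video_fps: float = 30.0
    mocap_fps: float = 100.0
    # observation noise
    pixel_noise_sd: float = 1.0
    confidence_base: float = 0.97
    confidence_noise_sd: float = 0.03
    occlusion_penalty: float = 0.75
    dropout_prob: float = 0.002
    mocap_dropout_hazard: float = 1e-5
    persistent_mocap_dropout: bool = True
    marker_offset_mm: float = 10.0
    mono_depth_noise_mm: float = 150.0
    mono_lateral_noise_mm: float = 8.0
    mono_scale_range: Tuple[float, float] = (0.8, 1.25)
    # body / motion
    bone_length_range_mm: Tuple[float, float] = (260.0, 320.0)
    motion_amplitude_scale: float = 1.0
    torso_radius_mm: float = 160.0
    # session timing
    clap_pad_s: float = 2.0
    margin_s: float = 5.0
    # camera rig
    camera_distance_mm: float = 3000.0
    camera_angles_deg: Tuple[float, ...] = (-30.0, 0.0, 30.0)
    focal_px: float = 1400.0
    image_width: int = 1920
    image_height: int = 1080
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "mocap_dropout_hazard"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FormatError(f"{name} must be in [0, 1]")
        for name in (
            "duration_s", "video_fps", "mocap_fps", "camera_distance_mm",
            "focal_px", "torso_radius_mm",
        ):
            if getattr(self, name) <= 0:
                raise FormatError(f"{name} must be positive")
        for name in ("n_participants", "n_sequences", "n_cameras"):
            if getattr(self, name) < 1:
                raise FormatError(f"{name} must be >= 1")
        if self.n_cameras != len(self.camera_angles_deg):
            raise FormatError("n_cameras must match camera_angles_deg")
        lo, hi = self.bone_length_range_mm
        if not (0 < lo <= hi):
            raise FormatError("bone_length_range_mm must be positive and ordered")
        if not (0 < self.mono_scale_range[0] <= self.mono_scale_range[1]):
            raise FormatError("mono_scale_range must be positive and ordered")
        if self.pixel_noise_sd < 0 or self.marker_offset_mm < 0:
            raise FormatError("noise magnitudes must be non-negative")

    # -- session frame layout -------------------------------------------
    @property
    def n_pad_frames(self) -> int:
        return int(round(self.clap_pad_s * self.video_fps))

    @property
    def n_content_frames(self) -> int:
        return int(round(self.duration_s * self.video_fps))

    @property
    def n_video_frames(self) -> int:
        return self.n_content_frames + 2 * self.n_pad_frames

    def participant_id(self, index: int) -> str:
        return f"P{index + 1:02d}"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mono_scale_range"] = list(self.mono_scale_range)
        d["bone_length_range_mm"] = list(self.bone_length_range_mm)
        d["camera_angles_deg"] = list(self.camera_angles_deg)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        for key in ("mono_scale_range", "bone_length_range_mm", "camera_angles_deg"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class BodyShape:
    """Per-participant constant skeleton dimensions and rest pose (mm)."""

    upper_arm_mm: float
    forearm_mm: float
    thumb_mm: float
    middle_mm: float
    shoulder_half_mm: float
    rest: np.ndarray  # (13, 3) rest pose in the scene frame
    torso_center: np.ndarray
    torso_axis: Tuple[np.ndarray, np.ndarray]  # capsule segment endpoints


def _rng(config: SimulationConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *keys])


def _body_shape(config: SimulationConfig, participant: int) -> BodyShape:
    rng = _rng(config, _SUB_BODY, participant)
    lo, hi = config.bone_length_range_mm
    upper = rng.uniform(lo, hi)
    fore = rng.uniform(230.0, 280.0)
    thumb = rng.uniform(72.0, 88.0)
    middle = rng.uniform(100.0, 120.0)
    half = rng.uniform(165.0, 195.0)
    rest = np.zeros((13, 3))
    rest[I_SHO_R] = (-half, 1500.0, 0.0)
    rest[I_SHO_L] = (half, 1500.0, 0.0)
    rest[I_ELB_R] = (-half - 40.0, 1500.0 - upper, 20.0)
    rest[I_ELB_L] = (half + 40.0, 1500.0 - upper, 20.0)
    rest[I_WRI_R] = (-half - 30.0, 1500.0 - upper - 0.8 * fore, 150.0)
    rest[I_WRI_L] = (half + 30.0, 1500.0 - upper - 0.8 * fore, 150.0)
    rest[I_THU_R] = rest[I_WRI_R] + (20.0, -30.0, thumb * 0.7)
    rest[I_THU_L] = rest[I_WRI_L] + (-20.0, -30.0, thumb * 0.7)
    rest[I_MID_R] = rest[I_WRI_R] + (0.0, -40.0, middle * 0.8)
    rest[I_MID_L] = rest[I_WRI_L] + (0.0, -40.0, middle * 0.8)
    rest[I_CHE_R] = (-62.0, 1670.0, 58.0)
    rest[I_CHE_L] = (62.0, 1670.0, 58.0)
    rest[I_CHIN] = (0.0, 1598.0, 92.0)
    center = np.array([0.0, 1250.0, 0.0])
    axis = (np.array([0.0, 950.0, 0.0]), np.array([0.0, 1550.0, 0.0]))
    return BodyShape(upper, fore, thumb, middle, half, rest, center, axis)


def _harmonics(
    rng: np.random.Generator,
    t: np.ndarray,
    total_amp: float,
    scale: float,
    fmin: float = 0.2,
    fmax: float = 2.0,
) -> np.ndarray:
    """Smooth zero-mean signal: sum of 2-5 random harmonics in [fmin, fmax] Hz."""
    n = int(rng.integers(2, 6))
    freqs = rng.uniform(fmin, fmax, n)
    raw = rng.uniform(0.3, 1.0, n)
    amps = raw / raw.sum() * total_amp * scale
    phases = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.sum(
        amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
                               + phases[:, None]),
        axis=0,
    )


def _direction(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Unit vector from polar angle off the hanging (-y) axis and azimuth.

    phi = 0 points forward (+z); positive phi swings toward +x.
    """
    st = np.sin(theta)
    return np.stack([st * np.sin(phi), -np.cos(theta), st * np.cos(phi)], axis=-1)


def generate_motion(
    config: SimulationConfig,
    participant: int,
    sequence: int,
    rng: Optional[np.random.Generator] = None,
) -> Stream3D:
    """Ground-truth 13-keypoint motion at video fps, in the scene frame.

    The torso anchor is static; shoulders and face move near-rigidly with
    small sway; each arm is a shoulder-elbow-wrist-fingertip chain driven
    by smooth random harmonics, with exactly constant per-participant bone
    lengths.  Deterministic under (seed, participant, sequence).
    """
    if rng is None:
        rng = _rng(config, _SUB_MOTION, participant, sequence)
    body = _body_shape(config, participant)
    n = config.n_video_frames
    t = np.arange(n) / config.video_fps
    amp = config.motion_amplitude_scale
    d2r = np.deg2rad

    xyz = np.zeros((n, 13, 3))

    # near-rigid torso/face sway: yaw about the vertical torso axis plus a
    # small translation drift
    yaw = _harmonics(rng, t, d2r(4.0), amp, 0.05, 0.5)
    sway = np.stack(
        [
            _harmonics(rng, t, 12.0, amp, 0.05, 0.5),
            _harmonics(rng, t, 6.0, amp, 0.05, 0.5),
            _harmonics(rng, t, 10.0, amp, 0.05, 0.5),
        ],
        axis=-1,
    )
    cy, sy = np.cos(yaw), np.sin(yaw)
    torso_idx = [I_SHO_R, I_SHO_L, I_CHE_R, I_CHE_L, I_CHIN]
    rel = body.rest[torso_idx] - body.torso_center  # (5, 3)
    rx = cy[:, None] * rel[None, :, 0] + sy[:, None] * rel[None, :, 2]
    rz = -sy[:, None] * rel[None, :, 0] + cy[:, None] * rel[None, :, 2]
    for j, idx in enumerate(torso_idx):
        xyz[:, idx, 0] = body.torso_center[0] + rx[:, j]
        xyz[:, idx, 1] = body.torso_center[1] + rel[j, 1]
        xyz[:, idx, 2] = body.torso_center[2] + rz[:, j]
    xyz[:, torso_idx] += sway[:, None, :]

    # arms: spherical-angle harmonics through the kinematic chain
    for side_sign, i_sho, i_elb, i_wri, i_thu, i_mid in (
        (-1.0, I_SHO_R, I_ELB_R, I_WRI_R, I_THU_R, I_MID_R),
        (+1.0, I_SHO_L, I_ELB_L, I_WRI_L, I_THU_L, I_MID_L),
    ):
        th1 = d2r(40.0) + _harmonics(rng, t, d2r(22.0), amp)
        ph1 = side_sign * d2r(20.0) + _harmonics(rng, t, d2r(28.0), amp)
        th2 = d2r(65.0) + _harmonics(rng, t, d2r(30.0), amp)
        ph2 = side_sign * d2r(8.0) + _harmonics(rng, t, d2r(40.0), amp)
        d1 = _direction(th1, ph1)
        d2 = _direction(th2, ph2)
        sho = xyz[:, i_sho]
        elb = sho + body.upper_arm_mm * d1
        wri = elb + body.forearm_mm * d2
        dth_a = d2r(12.0) + _harmonics(rng, t, d2r(8.0), amp)
        dph_a = side_sign * d2r(14.0) + _harmonics(rng, t, d2r(10.0), amp)
        dth_b = d2r(2.0) + _harmonics(rng, t, d2r(6.0), amp)
        dph_b = -side_sign * d2r(4.0) + _harmonics(rng, t, d2r(8.0), amp)
        d3a = _direction(th2 + dth_a, ph2 + dph_a)
        d3b = _direction(th2 + dth_b, ph2 + dph_b)
        xyz[:, i_elb] = elb
        xyz[:, i_wri] = wri
        xyz[:, i_thu] = wri + body.thumb_mm * d3a
        xyz[:, i_mid] = wri + body.middle_mm * d3b

    return Stream3D(
        frame_rate=config.video_fps,
        coordinate_frame="mocap",
        xyz=xyz,
        confidence=None,
        missing=np.zeros((n, 13), dtype=bool),
        keypoint_names=TARGET_NAMES,
    )


# ---------------------------------------------------------------------------
# Camera rig
# ---------------------------------------------------------------------------


def _look_at(center: np.ndarray, target: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Extrinsics (R, t) of a camera at ``center`` looking at ``target``.

    Image convention: x right, y down, z forward (right-handed).
    """
    z = target - center
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    return R, -R @ center


def build_cameras(
    config: SimulationConfig,
) -> Tuple[List[CameraParams], RigidTransform]:
    """Camera rig: one frontal plus diagonal cameras on an arc.

    Returns the cameras with extrinsics expressed relative to camera 1
    (the reference camera: identity rotation, zero translation) together
    with the hidden scene-to-reference-frame transform — the quantity the
    spatial-alignment stage must recover for the stereo methods.
    """
    d = config.camera_distance_mm
    target = np.array([0.0, 1400.0, 0.0])
    poses = []
    for ang in config.camera_angles_deg:
        a = np.deg2rad(ang)
        center = np.array([d * np.sin(a), 1400.0, d * np.cos(a)])
        poses.append(_look_at(center, target))
    R1, t1 = poses[0]
    scene_to_world = RigidTransform(R1, t1, 1.0)
    dist = np.array([-0.05, 0.01, 0.0005, -0.0005, 0.002])
    cams = []
    for i, (Ri, ti) in enumerate(poses):
        if i == 0:
            R_rel, t_rel = np.eye(3), np.zeros(3)
        else:
            R_rel = Ri @ R1.T
            t_rel = ti - R_rel @ t1
        cams.append(
            CameraParams(
                camera_id=f"cam{i + 1}",
                fx=config.focal_px,
                fy=config.focal_px,
                cx=config.image_width / 2.0,
                cy=config.image_height / 2.0,
                dist=dist,
                rotation=R_rel,
                translation=t_rel,
                width=config.image_width,
                height=config.image_height,
            )
        )
    return cams, scene_to_world


# ---------------------------------------------------------------------------
# Observation rendering
# ---------------------------------------------------------------------------


def _segment_occlusion(
    cam_center: np.ndarray,
    points: np.ndarray,
    axis0: np.ndarray,
    axis1: np.ndarray,
    radius: float,
) -> np.ndarray:
    """True where the camera-to-keypoint segment passes through the torso
    capsule while the keypoint itself lies outside it."""
    p = points.reshape(-1, 3)
    # distance between segment cam->p and segment axis0->axis1
    d1 = p - cam_center  # direction of sight segments
    d2 = axis1 - axis0
    r = cam_center - axis0
    a = np.sum(d1 * d1, axis=1)
    e = float(d2 @ d2)
    f = d1 @ d2
    c = d1 @ r
    b = float(d2 @ r)
    denom = a * e - f * f
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 1e-12, (f * b - c * e) / denom, 0.0)
    s = np.clip(s, 0.0, 1.0)
    tt = np.clip((f * s + b) / e, 0.0, 1.0)
    s = np.clip((f * tt - c) / a, 0.0, 1.0)
    closest_sight = cam_center + s[:, None] * d1
    closest_axis = axis0 + tt[:, None] * d2
    seg_dist = np.linalg.norm(closest_sight - closest_axis, axis=1)
    # keypoint distance to the axis segment (is the point itself on the torso?)
    w = p - axis0
    u = np.clip((w @ d2) / e, 0.0, 1.0)
    kp_dist = np.linalg.norm(w - u[:, None] * d2, axis=1)
    occ = (seg_dist < radius) & (kp_dist > radius)
    return occ.reshape(points.shape[:-1])


def _smooth_noise(
    rng: np.random.Generator, t: np.ndarray, sd: float, shape_cols: int
) -> np.ndarray:
    """Temporally smooth noise columns with the requested marginal sd."""
    out = np.empty((t.size, shape_cols))
    for j in range(shape_cols):
        n = 6
        freqs = rng.uniform(0.05, 0.5, n)
        raw = rng.uniform(0.5, 1.0, n)
        phases = rng.uniform(0.0, 2.0 * np.pi, n)
        amps = raw * (sd / np.sqrt(np.sum(raw * raw) / 2.0))
        out[:, j] = np.sum(
            amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                                   + phases[:, None]),
            axis=0,
        )
    return out


@dataclass
class SessionBundle:
    """All observation streams of one synthetic recording session."""

    participant_id: str
    sequence_id: int
    ground_truth: Stream3D
    mocap: Stream3D
    cam_streams: List[Stream2D]
    mono_streams: Dict[str, Stream3D]
    meta: SessionMeta
    tape_length_mm: float
    true_mono_scales: Dict[str, float] = field(default_factory=dict)
    true_scene_to_world: Optional[RigidTransform] = None


def render_observations(
    truth: Stream3D,
    config: SimulationConfig,
    cameras: Optional[List[CameraParams]] = None,
    scene_to_world: Optional[RigidTransform] = None,
    *,
    participant: int = 0,
    sequence: int = 0,
) -> SessionBundle:
    """Render MoCap, per-camera 2D and monocular 3D observations of a
    ground-truth motion stream."""
    if cameras is None or scene_to_world is None:
        cameras, scene_to_world = build_cameras(config)
    body = _body_shape(config, participant)
    n = truth.n_frames
    fps = config.video_fps
    t_video = np.arange(n) / fps

    # --- MoCap reference: upsample, marker offset, persistent dropout ----
    rng_mc = _rng(config, _SUB_MOCAP, participant, sequence)
    t_last = (n - 1) / fps
    n_mocap = int(np.floor(t_last * config.mocap_fps)) + 1
    t_mocap = np.arange(n_mocap) / config.mocap_fps
    spline = CubicSpline(t_video, truth.xyz.reshape(n, -1), axis=0)
    mocap_xyz = spline(t_mocap).reshape(n_mocap, 13, 3)
    outward = body.rest - body.torso_center
    outward /= np.linalg.norm(outward, axis=1, keepdims=True)
    mocap_xyz = mocap_xyz + config.marker_offset_mm * outward[None, :, :]
    hazard_draw = rng_mc.random((n_mocap, 13)) < config.mocap_dropout_hazard
    if config.persistent_mocap_dropout:
        mocap_missing = np.maximum.accumulate(hazard_draw, axis=0)
    else:
        mocap_missing = hazard_draw
    mocap_xyz = mocap_xyz.copy()
    mocap_xyz[mocap_missing] = np.nan
    mocap = Stream3D(
        config.mocap_fps, "mocap", mocap_xyz, None, mocap_missing, TARGET_NAMES
    )

    # --- per-camera 2D detections ---------------------------------------
    world_xyz = scene_to_world.apply(truth.xyz)
    world_to_scene = scene_to_world.inverse()
    cam_streams = []
    ax0, ax1 = body.torso_axis
    for ci, cam in enumerate(cameras):
        rng_c = _rng(config, _SUB_CAM + ci, participant, sequence)
        uv, in_front = project(world_xyz, cam, strict=False)
        uv = uv + rng_c.normal(0.0, config.pixel_noise_sd, uv.shape)
        cam_center_scene = world_to_scene.apply(cam.center)
        occluded = _segment_occlusion(
            cam_center_scene, truth.xyz, ax0, ax1, config.torso_radius_mm
        )
        conf = (
            config.confidence_base
            + rng_c.normal(0.0, config.confidence_noise_sd, (n, 13))
            - occluded * config.occlusion_penalty * rng_c.uniform(0.7, 1.3, (n, 13))
        )
        conf = np.clip(conf, 0.0, 1.0)
        missing = ~in_front | (rng_c.random((n, 13)) < config.dropout_prob)
        uv[missing] = np.nan
        conf[missing] = np.nan
        cam_streams.append(
            Stream2D(
                cam.camera_id, fps,
                (config.image_width, config.image_height),
                uv, conf, missing, TARGET_NAMES,
            )
        )

    # --- monocular 3D streams (frontal camera frame) ---------------------
    frontal = cameras[min(1, len(cameras) - 1)]
    x_front = frontal.to_camera_frame(world_xyz.reshape(-1, 3)).reshape(n, 13, 3)
    cam_center_scene = world_to_scene.apply(frontal.center)
    occluded_front = _segment_occlusion(
        cam_center_scene, truth.xyz, ax0, ax1, config.torso_radius_mm
    )
    mono_streams: Dict[str, Stream3D] = {}
    true_scales: Dict[str, float] = {}
    for mi, name in enumerate(MONO_METHODS):
        # the hidden scale is a property of the (participant, method)
        # combination — one monocular reconstruction scale per person —
        # while the noise below varies per sequence
        rng_scale = _rng(config, _SUB_MONO + mi, participant)
        scale = float(rng_scale.uniform(*config.mono_scale_range))
        rng_m = _rng(config, _SUB_MONO + mi, participant, sequence)
        xyz_m = scale * x_front
        # depth error: a shared whole-body component plus per-keypoint
        # components, both slowly varying — monocular depth is wrong in a
        # correlated, drifting way rather than as white noise
        shared = _smooth_noise(rng_m, t_video, 0.8 * config.mono_depth_noise_mm, 1)
        per_kp = _smooth_noise(rng_m, t_video, 0.6 * config.mono_depth_noise_mm, 13)
        xyz_m[..., 2] += shared + per_kp
        lateral = _smooth_noise(rng_m, t_video, config.mono_lateral_noise_mm, 26)
        xyz_m[..., 0] += lateral[:, :13]
        xyz_m[..., 1] += lateral[:, 13:]
        conf = (
            config.confidence_base
            + rng_m.normal(0.0, config.confidence_noise_sd, (n, 13))
            - occluded_front * config.occlusion_penalty
            * rng_m.uniform(0.7, 1.3, (n, 13))
        )
        conf = np.clip(conf, 0.0, 1.0)
        missing = rng_m.random((n, 13)) < config.dropout_prob
        xyz_m[missing] = np.nan
        conf[missing] = np.nan
        mono_streams[name] = Stream3D(
            fps, "mono_raw", xyz_m, conf, missing, TARGET_NAMES
        )
        true_scales[name] = scale

    n_pad = config.n_pad_frames
    meta = SessionMeta(
        participant_id=config.participant_id(participant),
        sequence_id=sequence + 1,
        clap_start_frame=n_pad - 1,
        clap_end_frame=n_pad + config.n_content_frames,
        video_fps=fps,
        mocap_fps=config.mocap_fps,
        margin_s=config.margin_s,
    )
    return SessionBundle(
        participant_id=meta.participant_id,
        sequence_id=meta.sequence_id,
        ground_truth=truth,
        mocap=mocap,
        cam_streams=cam_streams,
        mono_streams=mono_streams,
        meta=meta,
        tape_length_mm=body.upper_arm_mm,
        true_mono_scales=true_scales,
        true_scene_to_world=scene_to_world,
    )


def generate_bundle(
    config: SimulationConfig, participant: int, sequence: int,
    cameras: Optional[List[CameraParams]] = None,
    scene_to_world: Optional[RigidTransform] = None,
) -> SessionBundle:
    truth = generate_motion(config, participant, sequence)
    return render_observations(
        truth, config, cameras, scene_to_world,
        participant=participant, sequence=sequence,
    )


def iter_study(config: SimulationConfig) -> Iterator[SessionBundle]:
    """Yield all n_participants x n_sequences session bundles."""
    cameras, scene_to_world = build_cameras(config)
    for p in range(config.n_participants):
        for s in range(config.n_sequences):
            yield generate_bundle(config, p, s, cameras, scene_to_world)


def generate_study(config: SimulationConfig) -> List[SessionBundle]:
    """Generate the full synthetic study (defaults: 80 bundles)."""
    return list(iter_study(config))


def export_study(
    bundles: Sequence[SessionBundle],
    root: Union[str, Path],
    config: SimulationConfig,
) -> dict:
    """Write a study to disk.

    Layout: ``root/participant_PP/sequence_S/{cam*.json, mocap.csv,
    mono_*.csv, meta.json}`` plus ``root/cameras/cam*.json`` and the
    configuration as YAML.  Returns a manifest with file counts.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    cameras, _ = build_cameras(config)
    cam_dir = root / "cameras"
    cam_dir.mkdir(exist_ok=True)
    for cam in cameras:
        save_camera_params(cam, cam_dir / f"{cam.camera_id}.json")
    (root / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    n_2d = 0
    for b in bundles:
        p_idx = int(b.participant_id[1:])
        seq_dir = root / f"participant_{p_idx:02d}" / f"sequence_{b.sequence_id}"
        seq_dir.mkdir(parents=True, exist_ok=True)
        for stream in b.cam_streams:
            write_stream(stream, seq_dir / f"{stream.camera_id}.json", "json2d")
            n_2d += 1
        write_stream(b.mocap, seq_dir / "mocap.csv", "csv3d")
        for name, stream in b.mono_streams.items():
            write_stream(stream, seq_dir / f"{name}.csv", "csv3d")
        meta = b.meta.to_json()
        meta["tape_length_mm"] = b.tape_length_mm
        (seq_dir / "meta.json").write_text(json.dumps(meta, indent=1))
    manifest = {
        "n_bundles": len(bundles),
        "n_2d_files": n_2d,
        "n_cameras": len(cameras),
        "seed": config.seed,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
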