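"""Temporal and spatial alignment of method streams onto the reference.

Temporal: sessions are trimmed to the content strictly between the two
clapperboard frames, the first and last 5 s are excluded (the margin), and
the 100 fps reference is downsampled to the video frame count by uniform
nearest-index selection.

Spatial: a validity mask keeps only (frame, keypoint) entries where the
reference tracked the marker AND every participating method reports
confidence at or above the threshold (0.3 by default; ties count as
valid).  Monocular streams have no metric scale, so a uniform scale is
first estimated from the tape-measured right elbow-shoulder length; the
rigid rotation/translation is then fit per participant from all valid
correspondences pooled over that participant's sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateFitError,
    EmptySequenceError,
    ScaleEstimationError,
)
from .geometry import RigidTransform, rigid_fit
from .keypoints import SessionMeta, Stream2D, Stream3D
from .simulate import I_ELB_R, I_SHO_R

__all__ = [
    "ValidityConfig",
    "ValidityMask",
    "AlignmentParams",
    "trim_to_claps",
    "downsample_uniform",
    "build_validity_mask",
    "estimate_scale",
    "fit_alignment",
    "apply_alignment",
]


@dataclass(frozen=True)
class ValidityConfig:
    """Confidence threshold tau for a detection to count as valid."""

    confidence_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise AlignmentError("confidence_threshold must be in [0, 1]")


@dataclass
class ValidityMask:
    """Frames x 13 conjunction of reference presence and method validity."""

    valid: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.ndim != 2:
            raise AlignmentError("validity mask must be 2-D (frames x keypoints)")

    @property
    def n_frames(self) -> int:
        return self.valid.shape[0]


@dataclass
class AlignmentParams:
    """Per-(participant, method) similarity transform into the reference frame."""

    participant_id: str
    method_id: str
    transform: RigidTransform

    def to_json(self) -> dict:
        return {
            "participant": self.participant_id,
            "method": self.method_id,
            "s": self.transform.s,
            "R": self.transform.R.ravel().tolist(),
            "t": self.transform.t.tolist(),
        }

    @classmethod
    def from_json(cls, raw: dict) -> "AlignmentParams":
        return cls(
            str(raw["participant"]),
            str(raw["method"]),
            RigidTransform(
                np.asarray(raw["R"], dtype=float).reshape(3, 3),
                np.asarray(raw["t"], dtype=float),
                float(raw["s"]),
            ),
        )


def trim_to_claps(
    stream: Union[Stream2D, Stream3D], meta: SessionMeta
) -> Union[Stream2D, Stream3D]:
    """Trim a stream to the analysable span.

    Clap frames themselves are excluded (content strictly between them),
    then ``margin_s`` seconds are dropped from each end.  Clap frames are
    video-frame indices; streams at other rates (the 100 fps reference)
    are trimmed at the corresponding times.  Frame indices re-zero.
    """
    rate = stream.fps if isinstance(stream, Stream2D) else stream.frame_rate
    ratio = rate / meta.video_fps
    first = int(np.ceil((meta.clap_start_frame + 1) * ratio - 1e-9))
    last = int(np.floor((meta.clap_end_frame - 1) * ratio + 1e-9))
    if not (0 <= first <= last < stream.n_frames):
        raise AlignmentError(
            f"clap frames [{meta.clap_start_frame}, {meta.clap_end_frame}] "
            f"outside stream bounds (n={stream.n_frames} @ {rate} fps)"
        )
    margin = int(round(meta.margin_s * rate))
    first += margin
    last -= margin
    if first > last:
        raise EmptySequenceError(
            f"margin of {meta.margin_s} s exhausts the clap-to-clap span"
        )
    return stream.select_frames(np.arange(first, last + 1))


def downsample_uniform(mocap: Stream3D, target_frames: int) -> Stream3D:
    """Uniform nearest-index downsampling to ``target_frames``.

    Selects source indices round(i * (N-1) / (T-1)); endpoints are always
    preserved and missing flags carried through.  No interpolation — the
    nearest reference sample represents each video frame (see
    :func:`resample_interpolated` for the smoothed variant).
    """
    n = mocap.n_frames
    if target_frames < 2:
        raise AlignmentError("target_frames must be >= 2")
    if target_frames > n:
        raise AlignmentError(
            f"cannot downsample {n} frames to {target_frames}"
        )
    idx = np.round(np.arange(target_frames) * (n - 1) / (target_frames - 1)).astype(int)
    out = mocap.select_frames(idx)
    return replace(out, frame_rate=mocap.frame_rate * (target_frames - 1) / (n - 1))


def resample_interpolated(mocap: Stream3D, target_frames: int) -> Stream3D:
    """Linear-interpolation alternative to nearest-index downsampling.

    A (frame, keypoint) is missing if either bracketing source frame is.
    """
    n = mocap.n_frames
    if target_frames < 2 or target_frames > n:
        raise AlignmentError("target_frames out of range")
    pos = np.arange(target_frames) * (n - 1) / (target_frames - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = (pos - lo)[:, None, None]
    xyz = (1 - w) * mocap.xyz[lo] + w * mocap.xyz[hi]
    missing = mocap.missing[lo] | mocap.missing[hi]
    xyz[missing] = np.nan
    conf = None
    if mocap.confidence is not None:
        conf = (1 - w[..., 0]) * mocap.confidence[lo] + w[..., 0] * mocap.confidence[hi]
        conf[missing] = np.nan
    return Stream3D(
        mocap.frame_rate * (target_frames - 1) / (n - 1),
        mocap.coordinate_frame, xyz, conf, missing, mocap.keypoint_names,
    )


def build_validity_mask(
    mocap: Stream3D,
    methods: Sequence[Stream3D],
    cfg: ValidityConfig = ValidityConfig(),
) -> ValidityMask:
    """Conjunction mask: reference present AND every method valid.

    A method entry is valid when it is not missing and its confidence is
    at or above the threshold; confidence exactly at the threshold counts
    as valid.  Reference keypoints lost by the tracker (missing flags,
    including persistent track loss) invalidate the entry regardless of
    method confidences.
    """
    tau = cfg.confidence_threshold
    n, k = mocap.missing.shape
    valid = ~mocap.missing
    names = ["mocap"]
    for m in methods:
        if m.missing.shape != (n, k):
            raise AlignmentError(
                f"method stream has {m.missing.shape[0]} frames, reference has {n}"
            )
        ok = ~m.missing
        if m.confidence is not None:
            with np.errstate(invalid="ignore"):
                ok &= np.nan_to_num(m.confidence, nan=-1.0) >= tau
        valid &= ok
        names.append(m.coordinate_frame)
    return ValidityMask(valid, provenance="&".join(names))


def _mask_array(mask) -> np.ndarray:
    return mask.valid if isinstance(mask, ValidityMask) else np.asarray(mask, dtype=bool)


def estimate_scale(
    mono: Union[Stream3D, Sequence[Stream3D]],
    mask,
    tape_length_mm: float,
) -> float:
    """Uniform scale for a monocular stream from the tape-measured
    right elbow-shoulder length.

    s = tape length / mean over valid frames of the estimated
    ||elbow_R - shoulder_R||; a frame contributes only when both keypoints
    are valid.  Accepts one stream or a list (sequences pooled).
    """
    streams = [mono] if isinstance(mono, Stream3D) else list(mono)
    masks = [mask] if isinstance(mask, (ValidityMask, np.ndarray)) else list(mask)
    if len(masks) != len(streams):
        raise AlignmentError("one mask per stream required")
    dists = []
    for st, mk in zip(streams, masks):
        m = _mask_array(mk)
        both = m[:, I_ELB_R] & m[:, I_SHO_R]
        if both.any():
            seg = st.xyz[both, I_ELB_R] - st.xyz[both, I_SHO_R]
            dists.append(np.linalg.norm(seg, axis=1))
    if not dists:
        raise ScaleEstimationError(
            "no frame with both right elbow and right shoulder valid"
        )
    mean_est = float(np.mean(np.concatenate(dists)))
    if mean_est <= 0:
        raise ScaleEstimationError("degenerate zero elbow-shoulder distance")
    return float(tape_length_mm) / mean_est


def fit_alignment(
    method: Union[Stream3D, Sequence[Stream3D]],
    mocap: Union[Stream3D, Sequence[Stream3D]],
    mask,
    s: float = 1.0,
    *,
    participant_id: str = "",
    method_id: str = "",
) -> AlignmentParams:
    """Rigid fit of a (scaled) method stream onto the reference.

    Every valid (frame, keypoint) is one 3D correspondence; sequences of a
    participant are pooled and weighted equally.  The method points are
    scaled by ``s`` first (1 for stereo methods, tape-derived for
    monocular ones); the returned transform carries that scale.
    """
    m_streams = [method] if isinstance(method, Stream3D) else list(method)
    r_streams = [mocap] if isinstance(mocap, Stream3D) else list(mocap)
    masks = [mask] if isinstance(mask, (ValidityMask, np.ndarray)) else list(mask)
    if not (len(m_streams) == len(r_streams) == len(masks)):
        raise AlignmentError("method, reference and mask lists must align")
    P, Q = [], []
    for ms, rs, mk in zip(m_streams, r_streams, masks):
        m = _mask_array(mk)
        if ms.missing.shape != m.shape or rs.missing.shape != m.shape:
            raise AlignmentError("stream/mask frame-count mismatch")
        P.append(ms.xyz[m])
        Q.append(rs.xyz[m])
    P = np.concatenate(P) if P else np.empty((0, 3))
    Q = np.concatenate(Q) if Q else np.empty((0, 3))
    if P.shape[0] < 3:
        raise DegenerateFitError(
            f"only {P.shape[0]} valid correspondences; need >= 3"
        )
    fit = rigid_fit(s * P, Q)
    return AlignmentParams(
        participant_id, method_id, RigidTransform(fit.R, fit.t, float(s))
    )


def apply_alignment(method: Stream3D, params: AlignmentParams) -> Stream3D:
    """Map a method stream into the reference frame: x -> R(s x) + t."""
    xyz = params.transform.apply(method.xyz)
    xyz = xyz.copy()
    xyz[method.missing] = np.nan
    return replace(method, xyz=xyz, coordinate_frame="aligned")
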