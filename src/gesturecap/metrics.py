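"""Error metrics and gesture-space comparison.

Per-keypoint Euclidean errors against the reference are folded into 10
analysis groups (sided thumb/middle-finger/wrist/elbow groups, shoulders
pooled, cheeks+chin pooled as "face").  Gesture space is quantified as the
set of voxels the wrists visit at least once; spatial agreement between
two methods is the Dice coefficient of their occupied-voxel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .errors import AlignmentError, GestureCapError
from .keypoints import GROUPS, GROUP_OF_KEYPOINT, Stream3D, TARGET_NAMES
from .simulate import I_WRI_L, I_WRI_R

__all__ = [
    "VoxelGridSpec",
    "euclid_errors",
    "aggregate_participant_means",
    "voxelize",
    "dice",
    "dice_curve",
    "wrist_points",
    "low_confidence_flags",
    "low_confidence_breakdown",
    "breakdown_from_flags",
]

_GROUP_DTYPE = pd.CategoricalDtype(categories=list(GROUPS))


@dataclass(frozen=True)
class VoxelGridSpec:
    """Axis-aligned voxel grid with half-open cells [i*v, (i+1)*v).

    Anchored at the aligned reference-frame origin by default; the voxel
    index of a point is floor((p - anchor) / v) componentwise.
    """

    voxel_size_mm: float = 50.0
    anchor: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise GestureCapError("voxel size must be positive")


def euclid_errors(
    aligned: Stream3D,
    mocap: Stream3D,
    mask,
    *,
    participant: str = "",
    method: str = "",
    sequence: int = 0,
) -> pd.DataFrame:
    """Tidy per-(frame, keypoint) Euclidean errors at valid entries.

    Columns: participant, method, sequence, group, frame, keypoint, e_mm.
    Records exist only where the validity mask is true.
    """
    m = mask.valid if hasattr(mask, "valid") else np.asarray(mask, dtype=bool)
    if aligned.n_frames != mocap.n_frames or m.shape != aligned.missing.shape:
        raise AlignmentError("aligned/reference/mask frame counts differ")
    diff = aligned.xyz - mocap.xyz
    e = np.sqrt(np.sum(diff * diff, axis=2))
    frames, kps = np.nonzero(m)
    group_codes = np.array([GROUPS.index(g) for g in GROUP_OF_KEYPOINT])
    return pd.DataFrame(
        {
            "participant": pd.Categorical([participant] * len(frames)),
            "method": pd.Categorical([method] * len(frames)),
            "sequence": np.full(len(frames), sequence, dtype=np.int32),
            "group": pd.Categorical.from_codes(group_codes[kps], list(GROUPS)),
            "frame": frames.astype(np.int32),
            "keypoint": pd.Categorical.from_codes(kps, list(TARGET_NAMES)),
            "e_mm": e[frames, kps],
        }
    )


def aggregate_participant_means(
    table: pd.DataFrame,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Participant x method x group mean errors, plus overall method means.

    Cell means are unweighted means of e_mm within each cell; empty cells
    are NaN (flagged missing, never zero).  The overall per-method mean is
    the mean over participants of each participant's pooled mean error —
    participants, not frames, are the statistical unit.
    """
    if table.empty:
        raise GestureCapError("empty error table")
    cells = (
        table.groupby(["participant", "method", "group"], observed=True)["e_mm"]
        .mean()
        .reset_index()
        .rename(columns={"e_mm": "mean_e_mm"})
    )
    per_participant = (
        table.groupby(["participant", "method"], observed=True)["e_mm"]
        .mean()
        .reset_index()
    )
    overall = (
        per_participant.groupby("method", observed=True)["e_mm"]
        .mean()
        .reset_index()
        .rename(columns={"e_mm": "overall_mean_e_mm"})
    )
    return cells, overall


def voxelize(points: np.ndarray, spec: VoxelGridSpec = VoxelGridSpec()) -> Set[tuple]:
    """Set of integer voxel indices visited by the points.

    Floor indexing (half-open cells) so negative coordinates land in
    negative indices; duplicates collapse by set semantics.  NaN points
    are ignored.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    idx = np.floor((pts - np.asarray(spec.anchor)) / spec.voxel_size_mm).astype(int)
    return set(map(tuple, idx))


def dice(A: Set[tuple], B: Set[tuple]) -> float:
    """Dice set-similarity 2|A∩B| / (|A| + |B|)."""
    if not A and not B:
        raise GestureCapError("Dice undefined for two empty sets")
    return 2.0 * len(A & B) / (len(A) + len(B))


def dice_curve(
    mocap_points: np.ndarray,
    method_points: np.ndarray,
    v_list: Sequence[float],
) -> List[Tuple[float, float]]:
    """Dice coefficient of the two occupancy sets at each voxel size."""
    out = []
    for v in v_list:
        spec = VoxelGridSpec(float(v))
        out.append((float(v), dice(voxelize(mocap_points, spec),
                                   voxelize(method_points, spec))))
    return out


def wrist_points(stream: Stream3D, mask=None) -> np.ndarray:
    """Pooled left+right wrist positions over all frames (gesture space).

    Laterality and time are deliberately discarded; an optional validity
    mask restricts to valid entries.
    """
    m = None
    if mask is not None:
        m = mask.valid if hasattr(mask, "valid") else np.asarray(mask, dtype=bool)
    pts = []
    for idx in (I_WRI_R, I_WRI_L):
        take = ~stream.missing[:, idx]
        if m is not None:
            take &= m[:, idx]
        pts.append(stream.xyz[take, idx])
    return np.concatenate(pts, axis=0)


def low_confidence_flags(stream: Stream3D, tau: float) -> np.ndarray:
    """Boolean frames x keypoints array: detection missing or below tau."""
    if stream.confidence is None:
        raise GestureCapError("stream carries no confidences")
    return stream.missing | (np.nan_to_num(stream.confidence, nan=-1.0) < tau)


def low_confidence_breakdown(
    stream_a: Stream3D,
    stream_b: Stream3D,
    tau: float = 0.3,
    *,
    name_a: str = "a",
    name_b: str = "b",
) -> pd.DataFrame:
    """Per-group breakdown of low-confidence events between two methods.

    Among (frame, keypoint) events where the confidence falls below tau
    (or the detection is missing) in at least one stream: N is the event
    count and the percentage columns split events into a-only / b-only /
    both.  Groups with no event get N=0 and NA percentages.  Accepts
    streams of equal shape carrying confidences.
    """
    if stream_a.missing.shape != stream_b.missing.shape:
        raise AlignmentError("streams differ in shape")
    la = low_confidence_flags(stream_a, tau)
    lb = low_confidence_flags(stream_b, tau)
    return breakdown_from_flags(la, lb, name_a=name_a, name_b=name_b)


def breakdown_from_flags(
    la: np.ndarray, lb: np.ndarray, *, name_a: str = "a", name_b: str = "b"
) -> pd.DataFrame:
    """Breakdown table from precomputed low-confidence flag arrays
    (frames x 13); frames may be pooled across sequences."""
    rows = []
    group_codes = np.array([GROUPS.index(g) for g in GROUP_OF_KEYPOINT])
    for gi, group in enumerate(GROUPS):
        cols = np.nonzero(group_codes == gi)[0]
        a = la[:, cols].ravel()
        b = lb[:, cols].ravel()
        event = a | b
        n = int(event.sum())
        if n == 0:
            rows.append((group, 0, np.nan, np.nan, np.nan))
        else:
            a_only = int((a & ~b).sum()) / n * 100.0
            b_only = int((b & ~a).sum()) / n * 100.0
            both = int((a & b).sum()) / n * 100.0
            rows.append((group, n, a_only, b_only, both))
    return pd.DataFrame(
        rows,
        columns=["group", "N", f"pct_{name_a}_only", f"pct_{name_b}_only", "pct_both"],
    )
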