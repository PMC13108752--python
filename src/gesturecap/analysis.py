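"""End-to-end in-memory study analysis.

Drives the full evaluation on a (typically synthetic) study: stereo
triangulation of the 2D detection streams, temporal alignment and
reference downsampling, validity masking, per-participant scale and rigid
alignment, Euclidean-error tables, low-confidence breakdowns,
gesture-space Dice curves and the within-subject statistics.

Four methods are evaluated by default: two stereo routes (triangulation
from the two diagonal cameras — the primary pair — and from a
frontal+diagonal pair) and two monocular streams.  This yields the
2-stereo-vs-2-monocular within-subject design the statistics stage
expects (k = 4 methods).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .align import (
    AlignmentParams,
    ValidityConfig,
    ValidityMask,
    apply_alignment,
    build_validity_mask,
    downsample_uniform,
    estimate_scale,
    fit_alignment,
    trim_to_claps,
)
from .geometry import CameraParams, triangulate_batch
from .keypoints import Stream2D, Stream3D, TARGET_NAMES
from .metrics import (
    aggregate_participant_means,
    breakdown_from_flags,
    dice_curve,
    euclid_errors,
    low_confidence_flags,
    wrist_points,
)
from .simulate import (
    MONO_METHODS,
    SessionBundle,
    SimulationConfig,
    build_cameras,
    iter_study,
)
from .stats import AnovaResult, PairwiseResult, pairwise_bonferroni, rm_anova

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_STEREO_PAIRS",
    "DEFAULT_VOXEL_SIZES",
    "StudyResults",
    "triangulate_streams",
    "prepare_sequence",
    "run_study_analysis",
    "methods_matrix",
]

#: stereo method name -> pair of camera ids; the diagonal pair is primary.
DEFAULT_STEREO_PAIRS: Dict[str, Tuple[str, str]] = {
    "stereo_a": ("cam1", "cam3"),
    "stereo_b": ("cam2", "cam3"),
}

#: voxel-size sweep for the Dice curve (mm).
DEFAULT_VOXEL_SIZES: Tuple[float, ...] = tuple(float(v) for v in range(10, 101, 10))


def triangulate_streams(
    cam_streams: Sequence[Stream2D],
    cameras: Sequence[CameraParams],
    stereo_pairs: Dict[str, Tuple[str, str]] = DEFAULT_STEREO_PAIRS,
) -> Dict[str, Stream3D]:
    """DLT-triangulate each configured camera pair into a 3D stream.

    The fused confidence of each keypoint is the minimum of the two
    views' confidences; a keypoint missing in either view, or with
    degenerate geometry, is missing in the output.
    """
    by_id = {s.camera_id: s for s in cam_streams}
    cam_by_id = {c.camera_id: c for c in cameras}
    out: Dict[str, Stream3D] = {}
    for method, (ca, cb) in stereo_pairs.items():
        sa, sb = by_id[ca], by_id[cb]
        pts, ok = triangulate_batch(sa.uv, sb.uv, cam_by_id[ca], cam_by_id[cb])
        missing = sa.missing | sb.missing | ~ok
        conf = np.minimum(sa.confidence, sb.confidence)
        pts = pts.copy()
        pts[missing] = np.nan
        conf = conf.copy()
        conf[missing] = np.nan
        out[method] = Stream3D(
            sa.fps, "camera1", pts, conf, missing, TARGET_NAMES
        )
    return out


@dataclass
class SequenceData:
    """Trimmed, frame-matched streams and the joint validity mask of one
    sequence."""

    participant_id: str
    sequence_id: int
    mocap: Stream3D  # trimmed + downsampled to the video frame count
    methods: Dict[str, Stream3D]  # trimmed method streams (raw frames)
    mask: ValidityMask
    tape_length_mm: float


def prepare_sequence(
    bundle: SessionBundle,
    cameras: Sequence[CameraParams],
    validity: ValidityConfig = ValidityConfig(),
    stereo_pairs: Dict[str, Tuple[str, str]] = DEFAULT_STEREO_PAIRS,
) -> SequenceData:
    """Trim to claps, triangulate, downsample the reference and build the
    joint validity mask for one session."""
    meta = bundle.meta
    cams_trimmed = [trim_to_claps(s, meta) for s in bundle.cam_streams]
    methods: Dict[str, Stream3D] = dict(
        triangulate_streams(cams_trimmed, cameras, stereo_pairs)
    )
    for name, stream in bundle.mono_streams.items():
        methods[name] = trim_to_claps(stream, meta)
    n_video = next(iter(methods.values())).n_frames
    mocap = downsample_uniform(trim_to_claps(bundle.mocap, meta), n_video)
    mask = build_validity_mask(mocap, list(methods.values()), validity)
    return SequenceData(
        bundle.participant_id, bundle.sequence_id, mocap, methods, mask,
        bundle.tape_length_mm,
    )


def fit_participant_alignment(
    sequences: Sequence[SequenceData],
    method_names: Sequence[str],
    mono_names: Sequence[str] = MONO_METHODS,
) -> Dict[str, AlignmentParams]:
    """Per-method similarity transforms for one participant, pooled over
    that participant's sequences.

    Stereo methods are metric, so their scale is fixed to 1; monocular
    methods first receive the tape-measure scale.
    """
    pid = sequences[0].participant_id
    tape = sequences[0].tape_length_mm
    masks = [sd.mask for sd in sequences]
    mocaps = [sd.mocap for sd in sequences]
    params: Dict[str, AlignmentParams] = {}
    for name in method_names:
        streams = [sd.methods[name] for sd in sequences]
        s = estimate_scale(streams, masks, tape) if name in mono_names else 1.0
        params[name] = fit_alignment(
            streams, mocaps, masks, s, participant_id=pid, method_id=name
        )
    return params


@dataclass
class StudyResults:
    """Everything the analysis computes on a study."""

    config: SimulationConfig
    methods: List[str]
    error_table: pd.DataFrame
    cell_means: pd.DataFrame
    overall_means: pd.DataFrame
    anova: List[AnovaResult]
    pairwise: List[PairwiseResult]
    breakdown: pd.DataFrame
    dice_points: List[Tuple[float, float]]
    alignment: Dict[Tuple[str, str], AlignmentParams]
    n_bundles: int
    n_2d_streams: int
    n_valid_by_group: Dict[str, int]


def methods_matrix(cell_means: pd.DataFrame, group: str) -> pd.DataFrame:
    """Participant x method matrix of mean errors for one group."""
    sub = cell_means[cell_means["group"] == group]
    return sub.pivot(index="participant", columns="method", values="mean_e_mm")


def run_study_analysis(
    config: SimulationConfig,
    validity: ValidityConfig = ValidityConfig(),
    voxel_sizes: Sequence[float] = DEFAULT_VOXEL_SIZES,
    stereo_pairs: Dict[str, Tuple[str, str]] = DEFAULT_STEREO_PAIRS,
    gesture_space_participant: int = 0,
    gesture_space_method: str = "stereo_a",
) -> StudyResults:
    """Run the full evaluation on a synthetic study.

    Memory-friendly: bundles are generated, triangulated and reduced one
    participant at a time; only tidy error records and summaries are kept.
    """
    cameras, _ = build_cameras(config)
    stereo_names = list(stereo_pairs)
    method_names = stereo_names + list(MONO_METHODS)
    gs_pid = config.participant_id(gesture_space_participant)
    tau = validity.confidence_threshold

    tables: List[pd.DataFrame] = []
    alignment: Dict[Tuple[str, str], AlignmentParams] = {}
    flags_a: List[np.ndarray] = []
    flags_b: List[np.ndarray] = []
    gs_mocap_pts: List[np.ndarray] = []
    gs_method_pts: List[np.ndarray] = []
    n_bundles = 0
    n_2d = 0

    def flush_participant(seqs: List[SequenceData]) -> None:
        if not seqs:
            return
        pid = seqs[0].participant_id
        params = fit_participant_alignment(seqs, method_names)
        for name, par in params.items():
            alignment[(pid, name)] = par
        for sd in seqs:
            for name in method_names:
                aligned = apply_alignment(sd.methods[name], params[name])
                tables.append(
                    euclid_errors(
                        aligned, sd.mocap, sd.mask,
                        participant=pid, method=name, sequence=sd.sequence_id,
                    )
                )
            if pid == gs_pid:
                gs_mocap_pts.append(wrist_points(sd.mocap, sd.mask))
                gs_aligned = apply_alignment(
                    sd.methods[gesture_space_method], params[gesture_space_method]
                )
                gs_method_pts.append(wrist_points(gs_aligned, sd.mask))
        logger.info("participant %s: %d sequences aligned and scored",
                    pid, len(seqs))

    per_participant: List[SequenceData] = []
    current_p: Optional[str] = None
    for bundle in iter_study(config):
        if current_p is not None and bundle.participant_id != current_p:
            flush_participant(per_participant)
            per_participant = []
        current_p = bundle.participant_id
        sd = prepare_sequence(bundle, cameras, validity, stereo_pairs)
        per_participant.append(sd)
        n_bundles += 1
        n_2d += len(bundle.cam_streams)
        if len(stereo_names) >= 2:
            flags_a.append(low_confidence_flags(sd.methods[stereo_names[0]], tau))
            flags_b.append(low_confidence_flags(sd.methods[stereo_names[1]], tau))
    flush_participant(per_participant)

    error_table = pd.concat(tables, ignore_index=True)
    cell_means, overall_means = aggregate_participant_means(error_table)

    # gesture space: pooled wrists of the chosen participant, reference vs
    # the primary stereo method in the aligned frame
    mocap_pts = np.concatenate(gs_mocap_pts)
    method_pts = np.concatenate(gs_method_pts)
    dice_points = dice_curve(mocap_pts, method_pts, voxel_sizes)

    # low-confidence breakdown between the two stereo routes
    if len(stereo_names) >= 2 and flags_a:
        breakdown = breakdown_from_flags(
            np.concatenate(flags_a), np.concatenate(flags_b),
            name_a=stereo_names[0], name_b=stereo_names[1],
        )
    else:
        breakdown = pd.DataFrame()

    # per-group statistics on the participant x method cell means
    n_valid_by_group = (
        error_table[error_table["method"] == method_names[0]]
        .groupby("group", observed=False)["e_mm"]
        .size()
        .to_dict()
    )
    anova: List[AnovaResult] = []
    pairwise: List[PairwiseResult] = []
    for group in error_table["group"].cat.categories:
        mat = methods_matrix(cell_means, group)[method_names]
        anova.append(
            rm_anova(mat, group=group, n_valid=int(n_valid_by_group.get(group, 0)))
        )
        pairwise.extend(pairwise_bonferroni(mat, group=group))

    return StudyResults(
        config=config,
        methods=method_names,
        error_table=error_table,
        cell_means=cell_means,
        overall_means=overall_means,
        anova=anova,
        pairwise=pairwise,
        breakdown=breakdown,
        dice_points=dice_points,
        alignment=alignment,
        n_bundles=n_bundles,
        n_2d_streams=n_2d,
        n_valid_by_group={str(k): int(v) for k, v in n_valid_by_group.items()},
    )
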