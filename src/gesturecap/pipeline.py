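"""File-based pipeline stages: simulate, triangulate, align, evaluate, report.

Stages communicate only via files under a single output root, so each one
is re-runnable and inspectable:

    root/study/        exported synthetic study (2D JSON, reference CSV, ...)
    root/triangulated/ per-sequence stereo 3D streams
    root/aligned/      alignment parameters, validity masks, aligned streams
    root/metrics/      error table, breakdown, occupancy, Dice curve
    root/report/       ANOVA/pairwise tables and the markdown report

Every stage writes a ``manifest.json`` with the configuration hash, seed,
record counts and content hashes of its outputs; reruns with the same
seed produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .align import (
    AlignmentParams,
    ValidityConfig,
    ValidityMask,
    apply_alignment,
    build_validity_mask,
    downsample_uniform,
    trim_to_claps,
)
from .analysis import (
    DEFAULT_STEREO_PAIRS,
    DEFAULT_VOXEL_SIZES,
    SequenceData,
    fit_participant_alignment,
    methods_matrix,
    triangulate_streams,
)
from .errors import FormatError, PipelineError
from .geometry import load_camera_params
from .keypoints import SessionMeta, read_stream, write_stream
from .metrics import (
    VoxelGridSpec,
    aggregate_participant_means,
    breakdown_from_flags,
    dice_curve,
    euclid_errors,
    low_confidence_flags,
    voxelize,
    wrist_points,
)
from .simulate import MONO_METHODS, SimulationConfig, export_study, generate_study
from .stats import assemble_report, pairwise_bonferroni, rm_anova

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "cmd_simulate",
    "cmd_triangulate",
    "cmd_align",
    "cmd_evaluate",
    "cmd_report",
    "run_all",
]


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end pipeline."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    voxel_sizes_mm: Tuple[float, ...] = DEFAULT_VOXEL_SIZES
    stereo_pairs: Dict[str, Tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_STEREO_PAIRS)
    )
    gesture_space_participant: int = 0
    gesture_space_method: str = "stereo_a"
    write_aligned_streams: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_sizes_mm):
            raise PipelineError("voxel sizes must be positive")
        # one seed governs the whole pipeline
        self.sim = dataclasses.replace(self.sim, seed=int(self.seed))

    @property
    def method_names(self) -> List[str]:
        return list(self.stereo_pairs) + list(MONO_METHODS)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "validity": {"confidence_threshold": self.validity.confidence_threshold},
            "voxel_sizes_mm": list(self.voxel_sizes_mm),
            "stereo_pairs": {k: list(v) for k, v in self.stereo_pairs.items()},
            "gesture_space_participant": self.gesture_space_participant,
            "gesture_space_method": self.gesture_space_method,
            "write_aligned_streams": self.write_aligned_streams,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim" in raw:
            raw["sim"] = SimulationConfig.from_dict(raw["sim"])
        if "validity" in raw:
            raw["validity"] = ValidityConfig(**raw["validity"])
        if "voxel_sizes_mm" in raw:
            raw["voxel_sizes_mm"] = tuple(raw["voxel_sizes_mm"])
        if "stereo_pairs" in raw:
            raw["stereo_pairs"] = {
                k: tuple(v) for k, v in raw["stereo_pairs"].items()
            }
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifest helpers
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(
    stage_dir: Path, config: PipelineConfig, files: Sequence[Path], **counts
) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "files": {
            str(p.relative_to(stage_dir)): _sha256(p) for p in sorted(files)
        },
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _require(root: Path, subdir: str, produced_by: str) -> Path:
    p = root / subdir
    if not p.is_dir():
        raise PipelineError(
            f"missing {p}: run the '{produced_by}' stage first"
        )
    return p


def _sequence_dirs(study: Path) -> List[Path]:
    out = []
    for pdir in sorted(study.glob("participant_*")):
        out.extend(sorted(pdir.glob("sequence_*"),
                          key=lambda q: int(q.name.split("_")[1])))
    if not out:
        raise PipelineError(f"no sequences found under {study}")
    return out


def _load_meta(seq_dir: Path) -> Tuple[SessionMeta, float]:
    raw = json.loads((seq_dir / "meta.json").read_text())
    tape = float(raw.pop("tape_length_mm", 0.0))
    return SessionMeta.from_json(raw), tape


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def cmd_simulate(config: PipelineConfig, root: Union[str, Path]) -> Path:
    """Generate and export the synthetic study."""
    root = Path(root)
    t0 = time.perf_counter()
    bundles = generate_study(config.sim)
    study = root / "study"
    manifest = export_study(bundles, study, config.sim)
    config.to_yaml(root / "pipeline.yaml")
    logger.info(
        "simulate: %d bundles, %d 2D files in %.1fs (config %s)",
        manifest["n_bundles"], manifest["n_2d_files"],
        time.perf_counter() - t0, config.config_hash(),
    )
    return study


def cmd_triangulate(config: PipelineConfig, root: Union[str, Path]) -> Path:
    """Triangulate every sequence's camera pairs into 3D stream files."""
    root = Path(root)
    study = _require(root, "study", "simulate")
    t0 = time.perf_counter()
    cameras = [
        load_camera_params(p) for p in sorted((study / "cameras").glob("cam*.json"))
    ]
    out_root = root / "triangulated"
    written: List[Path] = []
    for seq_dir in _sequence_dirs(study):
        cam_streams = [
            read_stream(p, "json2d") for p in sorted(seq_dir.glob("cam*.json"))
        ]
        tri = triangulate_streams(cam_streams, cameras, config.stereo_pairs)
        out_dir = out_root / seq_dir.parent.name / seq_dir.name
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, stream in tri.items():
            path = out_dir / f"{name}.csv"
            write_stream(stream, path, "csv3d")
            written.append(path)
    _write_manifest(out_root, config, written, n_files=len(written))
    logger.info("triangulate: %d stream files in %.1fs",
                len(written), time.perf_counter() - t0)
    return out_root


def _load_sequence_data(
    config: PipelineConfig, study: Path, tri_root: Path, seq_dir: Path
) -> SequenceData:
    meta, tape = _load_meta(seq_dir)
    tri_dir = tri_root / seq_dir.parent.name / seq_dir.name
    methods = {}
    for name in config.stereo_pairs:
        path = tri_dir / f"{name}.csv"
        if not path.exists():
            raise PipelineError(
                f"missing {path}: run the 'triangulate' stage first"
            )
        methods[name] = trim_to_claps(read_stream(path, "csv3d"), meta)
    for name in MONO_METHODS:
        methods[name] = trim_to_claps(
            read_stream(seq_dir / f"{name}.csv", "csv3d"), meta
        )
    n_video = next(iter(methods.values())).n_frames
    mocap = downsample_uniform(
        trim_to_claps(read_stream(seq_dir / "mocap.csv", "csv3d"), meta), n_video
    )
    mask = build_validity_mask(mocap, list(methods.values()), config.validity)
    return SequenceData(
        meta.participant_id, meta.sequence_id, mocap, methods, mask, tape
    )


def _participant_dirs(study: Path) -> Dict[str, List[Path]]:
    groups: Dict[str, List[Path]] = {}
    for seq_dir in _sequence_dirs(study):
        groups.setdefault(seq_dir.parent.name, []).append(seq_dir)
    return groups


def cmd_align(config: PipelineConfig, root: Union[str, Path]) -> Path:
    """Estimate per-(participant, method) transforms; write params, masks
    and (optionally) aligned streams."""
    root = Path(root)
    study = _require(root, "study", "simulate")
    tri_root = _require(root, "triangulated", "triangulate")
    t0 = time.perf_counter()
    out_root = root / "aligned"
    out_root.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for pname, seq_dirs in _participant_dirs(study).items():
        seqs = [
            _load_sequence_data(config, study, tri_root, sd) for sd in seq_dirs
        ]
        params = fit_participant_alignment(seqs, config.method_names)
        pid = seqs[0].participant_id
        path = out_root / f"params_{pid}.json"
        path.write_text(
            json.dumps({k: v.to_json() for k, v in params.items()}, indent=1)
        )
        written.append(path)
        for sd, seq_dir in zip(seqs, seq_dirs):
            mask_dir = out_root / "masks" / pname
            mask_dir.mkdir(parents=True, exist_ok=True)
            mpath = mask_dir / f"{seq_dir.name}.csv"
            pd.DataFrame(
                sd.mask.valid.astype(int), columns=list(sd.mocap.keypoint_names)
            ).to_csv(mpath, index=False)
            written.append(mpath)
            if config.write_aligned_streams:
                adir = out_root / "streams" / pname / seq_dir.name
                adir.mkdir(parents=True, exist_ok=True)
                write_stream(sd.mocap, adir / "mocap_ds.csv", "csv3d")
                written.append(adir / "mocap_ds.csv")
                for name in config.method_names:
                    aligned = apply_alignment(sd.methods[name], params[name])
                    write_stream(aligned, adir / f"{name}.csv", "csv3d")
                    written.append(adir / f"{name}.csv")
    _write_manifest(out_root, config, written, n_files=len(written))
    logger.info("align: %d files in %.1fs", len(written), time.perf_counter() - t0)
    return out_root


def cmd_evaluate(config: PipelineConfig, root: Union[str, Path]) -> Path:
    """Compute error tables, breakdowns, occupancy sets and the Dice curve."""
    root = Path(root)
    study = _require(root, "study", "simulate")
    tri_root = _require(root, "triangulated", "triangulate")
    aligned_root = _require(root, "aligned", "align")
    t0 = time.perf_counter()
    out_root = root / "metrics"
    out_root.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    tables = []
    flags_a, flags_b = [], []
    stereo_names = list(config.stereo_pairs)
    gs_pid_name = config.sim.participant_id(config.gesture_space_participant)
    gs_mocap_pts, gs_method_pts = [], []
    tau = config.validity.confidence_threshold
    for pname, seq_dirs in _participant_dirs(study).items():
        seqs = [
            _load_sequence_data(config, study, tri_root, sd) for sd in seq_dirs
        ]
        pid = seqs[0].participant_id
        ppath = aligned_root / f"params_{pid}.json"
        if not ppath.exists():
            raise PipelineError(f"missing {ppath}: run the 'align' stage first")
        params = {
            k: AlignmentParams.from_json(v)
            for k, v in json.loads(ppath.read_text()).items()
        }
        for sd in seqs:
            for name in config.method_names:
                aligned = apply_alignment(sd.methods[name], params[name])
                tables.append(
                    euclid_errors(
                        aligned, sd.mocap, sd.mask,
                        participant=pid, method=name, sequence=sd.sequence_id,
                    )
                )
            if len(stereo_names) >= 2:
                flags_a.append(low_confidence_flags(sd.methods[stereo_names[0]], tau))
                flags_b.append(low_confidence_flags(sd.methods[stereo_names[1]], tau))
            if pid == gs_pid_name:
                gs_mocap_pts.append(wrist_points(sd.mocap, sd.mask))
                gs_aligned = apply_alignment(
                    sd.methods[config.gesture_space_method],
                    params[config.gesture_space_method],
                )
                gs_method_pts.append(wrist_points(gs_aligned, sd.mask))
    error_table = pd.concat(tables, ignore_index=True)
    epath = out_root / "errors.csv"
    error_table.to_csv(epath, index=False)
    written.append(epath)

    if flags_a:
        breakdown = breakdown_from_flags(
            np.concatenate(flags_a), np.concatenate(flags_b),
            name_a=stereo_names[0], name_b=stereo_names[1],
        )
        bpath = out_root / "low_confidence_breakdown.csv"
        breakdown.to_csv(bpath, index=False)
        written.append(bpath)

    mocap_pts = np.concatenate(gs_mocap_pts)
    method_pts = np.concatenate(gs_method_pts)
    points = dice_curve(mocap_pts, method_pts, config.voxel_sizes_mm)
    dpath = out_root / "dice_curve.csv"
    pd.DataFrame(points, columns=["voxel_mm", "dice"]).to_csv(dpath, index=False)
    written.append(dpath)
    spec = VoxelGridSpec(50.0)
    for label, pts in (("mocap", mocap_pts), ("method", method_pts)):
        occ = sorted(voxelize(pts, spec))
        opath = out_root / f"occupancy_{label}_50mm.csv"
        pd.DataFrame(occ, columns=["ix", "iy", "iz"]).to_csv(opath, index=False)
        written.append(opath)
    _write_manifest(out_root, config, written, n_error_records=len(error_table))
    logger.info("evaluate: %d error records in %.1fs",
                len(error_table), time.perf_counter() - t0)
    return out_root


def cmd_report(config: PipelineConfig, root: Union[str, Path]) -> Path:
    """Per-group ANOVA + Bonferroni pairwise stats and the report bundle."""
    root = Path(root)
    metrics_root = _require(root, "metrics", "evaluate")
    t0 = time.perf_counter()
    error_table = pd.read_csv(metrics_root / "errors.csv")
    error_table["group"] = pd.Categorical(error_table["group"])
    cell_means, overall = aggregate_participant_means(error_table)
    n_valid = (
        error_table[error_table["method"] == config.method_names[0]]
        .groupby("group", observed=True)["e_mm"]
        .size()
    )
    anova, pairwise = [], []
    from .keypoints import GROUPS

    for group in [g for g in GROUPS if g in set(error_table["group"])]:
        mat = methods_matrix(cell_means, group)[config.method_names]
        anova.append(
            rm_anova(mat, group=group, n_valid=int(n_valid.get(group, 0)))
        )
        pairwise.extend(pairwise_bonferroni(mat, group=group))
    dice_df = pd.read_csv(metrics_root / "dice_curve.csv")
    points = list(dice_df.itertuples(index=False, name=None))
    out_root = root / "report"
    paths = assemble_report(anova, pairwise, cell_means, points, out_root)
    opath = out_root / "overall_means.csv"
    overall.to_csv(opath, index=False)
    paths["overall_means"] = opath
    _write_manifest(out_root, config, list(paths.values()),
                    n_groups=len(anova))
    logger.info("report: %d groups in %.1fs", len(anova),
                time.perf_counter() - t0)
    return out_root


def run_all(config: PipelineConfig, root: Union[str, Path]) -> Path:
    """Run simulate -> triangulate -> align -> evaluate -> report."""
    root = Path(root)
    cmd_simulate(config, root)
    cmd_triangulate(config, root)
    cmd_align(config, root)
    cmd_evaluate(config, root)
    return cmd_report(config, root)
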