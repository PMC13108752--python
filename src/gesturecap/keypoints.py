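"""Keypoint vocabulary, skeleton schemas and stream containers.

The analysis targets 13 upper-body keypoints commonly used in gesture
research: the tips of the thumbs and middle fingers, the wrists, elbows,
shoulders, cheeks and the chin.  Pose estimators emit much larger keypoint
sets (COCO-WholeBody style with 133 points, MediaPipe Holistic style with
543); a :class:`SkeletonSchema` maps such a source layout onto the canonical
13-keypoint target set.

Conventions
-----------
* Frame indices are 0-based; pixel origin is the top-left corner, ``u``
  grows rightward, ``v`` downward.
* Missing observations are explicit boolean flags, never sentinel
  coordinates; coordinates at missing entries are NaN.
* Canonical target order is right-before-left, proximal-to-distal, chin
  last, so exported CSV columns are stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "Part",
    "Side",
    "KeypointId",
    "TARGET_KEYPOINTS",
    "TARGET_NAMES",
    "GROUPS",
    "GROUP_OF_KEYPOINT",
    "SkeletonSchema",
    "get_schema",
    "builtin_schemas",
    "read_schema",
    "Stream2D",
    "Stream3D",
    "SessionMeta",
    "map_to_target",
    "read_stream",
    "write_stream",
]


class Part(str, Enum):
    THUMB_TIP = "thumb_tip"
    MIDDLE_FINGER_TIP = "middle_finger_tip"
    WRIST = "wrist"
    ELBOW = "elbow"
    SHOULDER = "shoulder"
    CHEEK = "cheek"
    CHIN = "chin"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    CENTER = "center"


@dataclass(frozen=True)
class KeypointId:
    """A named anatomical landmark: body part plus laterality.

    The chin is the only midline part (side = center); every other part
    exists as a left/right pair, giving the 13-member target set.
    """

    part: Part
    side: Side

    def __post_init__(self) -> None:
        if self.part is Part.CHIN and self.side is not Side.CENTER:
            raise ValueError("chin must have side=center")
        if self.part is not Part.CHIN and self.side is Side.CENTER:
            raise ValueError(f"{self.part.value} must be left or right")

    @property
    def name(self) -> str:
        if self.side is Side.CENTER:
            return self.part.value
        return f"{self.part.value}_{self.side.value}"

    @classmethod
    def parse(cls, text: str) -> "KeypointId":
        t = text.strip().lower()
        if t in ("chin", "chin_center"):
            return cls(Part.CHIN, Side.CENTER)
        for side in (Side.LEFT, Side.RIGHT):
            suffix = "_" + side.value
            if t.endswith(suffix):
                part = t[: -len(suffix)]
                try:
                    return cls(Part(part), side)
                except ValueError as exc:
                    raise FormatError(f"unknown keypoint part {part!r}") from exc
        raise FormatError(f"cannot parse keypoint id {text!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


def _kp(part: Part, side: Side) -> KeypointId:
    return KeypointId(part, side)


#: Canonical order of the 13-keypoint target set: right before left,
#: proximal to distal, chin last.
TARGET_KEYPOINTS: tuple = (
    _kp(Part.SHOULDER, Side.RIGHT),
    _kp(Part.SHOULDER, Side.LEFT),
    _kp(Part.ELBOW, Side.RIGHT),
    _kp(Part.ELBOW, Side.LEFT),
    _kp(Part.WRIST, Side.RIGHT),
    _kp(Part.WRIST, Side.LEFT),
    _kp(Part.THUMB_TIP, Side.RIGHT),
    _kp(Part.THUMB_TIP, Side.LEFT),
    _kp(Part.MIDDLE_FINGER_TIP, Side.RIGHT),
    _kp(Part.MIDDLE_FINGER_TIP, Side.LEFT),
    _kp(Part.CHEEK, Side.RIGHT),
    _kp(Part.CHEEK, Side.LEFT),
    _kp(Part.CHIN, Side.CENTER),
)

TARGET_NAMES: tuple = tuple(k.name for k in TARGET_KEYPOINTS)
TARGET_INDEX: dict = {k: i for i, k in enumerate(TARGET_KEYPOINTS)}

#: The 10 analysis groups: sided groups for hands/arms, shoulders pooled,
#: cheeks and chin pooled as "face".
GROUPS: tuple = (
    "thumb_R",
    "thumb_L",
    "middle_finger_R",
    "middle_finger_L",
    "wrist_R",
    "wrist_L",
    "elbow_R",
    "elbow_L",
    "shoulder",
    "face",
)


def _group_of(k: KeypointId) -> str:
    if k.part is Part.SHOULDER:
        return "shoulder"
    if k.part in (Part.CHEEK, Part.CHIN):
        return "face"
    short = {
        Part.THUMB_TIP: "thumb",
        Part.MIDDLE_FINGER_TIP: "middle_finger",
        Part.WRIST: "wrist",
        Part.ELBOW: "elbow",
    }[k.part]
    return f"{short}_{'R' if k.side is Side.RIGHT else 'L'}"


#: Group label for each canonical keypoint column, in canonical order.
GROUP_OF_KEYPOINT: tuple = tuple(_group_of(k) for k in TARGET_KEYPOINTS)


@dataclass(frozen=True)
class SkeletonSchema:
    """Partial mapping from a source keypoint layout onto the target set.

    ``mapping`` sends source column indices to :class:`KeypointId`; it must
    be injective (no target keypoint claimed twice).  Source indices that do
    not appear are dropped by :func:`map_to_target`; target keypoints with
    no source are flagged missing throughout.
    """

    name: str
    size: int
    mapping: dict  # source index -> KeypointId

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise FormatError(f"schema {self.name!r}: size must be positive")
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise FormatError(f"schema {self.name!r}: mapping is not injective")
        for idx in self.mapping:
            if not (0 <= idx < self.size):
                raise FormatError(
                    f"schema {self.name!r}: source index {idx} out of range"
                )
        for tgt in targets:
            if tgt not in TARGET_INDEX:
                raise FormatError(f"schema {self.name!r}: {tgt} not a target keypoint")

    def source_index_of(self, target: KeypointId) -> Optional[int]:
        for src, tgt in self.mapping.items():
            if tgt == target:
                return src
        return None


def _coco_wholebody_schema() -> SkeletonSchema:
    # COCO-WholeBody layout: 17 body, 6 feet, 68 face (23..90),
    # 21 left hand (91..111), 21 right hand (112..132).
    # Face-contour cheek proxies (contour points 2 and 14) and the contour
    # chin point (8) are this package's convention for the "closest
    # keypoint" choice; the layout itself fixes body and hand indices.
    m = {
        6: _kp(Part.SHOULDER, Side.RIGHT),
        5: _kp(Part.SHOULDER, Side.LEFT),
        8: _kp(Part.ELBOW, Side.RIGHT),
        7: _kp(Part.ELBOW, Side.LEFT),
        10: _kp(Part.WRIST, Side.RIGHT),
        9: _kp(Part.WRIST, Side.LEFT),
        112 + 4: _kp(Part.THUMB_TIP, Side.RIGHT),
        91 + 4: _kp(Part.THUMB_TIP, Side.LEFT),
        112 + 12: _kp(Part.MIDDLE_FINGER_TIP, Side.RIGHT),
        91 + 12: _kp(Part.MIDDLE_FINGER_TIP, Side.LEFT),
        23 + 2: _kp(Part.CHEEK, Side.RIGHT),
        23 + 14: _kp(Part.CHEEK, Side.LEFT),
        23 + 8: _kp(Part.CHIN, Side.CENTER),
    }
    return SkeletonSchema("wholebody", 133, m)


def _holistic_schema() -> SkeletonSchema:
    # MediaPipe Holistic layout: 33 pose, 468 face mesh (33..500),
    # 21 left hand (501..521), 21 right hand (522..542).
    # Face-mesh cheek proxies 205/425 and chin 152 are conventions.
    m = {
        12: _kp(Part.SHOULDER, Side.RIGHT),
        11: _kp(Part.SHOULDER, Side.LEFT),
        14: _kp(Part.ELBOW, Side.RIGHT),
        13: _kp(Part.ELBOW, Side.LEFT),
        16: _kp(Part.WRIST, Side.RIGHT),
        15: _kp(Part.WRIST, Side.LEFT),
        522 + 4: _kp(Part.THUMB_TIP, Side.RIGHT),
        501 + 4: _kp(Part.THUMB_TIP, Side.LEFT),
        522 + 12: _kp(Part.MIDDLE_FINGER_TIP, Side.RIGHT),
        501 + 12: _kp(Part.MIDDLE_FINGER_TIP, Side.LEFT),
        33 + 205: _kp(Part.CHEEK, Side.RIGHT),
        33 + 425: _kp(Part.CHEEK, Side.LEFT),
        33 + 152: _kp(Part.CHIN, Side.CENTER),
    }
    return SkeletonSchema("holistic", 543, m)


def _mocap_markers_schema() -> SkeletonSchema:
    # 19 retroreflective markers: toes, knees, thumbs, middle fingers,
    # little-finger bases, wrists, elbows, shoulders, cheeks, chin.
    # Toes, knees and little-finger bases are outside the target set.
    m = {
        4: _kp(Part.THUMB_TIP, Side.RIGHT),
        5: _kp(Part.THUMB_TIP, Side.LEFT),
        6: _kp(Part.MIDDLE_FINGER_TIP, Side.RIGHT),
        7: _kp(Part.MIDDLE_FINGER_TIP, Side.LEFT),
        10: _kp(Part.WRIST, Side.RIGHT),
        11: _kp(Part.WRIST, Side.LEFT),
        12: _kp(Part.ELBOW, Side.RIGHT),
        13: _kp(Part.ELBOW, Side.LEFT),
        14: _kp(Part.SHOULDER, Side.RIGHT),
        15: _kp(Part.SHOULDER, Side.LEFT),
        16: _kp(Part.CHEEK, Side.RIGHT),
        17: _kp(Part.CHEEK, Side.LEFT),
        18: _kp(Part.CHIN, Side.CENTER),
    }
    return SkeletonSchema("mocap-markers", 19, m)


def _target_schema() -> SkeletonSchema:
    return SkeletonSchema(
        "target", 13, {i: k for i, k in enumerate(TARGET_KEYPOINTS)}
    )


_BUILTIN = {
    s.name: s
    for s in (
        _coco_wholebody_schema(),
        _holistic_schema(),
        _mocap_markers_schema(),
        _target_schema(),
    )
}


def builtin_schemas() -> dict:
    """Name -> SkeletonSchema for the built-in layouts (133/543/19/13)."""
    return dict(_BUILTIN)


def get_schema(name: str) -> SkeletonSchema:
    try:
        return _BUILTIN[name]
    except KeyError as exc:
        raise FormatError(f"unknown schema {name!r}") from exc


def read_schema(path: Union[str, Path]) -> SkeletonSchema:
    """Load a schema file: JSON {name, size, mapping: {index: "part_side"}}."""
    with open(path) as fh:
        raw = json.load(fh)
    try:
        mapping = {int(k): KeypointId.parse(v) for k, v in raw["mapping"].items()}
        return SkeletonSchema(str(raw["name"]), int(raw["size"]), mapping)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad schema file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Stream containers
# ---------------------------------------------------------------------------


def _as_names(names: Optional[Sequence[str]], n: int) -> tuple:
    if names is None:
        if n == 13:
            return TARGET_NAMES
        return tuple(f"kp_{i:03d}" for i in range(n))
    if len(names) != n:
        raise FormatError("keypoint_names length mismatch")
    return tuple(names)


@dataclass
class Stream2D:
    """Per-camera time series of pixel keypoints with confidences.

    ``uv`` has shape (frames, keypoints, 2) in pixels; ``confidence`` is in
    [0, 1] where present.  Detections may fall outside the image, so u, v
    are unconstrained.
    """

    camera_id: str
    fps: float
    resolution: tuple  # (width, height) px
    uv: np.ndarray
    confidence: np.ndarray
    missing: np.ndarray
    keypoint_names: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.uv = np.asarray(self.uv, dtype=float)
        if self.uv.ndim != 3 or self.uv.shape[2] != 2:
            raise FormatError("uv must have shape (frames, keypoints, 2)")
        f, k = self.uv.shape[:2]
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.confidence.shape != (f, k) or self.missing.shape != (f, k):
            raise FormatError("confidence/missing shape mismatch")
        self.keypoint_names = _as_names(self.keypoint_names, k)
        if self.fps <= 0:
            raise FormatError("fps must be positive")
        present = ~self.missing
        conf = self.confidence[present]
        if conf.size and (np.nanmin(conf) < 0 or np.nanmax(conf) > 1):
            raise FormatError("confidence out of [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.uv.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.uv.shape[1]

    def select_frames(self, index: np.ndarray) -> "Stream2D":
        return replace(
            self,
            uv=self.uv[index],
            confidence=self.confidence[index],
            missing=self.missing[index],
        )


@dataclass
class Stream3D:
    """Time series of 3D keypoints in millimetres, in a tagged frame.

    ``coordinate_frame`` is one of {"mocap", "camera1", "mono_raw",
    "aligned"}.  MoCap-style streams carry missing flags and no confidence
    (``confidence is None``); estimator-derived streams carry both.
    """

    frame_rate: float
    coordinate_frame: str
    xyz: np.ndarray
    confidence: Optional[np.ndarray]
    missing: np.ndarray
    keypoint_names: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise FormatError("xyz must have shape (frames, keypoints, 3)")
        f, k = self.xyz.shape[:2]
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (f, k):
            raise FormatError("missing shape mismatch")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (f, k):
                raise FormatError("confidence shape mismatch")
        self.keypoint_names = _as_names(self.keypoint_names, k)
        if self.frame_rate <= 0:
            raise FormatError("frame_rate must be positive")
        if not np.all(np.isfinite(self.xyz[~self.missing])):
            raise FormatError("non-finite coordinates at present entries")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_keypoints(self) -> int:
        return self.xyz.shape[1]

    def select_frames(self, index: np.ndarray) -> "Stream3D":
        conf = None if self.confidence is None else self.confidence[index]
        return replace(
            self, xyz=self.xyz[index], confidence=conf, missing=self.missing[index]
        )


@dataclass
class SessionMeta:
    """Session metadata: identities, clap frames and rates.

    Clap frames are 0-based video frame indices; the analysable content
    lies strictly between them (the clap frames themselves are excluded).
    """

    participant_id: str
    sequence_id: int
    clap_start_frame: int
    clap_end_frame: int
    video_fps: float = 30.0
    mocap_fps: float = 100.0
    margin_s: float = 5.0

    def __post_init__(self) -> None:
        if not (1 <= int(self.sequence_id)):
            raise FormatError("sequence_id must be >= 1")
        if self.clap_start_frame >= self.clap_end_frame:
            raise FormatError("clap_start_frame must precede clap_end_frame")
        span = (self.clap_end_frame - self.clap_start_frame - 1) / self.video_fps
        if span - 2 * self.margin_s <= 0:
            raise FormatError("margins leave no analysable frames")

    def to_json(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "sequence_id": int(self.sequence_id),
            "clap_start_frame": int(self.clap_start_frame),
            "clap_end_frame": int(self.clap_end_frame),
            "video_fps": self.video_fps,
            "mocap_fps": self.mocap_fps,
            "margin_s": self.margin_s,
        }

    @classmethod
    def from_json(cls, raw: dict) -> "SessionMeta":
        try:
            return cls(**raw)
        except (KeyError, TypeError) as exc:
            raise FormatError(f"bad session metadata: {exc}") from exc


# ---------------------------------------------------------------------------
# Target mapping
# ---------------------------------------------------------------------------


def map_to_target(stream, schema: SkeletonSchema):
    """Restrict a stream to the 13-keypoint target set in canonical order.

    Source keypoints not mapped by the schema are dropped; target keypoints
    without a source column are flagged missing throughout.  Confidence and
    missing flags are carried over per keypoint.
    """
    if stream.n_keypoints != schema.size:
        raise FormatError(
            f"schema {schema.name!r} expects {schema.size} keypoints, "
            f"stream has {stream.n_keypoints}"
        )
    f = stream.n_frames
    src_of = [schema.source_index_of(k) for k in TARGET_KEYPOINTS]
    cols = [s if s is not None else 0 for s in src_of]
    unmapped = np.array([s is None for s in src_of])

    if isinstance(stream, Stream2D):
        uv = stream.uv[:, cols].copy()
        conf = stream.confidence[:, cols].copy()
        miss = stream.missing[:, cols].copy()
        uv[:, unmapped] = np.nan
        conf[:, unmapped] = np.nan
        miss[:, unmapped] = True
        return Stream2D(
            stream.camera_id, stream.fps, stream.resolution, uv, conf, miss,
            TARGET_NAMES,
        )
    if isinstance(stream, Stream3D):
        xyz = stream.xyz[:, cols].copy()
        miss = stream.missing[:, cols].copy()
        xyz[:, unmapped] = np.nan
        miss[:, unmapped] = True
        conf = None
        if stream.confidence is not None:
            conf = stream.confidence[:, cols].copy()
            conf[:, unmapped] = np.nan
        return Stream3D(
            stream.frame_rate, stream.coordinate_frame, xyz, conf, miss,
            TARGET_NAMES,
        )
    raise FormatError(f"unsupported stream type {type(stream)!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _float_str(x: float) -> str:
    return repr(float(x))


def write_stream(stream, path: Union[str, Path], format: str) -> None:
    """Write a stream to ``path``; ``format`` is "json2d" or "csv3d"."""
    path = Path(path)
    if format == "json2d":
        if not isinstance(stream, Stream2D):
            raise FormatError("json2d format requires a Stream2D")
        _write_json2d(stream, path)
    elif format == "csv3d":
        if not isinstance(stream, Stream3D):
            raise FormatError("csv3d format requires a Stream3D")
        _write_csv3d(stream, path)
    else:
        raise FormatError(f"unknown stream format {format!r}")


def read_stream(path: Union[str, Path], format: str):
    path = Path(path)
    if format == "json2d":
        return _read_json2d(path)
    if format == "csv3d":
        return _read_csv3d(path)
    raise FormatError(f"unknown stream format {format!r}")


def _write_json2d(stream: Stream2D, path: Path) -> None:
    # One object per frame, keys = keypoint names, values = [u, v, conf];
    # missing observations are null.  Assembled as strings for speed on
    # full-study exports.
    names = stream.keypoint_names
    chunks = []
    uv = stream.uv
    conf = stream.confidence
    miss = stream.missing
    for f in range(stream.n_frames):
        items = []
        for k, name in enumerate(names):
            if miss[f, k]:
                items.append(f'"{name}":null')
            else:
                items.append(
                    f'"{name}":[{_float_str(uv[f, k, 0])},'
                    f'{_float_str(uv[f, k, 1])},{_float_str(conf[f, k])}]'
                )
        chunks.append("{" + ",".join(items) + "}")
    header = json.dumps(
        {
            "camera_id": stream.camera_id,
            "fps": stream.fps,
            "resolution": [int(stream.resolution[0]), int(stream.resolution[1])],
            "keypoints": list(names),
        }
    )
    body = ",\n".join(chunks)
    path.write_text(header[:-1] + ',"frames":[\n' + body + "\n]}")


def _read_json2d(path: Path) -> Stream2D:
    try:
        raw = json.loads(Path(path).read_text())
        names = list(raw["keypoints"])
        frames = raw["frames"]
        n, k = len(frames), len(names)
        uv = np.full((n, k, 2), np.nan)
        conf = np.full((n, k), np.nan)
        miss = np.ones((n, k), dtype=bool)
        for f, rec in enumerate(frames):
            if not isinstance(rec, dict):
                raise FormatError(f"{path}: frame {f} is not an object")
            for j, name in enumerate(names):
                val = rec.get(name)
                if val is None:
                    continue
                if len(val) != 3:
                    raise FormatError(
                        f"{path}: frame {f} keypoint {name!r} needs [u, v, conf]"
                    )
                uv[f, j] = val[:2]
                conf[f, j] = val[2]
                miss[f, j] = False
        return Stream2D(
            str(raw["camera_id"]), float(raw["fps"]),
            (int(raw["resolution"][0]), int(raw["resolution"][1])),
            uv, conf, miss, tuple(names),
        )
    except FormatError:
        raise
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed json2d file {path}: {exc}") from exc


def _write_csv3d(stream: Stream3D, path: Path) -> None:
    # Long format: frame, keypoint, x_mm, y_mm, z_mm, confidence, missing.
    # Metadata rides in '#' comment lines so the file is self-contained.
    names = stream.keypoint_names
    has_conf = stream.confidence is not None
    lines = [
        f"# frame_rate={_float_str(stream.frame_rate)}",
        f"# coordinate_frame={stream.coordinate_frame}",
        f"# has_confidence={int(has_conf)}",
        "frame,keypoint,x_mm,y_mm,z_mm,confidence,missing",
    ]
    xyz = stream.xyz
    miss = stream.missing
    conf = stream.confidence
    for f in range(stream.n_frames):
        for k, name in enumerate(names):
            if miss[f, k]:
                lines.append(f"{f},{name},,,,,1")
            else:
                c = _float_str(conf[f, k]) if has_conf else ""
                lines.append(
                    f"{f},{name},{_float_str(xyz[f, k, 0])},"
                    f"{_float_str(xyz[f, k, 1])},{_float_str(xyz[f, k, 2])},{c},0"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_csv3d(path: Path) -> Stream3D:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(
                fh,
                dtype={"frame": int, "keypoint": str, "missing": int},
                float_precision="round_trip",
            )
        except (pd.errors.ParserError, ValueError) as exc:
            raise FormatError(f"malformed csv3d file {path}: {exc}") from exc
    try:
        frame_rate = float(meta["frame_rate"])
        coordinate_frame = meta["coordinate_frame"]
        has_conf = bool(int(meta.get("has_confidence", "1")))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"csv3d file {path} lacks metadata header: {exc}") from exc

    if df.empty:
        shape = (0, 13)
        return Stream3D(
            frame_rate, coordinate_frame, np.zeros(shape + (3,)),
            np.zeros(shape) if has_conf else None, np.zeros(shape, dtype=bool),
        )
    names = list(dict.fromkeys(df["keypoint"]))
    k = len(names)
    name_idx = {n: i for i, n in enumerate(names)}
    frames = df["frame"].to_numpy()
    n = int(frames.max()) + 1
    counts = np.bincount(frames, minlength=n)
    bad = np.nonzero(counts != k)[0]
    if bad.size:
        raise FormatError(
            f"{path}: frame {int(bad[0])} has {int(counts[bad[0]])} keypoints, "
            f"expected {k}"
        )
    kidx = df["keypoint"].map(name_idx).to_numpy()
    miss_col = df["missing"].to_numpy().astype(bool)
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    present_bad = ~miss_col & ~np.all(np.isfinite(coords), axis=1)
    if present_bad.any():
        row = int(np.nonzero(present_bad)[0][0])
        raise FormatError(
            f"{path}: row for frame {int(frames[row])} keypoint "
            f"{df['keypoint'].iloc[row]!r} has a missing coordinate field"
        )
    xyz = np.full((n, k, 3), np.nan)
    miss = np.ones((n, k), dtype=bool)
    xyz[frames, kidx] = coords
    miss[frames, kidx] = miss_col
    conf = None
    if has_conf:
        conf = np.full((n, k), np.nan)
        conf[frames, kidx] = df["confidence"].to_numpy(dtype=float)
    return Stream3D(frame_rate, coordinate_frame, xyz, conf, miss, tuple(names))
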