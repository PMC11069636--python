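"""Landmark frame container and file dialects.

A frame is the 21-point hand skeleton a pose-estimation detector emits for
one video frame: normalized image coordinates in [0, 1] x [0, 1] with the
y axis pointing down, indexed 0 = WRIST ... 20 = PINKY_TIP.  Two on-disk
dialects are supported:

* CSV — header ``subject_id,frame_idx,true_angle_deg,x0,y0,...,x20,y20``,
  one row per frame;
* JSON-lines — one object per frame with a 21-element ``points`` array.

Both are written with fixed 9-significant-digit formatting so identical
data produces identical bytes.  An optional adapter registry lets a live
detector backend feed frames through the same contract without making the
core package depend on it.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .exceptions import CapabilityError, FormatError, UsageError

__all__ = [
    "LANDMARK_NAMES",
    "landmark_index",
    "LandmarkFrame",
    "read_frames",
    "write_frames",
    "register_backend",
    "detector_adapter",
]

log = logging.getLogger(__name__)

#: The 21-point hand landmark enumeration (detector convention).
LANDMARK_NAMES: tuple[str, ...] = (
    "WRIST",
    "THUMB_CMC",
    "THUMB_MCP",
    "THUMB_IP",
    "THUMB_TIP",
    "INDEX_FINGER_MCP",
    "INDEX_FINGER_PIP",
    "INDEX_FINGER_DIP",
    "INDEX_FINGER_TIP",
    "MIDDLE_FINGER_MCP",
    "MIDDLE_FINGER_PIP",
    "MIDDLE_FINGER_DIP",
    "MIDDLE_FINGER_TIP",
    "RING_FINGER_MCP",
    "RING_FINGER_PIP",
    "RING_FINGER_DIP",
    "RING_FINGER_TIP",
    "PINKY_MCP",
    "PINKY_PIP",
    "PINKY_DIP",
    "PINKY_TIP",
)

_NAME_TO_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}

N_LANDMARKS = 21


def landmark_index(name: str) -> int:
    """Resolve a landmark name to its index 0-20."""
    try:
        return _NAME_TO_INDEX[name]
    except KeyError:
        raise UsageError(f"unknown landmark name {name!r}") from None


@dataclass(frozen=True)
class LandmarkFrame:
    """One frame's 21 2D landmark points plus metadata.

    Parameters
    ----------
    points : (21, 2) float array
        Normalized image coordinates, y down.
    subject_id : str
        Subject label.
    frame_idx : int
        Frame index within the recording.
    true_angle_deg : float or None
        Ground-truth rotation angle label; None for unlabeled inference.
    width, height : int or None
        Optional pixel dimensions.  When present, coordinates are
        de-normalized to isotropic units before angle/area features are
        computed; absent means square pixels are assumed.
    """

    points: np.ndarray
    subject_id: str = ""
    frame_idx: int = 0
    true_angle_deg: float | None = None
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise FormatError(
                f"a frame needs exactly {N_LANDMARKS} (x, y) points, "
                f"got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise FormatError("landmark coordinates must all be finite")
        object.__setattr__(self, "points", pts)

    def point(self, idx_or_name: int | str) -> np.ndarray:
        """A single landmark as a length-2 array, by index or name."""
        idx = idx_or_name if isinstance(idx_or_name, int) else landmark_index(idx_or_name)
        return self.points[idx]

    def isotropic_points(self) -> np.ndarray:
        """Points scaled to isotropic units using width/height when present.

        Normalized coordinates on a non-square image are anisotropic;
        multiplying each axis by its pixel dimension restores true aspect so
        angles and length ratios are undistorted.
        """
        if self.width is None or self.height is None:
            return self.points
        return self.points * np.array([float(self.width), float(self.height)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkFrame):
            return NotImplemented
        return (
            np.array_equal(self.points, other.points)
            and self.subject_id == other.subject_id
            and self.frame_idx == other.frame_idx
            and self.true_angle_deg == other.true_angle_deg
            and self.width == other.width
            and self.height == other.height
        )


_CSV_HEADER = "subject_id,frame_idx,true_angle_deg," + ",".join(
    f"x{i},y{i}" for i in range(N_LANDMARKS)
)


def _fmt(v: float) -> str:
    return f"{v:.9g}"


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


def _infer_dialect(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if ".csv" in suffixes:
        return "csv"
    if ".jsonl" in suffixes or ".json" in suffixes:
        return "jsonl"
    raise UsageError(
        f"cannot infer dialect from {path.name!r}; pass dialect='csv' or 'jsonl'"
    )


def write_frames(
    frames: Iterable[LandmarkFrame],
    path: str | Path,
    dialect: str | None = None,
) -> Path:
    """Write frames to ``path`` in the CSV or JSON-lines dialect.

    Column order and number formatting are fixed, so the same frames always
    produce byte-identical files.  An empty sequence yields a header-only
    CSV (or an empty JSON-lines file).
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in ("csv", "jsonl"):
        raise UsageError(f"unknown dialect {dialect!r} (expected 'csv' or 'jsonl')")
    with _open_text(path, "w") as fh:
        if dialect == "csv":
            fh.write(_CSV_HEADER + "\n")
            for fr in frames:
                label = "" if fr.true_angle_deg is None else _fmt(fr.true_angle_deg)
                coords = ",".join(_fmt(v) for v in fr.points.ravel())
                fh.write(f"{fr.subject_id},{fr.frame_idx},{label},{coords}\n")
        else:
            for fr in frames:
                obj = {
                    "subject_id": fr.subject_id,
                    "frame_idx": fr.frame_idx,
                    "true_angle_deg": None
                    if fr.true_angle_deg is None
                    else float(_fmt(fr.true_angle_deg)),
                    "points": [
                        [float(_fmt(x)), float(_fmt(y))] for x, y in fr.points
                    ],
                }
                if fr.width is not None and fr.height is not None:
                    obj["width"] = fr.width
                    obj["height"] = fr.height
                fh.write(json.dumps(obj, separators=(",", ":")) + "\n")
    return path


def _parse_csv_row(line: str, lineno: int) -> LandmarkFrame:
    fields = line.rstrip("\n").split(",")
    expected = 3 + 2 * N_LANDMARKS
    if len(fields) != expected:
        raise FormatError(
            f"row {lineno}: expected {expected} columns "
            f"({N_LANDMARKS} landmark pairs), got {len(fields)}"
        )
    subject_id, frame_idx_s, label_s = fields[:3]
    try:
        coords = np.array([float(v) for v in fields[3:]], dtype=float)
        frame_idx = int(frame_idx_s)
        label = None if label_s == "" else float(label_s)
    except ValueError as exc:
        raise FormatError(f"row {lineno}: {exc}") from None
    try:
        return LandmarkFrame(
            points=coords.reshape(N_LANDMARKS, 2),
            subject_id=subject_id,
            frame_idx=frame_idx,
            true_angle_deg=label,
        )
    except FormatError as exc:
        raise FormatError(f"row {lineno}: {exc}") from None


def read_frames(path: str | Path, dialect: str | None = None) -> list[LandmarkFrame]:
    """Read frames from a CSV or JSON-lines landmark file, in file order.

    Malformed rows raise :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    frames: list[LandmarkFrame] = []
    with _open_text(path, "r") as fh:
        if dialect == "csv":
            header = fh.readline().rstrip("\n")
            if header != _CSV_HEADER:
                raise FormatError(
                    f"{path.name}: CSV header does not match the landmark "
                    f"dialect (expected {_CSV_HEADER.split(',')[:4]}...)"
                )
            for lineno, line in enumerate(fh, start=2):
                if line.strip() == "":
                    continue
                frames.append(_parse_csv_row(line, lineno))
        elif dialect == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                if line.strip() == "":
                    continue
                try:
                    obj = json.loads(line)
                    frames.append(
                        LandmarkFrame(
                            points=np.array(obj["points"], dtype=float),
                            subject_id=str(obj.get("subject_id", "")),
                            frame_idx=int(obj.get("frame_idx", 0)),
                            true_angle_deg=obj.get("true_angle_deg"),
                            width=obj.get("width"),
                            height=obj.get("height"),
                        )
                    )
                except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
                    raise FormatError(f"line {lineno}: {exc}") from None
        else:
            raise UsageError(f"unknown dialect {dialect!r} (expected 'csv' or 'jsonl')")
    return frames


# --- optional detector backend -------------------------------------------

_BACKENDS: dict[str, Callable[..., Iterable]] = {}


def register_backend(name: str, fn: Callable[..., Iterable]) -> None:
    """Register a pose-estimation backend callable.

    The callable takes an image source and yields per-frame landmark arrays
    (or None where no hand was detected).  Real detectors also emit a z
    coordinate; it is discarded because the angle features use x and y only.
    """
    _BACKENDS[name] = fn


def detector_adapter(
    source,
    backend: str = "mediapipe",
    subject_id: str = "",
) -> Iterator[LandmarkFrame]:
    """Run a registered pose-estimation backend over an image source.

    Yields frames in the :class:`LandmarkFrame` contract.  Frames where the
    backend detected no hand are skipped with a logged warning.  A missing
    backend raises :class:`CapabilityError`; the core package works without
    any backend installed.
    """
    if backend not in _BACKENDS:
        raise CapabilityError(
            f"pose-estimation backend {backend!r} is not registered; install "
            f"the optional detector extra (e.g. 'pip install thumbrot[{backend}]') "
            "and register it with thumbrot.landmark_io.register_backend"
        )
    fn = _BACKENDS[backend]
    for idx, raw in enumerate(fn(source)):
        if raw is None:
            log.warning("frame %d: no hand detected, skipping", idx)
            continue
        pts = np.asarray(raw, dtype=float)
        if pts.ndim != 2 or pts.shape[0] != N_LANDMARKS:
            raise FormatError(
                f"backend {backend!r} returned {pts.shape[0] if pts.ndim == 2 else '?'} "
                f"points for frame {idx}; the landmark contract requires {N_LANDMARKS}"
            )
        yield LandmarkFrame(points=pts[:, :2], subject_id=subject_id, frame_idx=idx)
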