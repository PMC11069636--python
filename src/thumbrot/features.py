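"""Geometric predictors computed from one landmark frame.

Nine scale-free quantities describe the thumb's configuration relative to
the palm: three interior angles at the thumb CMC, three distances from the
index MCP to the thumb joints normalized by the index-finger length
(MCP-to-tip segment), and three parallelogram areas normalized by that
length squared.  Because every predictor is an angle, a length ratio, or an
area ratio, all nine are invariant under similarity transforms of the image
(translation, rotation, uniform scaling) — the property that makes them
usable across camera distances and hand sizes.

Landmark indices follow the 21-point scheme; the reference segment is
INDEX_FINGER_MCP (5) to INDEX_FINGER_TIP (8).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, UsageError
from .landmark_io import LandmarkFrame

__all__ = [
    "FEATURE_COLUMNS",
    "PREDICTOR_COLUMNS",
    "angle_at",
    "normalized_distance",
    "normalized_area",
    "compute_features",
    "feature_table",
]

log = logging.getLogger(__name__)

#: Feature-table column order: label first, then the nine predictors.
FEATURE_COLUMNS: tuple[str, ...] = (
    "true_angle",
    "tip_angle",
    "mp_angle",
    "palm_angle",
    "norm_tip_distance",
    "norm_ip_distance",
    "norm_mp_distance",
    "norm_tip_size",
    "norm_mp_size",
    "norm_palm_size",
)

PREDICTOR_COLUMNS: tuple[str, ...] = FEATURE_COLUMNS[1:]

_REF_A, _REF_B = 5, 8  # index MCP -> index tip, the normalization segment


def angle_at(vertex: Sequence[float], p: Sequence[float], q: Sequence[float]) -> float:
    """Interior angle p-vertex-q in degrees, in [0, 180].

    Raises :class:`DegenerateGeometryError` when either ray has zero length.
    """
    v = np.asarray(vertex, float)
    a = np.asarray(p, float) - v
    b = np.asarray(q, float) - v
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateGeometryError(
            "angle undefined: a ray endpoint coincides with the vertex"
        )
    cosang = float(np.dot(a, b) / (na * nb))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def _reference_length(pts: np.ndarray) -> float:
    ref = float(np.linalg.norm(pts[_REF_A] - pts[_REF_B]))
    if ref < 1e-12:
        raise DegenerateGeometryError(
            f"zero-length reference segment ({_REF_A})-({_REF_B})"
        )
    return ref


def normalized_distance(a: int, b: int, frame: LandmarkFrame) -> float:
    """Distance between landmarks a and b divided by the reference length.

    The reference is the index-finger segment (5)-(8), so the ratio is
    invariant to image scale.
    """
    pts = frame.isotropic_points()
    return float(np.linalg.norm(pts[a] - pts[b])) / _reference_length(pts)


def normalized_area(
    u_from: int, u_to: int, v_from: int, v_to: int, frame: LandmarkFrame, *, signed: bool = False
) -> float:
    """Parallelogram area |u x v| divided by the squared reference length.

    ``u`` and ``v`` are the 2D vectors between the given landmark indices;
    the scalar cross product is their determinant.  The absolute value is
    taken by default (the quantities are areas); ``signed=True`` exposes the
    raw determinant for experimentation.
    """
    pts = frame.isotropic_points()
    u = pts[u_to] - pts[u_from]
    v = pts[v_to] - pts[v_from]
    cross = float(u[0] * v[1] - u[1] * v[0])
    ref = _reference_length(pts)
    val = cross / (ref * ref)
    return val if signed else abs(val)


def compute_features(frame: LandmarkFrame, *, signed_areas: bool = False) -> dict[str, float]:
    """The nine predictors (plus the label when present) for one frame.

    Definitions, by landmark index:

    ==================  =================================================
    tip_angle           angle (4)-(1)-(5)
    mp_angle            angle (2)-(1)-(5)
    palm_angle          angle (5)-(1)-(17)
    norm_tip_distance   |(5)(4)| / |(5)(8)|
    norm_ip_distance    |(5)(3)| / |(5)(8)|
    norm_mp_distance    |(5)(2)| / |(5)(8)|
    norm_tip_size       |(1->4) x (1->5)| / |(5)(8)|^2
    norm_mp_size        |(1->2) x (1->5)| / |(5)(8)|^2
    norm_palm_size      |(1->5) x (1->17)| / |(5)(8)|^2
    ==================  =================================================

    Raises :class:`DegenerateGeometryError` naming the feature whose
    sub-computation is undefined.
    """
    pts = frame.isotropic_points()
    out: dict[str, float] = {}
    if frame.true_angle_deg is not None:
        out["true_angle"] = float(frame.true_angle_deg)

    angle_defs = {
        "tip_angle": (1, 4, 5),
        "mp_angle": (1, 2, 5),
        "palm_angle": (1, 5, 17),
    }
    dist_defs = {
        "norm_tip_distance": (5, 4),
        "norm_ip_distance": (5, 3),
        "norm_mp_distance": (5, 2),
    }
    area_defs = {
        "norm_tip_size": (1, 4, 1, 5),
        "norm_mp_size": (1, 2, 1, 5),
        "norm_palm_size": (1, 5, 1, 17),
    }
    try:
        for name, (vtx, p, q) in angle_defs.items():
            out[name] = angle_at(pts[vtx], pts[p], pts[q])
        for name, (a, b) in dist_defs.items():
            out[name] = normalized_distance(a, b, frame)
        for name, args in area_defs.items():
            out[name] = normalized_area(*args, frame, signed=signed_areas)
    except DegenerateGeometryError as exc:
        raise DegenerateGeometryError(f"{name}: {exc}") from None
    return out


def feature_table(
    frames: Iterable[LandmarkFrame],
    *,
    signed_areas: bool = False,
    include_subject: bool = False,
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Feature matrix for a sequence of frames, plus a skip report.

    Returns a DataFrame with one row per valid frame (input order
    preserved) and a list of ``(position, reason)`` pairs for frames whose
    geometry was degenerate — those are skipped with a logged warning
    rather than failing the batch, since real detector streams glitch.

    Labels must be all present or all absent; mixing raises
    :class:`UsageError`.  ``include_subject`` adds a ``subject_id`` column
    (useful for grouped splits); it is never part of the predictor set.
    """
    rows: list[dict] = []
    skipped: list[tuple[int, str]] = []
    labelled: bool | None = None
    for pos, frame in enumerate(frames):
        has_label = frame.true_angle_deg is not None
        if labelled is None:
            labelled = has_label
        elif has_label != labelled:
            raise UsageError(
                "mixed labelled and unlabelled frames in one batch "
                f"(frame at position {pos})"
            )
        try:
            feats = compute_features(frame, signed_areas=signed_areas)
        except DegenerateGeometryError as exc:
            log.warning("skipping frame at position %d: %s", pos, exc)
            skipped.append((pos, str(exc)))
            continue
        if include_subject:
            feats["subject_id"] = frame.subject_id
        rows.append(feats)

    cols = list(FEATURE_COLUMNS) if (labelled or labelled is None) else list(PREDICTOR_COLUMNS)
    if include_subject:
        cols.append("subject_id")
    table = pd.DataFrame(rows, columns=cols)
    return table, skipped
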