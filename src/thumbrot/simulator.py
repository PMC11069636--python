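"""Synthetic hand-landmark generator emulating the study design.

The recording protocol it reproduces: 15 subjects hold 10 thumb rotation
angles (0-90 deg in 10 deg steps) while a camera films the hand at 30 fps
for 2 s, giving 15 x 10 x 60 = 9000 frames.  A guide device keeps the thumb
IP joint 3 cm from the index MCP joint at every angle.

Generation is three stages, each usable on its own:

1. :func:`pose_hand` — place a canonical 3D hand skeleton (21 landmarks) at
   a requested rotation angle: the thumb chain CMC-MCP-IP-TIP stays
   collinear on the ray from the CMC through the cone position of the IP
   joint; everything else is rigid.
2. :func:`project` — a pinhole (or weak-perspective) camera mapping the 3D
   landmarks to normalized image coordinates, y down.
3. :func:`generate_dataset` — the full subjects x angles x frames sweep,
   with per-subject hand-size variation and i.i.d. Gaussian landmark jitter
   emulating detector error.

All randomness flows from the seed in :class:`DatasetSpec`; identical seeds
give byte-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError, ProjectionError
from .kinematics import ConeCoordinate, SkeletonConfig, ip_position
from .landmark_io import LandmarkFrame

__all__ = [
    "HandTemplate",
    "CameraSpec",
    "DatasetSpec",
    "pose_hand",
    "project",
    "recover_theta",
    "generate_dataset",
]


def _base_points(B: float) -> np.ndarray:
    """Canonical landmark positions (cm, scale 1) for a flat right hand.

    Hand frame: x = palmar-plane normal, y = along the second metacarpal
    from the rotation centre toward the index MCP, z = in-palm radial
    (thumb-side) direction.  All non-thumb landmarks lie in the palmar
    plane x = 0; the thumb chain entries are placeholders overwritten by
    :func:`pose_hand`.  Segment lengths are anthropometrically plausible
    round numbers, not measured from any subject.
    """
    p = np.zeros((21, 3))
    p[0] = (0.0, -2.0, -0.5)        # WRIST
    p[1] = (0.0, 1.5, 2.5)          # THUMB_CMC (fixed at the palm edge)
    # 2,3,4 thumb chain: set per pose
    p[5] = (0.0, B, 0.0)            # INDEX_FINGER_MCP, on the base axis
    p[6] = (0.0, B + 4.5, 0.0)
    p[7] = (0.0, B + 7.0, 0.0)
    p[8] = (0.0, B + 9.2, 0.0)      # INDEX_FINGER_TIP
    p[9] = (0.0, B - 0.2, -2.2)     # MIDDLE_FINGER_MCP
    p[10] = (0.0, B + 4.6, -2.4)
    p[11] = (0.0, B + 7.4, -2.5)
    p[12] = (0.0, B + 9.8, -2.6)
    p[13] = (0.0, B - 0.6, -4.2)    # RING_FINGER_MCP
    p[14] = (0.0, B + 3.8, -4.5)
    p[15] = (0.0, B + 6.3, -4.7)
    p[16] = (0.0, B + 8.4, -4.9)
    p[17] = (0.0, B - 1.2, -6.0)    # PINKY_MCP
    p[18] = (0.0, B + 2.4, -6.3)
    p[19] = (0.0, B + 4.4, -6.5)
    p[20] = (0.0, B + 6.1, -6.7)
    return p


@dataclass(frozen=True)
class HandTemplate:
    """Canonical 3D landmark positions plus a per-subject size factor.

    ``points`` holds the scale-1 positions in the hand frame; ``scale``
    multiplies every length (including the effective cone radius, since a
    larger hand wears the guide device further out).  The thumb MCP sits a
    fixed fraction of the way from the CMC to the IP joint, and the tip
    extends a fixed distance beyond the IP, keeping the chain collinear.
    """

    points: np.ndarray
    scale: float = 1.0
    thumb_mcp_fraction: float = 0.55
    thumb_tip_extension: float = 2.8

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (21, 3):
            raise DomainError(f"template needs 21 3D points, got shape {pts.shape}")
        if not (self.scale > 0.0):
            raise DomainError(f"scale must be positive, got {self.scale!r}")
        if not (0.0 < self.thumb_mcp_fraction < 1.0):
            raise DomainError("thumb_mcp_fraction must lie in (0, 1)")
        object.__setattr__(self, "points", pts)
        # The palmar plane must be spanned non-degenerately.
        w, i_mcp, p_mcp = pts[0], pts[5], pts[17]
        n = np.cross(i_mcp - w, p_mcp - w)
        if np.linalg.norm(n) < 1e-9:
            raise DomainError("wrist, index MCP and pinky MCP are collinear")

    @classmethod
    def default(cls, skel: SkeletonConfig | None = None, scale: float = 1.0) -> "HandTemplate":
        skel = skel or SkeletonConfig()
        return cls(points=_base_points(skel.B), scale=scale)


def pose_hand(
    template: HandTemplate,
    theta_deg: float,
    skel: SkeletonConfig | None = None,
) -> np.ndarray:
    """3D landmark set (21, 3) for the hand posed at rotation angle theta.

    The thumb IP joint is placed on the cone: at distance
    ``r_default * scale`` from the index MCP, rotated ``theta`` from the
    palmar plane about the base axis.  CMC, MCP, IP and TIP stay collinear
    on the ray from the CMC through the IP position; all other landmarks
    are the (scaled) template.
    """
    skel = skel or SkeletonConfig()
    if not (0.0 <= theta_deg <= 180.0):
        raise DomainError(f"theta must lie in [0, 180] degrees, got {theta_deg!r}")
    s = template.scale
    pts = template.points * s
    r_s = skel.r_default * s
    t = math.radians(theta_deg)
    # Cone circle centred on the base axis at the index MCP: matches the
    # (r sin, B, r cos) coordinates when the index MCP sits at (0, B, 0).
    p5 = pts[5]
    ip = p5 + r_s * np.array([math.sin(t), 0.0, math.cos(t)])
    cmc = pts[1]
    ray = ip - cmc
    length = np.linalg.norm(ray)
    if length < 1e-9:
        raise DomainError("degenerate pose: IP coincides with the CMC joint")
    d = ray / length
    pts[2] = cmc + template.thumb_mcp_fraction * length * d
    pts[3] = ip
    pts[4] = cmc + (length + template.thumb_tip_extension * s) * d
    return pts


def recover_theta(landmarks3d: np.ndarray) -> float:
    """Rotation angle (degrees) read back from a posed 3D hand.

    Measures the IP joint's position about the base axis relative to the
    index MCP: atan2(out-of-palm component, in-palm component).
    """
    v = np.asarray(landmarks3d, dtype=float)[3] - np.asarray(landmarks3d, dtype=float)[5]
    return math.degrees(math.atan2(v[0], v[2]))


# --- camera ---------------------------------------------------------------

# Default pose emulating the recording geometry: the device sits ~50 cm
# above and ~1 m out from the hand.  The hand rests thumb-up with the palm
# nearly side-on to the camera (mid-forearm rotation), so raising the thumb
# out of the palm swings it toward the camera's image plane rather than
# along the optical axis.
_DEFAULT_CAMERA_POSITION = (30.0, 100.0, 45.0)
_DEFAULT_LOOK_AT = (0.0, 6.0, 0.0)
_DEFAULT_UP = (0.3, 0.0, 1.0)


@dataclass(frozen=True)
class CameraSpec:
    """Pinhole / weak-perspective camera, expressed in the hand frame.

    ``position`` and ``look_at`` are cm; ``up`` is the world-up hint fixing
    image roll; ``focal_scale`` converts camera-plane tangents to
    normalized image units; ``mode`` selects true perspective division or
    the weak-perspective (single mean depth) approximation used as the
    analytically tractable limit in tests.
    """

    position: tuple[float, float, float] = _DEFAULT_CAMERA_POSITION
    look_at: tuple[float, float, float] = _DEFAULT_LOOK_AT
    up: tuple[float, float, float] = _DEFAULT_UP
    focal_scale: float = 3.0
    mode: str = "perspective"

    def __post_init__(self) -> None:
        if self.mode not in ("perspective", "weak_perspective"):
            raise DomainError(f"unknown camera mode {self.mode!r}")
        if not (self.focal_scale > 0.0):
            raise DomainError("focal_scale must be positive")
        fwd = np.asarray(self.look_at, float) - np.asarray(self.position, float)
        if np.linalg.norm(fwd) < 1e-9:
            raise DomainError("camera position coincides with its look-at point")
        if np.linalg.norm(np.cross(fwd, np.asarray(self.up, float))) < 1e-9:
            raise DomainError("camera up vector is parallel to the view direction")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, down, forward) orthonormal camera axes in the hand frame."""
        fwd = np.asarray(self.look_at, float) - np.asarray(self.position, float)
        fwd = fwd / np.linalg.norm(fwd)
        up = np.asarray(self.up, float)
        right = np.cross(up, fwd)
        right = right / np.linalg.norm(right)
        down = np.cross(right, fwd)
        return right, down, fwd


def project(landmarks3d: np.ndarray, camera: CameraSpec | None = None) -> np.ndarray:
    """Project 3D landmarks to normalized 2D image coordinates (21, 2).

    Image origin top-left, y down, principal point at (0.5, 0.5).  In
    perspective mode each point is divided by its own depth; in
    weak-perspective mode all points share the mean depth, making the map
    an orthographic projection plus a global scale.

    Raises
    ------
    ProjectionError
        If any point lies at or behind the camera plane.
    """
    camera = camera or CameraSpec()
    pts = np.asarray(landmarks3d, dtype=float)
    right, down, fwd = camera.axes()
    rel = pts - np.asarray(camera.position, float)
    x = rel @ right
    y = rel @ down
    z = rel @ fwd
    if np.any(z <= 1e-9):
        raise ProjectionError("point at or behind the camera plane")
    depth = np.full_like(z, z.mean()) if camera.mode == "weak_perspective" else z
    u = 0.5 + camera.focal_scale * x / depth
    v = 0.5 + camera.focal_scale * y / depth
    return np.column_stack([u, v])


# --- dataset sweep --------------------------------------------------------


@dataclass(frozen=True)
class DatasetSpec:
    """The subjects x angles x frames study design.

    Defaults reproduce the recording protocol: 15 subjects, angles 0-90 deg
    in 10 deg steps, 30 fps for 2 s (60 frames per condition), 9000 frames
    in total.  ``noise_sd`` is the landmark jitter SD in normalized image
    units; 0 gives exact geometry.  Per-subject hand size is drawn once per
    subject from uniform(scale_range).
    """

    n_subjects: int = 15
    angle_grid: tuple[float, ...] = tuple(float(a) for a in range(0, 91, 10))
    fps: float = 30.0
    duration_s: float = 2.0
    noise_sd: float = 0.005
    seed: int = 0
    scale_range: tuple[float, float] = (0.85, 1.15)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise DomainError("need at least one subject")
        if len(self.angle_grid) == 0:
            raise DomainError("angle grid must be non-empty")
        for a in self.angle_grid:
            if not (0.0 <= a <= 90.0):
                raise DomainError(f"protocol angles lie in [0, 90] degrees, got {a!r}")
        n = self.fps * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise DomainError(
                f"fps * duration_s must be a positive integer frame count, got {n!r}"
            )
        if self.noise_sd < 0.0:
            raise DomainError("noise_sd must be non-negative")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi):
            raise DomainError(f"invalid scale range {self.scale_range!r}")

    @property
    def frames_per_condition(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def n_frames(self) -> int:
        return self.n_subjects * len(self.angle_grid) * self.frames_per_condition


def generate_dataset(
    spec: DatasetSpec | None = None,
    template: HandTemplate | None = None,
    camera: CameraSpec | None = None,
    skel: SkeletonConfig | None = None,
) -> list[LandmarkFrame]:
    """Generate the full synthetic sweep as labelled landmark frames.

    One hand-size scale is drawn per subject; every frame gets independent
    isotropic Gaussian jitter of SD ``spec.noise_sd`` added to the
    projected coordinates.  Frames are ordered subject-major, then angle,
    then frame index; ``frame_idx`` counts frames within a subject.  The
    same spec (including seed) always yields the same frames.
    """
    spec = spec or DatasetSpec()
    skel = skel or SkeletonConfig()
    camera = camera or CameraSpec()
    base = template or HandTemplate.default(skel)
    rng = np.random.default_rng(spec.seed)
    scales = rng.uniform(*spec.scale_range, size=spec.n_subjects)
    frames: list[LandmarkFrame] = []
    npc = spec.frames_per_condition
    for si in range(spec.n_subjects):
        subj = f"S{si + 1:02d}"
        tmpl = replace(base, scale=base.scale * scales[si])
        fidx = 0
        for angle in spec.angle_grid:
            pose3d = pose_hand(tmpl, angle, skel)
            clean2d = project(pose3d, camera)
            for _ in range(npc):
                pts = clean2d
                if spec.noise_sd > 0.0:
                    pts = pts + rng.normal(0.0, spec.noise_sd, size=(21, 2))
                frames.append(
                    LandmarkFrame(
                        points=pts,
                        subject_id=subj,
                        frame_idx=fidx,
                        true_angle_deg=float(angle),
                    )
                )
                fidx += 1
    return frames
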