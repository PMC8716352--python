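"""Synthetic CBCT phantom, ground truth and needle-outcome simulation.

This module stands in for the physical experiment: it renders a CBCT-like
volume of an abdominal phantom containing a calibration tool (a plastic
slab with four hollow, air-density spheres at pairwise-unique distances)
and spherical target lesions, and it simulates the stochastic outcome of
manually-inserted, robot-guided needle placements.

World frame is LPS in millimetres.  Voxel indices are 0-based and map to
world coordinates as ``world = origin + direction @ (index * spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "ToolModel",
    "VolumeGrid",
    "GroundTruth",
    "NeedleOutcome",
    "NeedleNoise",
    "RenderConfig",
    "make_tool_model",
    "default_lesions",
    "render_phantom_volume",
    "simulate_needle_outcome",
    "simulate_study",
    "SCAN_META_DEFAULT",
]

# C-arm acquisition protocol of the study, carried as inert metadata only.
SCAN_META_DEFAULT = {
    "rotation_deg": 200.0,
    "deg_per_frame": 0.5,
    "n_projections": 397,
    "scan_time_s": 6.0,
}

# Shipped default fiducial geometry (tool frame, mm).  Chosen so that all
# six pairwise distances are mutually separated by > 5 mm (the property
# that makes correspondence-free matching unambiguous) while the point
# cloud fits a 192-voxel / 0.48 mm scan volume with margin under any pose.
DEFAULT_FIDUCIALS = np.array(
    [
        [-27.0, 8.0, 11.0],
        [16.0, 8.0, -4.0],
        [24.0, -29.0, -4.0],
        [-13.0, 13.0, -4.0],
    ]
)


@dataclass(frozen=True)
class ToolModel:
    """Calibration-tool geometry: four hollow spheres in the tool frame.

    The spheres sit at pairwise-unique distances so that the detected
    blobs can be matched to the model without prior correspondence.
    """

    fiducials: np.ndarray  # (4, 3) mm, tool frame
    sphere_radius: float = 4.0  # mm
    bounding_box: tuple[float, float, float] = (200.0, 75.0, 30.0)  # mm
    min_signature_gap: float = 5.0  # mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.fiducials, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "fiducials", pts)
        if pts.shape[0] != 4:
            raise ValueError(f"tool model requires exactly 4 fiducials, got {pts.shape[0]}")
        half = np.asarray(self.bounding_box, float) / 2.0
        if np.any(np.abs(pts) > half + 1e-12):
            raise ValueError("fiducials fall outside the tool bounding box")
        gap = self.signature_gap()
        if gap <= 0.0:
            raise ValueError(
                "pairwise distances are not mutually distinct "
                "(achieved signature gap 0.000 mm)"
            )
        if gap < self.min_signature_gap:
            raise ValueError(
                "pairwise distances are not unique enough: achieved minimum "
                f"signature gap {gap:.3f} mm < required {self.min_signature_gap:.3f} mm"
            )

    def signature(self) -> np.ndarray:
        """All six pairwise distances, ascending (mm)."""
        d = [np.linalg.norm(self.fiducials[i] - self.fiducials[j])
             for i, j in combinations(range(4), 2)]
        return np.sort(np.asarray(d))

    def signature_gap(self) -> float:
        """Minimum |d_i - d_j| over all pairs of pairwise distances (mm)."""
        s = self.signature()
        return float(min(abs(a - b) for a, b in combinations(s, 2)))


def make_tool_model(
    bounding_box: tuple[float, float, float] = (200.0, 75.0, 30.0),
    sphere_radius: float = 4.0,
    min_signature_gap: float = 5.0,
    seed: int | None = None,
    spread: tuple[float, float, float] = (60.0, 44.0, 24.0),
    max_attempts: int = 20000,
) -> ToolModel:
    """Build a calibration-tool model.

    Without ``seed`` the fixed shipped geometry is returned, so every
    downstream computation is deterministic.  With a ``seed`` a randomized
    point set is searched for inside ``spread`` (a sub-box of the tool
    kept small enough to fit the default scan volume).

    Raises
    ------
    ValueError
        If no pairwise-unique configuration with the requested gap is
        found; the message reports the best gap achieved.
    """
    if np.any(np.asarray(bounding_box) <= 0):
        raise ValueError("bounding box extents must be positive")
    if seed is None:
        return ToolModel(
            DEFAULT_FIDUCIALS.copy(),
            sphere_radius=sphere_radius,
            bounding_box=bounding_box,
            min_signature_gap=min_signature_gap,
        )
    rng = np.random.default_rng(seed)
    half = np.minimum(np.asarray(spread, float), np.asarray(bounding_box, float)) / 2.0
    best_gap = -np.inf
    for _ in range(max_attempts):
        pts = rng.uniform(-half, half, size=(4, 3))
        d = np.sort([np.linalg.norm(pts[i] - pts[j]) for i, j in combinations(range(4), 2)])
        if d[0] < 4.0 * sphere_radius:  # spheres must not touch
            continue
        gap = float(np.min(np.diff(d)))
        best_gap = max(best_gap, gap)
        if gap >= min_signature_gap:
            return ToolModel(pts, sphere_radius, bounding_box, min_signature_gap)
    raise ValueError(
        f"could not place 4 fiducials with signature gap >= {min_signature_gap} mm "
        f"in the box; best achieved gap was {best_gap:.3f} mm"
    )


@dataclass
class VolumeGrid:
    """3-D scalar image with geometry (the CBCT stand-in).

    ``world = origin + direction @ (index * spacing)`` with 0-based
    indices; ``direction`` columns are the world directions of the three
    index axes.
    """

    voxels: np.ndarray  # (nx, ny, nz), HU-like intensities
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 0.48))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.direction = np.asarray(self.direction, float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=1e-9):
            raise ValueError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Continuous voxel index (…, 3) to world mm."""
        idx = np.asarray(index, float)
        return idx * self.spacing @ self.direction.T + self.origin

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """World mm to continuous voxel index."""
        w = np.asarray(world, float)
        return (w - self.origin) @ self.direction / self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of the voxel-center lattice."""
        corners_idx = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)], float)
        corners = self.index_to_world(corners_idx)
        return corners.min(axis=0), corners.max(axis=0)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the renderer knows about the scene, in world mm."""

    tool_pose: RigidTransform  # tool frame -> image world
    fiducial_centers_world: np.ndarray  # (4, 3) mm
    lesions: tuple[tuple[tuple[float, float, float], float], ...]  # (center, radius)
    scan_meta: dict = field(default_factory=lambda: dict(SCAN_META_DEFAULT))


@dataclass(frozen=True)
class RenderConfig:
    """Rendering levels and volume geometry.

    Intensity levels are HU-like: water-equivalent background 40, plastic
    slab 100, hollow (air) spheres -1000; lesions mildly hyperdense by
    default.  The default 192³ grid at 0.48 mm spans a ~92 mm cube; the
    full 512³ field of view is available by changing ``shape``.
    """

    shape: tuple[int, int, int] = (192, 192, 192)
    spacing: float = 0.48  # mm, isotropic
    background_level: float = 40.0
    slab_level: float = 100.0
    sphere_level: float = -1000.0
    lesion_level: float = 120.0
    origin: tuple[float, float, float] | None = None  # None: center on tool
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))


def default_lesions(n: int = 8, radius: float = 5.0) -> list[tuple[np.ndarray, float]]:
    """Fixed grid of spherical target lesions (world mm, radius mm).

    Two craniocaudal levels of four lesions each, in the posterior half
    of the field of view, emulating the liver-lesion layout of an
    abdominal phantom.
    """
    if n != 8:
        raise ValueError("the study layout defines exactly 8 lesions")
    centers = [
        np.array([x, 30.0, z])
        for z in (-18.0, 18.0)
        for x in (-27.0, -9.0, 9.0, 27.0)
    ]
    return [(c, radius) for c in centers]


def _paint_sphere(volume: VolumeGrid, center_world: np.ndarray, radius: float,
                  level: float) -> None:
    """Set voxels inside a sphere, with linear partial-volume edge blending."""
    edge = float(np.max(volume.spacing))
    r = radius + 2 * edge
    corners = center_world + r * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], float)
    idx_corners = volume.world_to_index(corners)
    lo = np.maximum(np.floor(idx_corners.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(idx_corners.max(axis=0)).astype(int) + 1, volume.shape)
    if np.any(hi <= lo):
        return
    ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(float)
    w = volume.index_to_world(idx)
    dist = np.linalg.norm(w - center_world, axis=-1)
    frac = np.clip((radius - dist) / edge + 0.5, 0.0, 1.0)  # coverage fraction
    sub = volume.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[...] = sub + frac * (level - sub)


def _check_sphere_inside(volume: VolumeGrid, center: np.ndarray, radius: float,
                         what: str) -> None:
    lo, hi = volume.world_bounds()
    if np.any(center - radius < lo) or np.any(center + radius > hi):
        raise ValueError(
            f"{what} at {np.round(center, 2).tolist()} (r={radius} mm) would be "
            "clipped by the volume boundary"
        )


def render_phantom_volume(
    tool_model: ToolModel,
    tool_pose: RigidTransform | None = None,
    lesions: Sequence[tuple[np.ndarray, float]] | None = None,
    noise_sd: float = 0.0,
    config: RenderConfig | None = None,
    seed: int | None = None,
) -> tuple[VolumeGrid, GroundTruth]:
    """Render the phantom scene into a scalar volume with ground truth.

    The calibration tool (slab + four air spheres) is placed at
    ``tool_pose`` (tool frame -> image world).  When ``config.origin`` is
    None the volume is centred on the posed fiducial centroid, mimicking
    a scan volume positioned over the tool.  Additive white Gaussian
    noise of standard deviation ``noise_sd`` is applied when positive.

    Raises
    ------
    ValueError
        If any fiducial or lesion sphere would be clipped by the volume.
    """
    pose = RigidTransform.identity() if tool_pose is None else tool_pose
    cfg = config if config is not None else RenderConfig()
    lesions = list(lesions) if lesions is not None else []

    centers_world = pose.apply(tool_model.fiducials)
    if cfg.origin is not None:
        origin = np.asarray(cfg.origin, float)
    else:
        extent = (np.asarray(cfg.shape, float) - 1.0) * cfg.spacing
        origin = centers_world.mean(axis=0) - np.asarray(cfg.direction) @ (extent / 2.0)

    vol = VolumeGrid(
        voxels=np.full(cfg.shape, cfg.background_level, dtype=np.float32),
        spacing=np.full(3, cfg.spacing),
        origin=origin,
        direction=np.asarray(cfg.direction, float),
    )

    for c in centers_world:
        _check_sphere_inside(vol, c, tool_model.sphere_radius, "fiducial sphere")
    for c, r in lesions:
        _check_sphere_inside(vol, np.asarray(c, float), r, "lesion")

    # Slab: the tool's bounding box, rasterised by mapping every voxel
    # into the tool frame (linear in index, so three broadcast terms).
    inv = pose.inverse()
    A = inv.rotation @ vol.direction * cfg.spacing  # maps index -> tool frame
    b = inv.rotation @ vol.origin + inv.translation
    axes = [np.arange(n, dtype=np.float32) for n in cfg.shape]
    half_box = np.asarray(tool_model.bounding_box, float) / 2.0
    inside = np.ones(cfg.shape, dtype=bool)
    for k in range(3):
        qk = (A[k, 0] * axes[0][:, None, None]
              + A[k, 1] * axes[1][None, :, None]
              + A[k, 2] * axes[2][None, None, :] + b[k])
        inside &= np.abs(qk) <= half_box[k]
    vol.voxels[inside] = cfg.slab_level

    for c in centers_world:
        _paint_sphere(vol, c, tool_model.sphere_radius, cfg.sphere_level)
    for c, r in lesions:
        _paint_sphere(vol, np.asarray(c, float), float(r), cfg.lesion_level)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol.voxels += noise_sd * rng.standard_normal(size=cfg.shape, dtype=np.float32)

    truth = GroundTruth(
        tool_pose=pose,
        fiducial_centers_world=centers_world,
        lesions=tuple((tuple(np.asarray(c, float)), float(r)) for c, r in lesions),
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Needle-outcome simulation
# ---------------------------------------------------------------------------

GroupLabel = Literal["in_plane", "out_of_plane"]


@dataclass(frozen=True)
class NeedleNoise:
    """Stochastic model of a manually-inserted, robot-guided needle.

    The guide fixes the trajectory; residual errors are two independent
    Gaussian transverse angular components (``angular_sd_deg`` each) and
    a Gaussian insertion-depth error (``depth_sd_mm``), since the
    insertion depth is set by hand.  Procedural time is Gaussian,
    truncated to positive values.  Angular and depth defaults are the
    study's observed outcome standard deviations (0.68°, 1.55 mm).
    """

    angular_sd_deg: float = 0.68
    depth_sd_mm: float = 1.55
    time_mean_s: float = 361.0
    time_sd_s: float = 43.0

    def __post_init__(self) -> None:
        if min(self.angular_sd_deg, self.depth_sd_mm,
               self.time_mean_s, self.time_sd_s) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class NeedleOutcome:
    """One simulated needle placement (world mm / seconds)."""

    entry_A: np.ndarray
    target_B: np.ndarray
    tip_C: np.ndarray
    procedural_time: float
    group_label: GroupLabel
    iterations: int = 0


def _transverse_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u and to each other (deterministic)."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def simulate_needle_outcome(
    plan,
    noise: NeedleNoise | None = None,
    seed: int | np.random.Generator | None = None,
) -> NeedleOutcome:
    """Draw a stochastic needle tip for a trajectory plan.

    The tip is ``C = A + d * v`` where ``v`` is the planned unit
    direction perturbed by two transverse angles ~ N(0, angular_sd) and
    ``d = |AB| + N(0, depth_sd)``.  With all noise zero, ``C = B``.
    """
    noise = noise if noise is not None else NeedleNoise()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = np.asarray(plan.entry_A, float)
    B = np.asarray(plan.target_B, float)
    depth = float(np.linalg.norm(B - A))
    if depth <= 0:
        raise ValueError("zero-length trajectory: entry and target coincide")
    u = (B - A) / depth
    e1, e2 = _transverse_basis(u)
    th1, th2 = np.radians(rng.normal(0.0, noise.angular_sd_deg, size=2))
    v = u + np.tan(th1) * e1 + np.tan(th2) * e2
    v /= np.linalg.norm(v)
    d = depth + rng.normal(0.0, noise.depth_sd_mm)
    if noise.time_sd_s == 0:
        t = noise.time_mean_s
    else:
        t = -1.0
        while t <= 0:
            t = rng.normal(noise.time_mean_s, noise.time_sd_s)
    return NeedleOutcome(
        entry_A=A, target_B=B, tip_C=A + d * v,
        procedural_time=float(t), group_label=plan.plane_class, iterations=0,
    )


def simulate_study(
    tool_model: ToolModel | None = None,
    lesions: Sequence[tuple[np.ndarray, float]] | None = None,
    limits=None,
    noise_by_group: dict[GroupLabel, NeedleNoise] | None = None,
    seed: int | None = None,
    depth_mm: float = 100.0,
) -> list[NeedleOutcome]:
    """Simulate the full study design: 8 lesions × {in-plane, out-of-plane}.

    Each lesion is targeted once with a purely axial trajectory
    (craniocaudal angle 0, RAO/LAO angulation only) and once with an
    additionally craniocaudally tilted trajectory; all 16 plans respect
    the gantry angulation limits.  Per-group procedural-time defaults
    follow the study (337 s in-plane, 380 s out-of-plane).

    Returns exactly 16 outcomes, deterministic for a fixed seed.
    """
    from .planning import AngulationLimits, direction_from_angles, plan_trajectory

    tool_model = tool_model if tool_model is not None else make_tool_model()
    lesions = list(lesions) if lesions is not None else default_lesions()
    if len(lesions) != 8:
        raise ValueError(f"study design requires 8 lesions, got {len(lesions)}")
    limits = limits if limits is not None else AngulationLimits()
    if noise_by_group is None:
        noise_by_group = {
            "in_plane": NeedleNoise(time_mean_s=337.0, time_sd_s=50.0),
            "out_of_plane": NeedleNoise(time_mean_s=380.0, time_sd_s=26.0),
        }
    rng = np.random.default_rng(seed)

    # Sampling margins keep plans strictly inside the limits, and the
    # out-of-plane tilt clearly away from the in-plane classification band.
    rao_span = 0.75 * limits.raolao_deg
    cc_lo, cc_hi = -0.9 * limits.caudal_deg, 0.9 * limits.cranial_deg

    outcomes: list[NeedleOutcome] = []
    for center, _radius in lesions:
        target = np.asarray(center, float)
        for group in ("in_plane", "out_of_plane"):
            if group == "in_plane":
                cc = 0.0
            else:
                cc = float(rng.uniform(cc_lo, cc_hi))
                if abs(cc) < 5.0:
                    cc = 5.0 if cc >= 0 else -5.0
            rao = float(rng.uniform(-rao_span, rao_span))
            u = direction_from_angles(cc, rao)
            plan = plan_trajectory(target - depth_mm * u, target, limits=limits)
            if not plan.reachable:
                raise ValueError(
                    f"no reachable trajectory for lesion at {center} under the limits"
                )
            assert plan.plane_class == group
            outcomes.append(simulate_needle_outcome(plan, noise_by_group[group], rng))
    return outcomes
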