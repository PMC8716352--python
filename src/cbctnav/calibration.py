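"""Robot-to-image calibration from detected fiducials.

The calibration tool's four spheres sit at pairwise-unique distances, so
detected blobs can be matched to the tool model purely from their
mutual-distance signature — no prior correspondence, no initialisation.
The matched pairs then give a closed-form least-squares rigid transform
(Kabsch/SVD with reflection correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

from .detection import DetectionConfig, detect_candidates
from .geometry import RigidTransform
from .phantom import ToolModel, VolumeGrid

__all__ = [
    "CalibrationError",
    "NoMatchError",
    "AmbiguousMatchError",
    "DegenerateGeometryError",
    "CalibrationConfig",
    "CalibrationResult",
    "distance_signature",
    "match_fiducials",
    "fit_rigid_transform",
    "fiducial_registration_error",
    "calibrate",
]


class CalibrationError(Exception):
    """Base class for calibration failures."""


class NoMatchError(CalibrationError):
    """No candidate subset matches the tool's distance signature."""


class AmbiguousMatchError(CalibrationError):
    """More than one assignment explains the candidates about equally well."""


class DegenerateGeometryError(CalibrationError):
    """Point configuration does not determine a rigid transform (collinear)."""


@dataclass(frozen=True)
class CalibrationConfig:
    """End-to-end calibration parameters.

    ``dist_tol_mm`` defaults to two voxel edges (0.96 mm at 0.48 mm
    spacing): each centroid is good to about half a voxel, so a pairwise
    distance can be off by about one voxel; doubling that is a safe gate.
    At most ``max_candidates`` largest blobs enter the brute-force
    matcher (C(20,4)·4! ≈ 116k assignments is still cheap).
    """

    dist_tol_mm: float = 0.96
    max_candidates: int = 20
    ambiguity_fre_ratio: float = 0.67  # runner-up within 1.5x of best -> ambiguous
    detection: DetectionConfig = DetectionConfig()


@dataclass(frozen=True)
class CalibrationResult:
    """Image-to-tool transform with fit diagnostics.

    ``correspondence[k]`` is the candidate index matched to model
    fiducial ``k``.  ``ambiguity_ratio`` is FRE(best)/FRE(runner-up)
    among tolerance-passing assignments (``inf`` marks a unique match —
    no runner-up existed, the strongest possible evidence).
    """

    transform: RigidTransform  # image world -> tool frame
    correspondence: tuple[int, int, int, int]
    fre_mm: float
    n_candidates: int
    ambiguity_ratio: float


def distance_signature(points: np.ndarray) -> np.ndarray:
    """All n(n-1)/2 pairwise distances, ascending.

    Invariant under any rigid transform of the point set, which is what
    makes correspondence-free matching possible.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for a distance signature")
    diffs = pts[:, None, :] - pts[None, :, :]
    d = np.linalg.norm(diffs, axis=-1)
    iu = np.triu_indices(pts.shape[0], k=1)
    return np.sort(d[iu])


def fit_rigid_transform(source_points: np.ndarray,
                        target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform T minimising Σ‖T(s_i) − t_i‖².

    Closed-form Kabsch solution via SVD of the cross-covariance, with
    the reflection corrected so det(R) = +1.

    Raises
    ------
    DegenerateGeometryError
        If either point set is collinear (rotation underdetermined).
    """
    src = np.asarray(source_points, float).reshape(-1, 3)
    tgt = np.asarray(target_points, float).reshape(-1, 3)
    if src.shape != tgt.shape or src.shape[0] < 3:
        raise ValueError("need >= 3 paired points of equal count")
    sc = src - src.mean(axis=0)
    tc = tgt - tgt.mean(axis=0)
    for pts in (sc, tc):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1e-30):
            raise DegenerateGeometryError("collinear points cannot fix a rotation")
    H = sc.T @ tc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    return RigidTransform(R, t)


def fiducial_registration_error(transform: RigidTransform,
                                source_points: np.ndarray,
                                target_points: np.ndarray) -> float:
    """Root-mean-square residual ‖T(s_i) − t_i‖ (mm)."""
    src = np.asarray(source_points, float).reshape(-1, 3)
    tgt = np.asarray(target_points, float).reshape(-1, 3)
    res = transform.apply(src) - tgt
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))


def match_fiducials(
    candidate_points: np.ndarray,
    tool_model: ToolModel,
    dist_tol_mm: float = 0.96,
    ambiguity_fre_ratio: float = 0.67,
) -> tuple[tuple[int, ...], float, float]:
    """Match detected points to the model by exhaustive signature search.

    Every 4-subset of candidates and every assignment of it to the model
    fiducials is tested; an assignment survives when each of its six
    pairwise distances matches the model's within ``dist_tol_mm``.  Among
    survivors the one with the smallest post-fit FRE wins.

    Returns ``(correspondence, fre_mm, ambiguity_ratio)`` where
    ``correspondence[k]`` is the candidate index for model fiducial k.

    Raises
    ------
    NoMatchError
        If no assignment satisfies the distance tolerance.
    AmbiguousMatchError
        If a runner-up assignment also passes and its FRE is within
        1/``ambiguity_fre_ratio`` (default 1.5x) of the best.
    """
    pts = np.asarray(candidate_points, float).reshape(-1, 3)
    n = pts.shape[0]
    if n < 4:
        raise NoMatchError(f"need >= 4 candidates, got {n}")

    # accept a bare (4, 3) point array as the model, e.g. for probing
    # degenerate geometries that ToolModel itself refuses to represent
    model = tool_model.fiducials if isinstance(tool_model, ToolModel) \
        else np.asarray(tool_model, float).reshape(4, 3)
    model_d = np.linalg.norm(model[:, None, :] - model[None, :, :], axis=-1)
    cand_d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    model_sig = distance_signature(model)

    passing: list[tuple[float, tuple[int, ...]]] = []
    for subset in combinations(range(n), 4):
        # cheap necessary condition: sorted signatures must agree
        sub_d = cand_d[np.ix_(subset, subset)]
        sub_sig = np.sort(sub_d[np.triu_indices(4, k=1)])
        if np.any(np.abs(sub_sig - model_sig) > dist_tol_mm):
            continue
        for perm in permutations(subset):
            ok = True
            for i, j in combinations(range(4), 2):
                if abs(cand_d[perm[i], perm[j]] - model_d[i, j]) > dist_tol_mm:
                    ok = False
                    break
            if not ok:
                continue
            src = pts[list(perm)]
            T = fit_rigid_transform(src, model)
            fre = fiducial_registration_error(T, src, model)
            passing.append((fre, perm))

    if not passing:
        raise NoMatchError(
            f"no 4-subset of {n} candidates matches the tool signature "
            f"within {dist_tol_mm} mm"
        )
    passing.sort(key=lambda item: item[0])
    best_fre, best_perm = passing[0]
    if len(passing) == 1:
        ratio = float("inf")
    else:
        second_fre = passing[1][0]
        ratio = 1.0 if second_fre <= 1e-12 else best_fre / second_fre
        if ratio > ambiguity_fre_ratio:
            raise AmbiguousMatchError(
                f"two assignments pass the tolerance with FRE {best_fre:.3f} and "
                f"{second_fre:.3f} mm (ratio {ratio:.2f}); correspondence is ambiguous"
            )
    return best_perm, float(best_fre), ratio


def calibrate(
    volume: VolumeGrid,
    tool_model: ToolModel,
    config: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Full calibration pipeline: detect → match → fit → FRE.

    Deterministic for fixed input.  The returned transform maps image
    world coordinates into the tool (robot) frame; its inverse is the
    tool pose in the image.

    Raises
    ------
    NoMatchError, AmbiguousMatchError, DegenerateGeometryError
        Propagated from the corresponding stage, labelled by stage.
    """
    cfg = config if config is not None else CalibrationConfig()
    candidates = detect_candidates(volume, config=cfg.detection)
    if len(candidates) < 4:
        raise NoMatchError(
            f"detection stage: only {len(candidates)} candidate blobs found, need 4"
        )
    candidates = candidates[: cfg.max_candidates]  # largest blobs first
    pts = np.array([c.centroid_world for c in candidates])
    try:
        perm, _, ratio = match_fiducials(
            pts, tool_model, cfg.dist_tol_mm, cfg.ambiguity_fre_ratio
        )
    except CalibrationError as err:
        raise type(err)(f"matching stage: {err}") from err
    src = pts[list(perm)]
    try:
        T = fit_rigid_transform(src, tool_model.fiducials)
    except DegenerateGeometryError as err:
        raise DegenerateGeometryError(f"fitting stage: {err}") from err
    fre = fiducial_registration_error(T, src, tool_model.fiducials)
    return CalibrationResult(
        transform=T,
        correspondence=tuple(int(i) for i in perm),
        fre_mm=fre,
        n_candidates=len(candidates),
        ambiguity_ratio=ratio,
    )
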