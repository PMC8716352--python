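"""Needle trajectory planning under gantry angulation limits.

A trajectory is an entry point A and target B in image world
coordinates (LPS, mm).  Its direction is decomposed into a craniocaudal
angulation (tilt toward head/feet, + = cranial) and an RAO/LAO
angulation in the axial plane (+ = RAO, toward the patient's right).
The C-arm setup of the study admits at most 17.5° cranial, 32.5° caudal
and 20° RAO/LAO tilt; a plan outside those limits is flagged
unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "AngulationLimits",
    "TrajectoryPlan",
    "GuidePose",
    "ZeroLengthTrajectoryError",
    "UnreachablePlanError",
    "angulation_angles",
    "direction_from_angles",
    "plan_trajectory",
    "image_to_robot",
]


class ZeroLengthTrajectoryError(ValueError):
    """Entry and target coincide."""


class UnreachablePlanError(ValueError):
    """Plan violates the angulation limits."""


@dataclass(frozen=True)
class AngulationLimits:
    """Maximal trajectory angulations of the robotic setup (degrees)."""

    cranial_deg: float = 17.5
    caudal_deg: float = 32.5
    raolao_deg: float = 20.0

    def allows(self, craniocaudal_deg: float, raolao_deg: float) -> bool:
        return (-self.caudal_deg <= craniocaudal_deg <= self.cranial_deg
                and abs(raolao_deg) <= self.raolao_deg)

    def violation(self, craniocaudal_deg: float, raolao_deg: float) -> str | None:
        """Human-readable name of the violated limit, or None."""
        if craniocaudal_deg > self.cranial_deg:
            return (f"craniocaudal angulation {craniocaudal_deg:.1f}° exceeds the "
                    f"cranial limit of {self.cranial_deg}°")
        if craniocaudal_deg < -self.caudal_deg:
            return (f"craniocaudal angulation {-craniocaudal_deg:.1f}° caudal exceeds "
                    f"the caudal limit of {self.caudal_deg}°")
        if abs(raolao_deg) > self.raolao_deg:
            side = "RAO" if raolao_deg > 0 else "LAO"
            return (f"{side} angulation {abs(raolao_deg):.1f}° exceeds the "
                    f"RAO/LAO limit of {self.raolao_deg}°")
        return None


@dataclass(frozen=True)
class TrajectoryPlan:
    """A validated needle path from entry A to target B (world mm)."""

    entry_A: np.ndarray
    target_B: np.ndarray
    direction_u: np.ndarray  # unit vector A -> B
    depth_mm: float
    craniocaudal_deg: float  # + = cranial
    raolao_deg: float  # + = RAO (patient right)
    plane_class: str  # "in_plane" | "out_of_plane"
    reachable: bool


@dataclass(frozen=True)
class GuidePose:
    """Needle-guide pose in the robot frame: position + axis."""

    position: np.ndarray  # mm, robot frame
    axis: np.ndarray  # unit vector, robot frame
    standoff_mm: float  # distance from guide to entry along the axis


def angulation_angles(direction_u: np.ndarray) -> tuple[float, float]:
    """Decompose a unit direction (LPS) into angulation angles (degrees).

    craniocaudal = asin of the superior (z) component, + toward cranial;
    RAO/LAO = axial-plane angle of the left-right component against the
    anterior-posterior component, + = RAO (toward patient right, -x).
    For a purely craniocaudal direction the RAO/LAO angle is undefined
    and returned as 0 by convention.
    """
    u = np.asarray(direction_u, float).reshape(3)
    norm = np.linalg.norm(u)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError(f"direction must be a unit vector (|u| = {norm:.6f})")
    craniocaudal = np.degrees(np.arcsin(np.clip(u[2], -1.0, 1.0)))
    lr, ap = -u[0], abs(u[1])
    if abs(lr) < 1e-15 and ap < 1e-15:
        raolao = 0.0
    else:
        raolao = np.degrees(np.arctan2(lr, ap))
    return float(craniocaudal), float(raolao)


def direction_from_angles(craniocaudal_deg: float, raolao_deg: float) -> np.ndarray:
    """Unit direction (LPS) with the given angulations; inverse of
    :func:`angulation_angles` for |RAO/LAO| < 90°.

    The base direction is anterior-to-posterior (0, 1, 0), the needle
    approach of a supine patient.
    """
    cc = np.radians(craniocaudal_deg)
    rao = np.radians(raolao_deg)
    return np.array([
        -np.cos(cc) * np.sin(rao),
        np.cos(cc) * np.cos(rao),
        np.sin(cc),
    ])


def plan_trajectory(
    entry_A: np.ndarray,
    target_B: np.ndarray,
    limits: AngulationLimits | None = None,
    plane_tol_deg: float = 1.0,
) -> TrajectoryPlan:
    """Turn an entry/target pair into a validated plan.

    ``plane_class`` is ``in_plane`` when the craniocaudal angulation is
    below ``plane_tol_deg`` in magnitude (a physical setup never hits
    exactly 0°), otherwise ``out_of_plane``.  Reachability follows the
    angulation limits; an unreachable plan is returned, not raised.
    """
    limits = limits if limits is not None else AngulationLimits()
    A = np.asarray(entry_A, float).reshape(3)
    B = np.asarray(target_B, float).reshape(3)
    depth = float(np.linalg.norm(B - A))
    if depth <= 0:
        raise ZeroLengthTrajectoryError("entry and target points coincide")
    u = (B - A) / depth
    cc, rao = angulation_angles(u)
    return TrajectoryPlan(
        entry_A=A, target_B=B, direction_u=u, depth_mm=depth,
        craniocaudal_deg=cc, raolao_deg=rao,
        plane_class="in_plane" if abs(cc) < plane_tol_deg else "out_of_plane",
        reachable=limits.allows(cc, rao),
    )


def image_to_robot(
    plan: TrajectoryPlan,
    calibration_transform: RigidTransform,
    standoff_mm: float = 20.0,
    force: bool = False,
) -> GuidePose:
    """Map a plan into the robot frame as a needle-guide pose.

    The guide is positioned ``standoff_mm`` behind the entry point along
    the (transformed) trajectory axis so it clears the skin.

    Raises
    ------
    UnreachablePlanError
        If the plan is not reachable, unless ``force`` is set.
    """
    if not plan.reachable and not force:
        limits = AngulationLimits()
        reason = limits.violation(plan.craniocaudal_deg, plan.raolao_deg)
        raise UnreachablePlanError(reason or "plan is flagged unreachable")
    entry_robot = calibration_transform.apply(plan.entry_A)
    axis = calibration_transform.apply_vector(plan.direction_u)
    axis = axis / np.linalg.norm(axis)
    return GuidePose(
        position=entry_robot - standoff_mm * axis,
        axis=axis,
        standoff_mm=float(standoff_mm),
    )
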