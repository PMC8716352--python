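"""File formats: NIfTI / raw volumes and JSON artifact schemas.

All JSON artifacts use millimetres and degrees.  Transforms are stored
as 4x4 homogeneous matrices, row-major.  Package world coordinates are
LPS; NIfTI affines are RAS by convention, so the first two world axes
are sign-flipped on write and flipped back on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

from .calibration import CalibrationResult
from .evaluation import GroupSummary, StudyReport
from .geometry import RigidTransform
from .phantom import GroundTruth, ToolModel, VolumeGrid
from .planning import TrajectoryPlan

__all__ = [
    "write_nifti", "read_nifti", "write_raw", "read_raw",
    "tool_model_to_dict", "tool_model_from_dict",
    "ground_truth_to_dict", "ground_truth_from_dict",
    "calibration_to_dict", "calibration_from_dict",
    "plan_to_dict", "plan_from_dict",
    "report_to_dict",
    "save_json", "load_json",
]

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _lps_affine(volume: VolumeGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = volume.direction @ np.diag(volume.spacing)
    aff[:3, 3] = volume.origin
    return aff


def write_nifti(volume: VolumeGrid, path: str | Path) -> None:
    """Write as NIfTI (.nii / .nii.gz); geometry converted LPS -> RAS."""
    aff = _lps_affine(volume)
    ras = aff.copy()
    ras[:3, :] = _LPS_TO_RAS @ aff[:3, :]
    img = nib.Nifti1Image(np.asarray(volume.voxels, np.float32), ras)
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> VolumeGrid:
    """Read a NIfTI volume back into the package's LPS world frame."""
    img = nib.load(str(path))
    ras = img.affine
    aff = ras.copy()
    aff[:3, :] = _LPS_TO_RAS @ ras[:3, :]
    M = aff[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    return VolumeGrid(
        voxels=np.asanyarray(img.dataobj).astype(np.float32),
        spacing=spacing,
        origin=aff[:3, 3],
        direction=direction,
    )


def write_raw(volume: VolumeGrid, raw_path: str | Path,
              sidecar_path: str | Path | None = None) -> None:
    """Write as raw little-endian float32 plus a JSON geometry sidecar."""
    raw_path = Path(raw_path)
    sidecar = Path(sidecar_path) if sidecar_path else raw_path.with_suffix(".json")
    np.asarray(volume.voxels, np.float32).astype("<f4").tofile(raw_path)
    save_json({
        "shape": list(volume.shape),
        "spacing": volume.spacing.tolist(),
        "origin": volume.origin.tolist(),
        "direction": volume.direction.tolist(),
        "dtype": "float32",
        "byte_order": "little",
    }, sidecar)


def read_raw(raw_path: str | Path, sidecar_path: str | Path | None = None) -> VolumeGrid:
    raw_path = Path(raw_path)
    sidecar = Path(sidecar_path) if sidecar_path else raw_path.with_suffix(".json")
    meta = load_json(sidecar)
    data = np.fromfile(raw_path, dtype="<f4").reshape(meta["shape"])
    return VolumeGrid(
        voxels=data,
        spacing=np.asarray(meta["spacing"]),
        origin=np.asarray(meta["origin"]),
        direction=np.asarray(meta["direction"]),
    )


# ---------------------------------------------------------------------------
# JSON artifact schemas
# ---------------------------------------------------------------------------

def _transform_to_list(t: RigidTransform) -> list[list[float]]:
    return t.as_matrix().tolist()


def tool_model_to_dict(model: ToolModel) -> dict[str, Any]:
    return {
        "fiducials_mm": model.fiducials.tolist(),
        "sphere_radius_mm": model.sphere_radius,
        "bounding_box_mm": list(model.bounding_box),
        "min_signature_gap_mm": model.min_signature_gap,
    }


def tool_model_from_dict(d: dict[str, Any]) -> ToolModel:
    return ToolModel(
        fiducials=np.asarray(d["fiducials_mm"]),
        sphere_radius=float(d["sphere_radius_mm"]),
        bounding_box=tuple(d["bounding_box_mm"]),
        min_signature_gap=float(d["min_signature_gap_mm"]),
    )


def ground_truth_to_dict(truth: GroundTruth) -> dict[str, Any]:
    return {
        "tool_pose": _transform_to_list(truth.tool_pose),
        "fiducial_centers_world_mm": truth.fiducial_centers_world.tolist(),
        "lesions": [{"center_mm": list(c), "radius_mm": r} for c, r in truth.lesions],
        "scan_meta": truth.scan_meta,
    }


def ground_truth_from_dict(d: dict[str, Any]) -> GroundTruth:
    return GroundTruth(
        tool_pose=RigidTransform.from_matrix(np.asarray(d["tool_pose"])),
        fiducial_centers_world=np.asarray(d["fiducial_centers_world_mm"]),
        lesions=tuple((tuple(item["center_mm"]), float(item["radius_mm"]))
                      for item in d["lesions"]),
        scan_meta=dict(d["scan_meta"]),
    )


def calibration_to_dict(result: CalibrationResult) -> dict[str, Any]:
    return {
        "image_to_tool": _transform_to_list(result.transform),
        "correspondence": list(result.correspondence),
        "fre_mm": result.fre_mm,
        "n_candidates": result.n_candidates,
        "ambiguity_ratio": (None if np.isinf(result.ambiguity_ratio)
                            else result.ambiguity_ratio),
    }


def calibration_from_dict(d: dict[str, Any]) -> CalibrationResult:
    ratio = d["ambiguity_ratio"]
    return CalibrationResult(
        transform=RigidTransform.from_matrix(np.asarray(d["image_to_tool"])),
        correspondence=tuple(d["correspondence"]),
        fre_mm=float(d["fre_mm"]),
        n_candidates=int(d["n_candidates"]),
        ambiguity_ratio=float("inf") if ratio is None else float(ratio),
    )


def plan_to_dict(plan: TrajectoryPlan) -> dict[str, Any]:
    return {
        "entry_mm": plan.entry_A.tolist(),
        "target_mm": plan.target_B.tolist(),
        "direction": plan.direction_u.tolist(),
        "depth_mm": plan.depth_mm,
        "craniocaudal_deg": plan.craniocaudal_deg,
        "raolao_deg": plan.raolao_deg,
        "plane_class": plan.plane_class,
        "reachable": plan.reachable,
    }


def plan_from_dict(d: dict[str, Any]) -> TrajectoryPlan:
    return TrajectoryPlan(
        entry_A=np.asarray(d["entry_mm"], float),
        target_B=np.asarray(d["target_mm"], float),
        direction_u=np.asarray(d["direction"], float),
        depth_mm=float(d["depth_mm"]),
        craniocaudal_deg=float(d["craniocaudal_deg"]),
        raolao_deg=float(d["raolao_deg"]),
        plane_class=d["plane_class"],
        reachable=bool(d["reachable"]),
    )


def _summary_to_dict(s: GroupSummary) -> dict[str, Any]:
    return {"n": s.n, "mean": s.mean, "std": s.std, "min": s.min, "max": s.max,
            "degenerate": s.degenerate}


def report_to_dict(report: StudyReport) -> dict[str, Any]:
    return {
        "n_total": report.n_total,
        "n_in_plane": report.n_in_plane,
        "n_out_of_plane": report.n_out_of_plane,
        "summaries": {g: {k: _summary_to_dict(s) for k, s in row.items()}
                      for g, row in report.summaries.items()},
        "anova_p": report.anova_p,
        "technical_success_rate": report.technical_success_rate,
        "per_needle": [
            {"angular_deg": m.angular_deg, "absolute_mm": m.absolute_mm,
             "longitudinal_mm": m.longitudinal_mm}
            for m in report.per_needle
        ],
    }
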