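"""Occlusal-third cropping and the tooth-local anatomical frame.

Local axes (right-handed): +X buccal, +Y mesial, +Z occlusal.  The axis
polarity is a package convention — so that an achieved molar sitting
distal of its prediction yields a positive mesiodistal (Y) prediction
difference — and is recorded in every output.  The frame origin is the
centre of the crown's axis-aligned bounding box expressed in those axes;
crowns are never auto-oriented from shape: the occlusal/buccal direction
hints come with the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .geometry import RigidTransform

__all__ = [
    "ToothFrame",
    "AXIS_POLARITY",
    "build_tooth_frame",
    "crop_occlusal_third",
    "occlusal_plane_z",
    "to_local_mesh",
    "tooth_type_of",
    "TOOTH_TYPES",
]

AXIS_POLARITY = "+X buccal, +Y mesial, +Z occlusal (right-handed)"

TOOTH_TYPES = ("incisor", "canine", "premolar", "molar")

_FDI_TO_TYPE = {
    31: "incisor", 32: "incisor", 41: "incisor", 42: "incisor",
    33: "canine", 43: "canine",
    34: "premolar", 35: "premolar", 44: "premolar", 45: "premolar",
    36: "molar", 37: "molar", 46: "molar", 47: "molar",
}


def tooth_type_of(fdi: int) -> str:
    """Map a mandibular FDI label to its tooth type (third molars excluded)."""
    try:
        return _FDI_TO_TYPE[int(fdi)]
    except KeyError:
        raise ValueError(
            f"FDI {fdi} is not a mandibular tooth of the study arch (31-37, 41-47; "
            "third molars excluded)"
        ) from None


@dataclass(frozen=True)
class ToothFrame:
    """Tooth-local anatomical frame; ``to_world`` maps local -> world."""

    to_world: RigidTransform

    @property
    def to_local(self) -> RigidTransform:
        return self.to_world.invert()


def _orthonormal_axes(occlusal_dir: np.ndarray, buccal_dir: np.ndarray) -> np.ndarray:
    z = np.asarray(occlusal_dir, dtype=float)
    x = np.asarray(buccal_dir, dtype=float)
    nz = np.linalg.norm(z)
    nx = np.linalg.norm(x)
    if nz == 0 or nx == 0:
        raise ValueError("axis hints must be non-zero")
    z = z / nz
    x = x - (x @ z) * z  # Gram-Schmidt: buccal orthogonalised against occlusal
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise ValueError("occlusal and buccal hints are parallel")
    x = x / nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])  # columns are the local axes in world


def build_tooth_frame(
    crown: trimesh.Trimesh,
    occlusal_dir: np.ndarray,
    buccal_dir: np.ndarray,
) -> ToothFrame:
    """Anatomical frame of a crown from its orientation hints.

    Z = normalised occlusal hint; X = buccal hint orthogonalised against Z;
    Y = Z x X.  Origin = centre of the crown's bounding box measured in
    these axes, so the crown expressed in local coordinates has its
    bounding-box centre at the origin.
    """
    r = _orthonormal_axes(occlusal_dir, buccal_dir)
    local_coords = np.asarray(crown.vertices, dtype=float) @ r  # = R^T v, per row
    center_local = (local_coords.min(axis=0) + local_coords.max(axis=0)) / 2.0
    origin_world = r @ center_local
    return ToothFrame(RigidTransform(r, origin_world))


def to_local_mesh(crown: trimesh.Trimesh, frame: ToothFrame) -> trimesh.Trimesh:
    """Copy of the crown expressed in the frame's local coordinates."""
    out = crown.copy()
    out.vertices = frame.to_local.apply(np.asarray(crown.vertices, dtype=float))
    return out


def occlusal_plane_z(
    crown: trimesh.Trimesh, frame: ToothFrame, fraction: float = 1.0 / 3.0
) -> float:
    """Height (along the frame's Z axis, world projection) of the plane that
    keeps the occlusal ``fraction`` of this crown's extent."""
    z = np.asarray(crown.vertices, dtype=float) @ frame.to_world.rotation[:, 2]
    z_min, z_max = float(z.min()), float(z.max())
    if z_max - z_min <= 0:
        raise ValueError("crown has no extent along the occlusal axis")
    return z_min + (1.0 - fraction) * (z_max - z_min)


def crop_occlusal_third(
    crown: trimesh.Trimesh,
    frame: ToothFrame,
    fraction: float = 1.0 / 3.0,
    plane_z: float | None = None,
) -> trimesh.Trimesh:
    """Keep the occlusal ``fraction`` of the crown along the frame's Z axis.

    The kept sub-mesh satisfies local z >= z_min + (1 - fraction) * extent
    of this crown (or z >= ``plane_z`` when an explicit plane is supplied);
    triangles crossing the plane are clipped at it.  The result is returned
    in the crown's original (world) coordinates.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    z_axis = frame.to_world.rotation[:, 2]
    if plane_z is None:
        plane_z = occlusal_plane_z(crown, frame, fraction)
    plane_origin = plane_z * z_axis
    kept = slice_mesh_plane(crown, plane_normal=z_axis, plane_origin=plane_origin)
    if kept is None or len(kept.faces) == 0:
        raise ValueError("occlusal crop produced an empty mesh (degenerate crown)")
    return kept
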