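"""Placement-comparison measures: unpaired maximum Hausdorff distance
between two plate meshes, and the total 3D rotation / translation separating
two plate poses (the manual adjustment needed to move one onto the other).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .frame import RigidPose
from .mesh_core import PlatePlanError, TriMesh


@dataclass(frozen=True)
class ComparisonMetrics:
    hausdorff_mm: float
    rotation_deg: float
    translation_mm: float


def hausdorff_max(a: TriMesh, b: TriMesh) -> float:
    """Symmetric maximum Hausdorff distance between the two vertex sets.

    "Unpaired": no correspondence between vertices is assumed; each side's
    worst nearest-neighbour distance is taken and the larger one returned.
    """
    va, vb = a.vertices, b.vertices
    if len(va) == 0 or len(vb) == 0:
        raise PlatePlanError("hausdorff_max requires non-empty meshes")
    d_ab = cKDTree(vb).query(va)[0].max()
    d_ba = cKDTree(va).query(vb)[0].max()
    return float(max(d_ab, d_ba))


def pose_difference(a: RigidPose, b: RigidPose) -> tuple[float, float]:
    """(rotation_deg, translation_mm) of the relative transform b ∘ a⁻¹.

    The rotation is the geodesic angle of the relative rotation (computed
    from the rotation matrices, so it is independent of the Euler-angle
    representation).  The translation is the displacement of the plate
    centroid; since a standardized plate has its centroid at the pose
    origin, this is simply the distance between the two pose translations.
    """
    ra, ta = a.matrix()
    rb, tb = b.matrix()
    r_rel = Rotation.from_matrix(rb @ ra.T)
    rot_deg = float(np.degrees(r_rel.magnitude()))
    trans_mm = float(np.linalg.norm(tb - ta))
    return rot_deg, trans_mm


def compare_placements(
    mesh_a: TriMesh,
    mesh_b: TriMesh,
    pose_a: RigidPose | None = None,
    pose_b: RigidPose | None = None,
) -> ComparisonMetrics:
    """Bundle the three comparison measures; pose metrics are zero-filled
    when no pose records are supplied."""
    h = hausdorff_max(mesh_a, mesh_b)
    if pose_a is not None and pose_b is not None:
        rot, trans = pose_difference(pose_a, pose_b)
    else:
        rot, trans = float("nan"), float("nan")
    return ComparisonMetrics(h, rot, trans)
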