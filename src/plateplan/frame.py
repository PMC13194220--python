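"""Standardized coordinate frames for bone and plate (algorithm step a).

The canonical frame is anatomy-driven: the origin sits at the bone mesh
centroid, the longest principal axis lies on Z with the distal end up
(verified against the osteotomy-plane centroids), +Y points through the most
distal vertex (the styloid process), and X completes a right-handed frame
pointing toward the volar aspect.  Right-side bones are mirrored across the
YZ plane into the canonical left-anatomy frame, so a single pipeline serves
both sides; the mirror is recorded and undone on outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh_core import Plane, PlatePlanError, TriMesh, mesh_centroid


class DegenerateFrameError(PlatePlanError):
    """PCA cannot produce a full frame (too few / collinear points)."""


class EmptyCropError(PlatePlanError):
    """No vertices above the distal crop threshold."""


@dataclass(frozen=True)
class RigidPose:
    """6-DOF rigid transform ``p -> R(rotation) p + translation``.

    ``rotation`` is Euler angles in degrees, XYZ order about fixed (extrinsic)
    axes, which maps directly onto the per-axis rotation limits of the final
    alignment.  ``translation`` is in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "rotation", np.asarray(self.rotation, dtype=np.float64)
        )
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64)
        )
        if self.rotation.shape != (3,) or self.translation.shape != (3,):
            raise PlatePlanError("RigidPose needs 3 Euler angles and a 3-vector")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.zeros(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, r: np.ndarray, t: np.ndarray) -> "RigidPose":
        rot = Rotation.from_matrix(np.asarray(r, float))
        return cls(rot.as_euler("xyz", degrees=True), np.asarray(t, float))

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidPose":
        params = np.asarray(params, float)
        return cls(params[:3], params[3:])

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation])

    def matrix(self):
        """(R, t) with R the 3x3 rotation matrix."""
        return (
            Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix(),
            self.translation.copy(),
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        r, t = self.matrix()
        return np.atleast_2d(np.asarray(points, float)) @ r.T + t

    def compose(self, other: "RigidPose") -> "RigidPose":
        """``self after other``: (self ∘ other)(p) = self(other(p))."""
        r1, t1 = other.matrix()
        r2, t2 = self.matrix()
        return RigidPose.from_matrix(r2 @ r1, r2 @ t1 + t2)

    def inverse(self) -> "RigidPose":
        r, t = self.matrix()
        return RigidPose.from_matrix(r.T, -r.T @ t)


@dataclass(frozen=True)
class FrameResult:
    """Outcome of standardization.

    ``transform`` maps the (possibly mirrored) input into the canonical frame;
    ``standardized_mesh`` is always expressed in the canonical left-anatomy
    frame.  ``flipped`` records the distal flip test, ``mirrored`` whether a
    right-side input was reflected across the YZ plane first.
    """

    transform: RigidPose
    standardized_mesh: TriMesh
    flipped: bool
    mirrored: bool = False


def mirror_x(mesh: TriMesh) -> TriMesh:
    """Reflect across the YZ plane, reversing winding to keep outward normals."""
    v = mesh.vertices.copy()
    v[:, 0] = -v[:, 0]
    return TriMesh(v, mesh.faces[:, ::-1].copy())


def mirror_plane_x(plane: Plane) -> Plane:
    p = plane.point.copy()
    n = plane.normal.copy()
    p[0] = -p[0]
    n[0] = -n[0]
    return Plane(p, n)


def principal_axes(points: np.ndarray) -> np.ndarray:
    """Orthonormal axes (rows) ordered by decreasing variance, right-handed.

    Sign convention: each axis points toward the non-negative skewness of its
    projections; the third axis is then flipped if needed to keep det = +1.
    The anatomical rules of the standardizers override these raw signs.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if len(np.unique(np.round(pts / 1e-9), axis=0)) < 2:
        raise DegenerateFrameError("need at least 2 distinct points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T  # rows
    for i in range(3):
        proj = centered @ axes[i]
        skew = np.mean(proj**3)
        if skew < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def _frame_from_zy(z_dir: np.ndarray, y_hint: np.ndarray) -> np.ndarray:
    """Rotation rows [x, y, z] with z = z_dir and y = y_hint orthogonalized."""
    z = z_dir / np.linalg.norm(z_dir)
    y = y_hint - (y_hint @ z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise DegenerateFrameError("styloid direction parallel to the long axis")
    y = y / ny
    x = np.cross(y, z)
    return np.vstack([x, y, z])


def standardize_bone(
    bone: TriMesh,
    osteotomy_planes: tuple[Plane, Plane],
    side: str = "left",
) -> FrameResult:
    """Put a bone into the canonical frame (origin at centroid, distal +Z,
    styloid side +Y, volar +X).

    The distal direction of the long axis is verified by checking that the
    osteotomy-plane centroids have a larger Z-value than the bone centroid;
    otherwise the mesh is flipped in the Z-direction (realized as a proper
    rotation, so no reflection is introduced).
    """
    if side not in ("left", "right"):
        raise PlatePlanError(f"side must be 'left' or 'right', got {side!r}")
    if osteotomy_planes is None or len(osteotomy_planes) != 2:
        raise PlatePlanError("two osteotomy planes are required")
    mirrored = side == "right"
    if mirrored:
        bone = mirror_x(bone)
        osteotomy_planes = tuple(mirror_plane_x(p) for p in osteotomy_planes)

    c = mesh_centroid(bone)
    axes = principal_axes(bone.vertices)
    z = axes[0]
    plane_mid = np.mean([p.point for p in osteotomy_planes], axis=0)
    flipped = bool((plane_mid - c) @ z <= 0)
    if flipped:
        z = -z
    rel = bone.vertices - c
    distal = rel[np.argmax(rel @ z)]
    rows = _frame_from_zy(z, distal)
    std = TriMesh(rel @ rows.T, bone.faces.copy())
    transform = RigidPose.from_matrix(rows, -rows @ c)
    return FrameResult(transform, std, flipped, mirrored)


def standardize_plate(plate: TriMesh) -> FrameResult:
    """Put a plate into the canonical frame: centroid at origin, long axis on
    Z with the (wider) head end up, contact face toward -X.

    The head end is the end with the larger transverse extent; the contact
    face is found from the skewness of the thickness-axis projections (a
    transversely bent plate has its edges displaced toward the concave side).
    """
    c = mesh_centroid(plate)
    axes = principal_axes(plate.vertices)
    rel = plate.vertices - c
    z = axes[0]
    proj = rel @ z
    lo, hi = np.quantile(proj, [0.25, 0.75])
    width = np.abs(rel @ axes[1])
    w_top = width[proj >= hi].max() if (proj >= hi).any() else 0.0
    w_bot = width[proj <= lo].max() if (proj <= lo).any() else 0.0
    if w_bot > w_top:
        z = -z
    x = axes[2]
    tx = rel @ x
    skew = np.mean(tx**3)
    if skew > 0:
        x = -x
    x = x - (x @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    rows = np.vstack([x, y, z])
    std = TriMesh(rel @ rows.T, plate.faces.copy())
    return FrameResult(RigidPose.from_matrix(rows, -rows @ c), std, flipped=False)


def crop_distal(bone: TriMesh, z_cut: float = 40.0) -> TriMesh:
    """Distal sub-mesh: faces whose vertices all lie above ``z_cut``.

    The strict all-vertices rule avoids sliver triangles at the cut.  The
    default (40 mm, about 17% of the average radius length) keeps every
    clinically relevant plate position while shrinking later computations.
    """
    above = bone.vertices[:, 2] > z_cut
    if not above.any():
        raise EmptyCropError(f"no vertices above z = {z_cut} mm")
    keep = above[bone.faces].all(axis=1)
    if keep.sum() < 4:
        raise EmptyCropError(f"fewer than 4 faces above z = {z_cut} mm")
    faces = bone.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(bone.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(bone.vertices[used], remap[faces])
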