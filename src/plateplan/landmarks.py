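"""Anatomical and plate landmark extraction (algorithm step b).

Bone landmarks: the two osteotomy planes (found from their conspicuously
large mesh triangles), the midplane halfway between them, the initial
alignment line (intersection of the midplane with the sagittal plane through
the most volar proximal point), and the watershed line — the most volar
ridge of the distal radius, extracted per Y-slice and smoothed by polynomial
regression.

Plate landmarks: centroid, the two distal (top) corners found per PCA
quadrant, the proximal (bottom) tip, and the alignment line through the
centroid parallel to the top-corner line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import (
    Line3D,
    Plane,
    PlatePlanError,
    TriMesh,
    face_centroids,
    face_normals,
    mesh_centroid,
    triangle_areas,
)


class PlaneDetectionError(PlatePlanError):
    """Not exactly two coplanar clusters of oversized faces."""

    def __init__(self, msg: str, n_clusters: int):
        super().__init__(msg)
        self.n_clusters = n_clusters


class NoIntersectionError(PlatePlanError):
    """Planes are parallel; no intersection line exists."""


class InsufficientDataError(PlatePlanError):
    """Too few slices / candidates for the requested fit."""


class LandmarkError(PlatePlanError):
    """Plate landmark detection failed (e.g. empty quadrant)."""


@dataclass(frozen=True)
class BoneLandmarks:
    distal_plane: Plane
    proximal_plane: Plane
    midplane: Plane
    point_P: np.ndarray
    alignment_line: Line3D
    watershed: np.ndarray  # (k, 3) polyline ordered by Y
    watershed_width: float
    radius_width: float
    styloid: np.ndarray


@dataclass(frozen=True)
class PlateLandmarks:
    centroid: np.ndarray
    top_left: np.ndarray
    top_right: np.ndarray
    bottom: np.ndarray
    alignment_line: Line3D
    plate_length: float


# ---------------------------------------------------------------------------
# osteotomy planes
# ---------------------------------------------------------------------------


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: (point, unit normal)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[-1]


def detect_osteotomy_planes(
    bone: TriMesh,
    area_factor: float = 4.0,
    normal_cos: float = 0.99,
    offset_tol_mm: float = 0.5,
    min_cluster_faces: int = 3,
) -> tuple[Plane, Plane]:
    """Find the two planar osteotomy cut faces from their oversized triangles.

    Faces with area >= ``area_factor`` times the median face area are grouped
    into coplanar clusters (normals within ``normal_cos``, plane offsets
    within ``offset_tol_mm``); exactly two clusters must remain.  Returns
    (distal, proximal) ordered by centroid Z, normals oriented outward (away
    from the bone centroid).
    """
    areas = triangle_areas(bone)
    med = np.median(areas)
    big = np.flatnonzero(areas >= area_factor * med)
    normals = face_normals(bone)[big]
    centers = face_centroids(bone)[big]

    clusters: list[list[int]] = []
    refs: list[tuple[np.ndarray, float]] = []
    for i, (n, p) in enumerate(zip(normals, centers)):
        placed = False
        for ci, (nr, dr) in enumerate(refs):
            if abs(n @ nr) >= normal_cos and abs(p @ nr - dr) <= offset_tol_mm:
                clusters[ci].append(i)
                placed = True
                break
        if not placed:
            clusters.append([i])
            refs.append((n, float(p @ n)))
    keep = [c for c in clusters if len(c) >= min_cluster_faces]
    if len(keep) != 2:
        raise PlaneDetectionError(
            f"expected 2 coplanar clusters of oversized faces, found {len(keep)}",
            n_clusters=len(keep),
        )

    c_bone = mesh_centroid(bone)
    planes = []
    for cluster in keep:
        vids = np.unique(bone.faces[big[cluster]])
        point, normal = _fit_plane(bone.vertices[vids])
        if (point - c_bone) @ normal < 0:
            normal = -normal
        planes.append(Plane(point, normal))
    planes.sort(key=lambda pl: pl.point[2], reverse=True)
    return planes[0], planes[1]


def compute_midplane(distal: Plane, proximal: Plane) -> Plane:
    """Average of the two osteotomy planes (point midpoint, normal bisector)."""
    n1 = distal.normal
    n2 = proximal.normal
    if n1 @ n2 < 0:
        n2 = -n2
    mean = n1 + n2
    norm = np.linalg.norm(mean)
    if norm < 1e-9:
        raise PlatePlanError("osteotomy-plane normals are anti-parallel")
    return Plane(0.5 * (distal.point + proximal.point), mean / norm)


# ---------------------------------------------------------------------------
# bone alignment line and watershed
# ---------------------------------------------------------------------------


def bone_alignment_line(
    bone: TriMesh, midplane: Plane, z_cut: float = 40.0
) -> tuple[np.ndarray, Line3D]:
    """Initial alignment line of the bone.

    Point P is the most volar (maximum-X) vertex of the proximal segment
    (below the distal crop); the line is the intersection of the sagittal
    plane {x = P.x} with the midplane.
    """
    proximal = bone.vertices[bone.vertices[:, 2] <= z_cut]
    if len(proximal) == 0:
        raise PlatePlanError("proximal segment is empty")
    point_p = proximal[np.argmax(proximal[:, 0])]

    x_hat = np.array([1.0, 0.0, 0.0])
    direction = np.cross(midplane.normal, x_hat)
    if np.linalg.norm(direction) < 1e-9:
        raise NoIntersectionError("midplane is parallel to the YZ plane")
    direction = direction / np.linalg.norm(direction)
    if direction[1] < 0:
        direction = -direction
    # min-norm point satisfying both plane equations
    a = np.vstack([midplane.normal, x_hat])
    b = np.array([midplane.normal @ midplane.point, point_p[0]])
    q0, *_ = np.linalg.lstsq(a, b, rcond=None)
    line = Line3D(q0, direction)
    # anchor at y = 0 for reproducible downstream use
    if abs(line.direction[1]) > 1e-9:
        q0 = line.point - (line.point[1] / line.direction[1]) * line.direction
        line = Line3D(q0, line.direction)
    return point_p.copy(), line


def compute_watershed(
    distal_segment: TriMesh,
    z_band_mm: float = 3.0,
    poly_degree: int = 3,
    slice_mm: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Watershed line of the distal segment.

    Per 1 mm Y-slice the maximum-X vertex is a candidate; candidates whose Z
    deviates more than ``z_band_mm`` from the candidates' mean Z are dropped
    (they belong to the styloid or the cut, not the volar rim).  X and Z are
    then smoothed as degree-``poly_degree`` polynomials in Y and the polyline
    is sampled at the surviving bin centers.  Returns (polyline, Y-extent).
    """
    v = distal_segment.vertices
    edges = np.arange(
        np.floor(v[:, 1].min()), np.ceil(v[:, 1].max()) + slice_mm, slice_mm
    )
    if len(edges) < 2:
        raise InsufficientDataError("distal segment spans no Y-slices")
    idx = np.digitize(v[:, 1], edges)
    cand = []
    centers = []
    for b in np.unique(idx):
        sel = np.flatnonzero(idx == b)
        if len(sel) == 0:
            continue
        best = sel[np.argmax(v[sel, 0])]
        cand.append(v[best])
        centers.append(edges[min(b, len(edges) - 1) - 1] + slice_mm / 2.0)
    cand = np.asarray(cand)
    centers = np.asarray(centers)
    zmean = cand[:, 2].mean()
    keep = np.abs(cand[:, 2] - zmean) <= z_band_mm
    cand, centers = cand[keep], centers[keep]
    if len(cand) < poly_degree + 2:
        raise InsufficientDataError(
            f"only {len(cand)} watershed candidates for degree-{poly_degree} fit"
        )
    px = np.polynomial.Polynomial.fit(cand[:, 1], cand[:, 0], poly_degree)
    pz = np.polynomial.Polynomial.fit(cand[:, 1], cand[:, 2], poly_degree)
    order = np.argsort(centers)
    yc = centers[order]
    polyline = np.column_stack([px(yc), yc, pz(yc)])
    width = float(yc[-1] - yc[0])
    if width <= 0:
        raise InsufficientDataError("watershed has zero Y-extent")
    return polyline, width


def watershed_interp(watershed: np.ndarray, y, column: int):
    """Linear interpolation of watershed X (column=0) or Z (column=2) at y."""
    return np.interp(np.asarray(y, float), watershed[:, 1], watershed[:, column])


# ---------------------------------------------------------------------------
# plate landmarks
# ---------------------------------------------------------------------------


def plate_landmarks(plate: TriMesh) -> PlateLandmarks:
    """Landmarks of a standardized plate.

    Quadrants are split by the signs of the coordinates along the first two
    principal axes (Z, Y in the standardized frame).  The vertex farthest
    from the centroid in each upper quadrant is a top corner; the bottom
    corner is the vertex farthest from the top-corner line.
    """
    v = plate.vertices
    c = mesh_centroid(plate)
    rel = v - c
    upper = rel[:, 2] > 0
    left = rel[:, 1] < 0
    corners = {}
    for name, quad in (("top_left", upper & left), ("top_right", upper & ~left)):
        sel = np.flatnonzero(quad)
        if len(sel) == 0:
            raise LandmarkError(f"empty quadrant for {name}")
        dist = np.linalg.norm(rel[sel], axis=1)
        corners[name] = v[sel[np.argmax(dist)]]
    tl, tr = corners["top_left"], corners["top_right"]
    d = tr - tl
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        raise LandmarkError("top corners coincide")
    d = d / nd
    rel_tl = v - tl
    perp = rel_tl - np.outer(rel_tl @ d, d)
    bottom = v[np.argmax(np.linalg.norm(perp, axis=1))]
    direction = d if d[1] >= 0 else -d
    line = Line3D(c, direction)
    length = float(np.ptp(v[:, 2]))
    return PlateLandmarks(
        centroid=c,
        top_left=tl.copy(),
        top_right=tr.copy(),
        bottom=bottom.copy(),
        alignment_line=line,
        plate_length=length,
    )


# ---------------------------------------------------------------------------
# assembled bone landmarks
# ---------------------------------------------------------------------------


def radius_width_at(bone: TriMesh, z_level: float, slab_mm: float = 1.0) -> float:
    """Y-extent of the bone in a thin slab around ``z_level``.

    The slab widens until it holds enough vertices to span the section —
    at the midplane level the slab straddles the (empty) osteotomy gap, so
    the width must come from the adjacent cut faces.
    """
    for slab in (slab_mm, 2.5 * slab_mm, 5.0 * slab_mm, 10.0 * slab_mm):
        sel = np.abs(bone.vertices[:, 2] - z_level) <= slab
        if sel.sum() >= 30:
            ys = bone.vertices[sel, 1]
            return float(ys.max() - ys.min())
    raise PlatePlanError(f"no vertices near z = {z_level:.1f} mm")


def extract_bone_landmarks(
    bone_std: TriMesh,
    z_cut: float = 40.0,
    area_factor: float = 4.0,
    z_band_mm: float = 3.0,
    poly_degree: int = 3,
    slice_mm: float = 1.0,
) -> BoneLandmarks:
    """Run the full bone landmark chain on a standardized bone."""
    from .frame import crop_distal  # local import to avoid a cycle

    distal_plane, proximal_plane = detect_osteotomy_planes(
        bone_std, area_factor=area_factor
    )
    midplane = compute_midplane(distal_plane, proximal_plane)
    point_p, line = bone_alignment_line(bone_std, midplane, z_cut=z_cut)
    distal_seg = crop_distal(bone_std, z_cut=z_cut)
    watershed, ws_width = compute_watershed(
        distal_seg, z_band_mm=z_band_mm, poly_degree=poly_degree, slice_mm=slice_mm
    )
    width = radius_width_at(bone_std, float(midplane.point[2]))
    styloid = bone_std.vertices[np.argmax(bone_std.vertices[:, 2])]
    return BoneLandmarks(
        distal_plane=distal_plane,
        proximal_plane=proximal_plane,
        midplane=midplane,
        point_P=point_p,
        alignment_line=line,
        watershed=watershed,
        watershed_width=ws_width,
        radius_width=width,
        styloid=styloid.copy(),
    )
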