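"""Triangle-mesh container, STL I/O and the geometric primitives used by
every later planning stage.

All coordinates are millimetres.  Meshes are stored as indexed triangle
surfaces; STL files store facets independently, so vertices are welded
(tolerance 1e-6 mm) at load time so that index-based landmarking works.

Distance and containment queries are implemented here directly (vectorized
NumPy): point-to-vertex distances back the placement objective, the
generalized winding number backs the penetration count, and point-to-triangle
distances back the contact searches of the initial alignment.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

log = logging.getLogger("plateplan")

WELD_TOL_MM = 1e-6
_DEGENERATE_AREA = 1e-12


class PlatePlanError(Exception):
    """Base class for all planning errors."""


class MeshFormatError(PlatePlanError):
    """Unreadable or corrupt mesh file."""


class DegenerateMeshError(PlatePlanError):
    """Mesh below the minimal size (>= 4 vertices and >= 4 faces)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriMesh:
    """Indexed triangle surface in millimetres."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise DegenerateMeshError("vertices must be (n,3), faces (m,3)")
        if len(v) < 4 or len(f) < 4:
            raise DegenerateMeshError(
                f"mesh too small: {len(v)} vertices, {len(f)} faces (need >= 4 each)"
            )
        if not np.isfinite(v).all():
            raise DegenerateMeshError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise DegenerateMeshError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Apply ``p -> R p + t`` to every vertex."""
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return TriMesh(self.vertices @ r.T + t, self.faces.copy())

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two faces."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        nn = np.linalg.norm(n)
        if abs(nn - 1.0) > 1e-9:
            if nn < 1e-12:
                raise PlatePlanError("plane normal has zero length")
            n = n / nn
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass(frozen=True)
class Line3D:
    """Line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=np.float64)
        d = np.asarray(self.direction, dtype=np.float64)
        dn = np.linalg.norm(d)
        if dn < 1e-12:
            raise PlatePlanError("line direction has zero length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / dn)

    def at(self, t) -> np.ndarray:
        return self.point + np.multiply.outer(np.asarray(t, float), self.direction)


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL_MM):
    """Merge vertices closer than ``tol`` (grid snap) and drop degenerate faces."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    v = vertices[first]
    f = inverse[faces]
    # drop faces with repeated indices
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 2] != f[:, 0])
    f = f[ok]
    if len(f):
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        f = f[areas > _DEGENERATE_AREA]
    # drop unreferenced vertices
    used = np.unique(f)
    remap = -np.ones(len(v), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return v[used], remap[f]


def load_stl(path) -> TriMesh:
    """Read a binary or ASCII STL file (dialect auto-detected)."""
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise MeshFormatError(f"cannot read STL file {path}: {exc}") from exc
    if not hasattr(tm, "vertices") or len(getattr(tm, "faces", ())) == 0:
        raise MeshFormatError(f"no triangles found in {path}")
    v, f = _weld(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
    if len(v) < 4 or len(f) < 4:
        raise DegenerateMeshError(
            f"{path}: {len(f)} faces after cleanup (need >= 4)"
        )
    return TriMesh(v, f)


def save_stl(mesh: TriMesh, path, binary: bool = False) -> None:
    """Write an STL file.

    ASCII with 10 significant digits by default: binary STL stores float32,
    whose quantization at typical bone coordinates (~1e2 mm) exceeds the
    1e-6 mm round-trip guarantee this function makes.
    """
    if binary:
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        data = tm.export(file_type="stl")
        mode, payload = "wb", data
    else:
        tri = mesh.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1)
        n = n / np.where(norm > 0, norm, 1.0)[:, None]
        buf = io.StringIO()
        buf.write("solid plateplan\n")
        for ni, ti in zip(n, tri):
            buf.write(f"facet normal {ni[0]:.10e} {ni[1]:.10e} {ni[2]:.10e}\n")
            buf.write(" outer loop\n")
            for p in ti:
                buf.write(f"  vertex {p[0]:.10e} {p[1]:.10e} {p[2]:.10e}\n")
            buf.write(" endloop\nendfacet\n")
        buf.write("endsolid plateplan\n")
        mode, payload = "w", buf.getvalue()
    try:
        with open(path, mode) as fh:
            fh.write(payload)
    except OSError as exc:
        raise PlatePlanError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def triangle_areas(mesh: TriMesh) -> np.ndarray:
    """Per-face area in mm^2."""
    tri = mesh.triangles()
    return 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )


def face_centroids(mesh: TriMesh) -> np.ndarray:
    return mesh.triangles().mean(axis=1)


def face_normals(mesh: TriMesh) -> np.ndarray:
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1)
    return n / np.where(norm > 0, norm, 1.0)[:, None]


def mesh_centroid(mesh: TriMesh) -> np.ndarray:
    """Unweighted vertex mean; a robust interior reference for orientation tests."""
    return mesh.vertices.mean(axis=0)


def nearest_distances(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance to the nearest target point."""
    points = np.atleast_2d(np.asarray(points, float))
    targets = np.atleast_2d(np.asarray(targets, float))
    if len(points) == 0 or len(targets) == 0:
        raise PlatePlanError("nearest_distances requires non-empty point sets")
    d, _ = cKDTree(targets).query(points)
    return d


def winding_numbers(points: np.ndarray, mesh: TriMesh, chunk: int = 4_000_000) -> np.ndarray:
    """Generalized winding number of each point w.r.t. the mesh surface.

    Sum of signed solid angles (van Oosterom & Strackee) over all faces,
    normalized by 4*pi; ~1 inside a closed outward-oriented surface, ~0 outside.
    """
    points = np.atleast_2d(np.asarray(points, float))
    tri = mesh.triangles()
    m = len(tri)
    out = np.empty(len(points))
    rows = max(1, int(chunk // max(m, 1)))
    for s in range(0, len(points), rows):
        p = points[s : s + rows]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        num = np.einsum("pmi,pmi->pm", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("pmi,pmi->pm", a, b) * lc
            + np.einsum("pmi,pmi->pm", b, c) * la
            + np.einsum("pmi,pmi->pm", a, c) * lb
        )
        out[s : s + rows] = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return out


def _ray_parity_inside(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    """Containment by ray-crossing parity, majority vote over 3 fixed rays."""
    tri = mesh.triangles()
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    dirs = np.array(
        [
            [0.57735027, 0.57735027, 0.57735027],
            [-0.21132487, 0.78867513, -0.57735027],
            [0.30459908, -0.89154411, 0.33526482],
        ]
    )
    votes = np.zeros(len(points), dtype=int)
    for d in dirs:
        h = np.cross(d, e2)  # (m,3)
        a = np.einsum("mi,mi->m", e1, h)
        ok = np.abs(a) > 1e-12
        crossings = np.zeros(len(points), dtype=int)
        s = points[:, None, :] - v0[None, :, :]  # (p,m,3)
        u = np.einsum("pmi,mi->pm", s, h) / np.where(ok, a, 1.0)
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pmi,i->pm", q, d) / np.where(ok, a, 1.0)
        t = np.einsum("pmi,mi->pm", q, e2) / np.where(ok, a, 1.0)
        hit = ok[None, :] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        crossings = hit.sum(axis=1)
        votes += crossings % 2
    return votes >= 2


def count_points_inside(points: np.ndarray, mesh: TriMesh) -> int:
    """Number of points strictly interior to the mesh surface.

    Uses the generalized winding number (threshold 0.5).  For non-watertight
    input, falls back to ray-parity with 3-ray majority voting and warns.
    """
    points = np.atleast_2d(np.asarray(points, float))
    if mesh.is_watertight():
        return int((winding_numbers(points, mesh) > 0.5).sum())
    log.warning("count_points_inside: mesh is not watertight, using ray-parity fallback")
    return int(_ray_parity_inside(points, mesh).sum())


# ---------------------------------------------------------------------------
# point-to-surface distance (used for contact searches)
# ---------------------------------------------------------------------------


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Elementwise point-triangle distances (Ericson's region method).

    ``points`` broadcasts against ``tri``: shapes (..., 3) and (..., 3, 3)
    give distances of shape (...).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    p = points
    ap = p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = va + vb + vc
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (vb / denom)[..., None]
    w = (vc / denom)[..., None]
    closest = a + v * ab + w * ac  # interior projection

    def _safe(num, den):
        return np.clip(num / np.where(np.abs(den) < 1e-300, 1.0, den), 0.0, 1.0)

    # region tests override the interior projection
    mask = ((d1 <= 0) & (d2 <= 0))[..., None]
    closest = np.where(mask, a, closest)
    mask = ((d3 >= 0) & (d4 <= d3))[..., None]
    closest = np.where(mask, b, closest)
    mask = ((d6 >= 0) & (d5 <= d6))[..., None]
    closest = np.where(mask, c, closest)
    t = _safe(d1, d1 - d3)[..., None]
    mask = ((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None]
    closest = np.where(mask, a + t * ab, closest)
    t = _safe(d2, d2 - d6)[..., None]
    mask = ((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None]
    closest = np.where(mask, a + t * ac, closest)
    t = _safe(d4 - d3, (d4 - d3) + (d5 - d6))[..., None]
    mask = ((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))[..., None]
    closest = np.where(mask, b + t * (c - b), closest)
    return np.linalg.norm(p - closest, axis=-1), closest


class SurfaceDistance:
    """Accelerated unsigned/signed point-to-surface distance for one mesh.

    Small faces are pruned with a KD-tree on their centroids (widened with
    the circumradius bound where needed); the handful of large faces (the
    osteotomy cap fans) are tested exhaustively, so the pruning radius stays
    tight.  The sign (negative inside) of a watertight, outward-oriented
    mesh comes from the angle-weighted pseudonormal of the closest surface
    feature (face / edge / vertex); non-watertight meshes fall back to
    ray-parity voting, with a logged warning.
    """

    _LARGE_R = 2.5  # mm circumradius separating brute-forced from tree faces

    def __init__(self, mesh: TriMesh):
        self.mesh = mesh
        self._tri = mesh.triangles()
        cent = self._tri.mean(axis=1)
        circum = np.linalg.norm(self._tri - cent[:, None, :], axis=2).max(axis=1)
        # bucket faces by circumradius: per-bucket KD-trees keep the
        # pruning bound tight where faces are fine; the few oversized faces
        # (the osteotomy cap fans) are tested exhaustively
        self._groups = []
        lo = 0.0
        for hi in (1.2, self._LARGE_R):
            ids = np.flatnonzero((circum > lo) & (circum <= hi))
            if len(ids):
                self._groups.append(
                    (ids, cKDTree(cent[ids]), float(circum[ids].max()))
                )
            lo = hi
        self._large = np.flatnonzero(circum > self._LARGE_R)
        self._watertight = mesh.is_watertight()
        self._pseudo = None  # built lazily for signed queries

    # -- pseudonormals ------------------------------------------------------

    def _build_pseudonormals(self):
        v, f = self.mesh.vertices, self.mesh.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(fn, axis=1, keepdims=True)
        fn = fn / np.where(norm > 0, norm, 1.0)
        vert_n = np.zeros_like(v)
        for c in range(3):
            i = f[:, c]
            e1 = v[f[:, (c + 1) % 3]] - v[i]
            e2 = v[f[:, (c + 2) % 3]] - v[i]
            cosang = np.einsum("ij,ij->i", e1, e2) / (
                np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(vert_n, i, ang[:, None] * fn)
        # edge pseudonormals: sum of the two incident face normals, keyed by
        # the sorted vertex pair packed into one integer
        nv = len(v)
        pairs = []
        for a, b in ((0, 1), (1, 2), (2, 0)):
            lo = np.minimum(f[:, a], f[:, b])
            hi = np.maximum(f[:, a], f[:, b])
            pairs.append(lo * nv + hi)
        keys = np.concatenate(pairs)
        normals3 = np.vstack([fn, fn, fn])
        ukeys, inv = np.unique(keys, return_inverse=True)
        edge_n = np.zeros((len(ukeys), 3))
        np.add.at(edge_n, inv, normals3)
        self._pseudo = (fn, vert_n, ukeys, edge_n)

    def vertex_pseudonormals(self) -> np.ndarray:
        """Angle-weighted vertex pseudonormals (unnormalized)."""
        if self._pseudo is None:
            self._build_pseudonormals()
        return self._pseudo[1]

    def _sign_from_features(self, points, cp, face_ids) -> np.ndarray:
        """+1 outside / -1 inside via the closest feature's pseudonormal
        (Baerentzen's angle-weighted construction), vectorized."""
        if self._pseudo is None:
            self._build_pseudonormals()
        fn, vert_n, ukeys, edge_n = self._pseudo
        v, f = self.mesh.vertices, self.mesh.faces
        tri_ids = f[face_ids]  # (n,3)
        tri = v[tri_ids]  # (n,3,3)
        # barycentric coordinates of the closest points
        e1 = tri[:, 1] - tri[:, 0]
        e2 = tri[:, 2] - tri[:, 0]
        q = cp - tri[:, 0]
        d11 = np.einsum("ij,ij->i", e1, e1)
        d12 = np.einsum("ij,ij->i", e1, e2)
        d22 = np.einsum("ij,ij->i", e2, e2)
        q1 = np.einsum("ij,ij->i", q, e1)
        q2 = np.einsum("ij,ij->i", q, e2)
        det = np.maximum(d11 * d22 - d12 * d12, 1e-300)
        b1 = (d22 * q1 - d12 * q2) / det
        b2 = (d11 * q2 - d12 * q1) / det
        bary = np.column_stack([1.0 - b1 - b2, b1, b2])
        on = bary > 1e-9
        n_on = on.sum(axis=1)
        normal = fn[face_ids].copy()  # face case (all three positive)
        # vertex case: only one barycentric coordinate positive
        mask = n_on == 1
        if mask.any():
            vid = tri_ids[mask][on[mask]]
            normal[mask] = vert_n[vid]
        # edge case: exactly one coordinate ~0
        mask = n_on == 2
        if mask.any():
            ids = tri_ids[mask]
            onm = on[mask]
            a = np.where(~onm[:, 0], ids[:, 1], ids[:, 0])
            b = np.where(~onm[:, 2], ids[:, 1], ids[:, 2])
            key = np.minimum(a, b) * len(v) + np.maximum(a, b)
            normal[mask] = edge_n[np.searchsorted(ukeys, key)]
        side = np.einsum("ij,ij->i", normal, points - cp)
        return np.where(side >= 0, 1.0, -1.0)

    # -- queries ------------------------------------------------------------

    def _closest(self, points: np.ndarray):
        """(distance, closest_point, face_id) for each query point.

        Tiered candidate search: k-NN over small-face centroids with k
        escalating only for points whose bound (k-th centroid distance
        minus the maximum small-face circumradius) is not yet conclusive,
        then an exact ball query for the rare leftovers.
        """
        points = np.atleast_2d(np.asarray(points, float))
        n = len(points)
        best = np.full(n, np.inf)
        best_cp = np.zeros((n, 3))
        best_face = np.zeros(n, dtype=np.int64)

        def consider(sel, d, cp, faces):
            better = d < best[sel]
            ids = sel[better] if sel.dtype.kind == "i" else np.flatnonzero(sel)[better]
            best[ids] = d[better]
            best_cp[ids] = cp[better]
            best_face[ids] = faces[better]

        for ids_g, tree, rmax in self._groups:
            remaining = np.arange(n)
            for k in (16, 128):
                k_eff = min(k, len(ids_g))
                pts = points[remaining]
                d0, idx = tree.query(pts, k=k_eff)
                d0 = d0.reshape(len(pts), k_eff)
                idx = idx.reshape(len(pts), k_eff)
                cand = ids_g[idx]
                d, cp = _point_triangle_distance(pts[:, None, :], self._tri[cand])
                j = d.argmin(axis=1)
                rows = np.arange(len(pts))
                consider(remaining, d[rows, j], cp[rows, j], cand[rows, j])
                # unexamined faces of this group cannot beat the incumbent
                # once the k-th centroid is beyond best + circumradius
                proven = d0[:, -1] >= best[remaining] + rmax
                remaining = remaining[~proven]
                if len(remaining) == 0 or k_eff == len(ids_g):
                    remaining = remaining[:0] if k_eff == len(ids_g) else remaining
                    break
            for i in remaining:
                more = ids_g[tree.query_ball_point(points[i], best[i] + rmax)]
                if len(more):
                    dm, cpm = _point_triangle_distance(points[i], self._tri[more])
                    jm = dm.argmin()
                    if dm[jm] < best[i]:
                        best[i] = dm[jm]
                        best_cp[i] = cpm[jm]
                        best_face[i] = more[jm]
        if len(self._large):
            d, cp = _point_triangle_distance(
                points[:, None, :], self._tri[self._large][None, :, :, :]
            )
            j = d.argmin(axis=1)
            rows = np.arange(n)
            better = d[rows, j] < best
            best = np.where(better, d[rows, j], best)
            best_cp = np.where(better[:, None], cp[rows, j], best_cp)
            best_face = np.where(better, self._large[j], best_face)
        return best, best_cp, best_face

    def unsigned(self, points: np.ndarray) -> np.ndarray:
        return self._closest(points)[0]

    def signed(self, points: np.ndarray, band: float | None = None) -> np.ndarray:
        """Positive outside, negative inside.

        With ``band`` set, the sign is only resolved for points within that
        distance of the surface; farther points are reported positive (valid
        for contact searches, where deep-interior states never arise).
        """
        points = np.atleast_2d(np.asarray(points, float))
        d, cp, fid = self._closest(points)
        sign = np.ones(len(points))
        sel = np.arange(len(points)) if band is None else np.flatnonzero(d < band)
        if len(sel):
            if self._watertight:
                sign[sel] = self._sign_from_features(points[sel], cp[sel], fid[sel])
            else:
                log.warning("signed distance on a non-watertight mesh: ray parity")
                sign[sel] = np.where(
                    _ray_parity_inside(points[sel], self.mesh), -1.0, 1.0
                )
        return sign * d
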