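"""Synthetic radius-like bones and T-shaped volar plates with known ground
truth, so every pipeline stage is testable without clinical data.

The bone is a lofted tube in the canonical frame (distal +Z, volar +X,
styloid side +Y).  Cross-sections have a circular dorsal half of half-width
``b(z)`` and a volar half whose outline is exactly the parabola
``x(y) = a(z) * (1 - y^2 / b(z)^2)``; along a short prismatic metaphyseal
band the section is held at its maximum, so the most volar ("watershed")
crest is the closed-form curve ``x(y) = a_max (1 - y^2 / b_max^2)`` with a
known Z-plateau — an analytic oracle for the watershed extraction.  Two
oblique planar osteotomy cuts are capped with triangle fans whose facets are
an order of magnitude larger than the median face, the signature the plane
detector keys on.  A shifted distal taper ends in a +Y apex vertex (the
styloid), which is the most distal vertex by construction.

The plate is a watertight gridded T-slab with a proximal tip vertex and an
optional cylindrical transverse bend; its corner landmarks are emitted
exactly.

Statistical realism of radius anatomy is a non-goal; the generator exists to
exhibit every geometric feature the placement algorithm keys on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frame import RigidPose
from .mesh_core import Plane, PlatePlanError, TriMesh


class GenerationError(PlatePlanError):
    """Spec describes an impossible / self-intersecting shape."""


@dataclass(frozen=True)
class SyntheticBoneSpec:
    length: float = 230.0  # the 40 mm distal cutoff is ~17% of this
    shaft_radius: float = 8.0
    distal_flare: float = 1.55  # transverse half-width multiplier at the metaphysis
    styloid_height: float = 10.0  # distal taper length ending in the styloid apex
    ridge_height: float = 2.5  # volar crest prominence above the shaft line
    cut_z_levels: tuple[float, float] = (90.0, 86.0)  # (distal, proximal)
    cut_tilt_deg: float = 8.0
    seed: int = 0
    n_theta: int = 40
    noise_mm: float = 0.05

    def validate(self):
        lo, hi = min(self.cut_z_levels), max(self.cut_z_levels)
        half = self.length / 2.0
        band_lo = half - self.styloid_height - 8.0
        if self.length <= 0 or self.shaft_radius <= 0:
            raise GenerationError("length and shaft_radius must be positive")
        if self.distal_flare <= 1.0 or self.ridge_height <= 0:
            raise GenerationError("flare must be > 1 and ridge_height > 0")
        if not (-half + 30.0 < lo < hi < band_lo - 4.0):
            raise GenerationError("cut levels must lie inside the shaft")
        if hi - lo < 1.0:
            raise GenerationError("osteotomy gap must be at least 1 mm")
        if abs(self.cut_tilt_deg) > 30.0:
            raise GenerationError("cut tilt beyond 30 degrees is not supported")
        if self.n_theta < 12:
            raise GenerationError("n_theta too small")


@dataclass(frozen=True)
class SyntheticPlateSpec:
    length: float = 58.0
    head_width: float = 20.0
    shaft_width: float = 11.0
    thickness: float = 2.4
    # anatomically contoured: matches the constant volar transverse
    # curvature of the default bone (precontoured plates sit flush)
    curvature_radius: float | None = 18.0  # None -> flat plate
    head_height: float = 12.0
    grid_mm: float = 2.0
    grid_jitter: float = 0.3  # interior-node jitter as a fraction of spacing
    seed: int = 0

    def validate(self):
        if min(self.length, self.head_width, self.shaft_width, self.thickness) <= 0:
            raise GenerationError("plate dimensions must be positive")
        if self.head_width <= self.shaft_width:
            raise GenerationError("head must be wider than the shaft")
        if self.curvature_radius is not None and (
            self.curvature_radius <= self.head_width / 2.0
        ):
            raise GenerationError("curvature radius smaller than the half head width")
        if self.head_height >= self.length / 2.0:
            raise GenerationError("head too tall for the plate length")


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference data consistent with a generated mesh."""

    frame_axes: np.ndarray  # (3,3) rows = x, y, z
    distal_plane: Plane | None = None
    proximal_plane: Plane | None = None
    watershed_y: np.ndarray | None = None  # dense samples of the crest
    watershed_x: np.ndarray | None = None
    watershed_z_range: tuple[float, float] | None = None
    styloid: np.ndarray | None = None
    corners: dict | None = None  # plate: top_left / top_right / bottom
    plate_length: float | None = None


# ---------------------------------------------------------------------------
# bone
# ---------------------------------------------------------------------------


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)




def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


class _MeshBuilder:
    def __init__(self):
        self.verts: list[np.ndarray] = []
        self.faces: list[tuple[int, int, int]] = []

    def add_ring(self, pts: np.ndarray) -> np.ndarray:
        start = len(self.verts)
        self.verts.extend(pts)
        return np.arange(start, start + len(pts))

    def add_vertex(self, p: np.ndarray) -> int:
        self.verts.append(np.asarray(p, float))
        return len(self.verts) - 1

    def connect_rings(self, lo: np.ndarray, hi: np.ndarray):
        n = len(lo)
        for j in range(n):
            k = (j + 1) % n
            self.faces.append((lo[j], lo[k], hi[k]))
            self.faces.append((lo[j], hi[k], hi[j]))

    def fan(self, center: int, ring: np.ndarray, upward: bool):
        n = len(ring)
        for j in range(n):
            k = (j + 1) % n
            if upward:
                self.faces.append((center, ring[j], ring[k]))
            else:
                self.faces.append((center, ring[k], ring[j]))

    def finish(self) -> tuple[np.ndarray, np.ndarray]:
        v = np.asarray(self.verts, float)
        f = np.asarray(self.faces, np.int64)
        if _signed_volume(v, f) < 0:
            f = f[:, ::-1]
        return v, f


def _bone_sections(spec: SyntheticBoneSpec):
    """Closure returning (a(z), w(z)) of the cross-section profile.

    The volar apex height ``a`` is tied to the half-width ``w`` so that the
    volar transverse curvature radius ``w^2 / 2a`` is the same at every
    level: a_shaft = ridge_height / (flare^2 - 1), a_max = a_shaft *
    flare^2, hence the crest rises exactly ``ridge_height`` above the
    shaft's volar line and a single plate bend conforms along the bone.
    """
    half = spec.length / 2.0
    z2 = half - spec.styloid_height  # top of the metaphyseal band
    z1 = z2 - 8.0  # bottom of the band
    z_f0 = z1 - 45.0  # flare onset
    zc = 0.5 * (z1 + z2)
    droop = 0.8  # mm of crest droop toward the band edges, localizes the crest
    a_shaft = spec.ridge_height / (spec.distal_flare**2 - 1.0)

    a_max = a_shaft * spec.distal_flare**2

    def aw(z):
        z = np.asarray(z, float)
        # linear volar crest line along the flare ramp: a straight plate
        # can then lie flush on the ramp (the transverse curvature w^2/2a
        # stays constant because w follows as sqrt of a)
        s = np.clip((z - z_f0) / (z1 - z_f0), 0.0, 1.0)
        # crest droop: zero at the band center (localizing the crest),
        # maximal at the band edges, fading out within two band widths so
        # the rest of the profile is untouched
        u = np.abs(z - zc) / (0.5 * (z2 - z1))
        dip = droop * np.where(u <= 1.0, u**2, np.maximum(0.0, 1.0 - (u - 1.0) / 2.0))
        a = a_shaft + (a_max - a_shaft) * s - dip
        w = spec.shaft_radius * np.sqrt(np.maximum(a + dip, 1e-9) / a_shaft)
        return a, w

    return aw, z1, z2


def _column_params(n: int):
    """Per-column parameters: volar columns (fraction u of the half-width)
    followed by dorsal columns (angle phi), ordered around the ring."""
    n_v = max(12, (2 * n) // 5)
    n_d = n - n_v
    u = np.linspace(1.0, -1.0, n_v)
    phi = -np.pi / 2.0 - np.arange(1, n_d + 1) * np.pi / (n_d + 1)
    return u, phi


def _ring_points(a_col, w_col, u, phi, z_col) -> np.ndarray:
    """Cross-section outline points, one per column.

    Volar half (columns parametrized by the half-width fraction ``u``): the
    parabola ``x = a (1 - u^2)``, ``y = u w`` — a flat volar cortex.
    Dorsal half (columns parametrized by angle ``phi``): a half-circle of
    radius ``w``.  ``a``/``w``/``z_col`` may be scalars or per-column.
    """
    n = len(u) + len(phi)
    a_col = np.broadcast_to(np.asarray(a_col, float), (n,))
    w_col = np.broadcast_to(np.asarray(w_col, float), (n,))
    n_v = len(u)
    xv = a_col[:n_v] * (1.0 - u**2)
    yv = u * w_col[:n_v]
    xd = w_col[n_v:] * np.cos(phi)
    yd = w_col[n_v:] * np.sin(phi)
    x = np.concatenate([xv, xd])
    y = np.concatenate([yv, yd])
    return np.column_stack([x, y, np.broadcast_to(z_col, (n,))])


def _cut_ring(spec: SyntheticBoneSpec, u, phi, level: float, aw) -> np.ndarray:
    """Ring of surface points lying exactly on the plane z = level + m*x."""
    m = np.tan(np.deg2rad(spec.cut_tilt_deg))
    n = len(u) + len(phi)
    z = np.full(n, float(level))
    pts = None
    for _ in range(4):
        a, w = aw(z)
        pts = _ring_points(a, w, u, phi, z)
        z = level + m * pts[:, 0]
    pts[:, 2] = level + m * pts[:, 0]
    return pts


def _stations(start: float, stop: float, segments) -> np.ndarray:
    """Nominal z levels: [(z_to, dz), ...] piecewise spacing, inclusive ends."""
    zs = [start]
    z = start
    for z_to, dz in segments:
        while z + dz < min(z_to, stop) - 1e-9:
            z += dz
            zs.append(z)
        if z_to <= stop and z_to - zs[-1] > 0.25 * dz:
            zs.append(min(z_to, stop))
            z = zs[-1]
    if stop - zs[-1] > 1e-9:
        zs.append(stop)
    return np.unique(np.asarray(zs))


def make_bone(spec: SyntheticBoneSpec = SyntheticBoneSpec()) -> tuple[TriMesh, GroundTruth]:
    """Generate the two-fragment osteotomized bone and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    half = spec.length / 2.0
    aw, z1, z2 = _bone_sections(spec)
    u_col, phi_col = _column_params(spec.n_theta)
    cut_hi, cut_lo = max(spec.cut_z_levels), min(spec.cut_z_levels)
    styloid_y = 0.6 * spec.shaft_radius
    apex_distal = np.array([0.0, styloid_y, half])

    n_v = len(u_col)
    du = float(u_col[0] - u_col[1])
    dphi = float(phi_col[0] - phi_col[1])

    def surface_ring(z_per_col) -> np.ndarray:
        # irregular sampling like a decimated CT segmentation: jitter the
        # surface parameters per vertex (points stay exactly on the
        # analytic surface), so no artificial vertex lattice forms
        z_j = np.broadcast_to(z_per_col, (spec.n_theta,)) + np.clip(
            rng.normal(0.0, 0.1, spec.n_theta), -0.2, 0.2
        )
        u_j = u_col + rng.uniform(-0.25, 0.25, n_v) * du
        u_j[0], u_j[-1] = u_col[0], u_col[-1]
        phi_j = phi_col + rng.uniform(-0.25, 0.25, len(phi_col)) * dphi
        a, w = aw(z_j)
        return _ring_points(a, w, u_j, phi_j, z_j)

    frozen: list[np.ndarray] = []  # vertex ids excluded from jitter

    # ---- proximal fragment: cone base .. tilted cut at cut_lo -------------
    bld = _MeshBuilder()
    apex_prox = bld.add_vertex([0.0, 0.0, -half])
    cone_base_z = -half + 8.0
    prev = None
    a0, w0 = aw(cone_base_z)
    for s in (0.35, 0.65, 0.9):
        ring = bld.add_ring(
            _ring_points(a0 * s, w0 * s, u_col, phi_col, -half + 8.0 * s)
        )
        if prev is None:
            bld.fan(apex_prox, ring, upward=False)
        else:
            bld.connect_rings(prev, ring)
        prev = ring
    cut_ring_lo = _cut_ring(spec, u_col, phi_col, cut_lo, aw)
    levels = _stations(cone_base_z, cut_lo, [(40.0, 1.8), (cut_lo, 0.58)])
    frac = (levels - cone_base_z) / (cut_lo - cone_base_z)
    for fk in frac:
        z_per = (1.0 - fk) * cone_base_z + fk * cut_ring_lo[:, 2]
        pts = surface_ring(z_per) if fk < 1.0 else cut_ring_lo
        ring = bld.add_ring(pts)
        bld.connect_rings(prev, ring)
        prev = ring
        if fk == 1.0:
            frozen.append(ring)
    cap_center = bld.add_vertex(cut_ring_lo.mean(axis=0))
    frozen.append(np.array([cap_center]))
    bld.fan(cap_center, prev, upward=True)
    v1, f1 = bld.finish()

    # ---- distal fragment: tilted cut at cut_hi .. styloid apex ------------
    bld = _MeshBuilder()
    cut_ring_hi = _cut_ring(spec, u_col, phi_col, cut_hi, aw)
    ring = bld.add_ring(cut_ring_hi)
    frozen2: list[np.ndarray] = [ring]
    cap_center = bld.add_vertex(cut_ring_hi.mean(axis=0))
    frozen2.append(np.array([cap_center]))
    bld.fan(cap_center, ring, upward=False)
    prev = ring
    levels = _stations(cut_hi, z2, [(z1, 0.5), (z2, 0.5)])
    frac = (levels - cut_hi) / (z2 - cut_hi)
    for fk in frac[1:]:
        z_per = (1.0 - fk) * cut_ring_hi[:, 2] + fk * z2
        ring = bld.add_ring(surface_ring(z_per))
        bld.connect_rings(prev, ring)
        prev = ring
    a2, w2 = aw(z2)
    # the asymmetric section puts the vertex mean dorsal of the axis; shift
    # the taper so the styloid apex sits on +Y as seen from the centroid,
    # which is how the standardized frame pins its Y-axis
    cx = float(np.concatenate([v1[:, 0], np.asarray(bld.verts)[:, 0]]).mean())
    apex_distal = np.array([cx, styloid_y, half])
    for s in (0.06, 0.14, 0.24, 0.36, 0.5, 0.65, 0.8, 0.92):
        scale = (1.0 - s) ** 0.9
        shift = _smoothstep(s)
        pts = _ring_points(
            a2 * scale, w2 * scale, u_col, phi_col, z2 + s * (half - z2)
        )
        pts[:, 0] += cx * shift
        pts[:, 1] += styloid_y * shift
        ring = bld.add_ring(pts)
        bld.connect_rings(prev, ring)
        prev = ring
    apex = bld.add_vertex(apex_distal)
    frozen2.append(np.array([apex]))
    bld.fan(apex, prev, upward=True)
    v2, f2 = bld.finish()

    # ---- merge, jitter, ground truth --------------------------------------
    verts = np.vstack([v1, v2])
    faces = np.vstack([f1, f2 + len(v1)])
    keep_exact = np.zeros(len(verts), dtype=bool)
    for ids in frozen:
        keep_exact[ids] = True
    for ids in frozen2:
        keep_exact[ids + len(v1)] = True
    keep_exact[apex + len(v1)] = True
    if spec.noise_mm > 0:
        radial = verts[:, :2].copy()
        norm = np.linalg.norm(radial, axis=1, keepdims=True)
        radial = np.where(norm > 1e-9, radial / np.maximum(norm, 1e-9), 0.0)
        jitter = rng.normal(0.0, spec.noise_mm, size=len(verts))[:, None] * radial
        jitter[keep_exact] = 0.0
        verts = verts + np.column_stack([jitter, np.zeros(len(verts))])

    # center on the vertex mean: the standardized frame puts the origin at
    # the mesh centroid and pins +Y through the styloid as seen from it, so
    # the emitted bone (and its ground truth) use the same origin
    center = verts.mean(axis=0)
    verts = verts - center
    mesh = TriMesh(verts, faces)
    normal = np.array([-np.sin(np.deg2rad(spec.cut_tilt_deg)), 0.0,
                       np.cos(np.deg2rad(spec.cut_tilt_deg))])
    a_shaft = spec.ridge_height / (spec.distal_flare**2 - 1.0)
    a_max = a_shaft * spec.distal_flare**2
    b_max = spec.shaft_radius * spec.distal_flare
    y_gt = np.linspace(-0.995 * b_max, 0.995 * b_max, 801)
    gt = GroundTruth(
        frame_axes=np.eye(3),
        distal_plane=Plane(cut_ring_hi.mean(axis=0) - center, normal),
        proximal_plane=Plane(cut_ring_lo.mean(axis=0) - center, normal),
        watershed_y=y_gt - center[1],
        watershed_x=a_max * (1.0 - y_gt**2 / b_max**2) - center[0],
        watershed_z_range=(z1 - center[2], z2 - center[2]),
        styloid=apex_distal - center,
    )
    return mesh, gt


# ---------------------------------------------------------------------------
# plate
# ---------------------------------------------------------------------------


def make_plate(spec: SyntheticPlateSpec = SyntheticPlateSpec()) -> tuple[TriMesh, GroundTruth]:
    """Generate the T-shaped plate (centered on its vertex mean)."""
    spec.validate()
    L, hw, sw, th = spec.length, spec.head_width, spec.shaft_width, spec.thickness
    tip_len = min(6.0, 0.15 * L)
    z_lo, z_hi = -L / 2.0 + tip_len, L / 2.0
    nz = max(2, int(round((z_hi - z_lo) / spec.grid_mm))) + 1
    z_nodes = np.linspace(z_lo, z_hi, nz)
    ny = max(2, int(round(hw / spec.grid_mm))) + 1
    y_nodes = np.unique(
        np.concatenate(
            [np.linspace(-hw / 2.0, hw / 2.0, ny), [-sw / 2.0, sw / 2.0]]
        )
    )

    def inside(yc, zc):
        limit = hw / 2.0 if zc >= z_hi - spec.head_height else sw / 2.0
        return abs(yc) <= limit + 1e-9

    n_y, n_z = len(y_nodes), len(z_nodes)
    node_id = -np.ones((n_y, n_z), dtype=int)
    pts2d = []
    cells = []
    for i in range(n_y - 1):
        for j in range(n_z - 1):
            yc = 0.5 * (y_nodes[i] + y_nodes[i + 1])
            zc = 0.5 * (z_nodes[j] + z_nodes[j + 1])
            if inside(yc, zc):
                cells.append((i, j))
                for a, b in ((i, j), (i + 1, j), (i + 1, j + 1), (i, j + 1)):
                    if node_id[a, b] < 0:
                        node_id[a, b] = len(pts2d)
                        pts2d.append((y_nodes[a], z_nodes[b]))
    pts2d = np.asarray(pts2d)
    # jitter interior nodes so the surfaces carry no regular vertex lattice
    # (commercial plate meshes are irregular); boundary nodes stay exact so
    # the corner landmarks and outline are unchanged
    rng = np.random.default_rng(spec.seed)
    cellset = set(cells)
    dz = (z_hi - z_lo) / (n_z - 1)
    for i in range(1, n_y - 1):
        for j in range(1, n_z - 1):
            nid = node_id[i, j]
            if nid < 0:
                continue
            if all(
                (a, b) in cellset
                for a, b in ((i - 1, j - 1), (i - 1, j), (i, j - 1), (i, j))
            ):
                dy = min(y_nodes[i] - y_nodes[i - 1], y_nodes[i + 1] - y_nodes[i])
                pts2d[nid, 0] += rng.uniform(-spec.grid_jitter, spec.grid_jitter) * dy
                pts2d[nid, 1] += rng.uniform(-spec.grid_jitter, spec.grid_jitter) * dz
    tip2d = len(pts2d)
    pts2d = np.vstack([pts2d, [0.0, -L / 2.0]])

    tris2d = []
    for i, j in cells:
        a, b, c, d = node_id[i, j], node_id[i + 1, j], node_id[i + 1, j + 1], node_id[i, j + 1]
        tris2d.append((a, b, c))
        tris2d.append((a, c, d))
    # proximal tip fan over the lowest shaft edge
    edge = [
        node_id[i, 0]
        for i in range(n_y)
        if node_id[i, 0] >= 0 and abs(y_nodes[i]) <= sw / 2.0 + 1e-9
    ]
    edge = sorted(edge, key=lambda k: pts2d[k, 0])
    for a, b in zip(edge[:-1], edge[1:]):
        tris2d.append((b, a, tip2d))
    tris2d = np.asarray(tris2d, np.int64)

    n_pts = len(pts2d)
    top = np.column_stack([np.full(n_pts, th / 2.0), pts2d[:, 0], pts2d[:, 1]])
    bot = np.column_stack([np.full(n_pts, -th / 2.0), pts2d[:, 0], pts2d[:, 1]])
    # chisel tip: both surfaces taper to a single bone-facing tip vertex,
    # like the tapered insertion tip of a real plate
    top[tip2d, 0] = -th / 2.0
    verts = np.vstack([top, bot])
    faces = [tris2d, tris2d[:, ::-1] + n_pts]
    # boundary walls: directed edges of the top surface used exactly once
    edges = {}
    for t in tris2d:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            if (b, a) in edges:
                edges.pop((b, a))
            else:
                edges[(a, b)] = True
    wall = []
    for a, b in edges:
        wall.append((b, a, a + n_pts))
        wall.append((b, a + n_pts, b + n_pts))
    faces.append(np.asarray(wall, np.int64))
    faces = np.vstack(faces)
    # merge the duplicate tip vertex and drop the collapsed seam triangles
    faces = np.where(faces == tip2d + n_pts, tip2d, faces)
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[ok]
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = verts[used]
    faces = remap[faces]
    if _signed_volume(verts, faces) < 0:
        faces = faces[:, ::-1]

    if spec.curvature_radius is not None:
        rc = spec.curvature_radius
        verts[:, 0] += np.sqrt(rc**2 - verts[:, 1] ** 2) - rc

    centroid = verts.mean(axis=0)
    verts = verts - centroid

    def bend(y):
        if spec.curvature_radius is None:
            return 0.0
        return float(np.sqrt(spec.curvature_radius**2 - y**2) - spec.curvature_radius)

    corners = {
        "top_left": np.array([-th / 2.0 + bend(-hw / 2.0), -hw / 2.0, L / 2.0]) - centroid,
        "top_right": np.array([-th / 2.0 + bend(hw / 2.0), hw / 2.0, L / 2.0]) - centroid,
        "bottom": np.array([-th / 2.0, 0.0, -L / 2.0]) - centroid,
    }
    gt = GroundTruth(frame_axes=np.eye(3), corners=corners, plate_length=L)
    return TriMesh(verts, faces), gt


# ---------------------------------------------------------------------------
# pose perturbation (for pose-recovery experiments)
# ---------------------------------------------------------------------------


def perturb_pose(
    pose: RigidPose, max_rot_deg: float, max_trans_mm: float, seed: int
) -> RigidPose:
    """Uniform per-axis perturbation of the pose parameters; deterministic."""
    if max_rot_deg < 0 or max_trans_mm < 0:
        raise PlatePlanError("perturbation magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    d_rot = rng.uniform(-max_rot_deg, max_rot_deg, 3)
    d_tr = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    return RigidPose(pose.rotation + d_rot, pose.translation + d_tr)
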