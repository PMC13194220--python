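"""Deterministic initial plate pose on the volar distal radius (step c).

Five sub-steps, applied in order:

1. overlap the plate's alignment line with the bone's alignment line;
2. translate along Z until both top corners lie at least ``margin`` (2 mm)
   below the watershed line;
3. rotate about the plate's center line until the bottom point contacts the
   bone surface;
4. rotate about the plate's long axis to align the top corners with the
   watershed X-values;
5. translate toward the bone until the first vertex touches the surface.

Because sub-steps 3-5 can slightly perturb the watershed margin achieved in
sub-step 2, a short polish loop re-applies the downward Z correction and the
contact translation until both hold; the routine is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .frame import RigidPose
from .landmarks import BoneLandmarks, PlateLandmarks, watershed_interp
from .mesh_core import PlatePlanError, SurfaceDistance, TriMesh


class NoContactError(PlatePlanError):
    """Rotation search found no bone contact within +/- 90 degrees."""


class CoverageError(PlatePlanError):
    """Watershed line too short to cover the plate's Y-extent."""


@dataclass(frozen=True)
class InitialPlacement:
    pose: RigidPose
    contact_vertex: int
    watershed_margin: float


def _rot_about_axis(axis: np.ndarray, angle_deg: float, center: np.ndarray):
    """(R, t) of a rotation about an axis through ``center``."""
    r = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    return r, center - r @ center


def _min_rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(a @ b)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # pick any axis orthogonal to a for the 180 degree case
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _golden_min(fun, lo: float, hi: float, iters: int = 48) -> float:
    """Golden-section minimizer on [lo, hi]; deterministic."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(iters):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def _bisect_root(fun, lo: float, hi: float, tol: float) -> float:
    flo = fun(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = fun(mid)
        if abs(fm) <= tol or (hi - lo) < 1e-12:
            return mid
        if (flo < 0) == (fm < 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def initial_place(
    bone_lm: BoneLandmarks,
    plate_lm: PlateLandmarks,
    bone: TriMesh,
    plate: TriMesh,
    margin: float = 2.0,
    contact_tol: float = 0.05,
) -> InitialPlacement:
    """Compose the five deterministic sub-steps into the initial pose."""
    surf = SurfaceDistance(bone)
    ws = bone_lm.watershed
    ws_ymin, ws_ymax = ws[0, 1], ws[-1, 1]

    # The bottom landmark is the outermost tip vertex; contact must be
    # probed on the bone-facing side of the bottom end, or the plate's own
    # thickness would register as penetration whenever the landmark touches.
    bottom_region = plate.vertices[
        np.linalg.norm(plate.vertices - plate_lm.bottom, axis=1) <= 4.0
    ]

    def corners(r, t):
        return (
            r @ plate_lm.top_left + t,
            r @ plate_lm.top_right + t,
            r @ plate_lm.bottom + t,
        )

    # -- step 1: overlap alignment lines ------------------------------------
    r = _min_rotation_between(
        plate_lm.alignment_line.direction, bone_lm.alignment_line.direction
    )
    t = bone_lm.alignment_line.point - r @ plate_lm.centroid

    # -- step 2: Z-translation for the watershed margin ---------------------
    tl, tr, _ = corners(r, t)
    for cy in (tl[1], tr[1]):
        if cy < ws_ymin - 2.0 or cy > ws_ymax + 2.0:
            raise CoverageError(
                f"plate corner at y = {cy:.1f} outside watershed span "
                f"[{ws_ymin:.1f}, {ws_ymax:.1f}]"
            )
    dz = min(
        float(watershed_interp(ws, c[1], 2)) - margin - c[2] for c in (tl, tr)
    )
    t = t + np.array([0.0, 0.0, dz])

    # -- step 3: rotate about the center line until bottom contact ----------
    def bottom_contact_dist(r, t):
        pts = bottom_region @ r.T + t
        return float(surf.signed(pts, band=8.0).min())

    def rotate_bottom_to_contact(r, t):
        axis = r @ plate_lm.alignment_line.direction
        center = r @ plate_lm.centroid + t
        base = bottom_region @ r.T + t

        def bottom_dist(angle):
            rr, tt = _rot_about_axis(axis, angle, center)
            return float(surf.signed(base @ rr.T + tt, band=8.0).min())

        if abs(bottom_dist(0.0)) <= 0.5 * contact_tol:
            return r, t
        grid = np.arange(-90.0, 90.0 + 1e-9, 2.0)
        rotated = np.concatenate(
            [
                base @ _rot_about_axis(axis, a, center)[0].T
                + _rot_about_axis(axis, a, center)[1]
                for a in grid
            ]
        )
        vals = (
            surf.signed(rotated, band=8.0)
            .reshape(len(grid), len(base))
            .min(axis=1)
        )
        sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
        if len(sign_change) == 0:
            raise NoContactError("bottom point never contacts the bone within ±90°")
        # interval closest to zero rotation
        mids = 0.5 * (grid[sign_change] + grid[sign_change + 1])
        k = sign_change[np.argmin(np.abs(mids))]
        angle = _bisect_root(bottom_dist, grid[k], grid[k + 1], tol=1e-3)
        rr, tt = _rot_about_axis(axis, angle, center)
        return rr @ r, rr @ t + tt

    r, t = rotate_bottom_to_contact(r, t)

    # -- step 4: align top corners with watershed X-values ------------------
    long_axis = r @ np.array([0.0, 0.0, 1.0])
    center = r @ plate_lm.centroid + t

    def corner_cost(angle):
        rr4, tt4 = _rot_about_axis(long_axis, angle, center)
        cost = 0.0
        for corner in (plate_lm.top_left, plate_lm.top_right):
            p = rr4 @ (r @ corner + t) + tt4
            wx = float(watershed_interp(ws, np.clip(p[1], ws_ymin, ws_ymax), 0))
            cost += (p[0] - wx) ** 2
        return cost

    angle4 = _golden_min(corner_cost, -30.0, 30.0)
    rr4, tt4 = _rot_about_axis(long_axis, angle4, center)
    r, t = rr4 @ r, rr4 @ t + tt4

    # -- step 5: approach along -X until first contact ----------------------
    def contact_shift(r, t):
        verts0 = plate.vertices @ r.T

        def min_signed(shift_x):
            return float(
                surf.signed(verts0 + t + np.array([shift_x, 0.0, 0.0]), band=8.0).min()
            )

        # the gap function is 1-Lipschitz in the shift, so the fixed-point
        # update s -> s - g(s) walks to the contact root in a few full
        # evaluations; bisection remains as the safety net
        s, g = 0.0, min_signed(0.0)
        if abs(g) <= 0.5 * contact_tol:
            return t
        s_prev, g_prev = s, g
        for _ in range(30):
            s = s - g
            if abs(s) > 60.0:
                raise NoContactError("no contact found along the approach direction")
            g = min_signed(s)
            if abs(g) <= 1e-3:
                return t + np.array([s, 0.0, 0.0])
            if (g < 0) != (g_prev < 0):
                lo, hi = min(s, s_prev), max(s, s_prev)
                s = _bisect_root(min_signed, lo, hi, tol=1e-3)
                return t + np.array([s, 0.0, 0.0])
            s_prev, g_prev = s, g
        raise NoContactError("contact iteration did not converge")

    t = contact_shift(r, t)

    # -- settle: restore bottom contact and margin without penetration ------
    # The contact translation can lift the bottom point off the shaft; a
    # bottom-contact rotation then swings the distal end away from the bone,
    # so alternating the two (with a downward Z correction whenever the
    # watershed margin is violated) converges to a seated pose.
    def margin_deficit(r, t):
        tl, tr, _ = corners(r, t)
        return min(
            float(watershed_interp(ws, np.clip(c[1], ws_ymin, ws_ymax), 2))
            - margin
            - c[2]
            for c in (tl, tr)
        )

    for _ in range(12):
        bdist = bottom_contact_dist(r, t)
        deficit = margin_deficit(r, t)
        if abs(bdist) <= contact_tol and deficit >= -1e-9:
            break
        if deficit < -1e-9:
            t = t + np.array([0.0, 0.0, deficit])
        r, t = rotate_bottom_to_contact(r, t)
        t = contact_shift(r, t)
    # closing Z-only correction: the last round's own contact operations can
    # leave a residual margin deficit of the order of the bisection
    # tolerance; a pure downward translation of that size restores the
    # margin while moving every contact distance by at most the same amount
    deficit = margin_deficit(r, t)
    if -0.5 < deficit < 0.0:
        t = t + np.array([0.0, 0.0, deficit])

    pose = RigidPose.from_matrix(r, t)
    placed = plate.vertices @ r.T + t
    dists = surf.signed(placed)
    contact_vertex = int(np.argmin(dists))
    tl, tr, _ = corners(r, t)
    margin_val = min(
        float(watershed_interp(ws, np.clip(c[1], ws_ymin, ws_ymax), 2)) - c[2]
        for c in (tl, tr)
    )
    return InitialPlacement(pose, contact_vertex, float(margin_val))
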