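"""Idealized biventricular anatomy bounded by truncated ellipsoids.

The left ventricle is the shell between two concentric ellipsoids; the
right ventricular free wall is the crescent between two larger, laterally
offset ellipsoids, clipped to the outside of the LV epicardium.  Both are
truncated by a basal plane (z = base_z, long axis along z, apex at -z).

Tissue membership is boundary-inclusive.  Distances and surface normals
are computed from the exact nearest point on each ellipsoid (bisection on
the standard one-parameter projection), good to ~1e-6 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_TOL = 1e-9


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (mm) and semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def implicit(self, points: np.ndarray) -> np.ndarray:
        """sum(((p - c)/s)^2); 1 on the surface, <1 inside."""
        q = (np.atleast_2d(points) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.einsum("ij,ij->i", q, q)

    def nearest_surface(self, points: np.ndarray):
        """Nearest surface point, distance and outward unit normal.

        Vectorized; exact for the generic case (degenerate on-axis interior
        points are perturbed by 1e-9 mm toward a unique projection).
        Returns (proj (n,3), dist (n,), normal (n,3)).
        """
        p = np.atleast_2d(points).astype(float)
        c = np.asarray(self.center, dtype=float)
        s2 = np.asarray(self.semi_axes, dtype=float) ** 2
        q = p - c
        i_min = int(np.argmin(s2))
        col = q[:, i_min]
        col[col == 0.0] = 1e-9
        q[:, i_min] = col

        def f(t):
            return np.sum(s2 * q**2 / (s2 + t[:, None]) ** 2, axis=1) - 1.0

        norm_q = np.linalg.norm(q, axis=1)
        s_max = np.sqrt(s2.max())
        t_lo = np.full(len(q), -s2.min() * (1.0 - 1e-14))
        t_hi = s_max * (norm_q + s_max)
        for _ in range(80):
            t_mid = 0.5 * (t_lo + t_hi)
            pos = f(t_mid) > 0
            t_lo = np.where(pos, t_mid, t_lo)
            t_hi = np.where(pos, t_hi, t_mid)
        t = 0.5 * (t_lo + t_hi)
        proj_local = s2 * q / (s2 + t[:, None])
        proj = proj_local + c
        dist = np.linalg.norm(p - proj, axis=1)
        grad = proj_local / s2
        normal = grad / np.linalg.norm(grad, axis=1, keepdims=True)
        return proj, dist, normal


# surfaces bounding each wall region, with the sign that turns the
# ellipsoid's outward normal into the inward-into-tissue direction
_LV_WALLS = (("lv_endo", +1), ("lv_epi", -1), ("base", 0))
_RV_WALLS = (("rv_endo", +1), ("rv_epi", -1), ("lv_epi", +1), ("base", 0))


@dataclass(frozen=True)
class VentricleAnatomy:
    """Four truncated-ellipsoid surfaces plus the basal truncation plane."""

    lv_endo: Ellipsoid = Ellipsoid((0.0, 0.0, 0.0), (25.5, 25.5, 49.5))
    lv_epi: Ellipsoid = Ellipsoid((0.0, 0.0, 0.0), (34.0, 34.0, 58.0))
    # the RV pair is offset right (-x) far enough that its +x closure stays
    # inside the LV epicardium: the free wall is then a true crescent with
    # no spurious shell beyond the left epicardial surface
    rv_endo: Ellipsoid = Ellipsoid((-14.0, 0.0, -2.0), (42.0, 37.0, 47.0))
    rv_epi: Ellipsoid = Ellipsoid((-14.0, 0.0, -2.0), (48.0, 42.0, 52.0))
    base_z: float = 10.0

    def validate(self) -> None:
        for endo, epi, name in ((self.lv_endo, self.lv_epi, "lv"),
                                (self.rv_endo, self.rv_epi, "rv")):
            gap = np.asarray(epi.semi_axes) - np.asarray(endo.semi_axes)
            off = np.asarray(epi.center) - np.asarray(endo.center)
            if np.any(gap <= np.abs(off)):
                raise ValueError(f"{name}_endo not strictly inside {name}_epi")

    def surface(self, name: str) -> Ellipsoid:
        return getattr(self, name)

    # -- membership -------------------------------------------------------

    def region(self, points: np.ndarray) -> np.ndarray:
        """0 outside tissue, 1 in the LV wall, 2 in the RV free wall."""
        p = np.atleast_2d(points)
        below = p[:, 2] <= self.base_z + _TOL
        e_lv_endo = self.lv_endo.implicit(p)
        e_lv_epi = self.lv_epi.implicit(p)
        lv = below & (e_lv_endo >= 1.0 - _TOL) & (e_lv_epi <= 1.0 + _TOL)
        e_rv_endo = self.rv_endo.implicit(p)
        e_rv_epi = self.rv_epi.implicit(p)
        rv = (below & ~lv & (e_rv_epi <= 1.0 + _TOL)
              & (e_rv_endo >= 1.0 - _TOL) & (e_lv_epi >= 1.0 - _TOL))
        return np.where(lv, 1, np.where(rv, 2, 0))

    def inside_tissue(self, points: np.ndarray):
        """Boundary-inclusive tissue membership (scalar in, scalar out)."""
        r = self.region(points)
        out = r > 0
        if np.ndim(points) == 1:
            return bool(out[0])
        return out

    # -- walls ------------------------------------------------------------

    def walls_for_region(self, region: int):
        if region == 1:
            return _LV_WALLS
        if region == 2:
            return _RV_WALLS
        raise ValueError("point outside tissue")

    def wall_normals_distances(self, points: np.ndarray, region: int):
        """Inward unit normals and distances to each bounding surface.

        Vectorized over points sharing one region.  Returns
        (normals (n, n_walls, 3), distances (n, n_walls)).
        """
        p = np.atleast_2d(points).astype(float)
        walls = self.walls_for_region(region)
        normals = np.zeros((len(p), len(walls), 3))
        dists = np.zeros((len(p), len(walls)))
        for k, (name, sign) in enumerate(walls):
            if name == "base":
                normals[:, k] = (0.0, 0.0, -1.0)
                dists[:, k] = self.base_z - p[:, 2]
            else:
                _, d, n = self.surface(name).nearest_surface(p)
                normals[:, k] = sign * n
                dists[:, k] = d
        return normals, np.maximum(dists, 0.0)

    def boundary_normals_and_distances(self, point: np.ndarray):
        """List of (inward unit normal, distance mm) for one tissue point."""
        region = int(self.region(point)[0])
        if region == 0:
            raise ValueError("point outside tissue")
        normals, dists = self.wall_normals_distances(point, region)
        return [(normals[0, k], float(dists[0, k])) for k in range(normals.shape[1])]

    # -- extents ----------------------------------------------------------

    def bounding_box(self, margin: float = 1.0):
        los, his = [], []
        for e in (self.lv_epi, self.rv_epi):
            c, s = np.asarray(e.center), np.asarray(e.semi_axes)
            los.append(c - s)
            his.append(c + s)
        lo = np.min(los, axis=0) - margin
        hi = np.max(his, axis=0) + margin
        hi[2] = self.base_z + margin
        return lo, hi
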