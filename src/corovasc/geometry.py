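"""Space-filling assignment of 3D coordinates to arterial tree nodes.

The three epicardial trunks are laid along parametric paths on the
epicardial surface (RCA wrapping the right atrioventricular groove, LAD
descending anteriorly from base to apex and wrapping it, LCX leaving the
LAD attachment and wrapping the left lateral wall).  Every other junction
is then processed root-outward:

1. initial daughter branching angles from parent/daughter radii and flows
   (law-of-cosines on vectors of magnitude Q/r^2, minimum-shear branching);
2. a self-avoidance vector summing decaying unit pulls away from the distal
   nodes of already-placed segments at least as large as the smaller
   daughter;
3. a boundary-avoidance vector summing inward wall normals weighted by
   exp(-d / 2L);
4. the two are combined, a branching plane normal constructed, and the
   daughter directions obtained by rotating the combined direction by
   +theta_L / -theta_R about it;
5. daughters landing outside tissue are nudged back along the violated-wall
   direction for up to 200 iterations; irreparable sub-trees are pruned.

Junctions of equal depth are processed as one vectorized batch; nodes
placed within the same batch do not see each other in the self-avoidance
sum (their interaction is dominated by the +-theta split at the shared
junction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anatomy import Ellipsoid, VentricleAnatomy
from .hemodynamics import PressureBoundary, solve
from .topology import Tree, subset_tree

# placement status codes
UNPLACED, PLACED, TRUNK, REPAIRED, PRUNED = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class AvoidanceParams:
    """Space-filling parameters.

    xi : avoidance exponent of the self-avoidance weight (default 2).
    c_s, c_b : combination weights of the self- and boundary-avoidance
        unit vectors (default 0.5 each).
    max_repair_iterations : budget of incremental boundary-repair steps.
    repair_step_fraction : step size as a fraction of the segment length.
    repair_recompute_every : iterations between direction recomputations.
    strict_printed_angles : use the branching-angle formula with the
        daughter terms in the printed (swapped) positions instead of the
        corrected law-of-cosines convention.
    """

    xi: float = 2.0
    c_s: float = 0.5
    c_b: float = 0.5
    max_repair_iterations: int = 200
    repair_step_fraction: float = 1.0 / 20.0
    repair_recompute_every: int = 10
    strict_printed_angles: bool = False

    def validate(self) -> None:
        if self.xi <= 0:
            raise ValueError("xi: must be > 0")
        if self.c_s + self.c_b <= 0:
            raise ValueError("c_s/c_b: c_s + c_b must be > 0")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def branching_angles(Qp, rp, QL, rL, QR, rR, strict_printed: bool = False):
    """Initial daughter branching angles (radians) from radii and flows.

    Law of cosines on vectors of magnitude Q/r^2; arccos arguments are
    clamped to [-1, 1].  With ``strict_printed`` the daughter quadratic
    terms swap places (the as-printed variant, which yields 90 degrees in
    the straight-continuation limit).
    """
    if Qp <= 0:
        raise ValueError("zero parent flow")
    up2 = (Qp / rp**2) ** 2
    uL2 = (QL / rL**2) ** 2
    uR2 = (QR / rR**2) ** 2
    up, uL, uR = math.sqrt(up2), math.sqrt(uL2), math.sqrt(uR2)
    if strict_printed:
        numL, numR = up2 + uR2 - uL2, up2 + uL2 - uR2
    else:
        numL, numR = up2 + uL2 - uR2, up2 + uR2 - uL2
    cosL = numL / (2 * up * uL) if uL > 0 else math.inf
    cosR = numR / (2 * up * uR) if uR > 0 else math.inf
    thL = math.acos(min(1.0, max(-1.0, cosL)))
    thR = math.acos(min(1.0, max(-1.0, cosR)))
    return thL, thR


def self_avoidance_vector(x_c, positions, radii, L_s, xi=2.0, min_daughter_radius=0.0):
    """Sum of decaying unit pulls from placed distal nodes toward ``x_c``.

    Nodes belonging to segments with radius smaller than the smaller
    daughter radius do not contribute; neither do nodes coincident with
    ``x_c``.  Each term is (L_s/d)^xi / (1 + (L_s/d)^xi) times the unit
    vector from the node to ``x_c``.
    """
    x_c = np.asarray(x_c, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if positions.size == 0:
        return np.zeros(3)
    radii = np.asarray(radii, dtype=float)
    s = x_c[None, :] - positions
    d = np.linalg.norm(s, axis=1)
    keep = (radii >= min_daughter_radius - 1e-12) & (d > 1e-12)
    if not keep.any():
        return np.zeros(3)
    s, d = s[keep], d[keep]
    ratio = (L_s / d) ** xi
    w = ratio / (1.0 + ratio)
    return (w / d) @ s


def boundary_avoidance_vector(x_c, anatomy: VentricleAnatomy, L: float):
    """Sum over walls of the inward unit normal times exp(-d / 2L)."""
    terms = anatomy.boundary_normals_and_distances(np.asarray(x_c, dtype=float))
    D = np.zeros(3)
    for n, d in terms:
        D += n * math.exp(-d / (2.0 * L))
    return D


def _unit_or_zero(v):
    n = np.linalg.norm(v)
    return v / n if n > 1e-300 else np.zeros_like(v)


def combined_direction(v_s, D, c_s=0.5, c_b=0.5, fallback=None):
    """c_s * unit(v_s) + c_b * unit(D); zero inputs contribute nothing."""
    v = c_s * _unit_or_zero(np.asarray(v_s, dtype=float)) \
        + c_b * _unit_or_zero(np.asarray(D, dtype=float))
    if np.linalg.norm(v) <= 1e-12:
        if fallback is None:
            raise ValueError("both avoidance vectors vanish and no fallback given")
        return np.asarray(fallback, dtype=float).copy()
    return v


def branching_plane_normal(s_p, v_d):
    """Unit normal of the branching plane: (s_p x v_d) x v_d, normalized.

    Degenerate (parallel) input falls back to a deterministic vector
    orthogonal to v_d (the x axis, or y if v_d is nearly axial).
    """
    s_p = np.asarray(s_p, dtype=float)
    v_d = np.asarray(v_d, dtype=float)
    w = np.cross(np.cross(s_p, v_d), v_d)
    n = np.linalg.norm(w)
    if n <= 1e-12 * max(np.linalg.norm(s_p) * np.linalg.norm(v_d) ** 2, 1e-300):
        vhat = _unit_or_zero(v_d)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(vhat @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        w = ref - (ref @ vhat) * vhat
        n = np.linalg.norm(w)
    return w / n


def rotate_about_axis(v, axis, angle):
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle`` (radians)."""
    v = np.asarray(v, dtype=float)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(k, v) * s + k * (k @ v) * (1.0 - c)


def assign_child_positions(x_c, v_d, n_b, theta_L, theta_R, L_L, L_R):
    """Daughter distal positions: rotate v_d by +theta_L / -theta_R, scale."""
    x_c = np.asarray(x_c, dtype=float)
    vL = rotate_about_axis(v_d, n_b, +theta_L)
    vR = rotate_about_axis(v_d, n_b, -theta_R)
    xL = x_c + L_L * _unit_or_zero(vL)
    xR = x_c + L_R * _unit_or_zero(vR)
    return xL, xR


# ---------------------------------------------------------------------------
# boundary repair
# ---------------------------------------------------------------------------

def _repair_directions(points, anatomy: VentricleAnatomy):
    """Unit push-back direction for points outside tissue.

    Sums the inward normals of every violated boundary: the basal plane if
    above it, the nearer epicardial surface if outside both, the relevant
    endocardial surface if inside a cavity.
    """
    p = np.atleast_2d(points)
    d = np.zeros_like(p)
    z_over = p[:, 2] > anatomy.base_z
    d[z_over, 2] -= 1.0

    e_lv_epi = anatomy.lv_epi.implicit(p)
    e_rv_epi = anatomy.rv_epi.implicit(p)
    outside = (e_lv_epi > 1.0) & (e_rv_epi > 1.0)
    if outside.any():
        _, d_lv, n_lv = anatomy.lv_epi.nearest_surface(p[outside])
        _, d_rv, n_rv = anatomy.rv_epi.nearest_surface(p[outside])
        inward = np.where((d_lv <= d_rv)[:, None], -n_lv, -n_rv)
        d[outside] += inward

    in_lv_cav = anatomy.lv_endo.implicit(p) < 1.0
    if in_lv_cav.any():
        _, _, n = anatomy.lv_endo.nearest_surface(p[in_lv_cav])
        d[in_lv_cav] += n
    in_rv_cav = (anatomy.rv_endo.implicit(p) < 1.0) & (e_lv_epi > 1.0) & (e_rv_epi <= 1.0)
    if in_rv_cav.any():
        _, _, n = anatomy.rv_endo.nearest_surface(p[in_rv_cav])
        d[in_rv_cav] += n

    norms = np.linalg.norm(d, axis=1, keepdims=True)
    zero = norms[:, 0] <= 1e-12
    d[zero] = (0.0, 0.0, -1.0)
    norms[zero] = 1.0
    return d / norms


def _repair_batch(points, lengths, anatomy, params: AvoidanceParams):
    """Incrementally move outside points back into tissue.

    Returns (points, repaired_mask, failed_mask); points already inside are
    untouched.
    """
    x = np.atleast_2d(points).astype(float).copy()
    L = np.atleast_1d(np.asarray(lengths, dtype=float))
    inside0 = anatomy.region(x) > 0
    active = ~inside0
    dirs = np.zeros_like(x)
    step = params.repair_step_fraction * L
    for it in range(params.max_repair_iterations):
        if not active.any():
            break
        if it % params.repair_recompute_every == 0:
            dirs[active] = _repair_directions(x[active], anatomy)
        x[active] += step[active, None] * dirs[active]
        idx = np.flatnonzero(active)
        now_in = anatomy.region(x[idx]) > 0
        active[idx[now_in]] = False
    repaired = ~inside0 & ~active
    return x, repaired, active.copy()


def repair_position(x, anatomy, length, params: AvoidanceParams = AvoidanceParams()):
    """Repair a single position; returns (position, status) where status is
    one of PLACED (was already inside), REPAIRED, PRUNED (budget exhausted)."""
    x = np.asarray(x, dtype=float)
    if anatomy.inside_tissue(x):
        return x.copy(), PLACED
    out, repaired, failed = _repair_batch(x[None, :], [length], anatomy, params)
    return out[0], (REPAIRED if repaired[0] else PRUNED)


# ---------------------------------------------------------------------------
# trunk paths
# ---------------------------------------------------------------------------

def _epi_points(epi: Ellipsoid, phi, s):
    a, b, c = epi.semi_axes
    cx, cy, cz = epi.center
    phi = np.asarray(phi, dtype=float)
    s = np.asarray(s, dtype=float)
    return np.stack([cx + a * np.sin(s) * np.cos(phi),
                     cy + b * np.sin(s) * np.sin(phi),
                     cz + c * np.cos(s)], axis=1)


def _s_of_z(epi: Ellipsoid, z):
    c = epi.semi_axes[2]
    return np.arccos(np.clip((np.asarray(z, dtype=float) - epi.center[2]) / c, -1.0, 1.0))


def _helix(epi, phi0, phi1, z0, z1, n=1500):
    t = np.linspace(0.0, 1.0, n)
    phi = np.deg2rad(phi0 + (phi1 - phi0) * t)
    s = _s_of_z(epi, z0 + (z1 - z0) * t)
    return _epi_points(epi, phi, s)


def trunk_path(anatomy: VentricleAnatomy, name: str,
               attach_point: np.ndarray | None = None) -> np.ndarray:
    """Polyline (m, 3) of the epicardial path for a named trunk.

    Orientation convention: +y anterior, -x right (RV free wall side),
    +x left lateral.  The LCX path starts at the supplied attachment point
    on the LAD trunk.
    """
    epi = anatomy.lv_epi
    zb = anatomy.base_z - 1.0
    if name == "RCA":
        return _helix(epi, 130.0, 130.0 + 350.0, zb - 1.0, -22.0, n=2500)
    if name == "LAD":
        # anterior descent to the apex, then posterior ascent with drift
        s0 = float(_s_of_z(epi, zb))
        down = _epi_points(epi, np.full(1500, np.deg2rad(75.0)),
                           np.linspace(s0, math.pi, 1500))
        t = np.linspace(0.0, 1.0, 1500)
        up = _epi_points(epi, np.deg2rad(255.0 + 60.0 * t),
                         np.linspace(math.pi, float(_s_of_z(epi, 8.0)), 1500))
        return np.vstack([down, up[1:]])
    if name == "LCX":
        if attach_point is None:
            raise ValueError("LCX path needs its LAD attachment point")
        q = np.asarray(attach_point, dtype=float) - np.asarray(epi.center)
        phi0 = math.degrees(math.atan2(q[1], q[0]))
        z0 = float(attach_point[2])
        return _helix(epi, phi0, phi0 - 340.0, z0, -24.0, n=2500)
    raise ValueError(f"unknown trunk {name}")


def _walk_path(path: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Points at the given cumulative arc-length distances along a polyline."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cl = np.concatenate([[0.0], np.cumsum(seg)])
    if distances[-1] > cl[-1] + 1e-9:
        raise ValueError(
            f"trunk length {distances[-1]:.1f} mm exceeds path length {cl[-1]:.1f} mm"
        )
    return np.stack([np.interp(distances, cl, path[:, k]) for k in range(3)], axis=1)


# ---------------------------------------------------------------------------
# placed tree
# ---------------------------------------------------------------------------

class PlacedTree:
    """A topology with 3D node coordinates and per-segment placement status.

    Node ``i`` is segment ``i``'s distal node; the inlet sits at
    ``root_position``.  Status is one of PLACED, TRUNK, REPAIRED (all
    retained) or PRUNED.
    """

    def __init__(self, tree: Tree, node_positions, root_position, status):
        self.tree = tree
        self.node_positions = node_positions
        self.root_position = np.asarray(root_position, dtype=float)
        self.status = status

    @property
    def retained(self) -> np.ndarray:
        return (self.status == PLACED) | (self.status == TRUNK) | (self.status == REPAIRED)

    @property
    def prune_fraction(self) -> float:
        """Fraction of the original terminals lost to pruning."""
        term = self.tree.terminal_segments()
        if len(term) == 0:
            return 0.0
        return 1.0 - float(self.retained[term].sum()) / len(term)

    def pruned(self):
        """(pruned Tree, node positions, root position) of retained segments."""
        keep = self.retained
        sub = subset_tree(self.tree, keep)
        return sub, self.node_positions[keep], self.root_position

    def to_vtk(self, path) -> None:
        """Legacy-VTK polyline export with radius/order point data."""
        keep = np.flatnonzero(self.retained)
        remap = {int(s): i + 1 for i, s in enumerate(keep)}
        pts = np.vstack([self.root_position[None, :], self.node_positions[keep]])
        lines = []
        for s in keep:
            p = self.tree.parent[s]
            a = 0 if p < 0 else remap.get(int(p))
            if a is None:
                continue
            lines.append((a, remap[int(s)]))
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\ncorovasc tree\nASCII\n"
                     "DATASET POLYDATA\n")
            fh.write(f"POINTS {len(pts)} float\n")
            for p in pts:
                fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
            fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
            for a, b in lines:
                fh.write(f"2 {a} {b}\n")
            fh.write(f"POINT_DATA {len(pts)}\nSCALARS radius_mm float 1\n"
                     "LOOKUP_TABLE default\n")
            radii = np.concatenate([[self.tree.radius_mm[keep[0]]],
                                    self.tree.radius_mm[keep]])
            for r in radii:
                fh.write(f"{r:.5f}\n")


# ---------------------------------------------------------------------------
# batched engine
# ---------------------------------------------------------------------------

def _batch_self_avoidance(x_c, L_s, r_min, positions, radii, xi):
    """Vectorized Eq.-3 sums for a batch of junctions (nj, 3)."""
    if positions.shape[0] == 0:
        return np.zeros_like(x_c)
    s = x_c[:, None, :] - positions[None, :, :]          # (nj, m, 3)
    d = np.sqrt(np.einsum("ijk,ijk->ij", s, s))
    keep = (radii[None, :] >= r_min[:, None] - 1e-12) & (d > 1e-12)
    ratio = np.where(keep, (L_s[:, None] / np.maximum(d, 1e-12)) ** xi, 0.0)
    w = np.where(keep, ratio / (1.0 + ratio) / np.maximum(d, 1e-12), 0.0)
    return np.einsum("ij,ijk->ik", w, s)


def _batch_boundary_avoidance(x_c, L, anatomy):
    """Vectorized Eq.-4 sums; junction positions are tissue points."""
    D = np.zeros_like(x_c)
    regions = anatomy.region(x_c)
    for reg in (1, 2):
        idx = np.flatnonzero(regions == reg)
        if len(idx) == 0:
            continue
        normals, dists = anatomy.wall_normals_distances(x_c[idx], reg)
        w = np.exp(-dists / (2.0 * L[idx, None]))
        D[idx] = np.einsum("ijk,ij->ik", normals, w)
    # a junction pushed exactly onto a boundary seam may fall outside by
    # round-off; leave its D at zero and let the fallback handle it
    return D


def _batch_combined(v_s, D, s_p, c_s, c_b):
    def unit_rows(v):
        n = np.linalg.norm(v, axis=1, keepdims=True)
        return np.where(n > 1e-12, v / np.maximum(n, 1e-300), 0.0)

    v = c_s * unit_rows(v_s) + c_b * unit_rows(D)
    bad = np.linalg.norm(v, axis=1) <= 1e-12
    v[bad] = s_p[bad]
    return v


def _batch_plane_normal(s_p, v_d):
    w = np.cross(np.cross(s_p, v_d), v_d)
    n = np.linalg.norm(w, axis=1)
    bad = n <= 1e-10
    if bad.any():
        vhat = v_d[bad] / np.linalg.norm(v_d[bad], axis=1, keepdims=True)
        ref = np.tile(np.array([1.0, 0.0, 0.0]), (bad.sum(), 1))
        axial = np.abs(vhat[:, 0]) > 0.9
        ref[axial] = (0.0, 1.0, 0.0)
        wb = ref - np.einsum("ij,ij->i", ref, vhat)[:, None] * vhat
        w[bad] = wb
        n[bad] = np.linalg.norm(wb, axis=1)
    return w / n[:, None]


def _batch_rotate(v, axis, angle):
    c = np.cos(angle)[:, None]
    s = np.sin(angle)[:, None]
    dot = np.einsum("ij,ij->i", axis, v)[:, None]
    return v * c + np.cross(axis, v) * s + axis * dot * (1.0 - c)


def _batch_angles(Qp, rp, QL, rL, QR, rR, strict):
    up2 = (Qp / rp**2) ** 2
    uL2 = (QL / rL**2) ** 2
    uR2 = (QR / rR**2) ** 2
    up, uL, uR = np.sqrt(up2), np.sqrt(uL2), np.sqrt(uR2)
    if strict:
        numL, numR = up2 + uR2 - uL2, up2 + uL2 - uR2
    else:
        numL, numR = up2 + uL2 - uR2, up2 + uR2 - uL2
    with np.errstate(divide="ignore", invalid="ignore"):
        cosL = np.where(uL > 0, numL / (2 * up * uL), np.inf)
        cosR = np.where(uR > 0, numR / (2 * up * uR), np.inf)
    return (np.arccos(np.clip(cosL, -1.0, 1.0)),
            np.arccos(np.clip(cosR, -1.0, 1.0)))


def _place_trunk_chain(tree, segs, path, pos, status, start_offset=0.0):
    cum = start_offset + np.cumsum(tree.length_mm[segs])
    pts = _walk_path(path, np.concatenate([[start_offset], cum]))
    pos[segs] = pts[1:]
    status[segs] = TRUNK
    return pts[0]


def generate_geometry(tree: Tree, anatomy: VentricleAnatomy,
                      params: AvoidanceParams = AvoidanceParams(),
                      rng: np.random.Generator | None = None,
                      flows: np.ndarray | None = None,
                      boundary: PressureBoundary = PressureBoundary()) -> PlacedTree:
    """Assign coordinates to every node of ``tree`` inside ``anatomy``.

    ``flows`` are the per-segment flows of the unplaced topology (solved
    internally when omitted); they set the branching angles.  The returned
    :class:`PlacedTree` keeps the full topology with per-segment status;
    call ``.pruned()`` for the retained tree and re-solve its flows.

    The procedure itself is deterministic given the topology; ``rng`` is
    accepted for interface symmetry and future stochastic placement rules.
    """
    params.validate()
    anatomy.validate()
    if flows is None:
        flows = solve(tree, boundary).segment_flows

    n = tree.n_segments
    pos = np.full((n, 3), np.nan)
    status = np.zeros(n, dtype=np.int8)

    # trunks
    path = trunk_path(anatomy, tree.name if tree.name in ("RCA", "LAD") else "LAD")
    root_pos = _place_trunk_chain(tree, tree.trunk_segments, path, pos, status)
    if tree.lcx_root_segment is not None:
        lcx_elem = tree.element_id[tree.lcx_root_segment]
        lcx_segs = np.flatnonzero(tree.element_id == lcx_elem)
        attach = pos[tree.parent[tree.lcx_root_segment]]
        lcx_path = trunk_path(anatomy, "LCX", attach_point=attach)
        _place_trunk_chain(tree, lcx_segs, lcx_path, pos, status)

    depth = tree.depth
    radii, lengths = tree.radius_mm, tree.length_mm
    n_children = tree.n_children

    for d in range(1, int(depth.max()) + 1):
        segs = np.flatnonzero((depth == d) & (status == UNPLACED))
        if len(segs) == 0:
            continue
        par = tree.parent[segs]
        # propagate pruning: children of pruned (or never-placed) parents die
        dead = (status[par] == PRUNED) | (status[par] == UNPLACED)
        status[segs[dead]] = PRUNED
        segs = segs[~dead]
        if len(segs) == 0:
            continue
        par = tree.parent[segs]

        # group by junction (parent segment)
        order_ = np.argsort(par, kind="stable")
        segs, par = segs[order_], par[order_]
        first = np.ones(len(segs), dtype=bool)
        first[1:] = par[1:] != par[:-1]
        jpar = par[first]                      # one row per junction
        starts = np.flatnonzero(first)
        counts = np.diff(np.append(starts, len(segs)))

        x_c = pos[jpar]
        gp = tree.parent[jpar]
        prox = np.where(gp[:, None] >= 0, pos[np.maximum(gp, 0)], root_pos[None, :])
        s_p = x_c - prox
        s_p /= np.maximum(np.linalg.norm(s_p, axis=1, keepdims=True), 1e-12)

        # daughter bookkeeping per junction
        nj = len(jpar)
        cL = np.empty(nj, dtype=np.int64)      # placed-now daughter (larger r)
        cR = np.full(nj, -1, dtype=np.int64)   # second placed-now daughter
        sib = np.full(nj, -1, dtype=np.int64)  # already-placed sibling (trunk)
        for j in range(nj):
            mine = segs[starts[j]:starts[j] + counts[j]]
            if len(mine) == 2:
                a, b = mine
                if radii[b] > radii[a]:
                    a, b = b, a
                cL[j], cR[j] = a, b
            else:
                cL[j] = mine[0]
                if n_children[jpar[j]] == 2:
                    others = tree.children_of(int(jpar[j]))
                    sib[j] = int(others[others != mine[0]][0])

        bifurc = cR >= 0
        sided = (~bifurc) & (sib >= 0)
        passthru = (~bifurc) & (sib < 0)

        other = np.where(bifurc, cR, np.where(sided, sib, cL))
        r_min = np.minimum(radii[cL], radii[other])
        r_min[passthru] = radii[cL[passthru]]
        L_exp = np.where(bifurc, 0.5 * (lengths[cL] + lengths[np.maximum(cR, 0)]),
                         lengths[cL])

        placed_idx = np.flatnonzero(status != UNPLACED)
        placed_idx = placed_idx[status[placed_idx] != PRUNED]
        v_s = _batch_self_avoidance(x_c, lengths[jpar], r_min,
                                    pos[placed_idx], radii[placed_idx], params.xi)
        D = _batch_boundary_avoidance(x_c, L_exp, anatomy)
        v_d = _batch_combined(v_s, D, s_p, params.c_s, params.c_b)
        n_b = _batch_plane_normal(s_p, v_d)

        QL = flows[cL]
        Qother = flows[other]
        Qp = flows[jpar]
        thL, thR = _batch_angles(np.maximum(Qp, 1e-300), radii[jpar],
                                 QL, radii[cL], Qother, radii[other],
                                 params.strict_printed_angles)

        dirL = _batch_rotate(v_d, n_b, thL)
        dirL /= np.maximum(np.linalg.norm(dirL, axis=1, keepdims=True), 1e-12)
        # side branches hang off a placed continuation: rotate the other way
        dirL[sided] = _batch_rotate(v_d[sided], n_b[sided], -thL[sided])
        dirL[sided] /= np.maximum(
            np.linalg.norm(dirL[sided], axis=1, keepdims=True), 1e-12)
        if passthru.any():
            drift = s_p[passthru] + v_d[passthru]
            dirL[passthru] = drift / np.maximum(
                np.linalg.norm(drift, axis=1, keepdims=True), 1e-12)

        new_pos = x_c + lengths[cL][:, None] * dirL
        new_pos, repaired, failed = _repair_batch(new_pos, lengths[cL], anatomy, params)
        pos[cL] = new_pos
        status[cL] = np.where(failed, PRUNED, np.where(repaired, REPAIRED, PLACED))

        if bifurc.any():
            jb = np.flatnonzero(bifurc)
            dirR = _batch_rotate(v_d[jb], n_b[jb], -thR[jb])
            dirR /= np.maximum(np.linalg.norm(dirR, axis=1, keepdims=True), 1e-12)
            posR = x_c[jb] + lengths[cR[jb]][:, None] * dirR
            posR, repairedR, failedR = _repair_batch(posR, lengths[cR[jb]],
                                                     anatomy, params)
            pos[cR[jb]] = posR
            status[cR[jb]] = np.where(failedR, PRUNED,
                                      np.where(repairedR, REPAIRED, PLACED))

    status[status == UNPLACED] = PRUNED
    return PlacedTree(tree, pos, root_pos, status)
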