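"""Stochastic binary arterial tree topologies for Strahler orders 6-11.

A tree is stored as flat per-segment arrays.  Segment ``i``'s distal end is
node ``i``; the root segment's proximal end is the inlet node (index -1).
Nodes carry one daughter (pass-through: mid-element chain nodes of SN 6
elements, or junctions left behind by pruning) or two daughters
(bifurcations).  Elements are chains of same-order segments sharing one
radius; an element of order m > 6 terminates in two order-(m-1) daughter
elements, and each of its internal junctions spawns one lower-order side
branch drawn from the connectivity matrix row.  The LCX arises as an
order-10 sub-tree attached at a junction in the proximal third of the LAD
trunk.

Total trunk lengths are enforced by reject-and-resample of the trunk
element alone: RCA within [120, 192] mm, LAD and LCX within [100, 160] mm.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import ORDER_MAX, ORDER_MIN, MorphometryTable
from .units import M_PER_MM

_MAX_SEGMENTS = 200_000
_TRUNK_RETRY = 10_000


class GenerationError(RuntimeError):
    """Raised when stochastic generation cannot satisfy its constraints."""


def segment_resistance(length_mm: float, radius_mm: float, viscosity: float):
    """Poiseuille resistance R = 8 mu L / (pi r^4) in Pa s m^-3.

    ``length_mm`` may be an array; a zero length gives zero resistance.
    """
    if np.any(np.asarray(radius_mm) <= 0):
        raise ValueError("radius must be > 0")
    if viscosity <= 0:
        raise ValueError("viscosity must be > 0")
    L = np.asarray(length_mm, dtype=float) * M_PER_MM
    r = np.asarray(radius_mm, dtype=float) * M_PER_MM
    return 8.0 * viscosity * L / (math.pi * r**4)


@dataclass(frozen=True)
class ElementRecord:
    """A chain of same-order segments with one shared radius."""

    order: int
    radius_mm: float
    segment_lengths_mm: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.segment_lengths_mm)


def sample_segment_lengths(order_stats, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n positive segment lengths (normal truncated at zero)."""
    mean, sd = order_stats.mean_segment_length, order_stats.sd_segment_length
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def sample_element(order: int, table: MorphometryTable, rng: np.random.Generator,
                   n_segments: int | None = None) -> ElementRecord:
    """Sample one element: segment count 1 + Poisson(spe - 1), lengths, radius."""
    if not (ORDER_MIN <= order <= ORDER_MAX):
        raise ValueError(f"order {order} outside {ORDER_MIN}..{ORDER_MAX}")
    st = table.stats(order)
    if n_segments is None:
        n_segments = 1 + int(rng.poisson(max(st.segments_per_element - 1.0, 0.0)))
    lengths = sample_segment_lengths(st, n_segments, rng)
    return ElementRecord(order=order, radius_mm=st.mean_radius,
                         segment_lengths_mm=lengths)


def _sample_trunk_element(order: int, table: MorphometryTable,
                          bounds: tuple[float, float],
                          rng: np.random.Generator) -> ElementRecord:
    """Trunk element with total length inside ``bounds`` (reject/resample)."""
    st = table.stats(order)
    lo, hi = bounds
    target_k = max(2, round(0.5 * (lo + hi) / st.mean_segment_length))
    for _ in range(_TRUNK_RETRY):
        k = max(2, 1 + int(rng.poisson(target_k - 1)))
        lengths = sample_segment_lengths(st, k, rng)
        if lo <= lengths.sum() <= hi:
            return ElementRecord(order, st.mean_radius, lengths)
    raise GenerationError(
        f"trunk length bounds {bounds} unsatisfiable after {_TRUNK_RETRY} tries"
    )


class Tree:
    """Arterial tree topology as flat per-segment arrays.

    Attributes
    ----------
    parent : (n,) int array, parent segment index, -1 for the root.
    order, length_mm, radius_mm, element_id : per-segment arrays.
    trunk_segments : indices of the root (maximal-order) element chain.
    lcx_root_segment : first segment of the LCX sub-tree, if present.
    """

    def __init__(self, name, parent, order, length_mm, radius_mm, element_id,
                 viscosity, trunk_segments, lcx_root_segment=None, seed=None):
        self.name = name
        self.parent = np.asarray(parent, dtype=np.int32)
        self.order = np.asarray(order, dtype=np.int16)
        self.length_mm = np.asarray(length_mm, dtype=float)
        self.radius_mm = np.asarray(radius_mm, dtype=float)
        self.element_id = np.asarray(element_id, dtype=np.int32)
        self.viscosity = float(viscosity)
        self.trunk_segments = np.asarray(trunk_segments, dtype=np.int32)
        self.lcx_root_segment = lcx_root_segment
        self.seed = seed
        self._children = None
        self._depth = None

    # -- structure --------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.parent)

    def _build_children(self):
        n = self.n_segments
        counts = np.zeros(n + 1, dtype=np.int32)  # slot n is the inlet
        p = np.where(self.parent < 0, n, self.parent)
        np.add.at(counts, p, 1)
        ptr = np.zeros(n + 2, dtype=np.int32)
        np.cumsum(counts, out=ptr[1:])
        idx = np.empty(n, dtype=np.int32)
        fill = ptr[:-1].copy()
        for i in range(n):
            idx[fill[p[i]]] = i
            fill[p[i]] += 1
        self._children = (ptr, idx)

    def children_of(self, seg: int) -> np.ndarray:
        if self._children is None:
            self._build_children()
        ptr, idx = self._children
        s = self.n_segments if seg < 0 else seg
        return idx[ptr[s]:ptr[s + 1]]

    @property
    def n_children(self) -> np.ndarray:
        if self._children is None:
            self._build_children()
        ptr, _ = self._children
        return np.diff(ptr)[: self.n_segments]

    @property
    def depth(self) -> np.ndarray:
        """Edge count from the root segment (root has depth 0)."""
        if self._depth is None:
            d = np.zeros(self.n_segments, dtype=np.int32)
            for i in range(self.n_segments):
                p = self.parent[i]
                d[i] = 0 if p < 0 else d[p] + 1  # parents precede children
            self._depth = d
        return self._depth

    @property
    def root_segment(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def leaves(self) -> np.ndarray:
        return np.flatnonzero(self.n_children == 0)

    def terminal_segments(self) -> np.ndarray:
        """Leaves of order 6 (all leaves, in an unpruned tree)."""
        lv = self.leaves()
        return lv[self.order[lv] == ORDER_MIN]

    def resistances(self) -> np.ndarray:
        return segment_resistance(self.length_mm, self.radius_mm, self.viscosity)

    def with_radii(self, radius_mm: np.ndarray) -> "Tree":
        t = Tree(self.name, self.parent, self.order, self.length_mm,
                 np.asarray(radius_mm, dtype=float), self.element_id,
                 self.viscosity, self.trunk_segments, self.lcx_root_segment,
                 self.seed)
        return t

    def recompute_strahler(self) -> np.ndarray:
        """Strahler order recomputed from the leaves (leaves pinned at 6)."""
        s = np.zeros(self.n_segments, dtype=np.int16)
        for i in range(self.n_segments - 1, -1, -1):
            ch = self.children_of(i)
            if len(ch) == 0:
                s[i] = ORDER_MIN
            elif len(ch) == 1:
                s[i] = s[ch[0]]
            else:
                a, b = s[ch[0]], s[ch[1]]
                s[i] = a + 1 if a == b else max(a, b)
        return s

    # -- serialization ----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_segments),
                "parent_node": self.parent,
                "child_node": np.arange(self.n_segments),
                "order": self.order,
                "element": self.element_id,
                "L_mm": self.length_mm,
                "r_mm": self.radius_mm,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def tobytes(self) -> bytes:
        """Canonical byte serialization (seed-determinism checks)."""
        parts = [self.name.encode(), self.parent.tobytes(), self.order.tobytes(),
                 self.length_mm.tobytes(), self.radius_mm.tobytes(),
                 self.element_id.tobytes()]
        return b"|".join(parts)


class _Builder:
    def __init__(self, name, viscosity, seed):
        self.name = name
        self.viscosity = viscosity
        self.seed = seed
        self.parent, self.order, self.length, self.radius, self.element = \
            [], [], [], [], []
        self.n_elements = 0

    def add_element(self, rec: ElementRecord, parent_seg: int) -> list[int]:
        eid = self.n_elements
        self.n_elements += 1
        ids = []
        p = parent_seg
        for L in rec.segment_lengths_mm:
            i = len(self.parent)
            self.parent.append(p)
            self.order.append(rec.order)
            self.length.append(float(L))
            self.radius.append(rec.radius_mm)
            self.element.append(eid)
            ids.append(i)
            p = i
        return ids


def _side_branch_weights(table: MorphometryTable, m: int):
    """Side-branch order distribution: connectivity row minus the two
    terminating (m-1) daughters, clipped at zero."""
    row = table.connectivity.row(m)
    orders, w = [], []
    for n, v in sorted(row.items()):
        vv = v - 2.0 if n == m - 1 else v
        if vv > 0:
            orders.append(n)
            w.append(vv)
    if not w:
        return None
    w = np.asarray(w, dtype=float)
    return np.asarray(orders), w / w.sum()


def assemble_tree(name: str, root_order: int, table: MorphometryTable,
                  rng: np.random.Generator, enforce_bounds: bool = True) -> Tree:
    """Assemble one stochastic binary tree (``RCA`` or ``LAD`` incl. LCX).

    Every path from the root ends in an order-6 element; internal junctions
    spawn side branches per the connectivity matrix.  Raises
    :class:`GenerationError` if the segment budget or trunk-length bounds
    cannot be met.
    """
    b = _Builder(name, table.viscosity, None)
    side = {m: _side_branch_weights(table, m) for m in range(ORDER_MIN + 1, ORDER_MAX + 1)}
    lcx_root_segment = None

    bounded = enforce_bounds and name in ("RCA", "LAD", "LCX")
    if bounded:
        trunk_rec = _sample_trunk_element(root_order, table,
                                          table.length_bounds.for_tree(name), rng)
    else:
        trunk_rec = sample_element(root_order, table, rng)
    trunk_ids = b.add_element(trunk_rec, -1)

    # queue entries: (parent_segment, order, is_lcx_trunk)
    queue: deque = deque()

    def expand(ids: list[int], order: int, lcx_junction: int | None = None):
        # internal junctions -> side branches; element end -> two daughters
        for j, seg in enumerate(ids[:-1]):
            if lcx_junction is not None and j == lcx_junction:
                queue.append((seg, ORDER_MAX - 1, True))
                continue
            sw = side.get(order)
            if sw is None:
                continue
            orders, w = sw
            n = int(rng.choice(orders, p=w))
            queue.append((seg, n, False))
        if order > ORDER_MIN:
            queue.append((ids[-1], order - 1, False))
            queue.append((ids[-1], order - 1, False))

    lcx_j = None
    if name == "LAD" and len(trunk_ids) > 1:
        n_j = len(trunk_ids) - 1
        lcx_j = int(rng.integers(0, max(1, math.ceil(n_j / 3))))
    expand(trunk_ids, root_order, lcx_j)

    while queue:
        parent_seg, order, is_lcx = queue.popleft()
        if len(b.parent) > _MAX_SEGMENTS:
            raise GenerationError("segment budget exceeded; check connectivity")
        if is_lcx:
            rec = (_sample_trunk_element(order, table,
                                         table.length_bounds.for_tree("LCX"), rng)
                   if bounded else sample_element(order, table, rng))
        else:
            rec = sample_element(order, table, rng)
        ids = b.add_element(rec, parent_seg)
        if is_lcx:
            lcx_root_segment = ids[0]
        expand(ids, order)

    return Tree(name, b.parent, b.order, b.length, b.radius, b.element,
                b.viscosity, trunk_ids, lcx_root_segment)


def total_trunk_length(tree: Tree) -> float:
    """Sum of segment lengths along the maximal-order element chain (mm)."""
    return float(tree.length_mm[tree.trunk_segments].sum())


def prune_subtree(tree: Tree, segment_id: int) -> Tree:
    """Remove ``segment_id`` and its entire distal sub-tree.

    The sibling branch (if any) remains as a serial continuation of the
    parent junction, which becomes a pass-through node.
    """
    if segment_id == tree.root_segment:
        raise ValueError("cannot prune the root segment")
    drop = np.zeros(tree.n_segments, dtype=bool)
    stack = [int(segment_id)]
    while stack:
        s = stack.pop()
        drop[s] = True
        stack.extend(int(c) for c in tree.children_of(s))
    return subset_tree(tree, ~drop)


def subset_tree(tree: Tree, keep: np.ndarray) -> Tree:
    """Restrict a tree to the kept segments (must stay root-connected)."""
    keep = np.asarray(keep, dtype=bool)
    if not keep[tree.root_segment]:
        raise ValueError("subset must retain the root segment")
    # every kept segment's parent must be kept
    bad = keep & (tree.parent >= 0) & ~keep[np.maximum(tree.parent, 0)]
    if bad.any():
        raise ValueError("subset is not root-connected")
    new_index = np.cumsum(keep) - 1
    parent = tree.parent[keep].copy()
    mask = parent >= 0
    parent[mask] = new_index[parent[mask]]
    trunk = tree.trunk_segments[keep[tree.trunk_segments]]
    lcx = tree.lcx_root_segment
    if lcx is not None:
        lcx = int(new_index[lcx]) if keep[lcx] else None
    return Tree(tree.name, parent, tree.order[keep], tree.length_mm[keep],
                tree.radius_mm[keep], tree.element_id[keep], tree.viscosity,
                new_index[trunk], lcx, tree.seed)
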