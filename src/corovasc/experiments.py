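"""Seeded ensembles and the virtual experiments.

An ensemble is a set of independently generated whole-heart instances
(RCA tree plus LAD tree carrying the LCX sub-tree), instance i seeded with
base_seed + i.  Geometry is generated once per instance under the control
boundary; the structural interventions (single-segment stenosis, order-wise
blocking) change radii only, so every experimental condition reuses the
same geometry and merely re-solves flows — a whole grid of conditions
shares one generation pass.

Experiments
-----------
control          ensemble BF map and all heterogeneity metrics at 100 mmHg.
pressure_sweep   inlet pressure 30..200 mmHg (step 10 by default).
stenosis         one deterministically chosen mid-trunk LAD segment set to
                 each radius in a list (default 1.53, 0.25, 0.075, 0.01 mm).
block_order      root segments of all sub-trees of one Strahler order
                 (terminal segments for order 6) narrowed by a fraction.
combined         pressures x blocking fractions x orders {6, 10}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import VentricleAnatomy
from .bfmap import (VoxelGrid, endocardial_distance_map, fd_convergence,
                    heterogeneity, histogram, make_grid, modality_count,
                    relative_flow_pdf, transmural_profile, voxelize)
from .geometry import AvoidanceParams, generate_geometry
from .hemodynamics import PressureBoundary, solve
from .morphometry import MorphometryTable, load_morphometry, scale_to_human
from .topology import Tree, assemble_tree, total_trunk_length


# ---------------------------------------------------------------------------
# structural interventions
# ---------------------------------------------------------------------------

def stenose_segment(tree: Tree, segment_id: int, new_radius: float) -> Tree:
    """Replace one segment's radius (resistance follows from Poiseuille)."""
    if new_radius <= 0:
        raise ValueError("new_radius: must be > 0")
    if not (0 <= segment_id < tree.n_segments):
        raise ValueError(f"segment_selector: no segment {segment_id}")
    r = tree.radius_mm.copy()
    r[segment_id] = new_radius
    return tree.with_radii(r)


def select_lad_stenosis_segment(tree: Tree) -> int:
    """The LAD trunk segment whose midpoint is nearest half the trunk length.

    Deterministic choice of the large LAD segment to stenose, so repeated
    runs and different analyses target the same vessel.
    """
    trunk = tree.trunk_segments
    cum = np.cumsum(tree.length_mm[trunk])
    mid = cum - 0.5 * tree.length_mm[trunk]
    k = int(np.argmin(np.abs(mid - 0.5 * cum[-1])))
    return int(trunk[k])


def order_subtree_roots(tree: Tree, order: int) -> np.ndarray:
    """Root segments of every order-``order`` sub-tree (parent order higher)."""
    sel = tree.order == order
    par = tree.parent
    par_order = np.where(par >= 0, tree.order[np.maximum(par, 0)], np.int16(99))
    return np.flatnonzero(sel & (par_order > order))


def block_order(tree: Tree, order: int, reduction_fraction: float) -> Tree:
    """Narrow an order's sub-tree root segments by the given fraction.

    For order 6 every terminal (leaf) segment is narrowed instead; order 11
    is single-segment stenosis territory and is rejected.
    """
    if not (6 <= order <= 10):
        raise ValueError("order: must be in 6..10 (11 is single-segment stenosis)")
    if not (0.0 < reduction_fraction < 1.0):
        raise ValueError("reduction_fraction: must be in (0, 1)")
    targets = tree.terminal_segments() if order == 6 else order_subtree_roots(tree, order)
    r = tree.radius_mm.copy()
    r[targets] *= (1.0 - reduction_fraction)
    return tree.with_radii(r)


# ---------------------------------------------------------------------------
# instances and ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlacedComponent:
    """One pruned, placed tree with its node coordinates."""

    tree: Tree
    node_positions: np.ndarray
    root_position: np.ndarray
    prune_fraction: float


@dataclass
class HeartInstance:
    seed: int
    components: list[PlacedComponent]

    def deposits(self, boundary: PressureBoundary, modify=None):
        """Leaf coordinates and flows under a boundary and optional
        structural modification (a Tree -> Tree callable)."""
        pts, q = [], []
        for comp in self.components:
            tree = modify(comp.tree) if modify is not None else comp.tree
            sol = solve(tree, boundary)
            leaves = tree.leaves()
            pts.append(comp.node_positions[leaves])
            q.append(sol.segment_flows[leaves])
        return np.vstack(pts), np.concatenate(q)

    def total_outflow(self, boundary: PressureBoundary, modify=None) -> float:
        _, q = self.deposits(boundary, modify)
        return float(q.sum())


@dataclass
class EnsembleSpec:
    """What to generate: size, seeding, morphometry, anatomy, parameters."""

    n_instances: int = 540
    base_seed: int = 0
    morphometry: str | MorphometryTable = "default"
    anatomy: VentricleAnatomy = field(default_factory=VentricleAnatomy)
    avoidance: AvoidanceParams = field(default_factory=AvoidanceParams)
    geometry_boundary: PressureBoundary = field(default_factory=PressureBoundary)

    def validate(self) -> None:
        if self.n_instances < 1:
            raise ValueError("n_instances: must be >= 1")
        self.avoidance.validate()
        self.anatomy.validate()

    def table(self) -> MorphometryTable:
        t = (self.morphometry if isinstance(self.morphometry, MorphometryTable)
             else load_morphometry(self.morphometry))
        return scale_to_human(t)


def generate_instance(table: MorphometryTable, anatomy: VentricleAnatomy,
                      params: AvoidanceParams, seed: int,
                      boundary: PressureBoundary = PressureBoundary()) -> HeartInstance:
    """Generate, place and prune one whole-heart instance from one seed."""
    rng = np.random.default_rng(seed)
    comps = []
    for name in ("RCA", "LAD"):
        tree = assemble_tree(name, 11, table, rng)
        flows = solve(tree, boundary).segment_flows
        placed = generate_geometry(tree, anatomy, params, rng, flows=flows,
                                   boundary=boundary)
        ptree, ppos, root = placed.pruned()
        comps.append(PlacedComponent(ptree, ppos, root, placed.prune_fraction))
    return HeartInstance(seed, comps)


class Ensemble:
    """Generated instances plus shared voxel-grid machinery."""

    def __init__(self, spec: EnsembleSpec, n_instances: int | None = None,
                 progress=None):
        spec.validate()
        self.spec = spec
        self.anatomy = spec.anatomy
        table = spec.table()
        n = spec.n_instances if n_instances is None else n_instances
        self.instances = []
        for i in range(n):
            self.instances.append(
                generate_instance(table, spec.anatomy, spec.avoidance,
                                  spec.base_seed + i, spec.geometry_boundary))
            if progress is not None:
                progress(i + 1, n)
        self._grid = None
        self._dist = None
        self._deposit_cache = {}

    def __len__(self):
        return len(self.instances)

    @property
    def grid(self) -> VoxelGrid:
        if self._grid is None:
            self._grid = make_grid(self.anatomy, 1.0)
        return self._grid

    def distance_maps(self):
        if self._dist is None:
            self._dist = endocardial_distance_map(self.anatomy, self.grid)
        return self._dist

    def deposits(self, boundary: PressureBoundary, modify=None, cache_key=None):
        if cache_key is not None and cache_key in self._deposit_cache:
            return self._deposit_cache[cache_key]
        out = [inst.deposits(boundary, modify) for inst in self.instances]
        if cache_key is not None:
            self._deposit_cache[cache_key] = out
        return out

    def bf_map(self, boundary: PressureBoundary, modify=None,
               cache_key=None) -> VoxelGrid:
        return voxelize(self.deposits(boundary, modify, cache_key),
                        self.anatomy, grid=self.grid)


def condition_metrics(ensemble: Ensemble, boundary: PressureBoundary,
                      modify=None, n_bins: int = 100, cache_key=None) -> dict:
    """All heterogeneity metrics of one experimental condition."""
    grid = ensemble.bf_map(boundary, modify, cache_key=cache_key)
    het = heterogeneity(grid)
    pdf = relative_flow_pdf(grid, n_bins=n_bins)
    hist = histogram(grid, n_bins=n_bins)
    dist, region = ensemble.distance_maps()
    profile = transmural_profile(grid, dist, region)
    return {
        "total_bf_mm3_s": grid.total_flow(),
        "mean_voxel_bf_mm3_s": hist.mean,
        "sd_voxel_bf_mm3_s": hist.sd,
        "rd_high": het.rd_high,
        "rd_low": het.rd_low,
        "fd": het.fd,
        "modality": modality_count(pdf.density),
        "transmural_lv": profile.lv_layer_flow.tolist(),
        "transmural_rv": profile.rv_layer_flow.tolist(),
    }


# ---------------------------------------------------------------------------
# experiment grid
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Which virtual experiment to run, and its condition grid."""

    kind: str = "control"
    inlet_pressures: tuple = tuple(range(30, 201, 10))
    terminal_pressure: float = 20.0
    stenosis_radii: tuple = (1.53, 0.25, 0.075, 0.01)
    block_orders: tuple = (6, 7, 8, 9, 10)
    block_fractions: tuple = (0.7, 0.8, 0.9)
    combined_pressures: tuple = (30.0, 100.0, 200.0)
    combined_orders: tuple = (6, 10)

    def validate(self) -> None:
        kinds = ("control", "pressure_sweep", "stenosis", "block_order", "combined")
        if self.kind not in kinds:
            raise ValueError(f"kind: {self.kind!r} not one of {kinds}")
        for p in tuple(self.inlet_pressures) + tuple(self.combined_pressures):
            if p <= self.terminal_pressure:
                raise ValueError(
                    f"inlet_pressure: {p} mmHg does not exceed the terminal "
                    f"pressure {self.terminal_pressure} mmHg")
        if any(r <= 0 for r in self.stenosis_radii):
            raise ValueError("stenosis_radii: must be > 0")
        if any(not (0 < f < 1) for f in self.block_fractions):
            raise ValueError("block_fractions: must be in (0, 1)")
        if any(not (6 <= o <= 10) for o in self.block_orders + self.combined_orders):
            raise ValueError("block_orders: must be in 6..10")


def _lad_stenosis_modify(radius):
    def modify(tree: Tree) -> Tree:
        if tree.name != "LAD":
            return tree
        return stenose_segment(tree, select_lad_stenosis_segment(tree), radius)
    return modify


def _block_modify(order, fraction):
    def modify(tree: Tree) -> Tree:
        return block_order(tree, order, fraction)
    return modify


def run_experiment(config: ExperimentConfig, ensemble: Ensemble) -> dict:
    """Run every condition of the configured experiment on an ensemble.

    Returns {condition label: metrics dict}; a failing condition is
    recorded as {"error": message} without aborting the grid.
    """
    config.validate()
    results = {}

    def conditions():
        t = config.terminal_pressure
        if config.kind == "control":
            yield "control", PressureBoundary(100.0, t), None
        elif config.kind == "pressure_sweep":
            for p in config.inlet_pressures:
                yield f"p{p:g}", PressureBoundary(float(p), t), None
        elif config.kind == "stenosis":
            for r in config.stenosis_radii:
                yield f"r{r:g}", PressureBoundary(100.0, t), _lad_stenosis_modify(r)
        elif config.kind == "block_order":
            for o in config.block_orders:
                for f in config.block_fractions:
                    yield (f"sn{o}_f{f:g}", PressureBoundary(100.0, t),
                           _block_modify(o, f))
        else:  # combined
            for p in config.combined_pressures:
                for o in config.combined_orders:
                    for f in config.block_fractions:
                        yield (f"p{p:g}_sn{o}_f{f:g}",
                               PressureBoundary(float(p), t), _block_modify(o, f))

    for label, boundary, modify in conditions():
        try:
            results[label] = condition_metrics(ensemble, boundary, modify)
        except Exception as exc:  # per-condition isolation
            results[label] = {"error": f"{type(exc).__name__}: {exc}"}
    return results


def save_results(results: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
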