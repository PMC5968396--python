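"""Steady-state pressures and flows on a tree under fixed pressure boundaries.

Every SN 6 terminal (every leaf, after pruning) is held at the terminal
pressure and the inlet at the inlet pressure.  Because the network is a tree
with a single common outlet pressure, the Kirchhoff system reduces exactly:
downstream equivalent resistances are accumulated leaf-to-root (series along
chains, parallel at bifurcations), then flows and nodal pressures propagate
root-to-leaf via dP = R Q.  The reduction is level-vectorized rather than
recursive, but is contractually identical to the recursive definition.

Internally SI (Pa, m^3/s); interfaces carry mmHg and mm^3/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import Tree
from .units import MM3_PER_M3, mmhg_to_pa, pa_to_mmhg


@dataclass(frozen=True)
class PressureBoundary:
    """Inlet and terminal pressures, mmHg (defaults 100 / 20)."""

    inlet_pressure: float = 100.0
    terminal_pressure: float = 20.0

    def validate(self) -> None:
        if not self.inlet_pressure > self.terminal_pressure:
            raise ValueError(
                "inlet_pressure: must exceed terminal_pressure "
                f"({self.inlet_pressure} <= {self.terminal_pressure})"
            )

    @property
    def delta_pa(self) -> float:
        return mmhg_to_pa(self.inlet_pressure - self.terminal_pressure)


@dataclass
class FlowSolution:
    """Per-node pressures (mmHg) and per-segment flows (mm^3/s).

    ``node_pressures`` holds the pressure at each segment's distal node;
    ``inlet_pressure`` is the pressure at the root's proximal node.
    """

    node_pressures: np.ndarray
    segment_flows: np.ndarray
    total_inflow: float
    inlet_pressure: float
    terminal_pressure: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": np.arange(len(self.segment_flows)),
                "Q_mm3_s": self.segment_flows,
                "P_distal_mmHg": self.node_pressures,
            }
        )


def _levels(tree: Tree):
    depth = tree.depth
    order = np.argsort(depth, kind="stable")
    bounds = np.searchsorted(depth[order], np.arange(depth.max() + 2))
    return [order[bounds[d]:bounds[d + 1]] for d in range(depth.max() + 1)]


def _reduce(tree: Tree, R: np.ndarray):
    """Leaf-to-root series/parallel reduction.

    Returns (Rdown, G): the downstream equivalent resistance of each
    segment, and the summed daughter conductance at each segment's distal
    node (0 at leaves).
    """
    Rdown = R.astype(float).copy()
    G = np.zeros(tree.n_segments)
    for segs in reversed(_levels(tree)[1:]):
        np.add.at(G, tree.parent[segs], 1.0 / Rdown[segs])
        parents = np.unique(tree.parent[segs])
        Rdown[parents] += 1.0 / G[parents]
    return Rdown, G


def downstream_resistances(tree: Tree, resistances: np.ndarray | None = None) -> np.ndarray:
    """Equivalent resistance of each segment plus everything distal to it (SI)."""
    R = tree.resistances() if resistances is None else np.asarray(resistances)
    return _reduce(tree, R)[0]


def equivalent_resistance(tree: Tree, resistances: np.ndarray | None = None) -> float:
    """Total equivalent resistance from inlet to the common terminal pressure."""
    return float(downstream_resistances(tree, resistances)[tree.root_segment])


def solve(tree: Tree, boundary: PressureBoundary = PressureBoundary(),
          resistances: np.ndarray | None = None) -> FlowSolution:
    """Solve pressures and flows; exact flow conservation and Poiseuille drops.

    Flows split at each bifurcation inversely to downstream equivalent
    resistances; leaf distal pressures equal the terminal pressure exactly.
    """
    boundary.validate()
    if tree.n_segments == 0:
        raise ValueError("empty tree")
    R = tree.resistances() if resistances is None else np.asarray(resistances, dtype=float)
    Rdown, G = _reduce(tree, R)
    P_in = mmhg_to_pa(boundary.inlet_pressure)
    P_term = mmhg_to_pa(boundary.terminal_pressure)

    Q = np.zeros(tree.n_segments)
    P_dist = np.zeros(tree.n_segments)
    levels = _levels(tree)
    root = tree.root_segment
    Q[root] = (P_in - P_term) / Rdown[root]
    P_dist[root] = P_in - R[root] * Q[root]
    for segs in levels[1:]:
        # split the parent flow by downstream conductance: exactly
        # conservative even where distal pressures approach the terminal
        # pressure within rounding
        par = tree.parent[segs]
        Q[segs] = Q[par] / (Rdown[segs] * G[par])
        P_dist[segs] = P_dist[par] - R[segs] * Q[segs]

    return FlowSolution(
        node_pressures=pa_to_mmhg(P_dist),
        segment_flows=Q * MM3_PER_M3,
        total_inflow=float(Q[root]) * MM3_PER_M3,
        inlet_pressure=boundary.inlet_pressure,
        terminal_pressure=boundary.terminal_pressure,
    )


def total_terminal_outflow(tree: Tree, solution: FlowSolution) -> float:
    """Sum of leaf segment flows, mm^3/s (equals total inflow by conservation)."""
    return float(solution.segment_flows[tree.leaves()].sum())
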