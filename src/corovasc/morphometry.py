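"""Per-Strahler-order morphometry statistics driving stochastic tree generation.

The coronary arterial tree is described order by order (Strahler numbers,
SN 6-11 here): a mean radius shared by every element of the order, a segment
length distribution, the mean number of segments per element, and an element
connectivity matrix giving the expected number of order-n daughter elements
spawned by one order-m parent element.  These are the quantities measured by
cast morphometry of large-animal hearts; radii are scaled to human so that
the SN 11 (main coronary) diameter is ~3.2 mm.

The packaged default table is a literature-scale stand-in, fully
configurable via YAML/JSON, validated on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

ORDER_MIN = 6
ORDER_MAX = 11
ORDERS = tuple(range(ORDER_MIN, ORDER_MAX + 1))


class MorphometryError(ValueError):
    """Raised when a morphometry table violates an invariant.

    The message names the offending field.
    """


@dataclass(frozen=True)
class OrderStats:
    """Statistical parameters of one Strahler order.

    Parameters
    ----------
    order : int
        Strahler number, 6..11.
    mean_radius : float
        Element radius in mm (constant along an element).
    mean_segment_length, sd_segment_length : float
        Mean and SD of the segment length distribution, mm.
    segments_per_element : float
        Mean number of same-order segments chained into one element.
    """

    order: int
    mean_radius: float
    mean_segment_length: float
    sd_segment_length: float
    segments_per_element: float

    def validate(self) -> None:
        if self.order not in ORDERS:
            raise MorphometryError(f"order: {self.order} outside {ORDER_MIN}..{ORDER_MAX}")
        for name in ("mean_radius", "mean_segment_length", "segments_per_element"):
            if getattr(self, name) <= 0:
                raise MorphometryError(f"{name}: must be > 0 at order {self.order}")
        if self.sd_segment_length < 0:
            raise MorphometryError(f"sd_segment_length: must be >= 0 at order {self.order}")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Expected count of order-n daughter elements per order-m parent element.

    Entries exist for 6 <= n < m <= 11.  Rows include the two same-chain
    terminating daughters of order m-1, so every row for m > 6 must sum to
    at least 1 (trees cannot dead-end above order 6).
    """

    entries: Mapping[int, Mapping[int, float]]

    def get(self, parent_order: int, daughter_order: int) -> float:
        return float(self.entries.get(parent_order, {}).get(daughter_order, 0.0))

    def row(self, parent_order: int) -> dict[int, float]:
        return {n: float(v) for n, v in self.entries.get(parent_order, {}).items()}

    def validate(self) -> None:
        for m, row in self.entries.items():
            if m not in ORDERS or m == ORDER_MIN:
                raise MorphometryError(f"connectivity: parent order {m} invalid")
            total = 0.0
            for n, v in row.items():
                if not (ORDER_MIN <= n < m):
                    raise MorphometryError(
                        f"connectivity: entry ({m},{n}) outside 6 <= n < m"
                    )
                if v < 0:
                    raise MorphometryError(f"connectivity: entry ({m},{n}) negative")
                total += v
            if total < 1.0:
                raise MorphometryError(
                    f"connectivity: row {m} expected daughter count {total} < 1"
                )
        for m in ORDERS[1:]:
            if m not in self.entries:
                raise MorphometryError(f"connectivity: row for parent order {m} missing")


@dataclass(frozen=True)
class LengthBounds:
    """Admissible total trunk lengths, mm (reject-and-resample bounds)."""

    rca_min: float = 120.0
    rca_max: float = 192.0
    left_min: float = 100.0
    left_max: float = 160.0

    def validate(self) -> None:
        if not (0 < self.rca_min < self.rca_max):
            raise MorphometryError("rca_min/rca_max: need 0 < min < max")
        if not (0 < self.left_min < self.left_max):
            raise MorphometryError("left_min/left_max: need 0 < min < max")

    def for_tree(self, name: str) -> tuple[float, float]:
        if name == "RCA":
            return (self.rca_min, self.rca_max)
        return (self.left_min, self.left_max)


@dataclass(frozen=True)
class MorphometryTable:
    """Full morphometry input: order statistics, connectivity, bounds, fluid.

    ``human_diameter_scale`` is a per-order (or uniform) multiplier applied by
    :func:`scale_to_human`; the default is calibrated so the scaled SN 11
    radius is 1.6 mm (3.2 mm diameter).
    """

    order_stats: Mapping[int, OrderStats]
    connectivity: ConnectivityMatrix
    length_bounds: LengthBounds = field(default_factory=LengthBounds)
    viscosity: float = 3.6e-3  # Pa s
    human_diameter_scale: Mapping[int, float] | float = 1.0

    def stats(self, order: int) -> OrderStats:
        try:
            return self.order_stats[order]
        except KeyError:
            raise MorphometryError(f"order_stats: order {order} missing") from None

    def radius(self, order: int) -> float:
        return self.stats(order).mean_radius

    def scale_for(self, order: int) -> float:
        s = self.human_diameter_scale
        if isinstance(s, Mapping):
            return float(s.get(order, 1.0))
        return float(s)

    def validate(self) -> None:
        present = sorted(self.order_stats)
        if present != list(ORDERS):
            missing = sorted(set(ORDERS) - set(present))
            extra = sorted(set(present) - set(ORDERS))
            if missing:
                raise MorphometryError(f"order_stats: missing orders {missing}")
            raise MorphometryError(f"order_stats: unexpected orders {extra}")
        for o in ORDERS:
            st = self.order_stats[o]
            if st.order != o:
                raise MorphometryError(f"order_stats: key {o} holds order {st.order}")
            st.validate()
        radii = [self.order_stats[o].mean_radius for o in ORDERS]
        for lo, hi, o in zip(radii, radii[1:], ORDERS[1:]):
            if hi <= lo:
                raise MorphometryError(
                    f"mean_radius: not strictly increasing at order {o}"
                )
        self.connectivity.validate()
        self.length_bounds.validate()
        if self.viscosity <= 0:
            raise MorphometryError("viscosity: must be > 0")
        for o in ORDERS:
            if self.scale_for(o) <= 0:
                raise MorphometryError(f"human_diameter_scale: order {o} scale <= 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        scale = self.human_diameter_scale
        if isinstance(scale, Mapping):
            scale = {int(k): float(v) for k, v in scale.items()}
        else:
            scale = float(scale)
        return {
            "orders": [
                {
                    "order": st.order,
                    "mean_radius_mm": st.mean_radius,
                    "mean_segment_length_mm": st.mean_segment_length,
                    "sd_segment_length_mm": st.sd_segment_length,
                    "segments_per_element": st.segments_per_element,
                }
                for st in (self.order_stats[o] for o in sorted(self.order_stats))
            ],
            "connectivity": {
                str(m): {str(n): float(v) for n, v in sorted(row.items())}
                for m, row in sorted(self.connectivity.entries.items())
            },
            "length_bounds_mm": {
                "rca": [self.length_bounds.rca_min, self.length_bounds.rca_max],
                "left": [self.length_bounds.left_min, self.length_bounds.left_max],
            },
            "viscosity_pa_s": self.viscosity,
            "human_scale": scale,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MorphometryTable":
        stats = {}
        for row in d["orders"]:
            st = OrderStats(
                order=int(row["order"]),
                mean_radius=float(row["mean_radius_mm"]),
                mean_segment_length=float(row["mean_segment_length_mm"]),
                sd_segment_length=float(row["sd_segment_length_mm"]),
                segments_per_element=float(row["segments_per_element"]),
            )
            stats[st.order] = st
        conn = ConnectivityMatrix(
            {
                int(m): {int(n): float(v) for n, v in row.items()}
                for m, row in d["connectivity"].items()
            }
        )
        lb = d.get("length_bounds_mm", {})
        rca = lb.get("rca", [120.0, 192.0])
        left = lb.get("left", [100.0, 160.0])
        bounds = LengthBounds(rca[0], rca[1], left[0], left[1])
        scale = d.get("human_scale", 1.0)
        if isinstance(scale, Mapping):
            scale = {int(k): float(v) for k, v in scale.items()}
        table = cls(
            order_stats=stats,
            connectivity=conn,
            length_bounds=bounds,
            viscosity=float(d.get("viscosity_pa_s", 3.6e-3)),
            human_diameter_scale=scale,
        )
        table.validate()
        return table

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Default fixture
# ---------------------------------------------------------------------------
#
# The radius ladder rises monotonically from SN 6 arterioles to the SN 11
# main coronaries; the default uniform human scale of 1.6 anchors the
# scaled SN 11 radius at 1.6 mm (3.2 mm diameter, the clinical adult main
# coronary).  Because the model truncates at SN 6 (no arteriolar/capillary
# orders below), the lower-order radii and the connectivity jointly set the
# network conductance; they are chosen so the control whole-heart flow
# reproduces the organ-scale mean voxel BF of this model class.
# Connectivity rows include the two terminating order-(m-1) daughters of
# each element plus a side-branch tail; the whole heart carries ~2-3
# thousand SN 6 terminals.

_DEFAULT_DICT = {
    "orders": [
        # order, radius (mm, pre-scale), length mean/sd (mm), segments/element
        {"order": 6, "mean_radius_mm": 0.2125, "mean_segment_length_mm": 1.5,
         "sd_segment_length_mm": 0.5, "segments_per_element": 2.0},
        {"order": 7, "mean_radius_mm": 0.3125, "mean_segment_length_mm": 2.0,
         "sd_segment_length_mm": 0.7, "segments_per_element": 2.6},
        {"order": 8, "mean_radius_mm": 0.4625, "mean_segment_length_mm": 3.0,
         "sd_segment_length_mm": 1.0, "segments_per_element": 3.5},
        {"order": 9, "mean_radius_mm": 0.65625, "mean_segment_length_mm": 4.5,
         "sd_segment_length_mm": 1.5, "segments_per_element": 4.0},
        {"order": 10, "mean_radius_mm": 0.875, "mean_segment_length_mm": 7.0,
         "sd_segment_length_mm": 2.0, "segments_per_element": 5.0},
        {"order": 11, "mean_radius_mm": 1.0, "mean_segment_length_mm": 9.0,
         "sd_segment_length_mm": 2.0, "segments_per_element": 16.0},
    ],
    "connectivity": {
        # expected daughters per parent element, including the two
        # terminating (m-1) daughters
        "7": {"6": 3.6},
        "8": {"7": 3.25, "6": 1.25},
        "9": {"8": 2.9, "7": 1.2, "6": 0.9},
        "10": {"9": 2.8, "8": 1.5, "7": 1.5, "6": 1.2},
        "11": {"10": 8.0, "9": 3.0, "8": 2.0, "7": 1.5, "6": 1.25},
    },
    "length_bounds_mm": {"rca": [120.0, 192.0], "left": [100.0, 160.0]},
    "viscosity_pa_s": 3.6e-3,
    "human_scale": 1.6,
}


def default_table() -> MorphometryTable:
    """The packaged default morphometry fixture (pre-human-scaling radii)."""
    return MorphometryTable.from_dict(_DEFAULT_DICT)


def load_morphometry(source: str | Path = "default") -> MorphometryTable:
    """Load and validate a morphometry table.

    Parameters
    ----------
    source : str or Path
        ``"default"`` for the packaged fixture, else a YAML or JSON file
        with keys ``orders``, ``connectivity``, ``length_bounds_mm``,
        ``viscosity_pa_s``, ``human_scale``.
    """
    if str(source) == "default":
        return default_table()
    path = Path(source)
    if not path.exists():
        raise MorphometryError(f"source: no such morphometry file {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return MorphometryTable.from_dict(data)


def scale_to_human(table: MorphometryTable) -> MorphometryTable:
    """Apply the per-order human diameter scaling to every radius.

    Returns a new table with scaled radii and the scale reset to 1, so the
    operation is idempotent.  With the default fixture the scaled SN 11
    radius is 1.6 mm (diameter 3.2 mm, the adult human main coronary).
    """
    table.validate()
    stats = {
        o: replace(st, mean_radius=st.mean_radius * table.scale_for(o))
        for o, st in table.order_stats.items()
    }
    out = replace(table, order_stats=stats, human_diameter_scale=1.0)
    out.validate()
    return out
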