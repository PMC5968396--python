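"""Voxelized blood-flow maps and heterogeneity statistics.

A BF map is a structured voxel grid over the ventricular anatomy: each
instance of the tree ensemble deposits its terminal outflows into the
voxels containing the terminal coordinates, and the ensemble mean is the
map.  Heterogeneity is quantified by

* the BF histogram (100 bins for model maps, 600 for imaging maps);
* the relative-flow distribution d_j = (a_j/m_j)/(A/M) with unit mean,
  whose mass-weighted standard deviation is the relative dispersion RD;
* the fractal dimension D relating RD at two voxel masses,
  RD(m2) = RD(m1) (m2/m1)^(1-D);
* transmural profiles: per-ventricle total flow in 1 mm layers of distance
  from the endocardial surface (sub-endocardium = 1-2 mm);
* a modality count of the smoothed relative-flow density.

Imaging-side maps (NIfTI volumes) are ingested with a value threshold and
analysed with the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .anatomy import VentricleAnatomy


@dataclass
class VoxelGrid:
    """Structured 3D grid of per-voxel flow with a tissue mask.

    ``values`` holds extensive flow (mm^3/s per voxel); ``mass`` is the
    number of constituent unit-resolution tissue voxels (1 at native
    resolution), used for relative-flow weighting after coarsening.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    mass: np.ndarray | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask incongruent with values")
        if self.mass is None:
            self.mass = self.mask.astype(float)

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def total_flow(self) -> float:
        """Total flow over the whole grid (conserves terminal outflow even
        for the few boundary deposits whose voxel center samples outside
        the tissue mask)."""
        return float(self.values.sum())

    def voxel_centers(self) -> np.ndarray:
        idx = np.stack(np.meshgrid(*[np.arange(s) for s in self.values.shape],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        return self.origin + (idx + 0.5) * self.spacing


def make_grid(anatomy: VentricleAnatomy, spacing: float = 1.0) -> VoxelGrid:
    """Empty grid covering the anatomy; mask = voxels whose center is tissue."""
    lo, hi = anatomy.bounding_box()
    sp = np.full(3, float(spacing))
    shape = tuple(np.ceil((hi - lo) / sp).astype(int))
    grid = VoxelGrid(lo, sp, np.zeros(shape), np.zeros(shape, dtype=bool))
    centers = grid.voxel_centers()
    grid.mask = (anatomy.region(centers) > 0).reshape(shape)
    grid.mass = grid.mask.astype(float)
    return grid


def deposit(points: np.ndarray, flows: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Sum flows into the voxels containing the points (half-open bins).

    Returns a dense array of the grid's shape; raises if a point falls
    outside the grid bounds.
    """
    pts = np.atleast_2d(points)
    idx = np.floor((pts - grid.origin) / grid.spacing).astype(int)
    shape = grid.values.shape
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise ValueError("terminal outside grid bounds")
    out = np.zeros(shape)
    np.add.at(out, (idx[:, 0], idx[:, 1], idx[:, 2]), np.asarray(flows, dtype=float))
    return out


def voxelize(instance_deposits, anatomy: VentricleAnatomy,
             spacing: float = 1.0, grid: VoxelGrid | None = None) -> VoxelGrid:
    """Ensemble-mean BF map from per-instance (points, flows) deposits.

    The statistics mask is the tissue mask (voxel centers inside the
    ventricle walls); unperfused tissue voxels stay in the mask with zero
    flow.  Terminals sitting in boundary voxels whose center samples just
    outside the walls still deposit into ``values``, so the grid-total
    flow equals the ensemble-mean total terminal outflow exactly.
    """
    base = make_grid(anatomy, spacing) if grid is None else grid
    total = np.zeros_like(base.values)
    n = 0
    for points, flows in instance_deposits:
        total += deposit(points, flows, base)
        n += 1
    if n == 0:
        raise ValueError("empty ensemble")
    return VoxelGrid(base.origin, base.spacing, total / n, base.mask.copy(),
                     mass=base.mask.astype(float))


# ---------------------------------------------------------------------------
# histograms and relative flow
# ---------------------------------------------------------------------------

@dataclass
class BFHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def histogram(grid: VoxelGrid, n_bins: int = 100) -> BFHistogram:
    """Equal-width histogram of masked voxel values; mean/SD of raw values."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    v = grid.masked_values
    if v.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        hi = lo + 1.0
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    return BFHistogram(edges, counts, float(v.mean()), float(v.std()))


@dataclass
class RelativeFlowPDF:
    """Per-voxel relative flows with their masses and a density histogram."""

    values: np.ndarray
    masses: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    rd: float

    @property
    def mean(self) -> float:
        return float(np.average(self.values, weights=self.masses))

    @property
    def area(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


def relative_flow_pdf(grid: VoxelGrid, n_bins: int = 100) -> RelativeFlowPDF:
    """Relative flows d_j = (a_j/m_j)/(A/M); mass-weighted mean is 1.

    RD is the mass-weighted standard deviation of the d_j themselves;
    the binned density is for display and modality counting.
    """
    m = grid.mass[grid.mask]
    a = grid.masked_values
    A = float(a.sum())
    if A <= 0:
        raise ValueError("total perfusion is zero")
    M = float(m.sum())
    d = (a / m) / (A / M)
    rd = float(np.sqrt(np.average((d - 1.0) ** 2, weights=m)))
    lo, hi = float(d.min()), float(d.max())
    if hi == lo:
        hi = lo + 1.0
    counts, edges = np.histogram(d, bins=n_bins, range=(lo, hi), weights=m)
    density = counts / (M * np.diff(edges))
    return RelativeFlowPDF(d, m, edges, density, rd)


def relative_dispersion(grid: VoxelGrid) -> float:
    return relative_flow_pdf(grid).rd


# ---------------------------------------------------------------------------
# resolution scaling and fractal dimension
# ---------------------------------------------------------------------------

def coarsen(grid: VoxelGrid, factors=(1, 1, 2)) -> VoxelGrid:
    """Aggregate non-overlapping blocks; flow and mass are summed.

    Extents not divisible by the factors are truncated (trailing partial
    blocks discarded).  A block is masked if any constituent voxel is.
    """
    f = np.asarray(factors, dtype=int)
    if np.any(f < 1):
        raise ValueError("factors must be >= 1")
    shape = np.asarray(grid.values.shape)
    trim = (shape // f) * f
    sl = tuple(slice(0, t) for t in trim)

    def blocks(a, red):
        r = a[sl].reshape(trim[0] // f[0], f[0], trim[1] // f[1], f[1],
                          trim[2] // f[2], f[2])
        return red(red(red(r, 5), 3), 1)

    values = blocks(grid.values, lambda a, ax: a.sum(axis=ax))
    mass = blocks(grid.mass, lambda a, ax: a.sum(axis=ax))
    mask = blocks(grid.mask, lambda a, ax: a.any(axis=ax))
    return VoxelGrid(grid.origin, grid.spacing * f, values, mask, mass=mass)


def fractal_dimension(rd_high: float, rd_low: float, mass_ratio: float) -> float:
    """Invert RD(m_low) = RD(m_high) (m_low/m_high)^(1-D) for D."""
    if rd_high <= 0 or rd_low <= 0:
        raise ValueError("relative dispersions must be > 0")
    if mass_ratio <= 1:
        raise ValueError("mass_ratio must be > 1")
    return 1.0 - np.log(rd_low / rd_high) / np.log(mass_ratio)


@dataclass
class HeterogeneityResult:
    rd_high: float
    rd_low: float
    mass_ratio: float
    fd: float


def heterogeneity(grid: VoxelGrid, factors=(1, 1, 2)) -> HeterogeneityResult:
    """RD at native and coarsened resolution, and the fractal dimension.

    The mass ratio is the nominal block volume ratio (2 for pairing along
    one axis, the literal two-resolution reading of the scaling relation).
    """
    rd_high = relative_dispersion(grid)
    rd_low = relative_dispersion(coarsen(grid, factors))
    ratio = float(np.prod(factors))
    return HeterogeneityResult(rd_high, rd_low, ratio,
                               fractal_dimension(rd_high, rd_low, ratio))


def fit_exponential_decay(ns, values):
    """Least-squares fit of f(n) = A + B exp(-n / tau); returns (A, B, tau)."""
    ns = np.asarray(ns, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ns) < 4:
        raise ValueError("need at least 4 points")
    A0 = values[-1]
    B0 = values[0] - values[-1]
    if abs(B0) < 1e-12:
        B0 = 1e-12
    tau0 = max(ns[len(ns) // 3], 1.0)

    def f(n, A, B, tau):
        return A + B * np.exp(-n / tau)

    popt, _ = curve_fit(f, ns, values, p0=(A0, B0, tau0),
                        bounds=([-np.inf, -np.inf, 1e-6], np.inf), maxfev=20000)
    return tuple(float(p) for p in popt)


def fd_convergence(instance_deposits, anatomy: VentricleAnatomy, batch_sizes,
                   spacing: float = 1.0, factors=(1, 1, 2),
                   grid: VoxelGrid | None = None):
    """Fractal dimension on cumulative sub-ensembles and its decay fit.

    ``instance_deposits`` is an ordered iterable of (points, flows) pairs;
    FD is evaluated each time the cumulative count reaches a batch size.
    Returns (sizes, fds, (A, B, tau)) with A the asymptotic FD.
    """
    sizes = sorted(int(s) for s in batch_sizes)
    if len(sizes) < 4:
        raise ValueError("need at least 4 batch sizes")
    base = make_grid(anatomy, spacing) if grid is None else grid
    total = np.zeros_like(base.values)
    fds, reached = [], []
    n = 0
    for points, flows in instance_deposits:
        total += deposit(points, flows, base)
        n += 1
        if n in sizes:
            g = VoxelGrid(base.origin, base.spacing, total / n,
                          base.mask.copy(), mass=base.mask.astype(float))
            fds.append(heterogeneity(g, factors).fd)
            reached.append(n)
    if len(reached) < 4:
        raise ValueError("ensemble smaller than the requested batch sizes")
    A, B, tau = fit_exponential_decay(reached, fds)
    return np.asarray(reached), np.asarray(fds), (A, B, tau)


# ---------------------------------------------------------------------------
# transmural layering
# ---------------------------------------------------------------------------

def endocardial_distance_map(anatomy: VentricleAnatomy, grid: VoxelGrid):
    """Distance (mm) of each tissue voxel center to its own ventricle's
    endocardial surface; NaN outside tissue.  Also returns the region map."""
    centers = grid.voxel_centers()
    region = anatomy.region(centers)
    dist = np.full(len(centers), np.nan)
    for reg, surf in ((1, anatomy.lv_endo), (2, anatomy.rv_endo)):
        idx = np.flatnonzero(region == reg)
        if len(idx):
            _, d, _ = surf.nearest_surface(centers[idx])
            dist[idx] = d
    shape = grid.values.shape
    return dist.reshape(shape), region.reshape(shape)


@dataclass
class TransmuralProfile:
    """Total flow (mm^3/s) per 1 mm-thick layer of endocardial distance.

    Layer k collects voxels at distance [k, k+1) mm; the sub-endocardial
    layer is k = 1 (1-2 mm).
    """

    lv_layer_flow: np.ndarray
    rv_layer_flow: np.ndarray
    layer_thickness: float = 1.0
    subendo_layer: int = 1

    def minimum_layer(self, ventricle: str, n_layers: int | None = None) -> int:
        f = self.lv_layer_flow if ventricle == "LV" else self.rv_layer_flow
        if n_layers is not None:
            f = f[:n_layers]
        return int(np.argmin(f))


def transmural_profile(grid: VoxelGrid, distance_map: np.ndarray,
                       region_map: np.ndarray,
                       layer_thickness: float = 1.0) -> TransmuralProfile:
    """Assign each voxel's flow to its distance layer, per ventricle."""
    if distance_map.shape != grid.values.shape:
        raise ValueError("distance map incongruent with grid")
    out = []
    for reg in (1, 2):
        sel = (region_map == reg) & grid.mask & np.isfinite(distance_map)
        layer = np.floor(distance_map[sel] / layer_thickness).astype(int)
        flows = grid.values[sel]
        n_layers = int(layer.max()) + 1 if layer.size else 0
        totals = np.zeros(max(n_layers, 1))
        np.add.at(totals, layer, flows)
        out.append(totals)
    return TransmuralProfile(out[0], out[1], layer_thickness)


# ---------------------------------------------------------------------------
# modality and external maps
# ---------------------------------------------------------------------------

def modality_count(density: np.ndarray, smoothing_window: int = 5,
                   prominence_fraction: float = 0.05) -> int:
    """Number of modes of a (histogram) density after moving-average
    smoothing, counting peaks with prominence >= the fraction of the
    maximum; a plateau counts once, and any nonempty density has >= 1."""
    density = np.asarray(density, dtype=float)
    if density.size == 0 or density.sum() == 0:
        return 0
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    smooth = np.convolve(density, kernel, mode="same")
    peaks, _ = find_peaks(smooth, prominence=prominence_fraction * smooth.max())
    return max(1, len(peaks))


def load_external_bf_map(path, threshold_range=(0.0, 600.0)) -> VoxelGrid:
    """Load a 3D scalar volume (NIfTI) as a thresholded perfusion map.

    Voxels outside the threshold range are removed from the mask; voxel
    spacing is taken from the file header.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if np.any(zooms <= 0):
        raise ValueError("missing or invalid spacing metadata")
    lo, hi = threshold_range
    mask = (data >= lo) & (data <= hi)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return VoxelGrid(origin, zooms, data, mask, mass=mask.astype(float))
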