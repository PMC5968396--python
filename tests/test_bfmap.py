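import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from corovasc.anatomy import Ellipsoid, VentricleAnatomy
from corovasc.bfmap import (VoxelGrid, coarsen, deposit,
                            endocardial_distance_map, fd_convergence,
                            fit_exponential_decay, fractal_dimension,
                            heterogeneity, histogram, load_external_bf_map,
                            make_grid, modality_count, relative_flow_pdf,
                            transmural_profile, voxelize)


def _grid(values, mask=None, spacing=1.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return VoxelGrid(np.zeros(3), np.full(3, spacing), values, mask)


@pytest.fixture(scope="module")
def shell_anatomy():
    """Degenerate spherical-shell anatomy (LV only; RV placed far away)."""
    return VentricleAnatomy(
        lv_endo=Ellipsoid((0.0, 0.0, 0.0), (10.0, 10.0, 10.0)),
        lv_epi=Ellipsoid((0.0, 0.0, 0.0), (20.0, 20.0, 20.0)),
        rv_endo=Ellipsoid((500.0, 0.0, 0.0), (5.0, 5.0, 5.0)),
        rv_epi=Ellipsoid((500.0, 0.0, 0.0), (8.0, 8.0, 8.0)),
        base_z=25.0,
    )


class TestVoxelize:
    def test_single_terminal_lands_in_one_voxel(self, anatomy):
        grid = make_grid(anatomy)
        pt = np.array([[30.0, 0.5, 0.5]])  # LV free wall
        out = deposit(pt, [7.0], grid)
        assert out.sum() == pytest.approx(7.0)
        assert (out > 0).sum() == 1

    def test_mean_of_two_disjoint_instances(self, anatomy):
        g = voxelize([(np.array([[30.0, 0.5, 0.5]]), np.array([4.0])),
                      (np.array([[-0.5, 30.0, 0.5]]), np.array([4.0]))],
                     anatomy)
        vals = g.values[g.values > 0]
        assert np.allclose(sorted(vals), [2.0, 2.0])

    def test_total_flow_conserved_through_binning(self, anatomy):
        rng = np.random.default_rng(0)
        # scatter points through the LV free wall
        pts = np.array([30.0, 0.0, 0.0]) + rng.uniform(-2, 2, size=(50, 3))
        q = rng.uniform(0, 5, size=50)
        g = voxelize([(pts, q)], anatomy)
        assert g.total_flow() == pytest.approx(q.sum(), rel=1e-12)

    def test_out_of_bounds_terminal_rejected(self, anatomy):
        grid = make_grid(anatomy)
        with pytest.raises(ValueError, match="outside grid"):
            deposit(np.array([[500.0, 0.0, 0.0]]), [1.0], grid)


class TestHistogram:
    def test_constant_field_is_one_bin_with_zero_sd(self):
        h = histogram(_grid(np.full((4, 4, 4), 2.5)), n_bins=100)
        assert h.counts.sum() == 64
        assert (h.counts > 0).sum() == 1
        assert h.sd == 0.0

    def test_counts_sum_to_masked_voxels(self):
        rng = np.random.default_rng(1)
        mask = rng.random((5, 5, 5)) > 0.4
        h = histogram(_grid(rng.random((5, 5, 5)), mask), n_bins=10)
        assert h.counts.sum() == mask.sum()

    def test_two_delta_mixture_occupies_exactly_two_bins(self):
        v = np.zeros((10, 10, 1))
        v[:5] = 1.0
        v[5:] = 9.0
        h = histogram(_grid(v), n_bins=8)
        occupied = h.counts > 0
        assert occupied.sum() == 2
        assert h.counts[occupied].tolist() == [50, 50]


class TestRelativeFlow:
    def test_uniform_flow_has_unit_values_and_zero_rd(self):
        pdf = relative_flow_pdf(_grid(np.full((4, 4, 4), 3.0)))
        assert np.allclose(pdf.values, 1.0)
        assert pdf.rd == pytest.approx(0.0)

    def test_two_point_distribution_closed_form(self):
        v = np.zeros((8, 8, 2))
        v[:4] = 2.0  # half at 2a, half at 0 -> d in {2, 0}, RD = 1
        pdf = relative_flow_pdf(_grid(v))
        assert set(np.round(pdf.values, 12)) == {0.0, 2.0}
        assert pdf.rd == pytest.approx(1.0)

    @given(st.integers(0, 500))
    def test_unit_mean_and_unit_area(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.exponential(2.0, size=(6, 6, 6))
        pdf = relative_flow_pdf(_grid(v))
        assert pdf.mean == pytest.approx(1.0, abs=1e-9)
        assert pdf.area == pytest.approx(1.0, abs=1e-9)

    def test_invariance_under_uniform_scaling(self):
        rng = np.random.default_rng(3)
        v = rng.exponential(1.0, size=(6, 6, 6))
        a = relative_flow_pdf(_grid(v))
        b = relative_flow_pdf(_grid(100.0 * v))
        assert np.allclose(a.values, b.values)
        assert a.rd == pytest.approx(b.rd, rel=1e-12)


class TestCoarsen:
    def test_identity_factors(self):
        rng = np.random.default_rng(0)
        g = _grid(rng.random((4, 6, 8)))
        c = coarsen(g, (1, 1, 1))
        assert np.array_equal(c.values, g.values)

    def test_uniform_grid_pairing_doubles_values_keeps_rd_zero(self):
        g = _grid(np.full((4, 4, 4), 1.5))
        c = coarsen(g, (1, 1, 2))
        assert np.allclose(c.values, 3.0)
        assert np.allclose(c.mass, 2.0)
        assert relative_flow_pdf(c).rd == pytest.approx(0.0)

    @given(st.integers(0, 200))
    def test_total_flow_conserved_for_divisible_extents(self, seed):
        rng = np.random.default_rng(seed)
        g = _grid(rng.random((4, 6, 8)))
        for f in [(2, 1, 1), (1, 3, 2), (2, 2, 2)]:
            assert coarsen(g, f).values.sum() == pytest.approx(
                g.values.sum(), rel=1e-12)

    def test_truncation_of_non_divisible_extents(self):
        g = _grid(np.ones((5, 5, 5)))
        c = coarsen(g, (2, 2, 2))
        assert c.values.shape == (2, 2, 2)
        assert np.allclose(c.values, 8.0)


class TestFractalDimension:
    def test_equal_rd_gives_dimension_one(self):
        assert fractal_dimension(0.4, 0.4, 2.0) == pytest.approx(1.0)

    def test_direct_inversion_example(self):
        assert fractal_dimension(0.30, 0.27, 2.0) == pytest.approx(
            1.0 - math.log(0.27 / 0.30) / math.log(2.0))
        assert fractal_dimension(0.30, 0.27, 2.0) == pytest.approx(1.152,
                                                                   abs=1e-3)

    @given(st.floats(0.05, 3.0), st.floats(1.0, 1.5), st.floats(1.5, 8.0))
    def test_forward_inverse_round_trip_exact(self, rd_high, D, ratio):
        rd_low = rd_high * ratio ** (1.0 - D)
        assert fractal_dimension(rd_high, rd_low, ratio) == pytest.approx(
            D, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fractal_dimension(0.0, 0.3, 2.0)
        with pytest.raises(ValueError):
            fractal_dimension(0.3, 0.3, 1.0)


class TestFdConvergenceFit:
    def test_exact_synthetic_decay_recovered(self):
        ns = np.array([10, 25, 50, 100, 200, 400])
        A, B, tau = 1.14, 0.3, 60.0
        fds = A + B * np.exp(-ns / tau)
        Af, Bf, tf = fit_exponential_decay(ns, fds)
        assert Af == pytest.approx(A, abs=1e-6)
        assert Bf == pytest.approx(B, abs=1e-5)
        assert tf == pytest.approx(tau, rel=1e-4)

    def test_constant_series_gives_that_constant(self):
        ns = np.array([10, 20, 40, 80])
        Af, Bf, _ = fit_exponential_decay(ns, np.full(4, 1.2))
        assert Af == pytest.approx(1.2, abs=1e-6)
        assert abs(Bf) < 1e-6

    def test_monotone_decreasing_asymptote_below_minimum(self):
        ns = np.array([10, 25, 50, 100, 200])
        fds = np.array([1.5, 1.4, 1.32, 1.26, 1.22])
        Af, _, _ = fit_exponential_decay(ns, fds)
        assert Af <= fds.min() + 0.02

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([1, 2, 3], [1, 2, 3])


class TestDistanceMapAndTransmural:
    def test_spherical_shell_distance_closed_form(self, shell_anatomy):
        grid = make_grid(shell_anatomy, 1.0)
        dist, region = endocardial_distance_map(shell_anatomy, grid)
        centers = grid.voxel_centers().reshape(*grid.values.shape, 3)
        rho = np.linalg.norm(centers, axis=-1)
        lv = region == 1
        assert lv.sum() > 1000
        assert np.allclose(dist[lv], rho[lv] - 10.0, atol=1e-5)

    def test_layer_totals_partition_the_flow(self, shell_anatomy):
        grid = make_grid(shell_anatomy, 1.0)
        rng = np.random.default_rng(0)
        grid.values[grid.mask] = rng.random(int(grid.mask.sum()))
        dist, region = endocardial_distance_map(shell_anatomy, grid)
        prof = transmural_profile(grid, dist, region)
        assert prof.lv_layer_flow.sum() == pytest.approx(
            grid.values[(region == 1) & grid.mask].sum(), rel=1e-12)

    def test_uniform_field_matches_analytic_shell_volumes(self, shell_anatomy):
        grid = make_grid(shell_anatomy, 1.0)
        grid.values[grid.mask] = 1.0
        dist, region = endocardial_distance_map(shell_anatomy, grid)
        prof = transmural_profile(grid, dist, region)
        for k in range(8):
            analytic = 4.0 / 3.0 * math.pi * ((10 + k + 1) ** 3 - (10 + k) ** 3)
            assert prof.lv_layer_flow[k] == pytest.approx(analytic, rel=0.08)

    def test_point_mass_in_subendocardial_layer(self, shell_anatomy):
        grid = make_grid(shell_anatomy, 1.0)
        dist, region = endocardial_distance_map(shell_anatomy, grid)
        g = VoxelGrid(grid.origin, grid.spacing, np.zeros_like(grid.values),
                      grid.mask)
        idx = np.argwhere((dist >= 1.2) & (dist < 1.8) & (region == 1))[0]
        g.values[tuple(idx)] = 5.0
        prof = transmural_profile(g, dist, region)
        assert prof.lv_layer_flow[prof.subendo_layer] == pytest.approx(5.0)
        assert prof.lv_layer_flow.sum() == pytest.approx(5.0)


class TestModality:
    def test_single_gaussian_counts_one(self):
        x = np.linspace(-4, 4, 100)
        density = np.exp(-x**2 / 2)
        assert modality_count(density) == 1

    def test_separated_mixture_counts_two(self):
        x = np.linspace(0, 10, 200)
        density = np.exp(-((x - 2) ** 2)) + 0.7 * np.exp(-((x - 8) ** 2))
        assert modality_count(density) == 2

    def test_uniform_plateau_counts_once(self):
        assert modality_count(np.ones(50)) == 1

    def test_empty_density(self):
        assert modality_count(np.zeros(10)) == 0


class TestExternalMap:
    def test_roundtrip_and_threshold(self, tmp_path):
        import nibabel as nib
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 500, size=(8, 9, 4))
        data[0, 0, 0] = 700.0  # above threshold
        affine = np.diag([0.5, 0.5, 5.0, 1.0])
        path = tmp_path / "map.nii.gz"
        nib.Nifti1Image(data, affine).to_filename(path)
        g = load_external_bf_map(path, (0.0, 600.0))
        assert np.allclose(g.values, data)
        assert np.allclose(g.spacing, [0.5, 0.5, 5.0])
        assert not g.mask[0, 0, 0]
        assert g.mask.sum() == data.size - 1

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib
        path = tmp_path / "map4d.nii.gz"
        nib.Nifti1Image(np.zeros((4, 4, 4, 2)), np.eye(4)).to_filename(path)
        with pytest.raises(ValueError, match="3D"):
            load_external_bf_map(path)


def test_fd_convergence_pipeline_on_synthetic_instances(shell_anatomy):
    rng = np.random.default_rng(7)
    grid = make_grid(shell_anatomy, 1.0)
    centers = grid.voxel_centers()[grid.mask.ravel()]
    deposits = []
    for _ in range(40):
        idx = rng.integers(0, len(centers), size=200)
        deposits.append((centers[idx], rng.exponential(1.0, size=200)))
    ns, fds, (A, B, tau) = fd_convergence(deposits, shell_anatomy,
                                          [5, 10, 20, 30, 40], grid=grid)
    assert list(ns) == [5, 10, 20, 30, 40]
    # iid deposits decorrelate neighboring voxels: FD near the random limit
    assert np.all(np.asarray(fds) > 1.2)
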