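import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import corovasc as cv
from corovasc.geometry import (AvoidanceParams, PLACED, PRUNED, REPAIRED,
                               assign_child_positions,
                               boundary_avoidance_vector, branching_angles,
                               branching_plane_normal, combined_direction,
                               generate_geometry, repair_position,
                               rotate_about_axis, self_avoidance_vector,
                               trunk_path)


class TestBranchingAngles:
    def test_symmetric_daughters_have_equal_angles(self):
        thL, thR = branching_angles(1.0, 1.0, 0.5, 0.8, 0.5, 0.8)
        assert thL == pytest.approx(thR)

    def test_independent_law_of_cosines_value(self):
        # Q_p=1, r_p=1, Q_L=Q_R=0.5, r_L=r_R=2^(-1/3)
        r = 2.0 ** (-1.0 / 3.0)
        u = 0.5 / r**2
        expected = math.acos(1.0 / (2.0 * u))  # 0.889 rad
        assert expected == pytest.approx(0.889, abs=1e-3)
        thL, thR = branching_angles(1.0, 1.0, 0.5, r, 0.5, r)
        assert thL == pytest.approx(expected, abs=1e-12)
        assert thR == pytest.approx(expected, abs=1e-12)

    def test_straight_continuation_limit_under_corrected_convention(self):
        thL, _ = branching_angles(1.0, 1.0, 1.0, 1.0, 1e-12, 0.3)
        assert thL == pytest.approx(0.0, abs=1e-6)

    def test_printed_convention_differs_in_the_degenerate_limit(self):
        thL, _ = branching_angles(1.0, 1.0, 1.0, 1.0, 1e-12, 0.3,
                                  strict_printed=True)
        assert thL == pytest.approx(math.pi / 2, abs=1e-6)

    def test_angles_clamped_to_valid_range(self):
        thL, thR = branching_angles(1.0, 1.0, 3.0, 0.2, 0.1, 0.2)
        assert 0.0 <= thL <= math.pi and 0.0 <= thR <= math.pi

    def test_zero_parent_flow_rejected(self):
        with pytest.raises(ValueError):
            branching_angles(0.0, 1.0, 0.5, 1.0, 0.5, 1.0)


class TestSelfAvoidance:
    def test_single_contributor_at_unit_ratio(self):
        x_c = np.array([0.0, 0.0, 0.0])
        pos = np.array([[2.0, 0.0, 0.0]])
        v = self_avoidance_vector(x_c, pos, np.array([1.0]), L_s=2.0)
        # weight (L/d)^2/(1+(L/d)^2) = 0.5, pointing from the node to x_c
        assert np.allclose(v, [-0.5, 0.0, 0.0])

    def test_far_contributor_decays(self):
        v = self_avoidance_vector(np.zeros(3), np.array([[1e6, 0, 0]]),
                                  np.array([1.0]), L_s=2.0)
        assert np.linalg.norm(v) < 1e-10

    def test_symmetric_contributors_cancel(self):
        pos = np.array([[3.0, 0.0, 0.0], [-3.0, 0.0, 0.0]])
        v = self_avoidance_vector(np.zeros(3), pos, np.ones(2), L_s=2.0)
        assert np.allclose(v, 0.0, atol=1e-15)

    def test_small_radius_nodes_do_not_contribute(self):
        pos = np.array([[2.0, 0.0, 0.0]])
        v = self_avoidance_vector(np.zeros(3), pos, np.array([0.1]),
                                  L_s=2.0, min_daughter_radius=0.5)
        assert np.allclose(v, 0.0)

    def test_empty_contributor_set_gives_zero(self):
        v = self_avoidance_vector(np.zeros(3), np.empty((0, 3)),
                                  np.empty(0), L_s=2.0)
        assert np.allclose(v, 0.0)


class TestBoundaryAvoidance:
    def test_wall_weights_follow_exponential_decay(self, anatomy):
        a_en = anatomy.lv_endo.semi_axes[0]
        a_ep = anatomy.lv_epi.semi_axes[0]
        p = np.array([0.5 * (a_en + a_ep), 0.0, 0.0])
        d_endo = p[0] - a_en
        L = d_endo / 2.0  # so the endo term weight is exactly e^-1
        D = boundary_avoidance_vector(p, anatomy, L)
        terms = anatomy.boundary_normals_and_distances(p)
        expected = sum(n * math.exp(-d / (2 * L)) for n, d in terms)
        assert np.allclose(D, expected)
        assert math.exp(-d_endo / (2 * L)) == pytest.approx(math.exp(-1))

    def test_deep_tissue_gives_near_zero(self, anatomy):
        a_en = anatomy.lv_endo.semi_axes[0]
        a_ep = anatomy.lv_epi.semi_axes[0]
        p = np.array([0.5 * (a_en + a_ep), 0.0, 0.0])
        D = boundary_avoidance_vector(p, anatomy, L=0.05)
        assert np.linalg.norm(D) < 1e-10


class TestCombinedDirection:
    def test_parallel_unit_inputs_recover_the_direction(self):
        v = np.array([0.0, 1.0, 0.0])
        out = combined_direction(v, v, 0.5, 0.5)
        assert np.allclose(out, v)

    def test_orthogonal_inputs_bisect(self):
        out = combined_direction(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        assert np.linalg.norm(out) == pytest.approx(math.sqrt(2) / 2)
        assert out[0] == pytest.approx(out[1])

    def test_single_term_when_boundary_vanishes(self):
        out = combined_direction(np.array([0, 0, 2.0]), np.zeros(3))
        assert np.allclose(out, [0, 0, 0.5])

    def test_double_zero_falls_back_to_parent_direction(self):
        sp = np.array([1.0, 0, 0])
        assert np.allclose(combined_direction(np.zeros(3), np.zeros(3),
                                              fallback=sp), sp)


class TestPlaneNormalAndRotation:
    def test_triple_product_example(self):
        n = branching_plane_normal(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        assert np.allclose(n, [-1.0, 0.0, 0.0])

    @given(st.integers(0, 10_000))
    def test_normal_is_unit_and_orthogonal_to_direction(self, seed):
        rng = np.random.default_rng(seed)
        sp, vd = rng.normal(size=3), rng.normal(size=3)
        n = branching_plane_normal(sp, vd)
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-9)
        assert abs(n @ vd) < 1e-8 * np.linalg.norm(vd)

    def test_parallel_fallback_is_deterministic_and_orthogonal(self):
        v = np.array([0.0, 0.0, 2.0])
        n = branching_plane_normal(v, v)
        assert np.linalg.norm(n) == pytest.approx(1.0)
        assert abs(n @ v) < 1e-12

    @given(st.integers(0, 10_000))
    def test_rotation_is_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=3)
        axis = rng.normal(size=3)
        angle = rng.uniform(-math.pi, math.pi)
        out = rotate_about_axis(v, axis, angle)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(v),
                                                    rel=1e-12)

    def test_child_positions_split_by_both_angles(self):
        x_c = np.array([1.0, 2.0, 3.0])
        v_d = np.array([0.0, 0.0, 1.0])
        n_b = np.array([1.0, 0.0, 0.0])
        thL, thR = 0.4, 0.7
        xL, xR = assign_child_positions(x_c, v_d, n_b, thL, thR, 2.0, 3.0)
        assert np.linalg.norm(xL - x_c) == pytest.approx(2.0, abs=1e-12)
        assert np.linalg.norm(xR - x_c) == pytest.approx(3.0, abs=1e-12)
        vL, vR = (xL - x_c) / 2.0, (xR - x_c) / 3.0
        assert math.acos(np.clip(vL @ vR, -1, 1)) == pytest.approx(thL + thR,
                                                                   abs=1e-9)

    def test_zero_angles_place_children_along_direction(self):
        x_c = np.zeros(3)
        xL, xR = assign_child_positions(x_c, np.array([0, 1.0, 0]),
                                        np.array([1.0, 0, 0]), 0.0, 0.0,
                                        1.5, 2.5)
        assert np.allclose(xL, [0, 1.5, 0])
        assert np.allclose(xR, [0, 2.5, 0])


class TestRepair:
    def test_point_already_inside_is_untouched(self, anatomy):
        a_en = anatomy.lv_endo.semi_axes[0]
        a_ep = anatomy.lv_epi.semi_axes[0]
        p = np.array([0.5 * (a_en + a_ep), 0.0, 0.0])
        out, status = repair_position(p, anatomy, 2.0)
        assert status == PLACED
        assert np.allclose(out, p)

    def test_point_just_outside_reenters(self, anatomy):
        p = np.array([anatomy.lv_epi.semi_axes[0] + 0.05, 0.0, 0.0])
        out, status = repair_position(p, anatomy, 2.0)
        assert status == REPAIRED
        assert anatomy.inside_tissue(out)

    def test_unreachable_point_exhausts_budget(self, anatomy):
        p = np.array([0.0, 0.0, -500.0])  # far beyond the apex
        out, status = repair_position(p, anatomy, 0.1,
                                      AvoidanceParams(max_repair_iterations=200))
        assert status == PRUNED


class TestTrunkPaths:
    @pytest.mark.parametrize("name,needed", [("RCA", 192.0), ("LAD", 160.0)])
    def test_paths_are_long_enough_and_on_tissue(self, anatomy, name, needed):
        path = trunk_path(anatomy, name)
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
        assert seg.sum() > needed
        assert anatomy.region(path).min() > 0


@pytest.fixture(scope="module")
def placed(small_table, anatomy):
    rng = np.random.default_rng(21)
    tree = cv.assemble_tree("LAD", 11, small_table, rng)
    return tree, generate_geometry(tree, anatomy, AvoidanceParams(), rng)


class TestGenerateGeometry:
    def test_all_retained_nodes_inside_tissue(self, placed, anatomy):
        tree, pt = placed
        pos = pt.node_positions[pt.retained]
        assert np.all(anatomy.region(pos) > 0)

    def test_unrepaired_segments_have_exact_length(self, placed):
        tree, pt = placed
        exact = np.flatnonzero(pt.status == PLACED)
        par = tree.parent[exact]
        prox = np.where(par[:, None] >= 0,
                        pt.node_positions[np.maximum(par, 0)],
                        pt.root_position[None, :])
        chord = np.linalg.norm(pt.node_positions[exact] - prox, axis=1)
        assert np.allclose(chord, tree.length_mm[exact], atol=1e-6)

    def test_seed_determinism(self, small_table, anatomy):
        def run():
            rng = np.random.default_rng(5)
            tree = cv.assemble_tree("LAD", 11, small_table, rng)
            pt = generate_geometry(tree, anatomy, AvoidanceParams(), rng)
            return pt.node_positions
        a, b = run(), run()
        assert np.array_equal(a, b, equal_nan=True)

    def test_prune_fraction_regression_guard(self, placed):
        _, pt = placed
        assert pt.prune_fraction < 0.20

    def test_pruned_tree_resolves_with_exact_conservation(self, placed):
        tree, pt = placed
        sub, pos, root = pt.pruned()
        sol = cv.solve(sub)
        assert cv.total_terminal_outflow(sub, sol) == pytest.approx(
            sol.total_inflow, rel=1e-9)
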