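"""Articular regions, coverage, joint space, congruence, and statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import arthroshape as ash
from arthroshape.articulation import ThresholdSpec, congruence_arrays
from arthroshape.synthetic import SyntheticJointSpec, make_joint

from conftest import sphere_mesh


def whole_mesh_region(mesh, joint_label="synthetic", stage="candidate"):
    return ash.ArticularRegion(mesh, np.arange(mesh.n_vertices),
                               np.arange(mesh.n_faces), stage=stage,
                               joint_label=joint_label)


class TestCandidateRegion:
    def test_socket_isolated_from_flange(self):
        """Socket patch next to a planar flange: Kmin < −0.05 selects only
        the socket (the flange is flat)."""
        _, socket, _ = make_joint(SyntheticJointSpec(
            radius_a=8, radius_b=10, gap=2, resolution=0.5,
            angular_extent=60))
        flange, _, _ = make_joint(SyntheticJointSpec(
            family="plane_pair", radius_a=6, gap=1, resolution=0.5))
        flange.vertices = flange.vertices + np.array([0, 0, 20.0])
        combined = ash.SurfaceMesh(
            np.vstack([socket.vertices, flange.vertices]),
            np.vstack([socket.faces, flange.faces + socket.n_vertices]))
        curv = ash.curvature_field(combined)
        region = ash.candidate_region(combined, curv,
                                      ThresholdSpec(-0.05, "below"))
        assert region.vertex_ids.max() < socket.n_vertices
        socket_interior = (~curv.boundary[:socket.n_vertices]).sum()
        assert len(region.vertex_ids) >= 0.9 * socket_interior

    def test_convex_sphere_has_no_concave_region(self):
        mesh = sphere_mesh(10.0, 3)
        curv = ash.curvature_field(mesh)
        with pytest.raises(ValueError, match="empty"):
            ash.candidate_region(mesh, curv, ThresholdSpec(0.0, "below"))

    def test_admit_all_threshold_selects_whole_mesh(self):
        mesh = sphere_mesh(10.0, 2)
        curv = ash.curvature_field(mesh)
        region = ash.candidate_region(mesh, curv, ThresholdSpec(1e6, "below"))
        assert len(region.vertex_ids) == mesh.n_vertices
        assert region.area == pytest.approx(mesh.area)


class TestCoverage:
    def test_hemisphere_in_socket_area(self):
        ball, _, _ = make_joint(SyntheticJointSpec(
            radius_a=10, radius_b=12, gap=2, resolution=0.5,
            angular_extent=90))
        _, socket, _ = make_joint(SyntheticJointSpec(
            radius_a=10, radius_b=12, gap=2, resolution=0.5,
            angular_extent=110))
        ra = whole_mesh_region(ball)
        rb = whole_mesh_region(socket)
        cov_a, cov_b = ash.coverage(ra, rb, max_ray_length=5.0)
        hemisphere = 2 * np.pi * 10.0 ** 2
        assert abs(cov_a.area - hemisphere) / hemisphere < 0.03
        # fully mated concentric joint: every candidate vertex is covered
        assert len(cov_a.vertex_ids) == ball.n_vertices

    def test_planar_offset_overlap_strip(self):
        a, b, _ = make_joint(SyntheticJointSpec(
            family="plane_pair", radius_a=0.5, gap=2.0, resolution=0.02,
            center_offset=np.array([0.5, 0.0, 0.0])))
        cov_a, cov_b = ash.coverage(whole_mesh_region(a),
                                    whole_mesh_region(b), max_ray_length=5.0)
        assert abs(cov_a.area - 0.5) / 0.5 < 0.05
        assert abs(cov_b.area - 0.5) / 0.5 < 0.05

    def test_back_to_back_patches_uncovered(self):
        a, b, _ = make_joint(SyntheticJointSpec(
            family="plane_pair", radius_a=1.0, gap=2.0, resolution=0.1))
        b.vertices = b.vertices - np.array([0, 0, 4.0])  # below a, facing away
        cov_a, cov_b = ash.coverage(whole_mesh_region(a),
                                    whole_mesh_region(b), max_ray_length=10.0)
        assert cov_a.area == 0.0 and cov_b.area == 0.0

    def test_ray_length_monotonicity(self):
        a, b, _ = make_joint(SyntheticJointSpec(resolution=0.8))
        ra, rb = whole_mesh_region(a), whole_mesh_region(b)
        areas = [ash.coverage(ra, rb, max_ray_length=L)[0].area
                 for L in (0.5, 1.0, 2.5, 5.0, 10.0)]
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))

    def test_same_mesh_rejected(self):
        a, _, _ = make_joint(SyntheticJointSpec(resolution=1.0))
        r = whole_mesh_region(a)
        with pytest.raises(ValueError):
            ash.coverage(r, r)


class TestJointSpace:
    def test_concentric_spheres(self):
        a, b, _ = make_joint(SyntheticJointSpec(
            radius_a=10, radius_b=12, gap=2, resolution=0.5,
            angular_extent=70))
        d = ash.joint_space(whole_mesh_region(a, stage="covered"), b)
        np.testing.assert_allclose(d, 2.0, atol=0.05)

    def test_parallel_planes(self):
        a, b, _ = make_joint(SyntheticJointSpec(
            family="plane_pair", radius_a=3.0, gap=1.7, resolution=0.2))
        d = ash.joint_space(whole_mesh_region(a, stage="covered"), b)
        np.testing.assert_allclose(d, 1.7, atol=1e-9)

    def test_offset_spheres_min_max(self):
        spec = SyntheticJointSpec(radius_a=10, radius_b=12, gap=2,
                                  resolution=0.4, angular_extent=90,
                                  center_offset=np.array([0.5, 0.0, 0.0]))
        a, b, oracle = make_joint(spec)
        # widen the socket so boundary footpoints stay interior
        _, b_wide, _ = make_joint(SyntheticJointSpec(
            radius_a=10, radius_b=12, gap=2, resolution=0.4,
            angular_extent=110, center_offset=spec.center_offset))
        d = ash.joint_space(whole_mesh_region(a, stage="covered"), b_wide)
        assert abs(d.min() - 1.5) < 0.05
        assert abs(d.max() - 2.5) < 0.05
        # full gap field matches the closed form
        np.testing.assert_allclose(d, oracle.gap_a, atol=0.05)

    def test_empty_region_rejected(self):
        a, b, _ = make_joint(SyntheticJointSpec(resolution=1.0))
        empty = ash.ArticularRegion(a, np.zeros(0, int), np.zeros(0, int))
        with pytest.raises(ValueError):
            ash.joint_space(empty, b)


class TestCongruence:
    def test_equal_radius_ball_and_socket_is_perfect(self):
        # r = 8: dyadic curvatures make the umbilic discriminant exactly 0
        d1, d2, delta, ke_min, ke_max, ci = congruence_arrays(
            0.125, 0.015625, -0.125, 0.015625)
        assert d1 == d2 == delta == 0.0
        assert ke_min == ke_max == 0.0
        assert ci == 0.0

    def test_ball_r10_in_socket_r12(self):
        _, _, _, _, _, ci = congruence_arrays(
            0.1, 0.01, -1.0 / 12.0, 1.0 / 144.0)
        assert ci == pytest.approx(1.0 / 60.0, abs=1e-15)

    def test_mated_cylinders_literal_approximation(self):
        """Under cos2α = 1 a perfectly mated cylinder pair gives CI = 1/r,
        not 0 — the printed small-angle form ignores principal-direction
        alignment. Kept literal by design."""
        d1, d2, delta, ke_min, ke_max, ci = congruence_arrays(
            0.05, 0.0, -0.05, 0.0)
        assert d1 == pytest.approx(-0.1) and d2 == pytest.approx(-0.1)
        assert delta == pytest.approx(0.2)
        assert ke_min == pytest.approx(-0.1) and ke_max == pytest.approx(0.1)
        assert ci == pytest.approx(0.1, abs=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-0.5, 0.5), st.floats(-0.2, 0.2),
           st.floats(-0.5, 0.5), st.floats(-0.2, 0.2))
    def test_swap_symmetry(self, ha, ga, hb, gb):
        *_, ci_ab = congruence_arrays(ha, ga, hb, gb)
        *_, ci_ba = congruence_arrays(hb, gb, ha, ga)
        assert ci_ab == pytest.approx(ci_ba, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-0.5, 0.5), st.floats(-0.2, 0.2),
           st.floats(-0.5, 0.5), st.floats(-0.2, 0.2),
           st.floats(0.1, 10.0))
    def test_inverse_length_scaling(self, ha, ga, hb, gb, s):
        """Scaling all lengths by s scales curvature by 1/s, G by 1/s²,
        hence CI by 1/s."""
        *_, ci = congruence_arrays(ha, ga, hb, gb)
        *_, ci_scaled = congruence_arrays(ha / s, ga / s ** 2,
                                          hb / s, gb / s ** 2)
        assert ci_scaled == pytest.approx(ci / s, rel=1e-9, abs=1e-12)

    def test_records_and_invariants(self):
        records = ash.congruence(
            _FakeField([0.1, 0.2], [0.01, 0.03]),
            _FakeField([-0.1, -0.15], [0.01, 0.02]),
            [(0, 0), (1, 1)])
        for r in records:
            assert r.delta >= 0
            assert r.Ke_min <= r.Ke_max
            assert r.CI >= 0
            assert r.alpha == 0.0


class _FakeField:
    def __init__(self, H, G):
        self.H = np.asarray(H, float)
        self.G = np.asarray(G, float)


class TestParticleMap:
    def test_identical_subjects(self):
        vals = np.array([1.0, 2.0, np.nan, 4.0])
        pm = ash.particle_map({"a": vals, "b": vals.copy()})
        np.testing.assert_allclose(pm.per_particle_sd[~np.isnan(
            pm.per_particle_sd)], 0.0)
        assert pm.global_mean == pytest.approx(np.nanmean(vals))

    def test_hand_computed_two_subject_aggregates(self):
        pm = ash.particle_map({"a": np.array([1.0, 3.0, np.nan]),
                               "b": np.array([2.0, 5.0, np.nan])},
                              inclusion_rule=0.5)
        np.testing.assert_array_equal(pm.particle_ids, [0, 1])
        np.testing.assert_allclose(pm.per_particle_mean, [1.5, 4.0])
        np.testing.assert_allclose(pm.per_particle_sd,
                                   [np.sqrt(0.5), np.sqrt(2.0)])
        assert pm.global_mean == pytest.approx(11.0 / 4.0)
        assert pm.global_min == 1.0 and pm.global_max == 5.0

    def test_aggregates_match_brute_force(self, rng):
        table = rng.normal(size=(6, 20))
        table[rng.random(table.shape) < 0.3] = np.nan
        values = {f"s{i}": table[i] for i in range(6)}
        pm = ash.particle_map(values, inclusion_rule=0.5)
        raw = table[:, pm.particle_ids]
        flat = raw[~np.isnan(raw)]
        assert pm.global_mean == pytest.approx(flat.mean())
        assert pm.global_sd == pytest.approx(flat.std(ddof=1))
        assert pm.global_min == flat.min() and pm.global_max == flat.max()

    def test_inclusion_rule(self):
        vals = {"a": np.array([1.0, np.nan]), "b": np.array([2.0, np.nan]),
                "c": np.array([3.0, 9.0])}
        pm = ash.particle_map(vals, inclusion_rule=0.5)
        np.testing.assert_array_equal(pm.particle_ids, [0])
        with pytest.raises(ValueError):
            ash.particle_map({"a": np.array([np.nan])})


class TestPairedStats:
    def test_hand_computed_example(self):
        """Differences [1,2,3]: mean 2, sd 1, d = 2, t = 2√3, p ≈ 0.0742."""
        s = ash.paired_area_stats([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert s.mean_difference == pytest.approx(2.0)
        assert s.sd_difference == pytest.approx(1.0)
        assert s.cohens_d == pytest.approx(2.0)
        assert s.t == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert s.df == 2
        assert s.p_two_tailed == pytest.approx(
            2 * sps.t.sf(2 * np.sqrt(3), 2), abs=1e-12)
        assert s.p_two_tailed == pytest.approx(0.0742, abs=2e-4)
        assert s.effect_label == "large"

    def test_identical_pairs_degenerate(self):
        s = ash.paired_area_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.degenerate
        assert s.mean_difference == 0.0

    @pytest.mark.parametrize("d,label", [(0.1, "small"), (0.2, "small"),
                                         (0.5, "medium"), (0.79, "medium"),
                                         (0.8, "large"), (2.0, "large")])
    def test_effect_labels(self, d, label, rng):
        from arthroshape.articulation import _effect_label
        assert _effect_label(d) == label

    def test_power_matches_monte_carlo(self, rng):
        """Post-hoc power agrees with simulated paired-t rejection rates."""
        d, n, alpha = 0.8, 15, 0.05
        power = ash.articulation.paired_t_power(d, n, alpha)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            x = rng.normal(d, 1.0, n)
            t = x.mean() / (x.std(ddof=1) / np.sqrt(n))
            rejections += abs(t) > sps.t.ppf(1 - alpha / 2, n - 1)
        assert abs(power - rejections / reps) < 0.025

    def test_sign_convention(self):
        s = ash.paired_area_stats([1.0, 1.5, 0.5], [2.0, 3.0, 2.5])
        assert np.sign(s.t) == np.sign(s.mean_difference) == -1


class TestRequiredN:
    def test_large_effect_small_n(self):
        assert ash.required_n(2.0, 0.05, 0.95) == 6

    def test_limit_of_huge_effect(self):
        assert ash.required_n(50.0, 0.05, 0.8) <= 3

    def test_small_effect_matches_normal_approximation(self):
        # exact noncentral-t count sits just above the normal approximation
        # (the usual small df correction), within ±2 of its rounded value
        n = ash.required_n(0.05, 0.05, 0.80)
        closed_form = ((sps.norm.ppf(0.975) + sps.norm.ppf(0.8)) / 0.05) ** 2
        assert abs(n - round(closed_form)) <= 2

    def test_minimality(self):
        n = ash.required_n(0.8, 0.05, 0.9)
        assert ash.articulation.paired_t_power(0.8, n) >= 0.9
        assert ash.articulation.paired_t_power(0.8, n - 1) < 0.9

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ash.required_n(-1.0)
        with pytest.raises(ValueError):
            ash.required_n(0.5, alpha=1.5)
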