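"""Pairwise force/torque laws and the force accumulator."""
import numpy as np
import pytest

import fibrenet as fn
from conftest import naive_force_sum, random_state


class TestRepulsion:
    def test_zero_out_of_contact(self, geom, box):
        ft = fn.repulsion_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 2.5 * geom.R_fib], [1, 0, 0],
            geom, 12.5, box,
        )
        assert np.all(ft.F_on_1 == 0) and np.all(ft.T_on_2 == 0)

    def test_action_reaction_and_direction(self, geom, box):
        ft = fn.repulsion_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 0.6], [1, 0, 0], geom, 12.5, box
        )
        np.testing.assert_allclose(ft.F_on_1, -ft.F_on_2)
        assert ft.F_on_1[2] < 0  # pushes fibre 1 away from fibre 2 (which sits above)
        # overlap 0.4: Hertz magnitude alpha * 0.4^1.5 / sqrt(1)
        assert np.linalg.norm(ft.F_on_1) == pytest.approx(12.5 * 0.4**1.5)

    def test_force_applied_at_closest_point_generates_torque(self, geom, box):
        # crossing near one end: lever arm produces opposite-sign torques
        ft = fn.repulsion_force_torque(
            [0, 0, 0], [1, 0, 0], [2.0, 0, 0.5], [0, 1, 0], geom, 12.5, box
        )
        assert np.linalg.norm(ft.T_on_1) > 0
        # torque on fibre 1 = (s1 w1) x F with s1 = 2
        np.testing.assert_allclose(
            ft.T_on_1, np.cross([2.0, 0, 0], ft.F_on_1), atol=1e-12
        )

    def test_coincident_fallback_is_deterministic_and_perpendicular(self, geom, box):
        ft1 = fn.repulsion_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 0], [1, 0, 0], geom, 12.5, box, indices=(3, 7)
        )
        ft2 = fn.repulsion_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 0], [1, 0, 0], geom, 12.5, box, indices=(3, 7)
        )
        np.testing.assert_array_equal(ft1.F_on_1, ft2.F_on_1)
        assert np.linalg.norm(ft1.F_on_1) > 0
        assert abs(ft1.F_on_1 @ np.array([1.0, 0, 0])) < 1e-9


class TestSpring:
    def test_zero_at_unloaded_length(self, geom, box):
        ft = fn.spring_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 1.0], [1, 0, 0], 0.0, 0.0,
            geom, 5.0, 1.0, box,
        )
        np.testing.assert_allclose(ft.F_on_1, 0, atol=1e-12)

    def test_restoring_sign(self, geom, box):
        stretched = fn.spring_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 2.0], [1, 0, 0], 0.0, 0.0,
            geom, 5.0, 1.0, box,
        )
        assert stretched.F_on_1[2] > 0  # pulled towards partner above
        compressed = fn.spring_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 0.5], [1, 0, 0], 0.0, 0.0,
            geom, 5.0, 1.0, box,
        )
        assert compressed.F_on_1[2] < 0
        np.testing.assert_allclose(stretched.F_on_1, -stretched.F_on_2)

    def test_attachment_abscissae_bounds(self, geom, box):
        with pytest.raises(ValueError):
            fn.spring_force_torque(
                [0, 0, 0], [1, 0, 0], [0, 0, 1], [1, 0, 0], 5.0, 0.0,
                geom, 5.0, 1.0, box,
            )

    def test_attachment_lever_arm_torque(self, geom, box):
        ft = fn.spring_force_torque(
            [0, 0, 0], [1, 0, 0], [0, 0, 2.0], [1, 0, 0], 2.0, -1.0,
            geom, 5.0, 1.0, box,
        )
        np.testing.assert_allclose(ft.T_on_1, np.cross([2.0, 0, 0], ft.F_on_1), atol=1e-12)
        np.testing.assert_allclose(ft.T_on_2, np.cross([-1.0, 0, 0], ft.F_on_2), atol=1e-12)


class TestAlignment:
    def test_zero_for_aligned(self):
        ft = fn.alignment_torque([1, 0, 0], [1, 0, 0], 2.0)
        assert np.all(ft.T_on_1 == 0)
        ft = fn.alignment_torque([1, 0, 0], [-1, 0, 0], 2.0)
        np.testing.assert_allclose(ft.T_on_1, 0, atol=1e-15)

    def test_nematic_sign_invariance(self, rng):
        w1 = rng.normal(size=3)
        w1 /= np.linalg.norm(w1)
        w2 = rng.normal(size=3)
        w2 /= np.linalg.norm(w2)
        a = fn.alignment_torque(w1, w2, 2.0)
        b = fn.alignment_torque(w1, -w2, 2.0)
        c = fn.alignment_torque(-w1, w2, 2.0)
        np.testing.assert_allclose(a.T_on_1, b.T_on_1, atol=1e-12)
        np.testing.assert_allclose(a.T_on_1, c.T_on_1, atol=1e-12)

    def test_pure_torque_no_force(self):
        ft = fn.alignment_torque([1, 0, 0], [0.6, 0.8, 0], 2.0)
        assert np.all(ft.F_on_1 == 0) and np.all(ft.F_on_2 == 0)
        np.testing.assert_allclose(ft.T_on_1, -ft.T_on_2)

    def test_perpendicular_is_stationary(self):
        """Exactly perpendicular fibres sit at the nematic potential's maximum
        where the torque of V = -(a/2)(w1.w2)^2 is exactly zero."""
        ft = fn.alignment_torque([1, 0, 0], [0, 1, 0], 2.0)
        np.testing.assert_allclose(ft.T_on_1, 0, atol=1e-15)

    def test_magnitude_cos_sin(self):
        th = 0.7
        w2 = [np.cos(th), np.sin(th), 0]
        ft = fn.alignment_torque([1, 0, 0], w2, 2.0)
        assert np.linalg.norm(ft.T_on_1) == pytest.approx(
            2.0 * abs(np.cos(th) * np.sin(th))
        )

    def test_rotates_towards_nearer_pole(self):
        """dw/dt = T ^ w moves w1 towards +-w2, whichever is nearer."""
        for th in (0.4, np.pi - 0.4):
            w1 = np.array([1.0, 0, 0])
            w2 = np.array([np.cos(th), np.sin(th), 0.0])
            ft = fn.alignment_torque(w1, w2, 2.0)
            dw = np.cross(ft.T_on_1, w1)
            target = w2 if np.dot(w1, w2) > 0 else -w2
            assert np.dot(dw, target - w1 * (w1 @ target)) > 0


class TestAccumulate:
    def test_empty_system_all_zero(self, params, box):
        state = random_state(10, box, seed=2)
        state.X[:, 0] = np.linspace(-14, 13, 10)  # spread out: no contacts
        state.X[:, 1] = np.linspace(-14, 13, 10)
        F, T = fn.accumulate_forces(state, fn.LinkTable(), params, box)
        assert np.all(F == 0) and np.all(T == 0)

    def test_matches_naive_all_pairs(self, params, box):
        """Neighbour-search accumulation equals the O(N^2) brute-force sums."""
        state = random_state(50, box, seed=3)
        links = fn.make_link_topology(
            state, "bernoulli", parameter=0.6, seed=11,
            geom=params.geometry, box=box, d_link_max=params.d_link_max,
        )
        F, T = fn.accumulate_forces(state, links, params, box)
        F0, T0 = naive_force_sum(state, links, params, box)
        np.testing.assert_allclose(F, F0, atol=1e-10)
        np.testing.assert_allclose(T, T0, atol=1e-10)

    def test_newtons_third_law_sums_to_zero(self, params, box):
        state = random_state(80, box, seed=8)
        links = fn.make_link_topology(
            state, "bernoulli", parameter=0.5, seed=12,
            geom=params.geometry, box=box, d_link_max=params.d_link_max,
        )
        F, _ = fn.accumulate_forces(state, links, params, box)
        np.testing.assert_allclose(F.sum(axis=0), 0, atol=1e-9)

    def test_two_fibre_potential_decreases(self, params, box):
        """Pair alignment potential decreases monotonically under the dynamics."""
        state, links = fn.make_two_fibre_fixture("align", params.geometry, tilt=0.3)
        p = params.with_(alpha_rep=0.0, alpha_rest=0.0)
        ctrl = fn.StepControl(dt_max=0.5)
        last = -0.5 * p.alpha_align * float(state.omega[0] @ state.omega[1]) ** 2
        for _ in range(200):
            state, _ = fn.euler_step(state, links, p, ctrl, box)
            v = -0.5 * p.alpha_align * float(state.omega[0] @ state.omega[1]) ** 2
            assert v <= last + 1e-12
            last = v
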