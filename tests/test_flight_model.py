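import numpy as np
import pytest

import hemotrace as ht


class TestDragCoefficient:
    def test_stokes_limit_via_cd_re_product(self):
        re = 1e-8
        assert ht.drag_coefficient(re) * re == pytest.approx(24.0, rel=1e-4)

    def test_unit_reynolds(self):
        assert ht.drag_coefficient(1.0) == pytest.approx(27.6, rel=1e-12)

    def test_value_at_cap(self):
        cd = ht.drag_coefficient(1000.0)
        assert cd == pytest.approx((24.0 / 1000.0) * (1.0 + 0.15 * 1000.0**0.687), rel=1e-12)
        assert cd == pytest.approx(0.438, abs=5e-3)

    def test_constant_above_cap(self):
        assert ht.drag_coefficient(5000.0) == ht.drag_coefficient(1000.0)

    def test_rejects_negative_reynolds(self):
        with pytest.raises(ValueError):
            ht.drag_coefficient(-1.0)


class TestAcceleration:
    def test_droplet_at_rest_feels_only_gravity(self, props, env):
        s = ht.DropletState(0.0, (0, 0, 1), (0, 0, 0), 1e-3)
        assert np.allclose(ht.acceleration(s, props, env), (0, 0, -9.81))

    def test_crosswind_pushes_droplet_downwind(self, props):
        env = ht.AirEnvironment(wind=(0.5, 0.0, 0.0))
        s = ht.DropletState(0.0, (0, 0, 1), (0, 0, 0), 1e-3)
        a = ht.acceleration(s, props, env)
        assert a[0] > 0 and a[1] == 0 and a[2] == pytest.approx(-9.81)

    def test_wind_matching_velocity_cancels_drag(self, props):
        env = ht.AirEnvironment(wind=(1.0, -2.0, 0.5))
        s = ht.DropletState(0.0, (0, 0, 1), (1.0, -2.0, 0.5), 1e-3)
        assert np.allclose(ht.acceleration(s, props, env), (0, 0, -9.81))

    def test_stokes_terminal_velocity_balance(self, props, env):
        # 20 um droplet: v_t = rho_b g D^2 / (18 eta_air); the residual
        # acceleration is only the small Schiller-Naumann correction
        d = 20e-6
        v_t = props.density * env.g * d**2 / (18.0 * env.air_viscosity)
        s = ht.DropletState(0.0, (0, 0, 1), (0, 0, -v_t), d)
        a = ht.acceleration(s, props, env)
        assert abs(a[2]) < 0.02 * env.g


class TestIntegrate:
    def test_gravity_model_matches_closed_form_parabola(self, props, env):
        s0 = ht.DropletState(0.0, (0, 0, 0), (2.0, 0.0, 3.0), 1e-3)
        traj = ht.integrate(s0, props, env, model="gravity", dt=1e-4, t_end=0.2)
        end = traj.end_state
        assert end.position[0] == pytest.approx(0.4, rel=1e-10)
        assert end.position[2] == pytest.approx(3.0 * 0.2 - 0.5 * 9.81 * 0.04, rel=1e-10)

    def test_straight_model_ignores_all_forces(self, props):
        env = ht.AirEnvironment(wind=(2.0, 2.0, 2.0))
        s0 = ht.DropletState(0.0, (1, 2, 3), (0.5, -0.25, 1.0), 1e-3)
        traj = ht.integrate(s0, props, env, model="straight", dt=1e-3, t_end=0.5)
        assert np.allclose(
            traj.end_state.position, np.array([1, 2, 3]) + 0.5 * np.array([0.5, -0.25, 1.0])
        )

    @pytest.mark.parametrize("model", ["straight", "gravity", "gravity_drag"])
    def test_time_reversal_round_trip(self, model, props, env):
        s0 = ht.DropletState(0.0, (0, 0, 1), (4.0, 0.5, 1.0), 1e-3)
        fwd = ht.integrate(s0, props, env, model=model, dt=1e-4, t_end=0.3)
        back = ht.integrate(fwd.end_state, props, env, model=model, dt=-1e-4, t_end=-0.3)
        assert np.allclose(back.end_state.position, s0.position, atol=1e-9)
        assert np.allclose(back.end_state.velocity, s0.velocity, atol=1e-9)

    def test_gravity_model_conserves_energy(self, props, env):
        s0 = ht.DropletState(0.0, (0, 0, 1), (3.0, 0.0, 2.0), 1e-3)
        traj = ht.integrate(s0, props, env, model="gravity", dt=1e-4, t_end=0.4)
        speeds2 = np.einsum("ij,ij->i", traj.velocities, traj.velocities)
        e = 0.5 * speeds2 + env.g * traj.positions[:, 2]
        assert np.ptp(e) < 1e-9 * e[0]

    def test_rk4_is_fourth_order(self, props, env):
        s0 = ht.DropletState(0.0, (0, 0, 1), (3.0, 0.0, 1.0), 5e-4)

        def end_pos(dt):
            return ht.integrate(
                s0, props, env, model="gravity_drag", dt=dt, t_end=0.256
            ).end_state.position

        ref = end_pos(0.004 / 64.0)
        e1 = np.linalg.norm(end_pos(0.004) - ref)
        e2 = np.linalg.norm(end_pos(0.002) - ref)
        assert 8.0 < e1 / e2 < 32.0  # ~16x per halving

    def test_step_budget_enforced(self, props, env):
        s0 = ht.DropletState(0.0, (0, 0, 1), (1.0, 0, 0), 1e-3)
        with pytest.raises(ht.RunawayIntegrationError):
            ht.integrate(s0, props, env, dt=1e-6, t_end=10.0, max_steps=100)

    def test_rejects_inconsistent_signs(self, props, env):
        s0 = ht.DropletState(0.0, (0, 0, 1), (1.0, 0, 0), 1e-3)
        with pytest.raises(ValueError):
            ht.integrate(s0, props, env, dt=-1e-4, t_end=1.0)


class TestBackwardTrajectory:
    def test_straight_model_is_a_ray_along_backward_dir(self, props, env):
        bdir = np.array([1.0, 0.0, 0.0])
        traj = ht.backward_trajectory(
            (0.0, 1.0, 1.0), 3.0, bdir, 1e-3, props, env, model="straight",
            max_depth_m=2.0,
        )
        assert traj.line_point is not None
        # point at arclength 1 m sits at stain + bdir
        arc = np.linalg.norm(traj.positions - traj.positions[0], axis=1)
        i = np.argmin(np.abs(arc - 1.0))
        assert np.allclose(traj.positions[i], np.array([0.0, 1.0, 1.0]) + bdir, atol=1e-3)

    def test_head_on_stain_is_the_apex_of_its_backward_parabola(self, props, env):
        # alpha = 90: impact velocity is horizontal, so the wall point is the
        # parabola's apex and the backward gravity path descends from it
        traj = ht.backward_trajectory(
            (0.0, 1.0, 1.0), 3.0, (1.0, 0.0, 0.0), 1e-3, props, env, model="gravity",
            max_depth_m=1.5, z_range_m=(0.0, 5.0),
        )
        z = traj.positions[:, 2]
        assert np.all(z <= z[0] + 1e-12) and z[-1] < z[0]
        assert np.all(np.diff(z) <= 0)

    def test_backward_speed_inflates_under_drag(self, props, env):
        traj = ht.backward_trajectory(
            (0.0, 1.0, 1.0), 3.0, (0.8, 0.0, 0.6), 1e-3, props, env,
            model="gravity_drag", max_depth_m=1.0, z_range_m=(0.0, 5.0),
        )
        speeds = np.linalg.norm(traj.velocities, axis=1)
        assert speeds[-1] > speeds[0]

    def test_drag_path_lies_between_straight_and_gravity(self, props, env):
        """At equal depth the drag path's height is bracketed by the other two."""
        stain = (0.0, 1.0, 1.2)
        bdir = np.array([0.7, 0.1, 0.702]) / np.linalg.norm([0.7, 0.1, 0.702])
        heights = {}
        for model in ("straight", "gravity", "gravity_drag"):
            traj = ht.backward_trajectory(
                stain, 4.0, bdir, 1e-3, props, env, model=model,
                max_depth_m=1.2, z_range_m=(0.0, 5.0),
            )
            x, z = traj.positions[:, 0], traj.positions[:, 2]
            heights[model] = float(np.interp(1.0, x, z))
        assert heights["gravity"] < heights["gravity_drag"] < heights["straight"]
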