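"""Unit tests for forces, torques, Brownian updates and constraints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinbind import (CargoMotorState, EnvironmentGeometry, MotorState,
                     PhysicalParams, motor_torque, tether_force,
                     update_cargo, update_head, update_orientation_anchor,
                     wall_correction_factors)


def mkstate(c, a, h, kstate=MotorState.ADP_FREE, a_mt=None):
    return CargoMotorState(c=c, a=a, h=h, kstate=kstate, a_mt=a_mt)


class TestTetherForce:
    def test_zero_at_rest_length(self, phys):
        a = np.zeros(3)
        h = np.array([0.0, 0.0, phys.L_m])
        fh, fc = tether_force(a, h, MotorState.ADP_FREE, None, phys)
        assert np.allclose(fh, 0) and np.allclose(fc, 0)

    def test_hookean_branch_magnitude(self):
        # kappa_m=0.32, L_m=45, 50 nm separation -> 1.6 pN toward anchor
        p = PhysicalParams(kappa_m=0.32, L_m=45.0)
        a = np.zeros(3)
        h = np.array([0.0, 0.0, 50.0])
        fh, fc = tether_force(a, h, MotorState.ADP_FREE, None, p)
        assert np.allclose(fh, [0, 0, -1.6], atol=1e-12)
        assert np.allclose(fc, [0, 0, 1.6], atol=1e-12)  # third law

    def test_weak_spring_when_slack(self, phys):
        # slack tether: only the weak bond acts on the head by default
        a = np.zeros(3)
        h = np.array([0.0, 0.0, 10.0])
        a_mt = np.array([0.0, 0.0, 0.0])
        fh, fc = tether_force(a, h, MotorState.WEAK, a_mt, phys,
                              kappa_w=0.0020)
        assert np.allclose(fh, [0, 0, -0.02], atol=1e-12)
        assert np.allclose(fc, 0)  # weak bond pulls against the MT, not cargo

    def test_taut_only_flag_suppresses_slack_weak_force(self):
        p = PhysicalParams(weak_force_taut_only=True)
        a = np.zeros(3)
        h = np.array([0.0, 0.0, 10.0])
        fh, _ = tether_force(a, h, MotorState.WEAK, np.zeros(3), p,
                             kappa_w=0.0020)
        assert np.allclose(fh, 0)

    def test_same_sign_convention_flag(self):
        p = PhysicalParams(third_law_cargo_force=False)
        a = np.zeros(3)
        h = np.array([0.0, 0.0, 50.0])
        fh, fc = tether_force(a, h, MotorState.ADP_FREE, None, p)
        assert np.allclose(fh, fc)

    def test_coincident_points_rejected(self, phys):
        with pytest.raises(ValueError, match="degenerate"):
            tether_force(np.zeros(3), np.zeros(3), MotorState.ADP_FREE,
                         None, phys)


class TestMotorTorque:
    def test_zero_when_unbound(self):
        tq = motor_torque(np.array([0, 0, -280.0]), np.zeros(3), np.zeros(3),
                          MotorState.ADP_FREE, np.array([1.0, 0, 0]))
        assert np.allclose(tq, 0)

    def test_zero_for_parallel_lever_and_force(self):
        tq = motor_torque(np.array([0, 0, -280.0]), None, np.zeros(3),
                          MotorState.WEAK, np.array([0, 0, 2.0]))
        assert np.allclose(tq, 0)

    def test_hand_cross_product(self):
        tq = motor_torque(np.array([0, 0, -280.0]), None, np.zeros(3),
                          MotorState.WEAK, np.array([1.0, 0, 0]))
        assert np.allclose(tq, [0.0, -280.0, 0.0])

    def test_torque_always_flag(self):
        tq = motor_torque(np.array([0, 0, -280.0]), None, np.zeros(3),
                          MotorState.ADP_FREE, np.array([1.0, 0, 0]),
                          torque_always=True)
        assert np.allclose(tq, [0.0, -280.0, 0.0])


class TestCargoUpdate:
    def test_fixed_point_with_trap_at_center(self, phys, geom):
        st = mkstate(geom.trap_center, geom.trap_center + [0, 0, -280.0],
                     [0, 0, 80.0])
        c = update_cargo(st, np.zeros(3), geom, phys, dt=0.004, rng=None)
        assert np.allclose(c, geom.trap_center)

    def test_deterministic_drift_through_mobility(self, phys, geom):
        # dz = F dt / (6 pi eta R): -1 pN over 0.004 s -> -7.58e-2 nm,
        # isolating the motor force by placing the trap at the current c
        st = mkstate(geom.trap_center, geom.trap_center + [0, 0, -280.0],
                     [0, 0, 80.0])
        c = update_cargo(st, np.array([0, 0, -1.0]), geom, phys, dt=0.004,
                        rng=None)
        expected = -1.0 * 0.004 / (6 * math.pi * 1e-5 * 280.0)
        assert np.isclose(c[2] - st.c[2], expected, rtol=1e-12)
        assert np.isclose(expected, -7.58e-2, atol=5e-4)

    def test_trap_restores_per_axis(self, phys, geom):
        st = mkstate(geom.trap_center + [10.0, 0, 0],
                     geom.trap_center + [10, 0, -280.0], [0, 0, 80.0])
        c = update_cargo(st, np.zeros(3), geom, phys, dt=0.004, rng=None)
        assert c[0] < st.c[0]  # pulled back toward the trap center

    def test_mt_exclusion_projection(self, phys):
        geom = EnvironmentGeometry(trap_center=np.array([0.0, 0.0, 250.0]))
        # propose a center overlapping the microtubule
        st = mkstate([0, 0, 270.0], [0, 0, -10.0], [0, 0, 5.0])
        st.c = np.array([0.0, 0.0, 250.0])
        c = update_cargo(st, np.array([0, 0, -500.0]), geom, phys, dt=0.01,
                        rng=None)
        d = math.hypot(c[1], c[2] - geom.mt_radius)
        assert d >= phys.R + geom.mt_radius - 1e-9


class TestAnchorUpdate:
    def test_identity_without_torque_or_noise(self, phys, geom):
        st = mkstate(geom.trap_center, geom.trap_center + [0, 0, -280.0],
                     [0, 0, 80.0])
        a = update_orientation_anchor(st, np.zeros(3), phys, dt=0.004,
                                      rng=None)
        assert np.allclose(a, st.a)

    def test_translates_with_cargo(self, phys, geom):
        st = mkstate(geom.trap_center, geom.trap_center + [0, 0, -280.0],
                     [0, 0, 80.0])
        c_new = st.c + np.array([3.0, 0, 0])
        a = update_orientation_anchor(st, np.zeros(3), phys, dt=0.004,
                                      rng=None, c_new=c_new)
        assert np.allclose(a, st.a + [3.0, 0, 0])

    def test_quarter_turn(self, geom):
        # drive a pi/2 rotation about z through the torque term
        p = PhysicalParams()
        xi_rot = 8 * math.pi * p.eta * p.R ** 3
        dt = 0.004
        torque = np.array([0.0, 0.0, (math.pi / 2) * xi_rot / dt])
        st = mkstate([0.0, 0, 0], [p.R, 0, 0], [0, 0, 500.0])
        st.c = np.zeros(3)
        a = update_orientation_anchor(st, torque, p, dt=dt, rng=None)
        assert np.allclose(a, [0.0, p.R, 0.0], atol=1e-9)

    def test_radius_preserved_over_many_noisy_steps(self, phys, geom):
        rng = np.random.default_rng(5)
        st = mkstate(geom.trap_center, geom.trap_center + [0, 0, -280.0],
                     [0, 0, 80.0])
        a = st.a.copy()
        for _ in range(2000):
            st.a = a
            a = update_orientation_anchor(
                st, rng.normal(size=3) * 1e3, phys, dt=0.004, rng=rng)
        assert abs(np.linalg.norm(a - st.c) - phys.R) < 1e-6


class TestHeadUpdate:
    def test_no_force_no_noise_is_identity(self, phys, geom):
        st = mkstate(geom.trap_center, geom.trap_center + [0, 0, -280.0],
                     [0, 0, 80.0])
        h = update_head(st, np.zeros(3), geom, phys, dt=0.004, rng=None)
        assert np.allclose(h, st.h)

    def test_mt_projection(self, phys):
        geom = EnvironmentGeometry()
        st = mkstate([0, 0, 1e6], [0, 0, 1e6 - 280], [0.0, 0.0, 15.0])
        # drive the head into the microtubule
        h = update_head(st, np.array([0, 0, -1e4]), geom, phys, dt=0.004,
                        rng=None)
        assert math.hypot(h[1], h[2] - geom.mt_radius) >= geom.mt_radius - 1e-9

    def test_coverslip_floor(self, phys):
        geom = EnvironmentGeometry()
        st = mkstate([0, 0, 1e6], [0, 0, 1e6 - 280], [0.0, 200.0, 2.0])
        h = update_head(st, np.array([0, 0, -1e4]), geom, phys, dt=0.004,
                        rng=None)
        assert h[2] >= 0.0

    def test_cargo_exclusion(self, phys):
        geom = EnvironmentGeometry()
        st = mkstate([0, 0, 500.0], [0, 0, 220.0], [0.0, 0.0, 230.0])
        h = update_head(st, np.zeros(3), geom, phys, dt=0.004, rng=None)
        assert np.linalg.norm(h - st.c) >= phys.R - 1e-9


class TestWallCorrection:
    def test_bulk_limit(self):
        ft, fr = wall_correction_factors(1e12, 280.0)
        assert math.isclose(ft, 1.0, rel_tol=1e-9)
        assert math.isclose(fr, 1.0, rel_tol=1e-9)

    def test_hand_evaluated_at_two_radii(self):
        # (1 - 9/16 + 1/64)^-1 and (1 - 5/128 + 15/16384)^-1 at z = 2R
        ft, fr = wall_correction_factors(560.0, 280.0)
        assert math.isclose(ft, 1.0 / (1 - 9 / 16 + 1 / 64), rel_tol=1e-14)
        assert math.isclose(fr, 1.0 / (1 - 5 / 128 + 15 / 16384),
                            rel_tol=1e-14)
        assert math.isclose(ft, 2.2069, rel_tol=1e-4)
        assert math.isclose(fr, 1.0397, rel_tol=1e-4)

    def test_wall_contact_rejected(self):
        with pytest.raises(ValueError):
            wall_correction_factors(280.0, 280.0)

    @given(st.floats(min_value=1.01, max_value=50.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_decreasing_with_height(self, ratio):
        ft1, fr1 = wall_correction_factors(ratio * 280.0, 280.0)
        ft2, fr2 = wall_correction_factors((ratio + 0.5) * 280.0, 280.0)
        assert ft1 >= ft2 >= 1.0
        assert fr1 >= fr2 >= 1.0


@given(st.floats(-60, 60), st.floats(-60, 60), st.floats(-60, 60))
@settings(max_examples=50, deadline=None)
def test_projection_moves_less_than_the_step(dx, dy, dz):
    """A projected head never moves farther from the proposal than the
    proposed step itself (nearest-point projection from a feasible
    start)."""
    phys = PhysicalParams()
    geom = EnvironmentGeometry()
    start = np.array([0.0, 30.0, 40.0])  # feasible
    st = mkstate([0, 0, 500.0], [0, 0, 220.0], start)
    step = np.array([dx, dy, dz])
    force = step * phys.kBT / (phys.D_m * 0.004)  # drift = step exactly
    h = update_head(st, force, geom, phys, dt=0.004, rng=None)
    proposed = start + step
    assert (np.linalg.norm(h - proposed)
            <= np.linalg.norm(step) + 1e-9)
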