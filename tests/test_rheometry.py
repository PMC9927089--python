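"""Rotating-disc rheometry: moment coefficients, slope transform, events,
wall shear stress, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmmech import DiscGeometry, TorqueVelocityCurve, generate_torque_curve
from biofilmmech.errors import DomainError
from biofilmmech.rheometry import (
    SlopeSeries,
    biofilm_momentum_coefficient,
    critical_detachment_shear_stress,
    detect_detachment_events,
    linearized_slope_transform,
    momentum_coefficient_curve,
    smooth_disc_moment_coefficient,
    torque_auc,
    wall_shear_stress,
)


class TestSmoothDiscCoefficient:
    def test_laminar_hand_value(self, geometry, fluid):
        # omega=25 -> Re = 25 * 0.02^2 / 1e-6 = 1e4 -> 1.935/sqrt(Re)
        assert smooth_disc_moment_coefficient(25.0, geometry, fluid) == pytest.approx(
            0.01935, rel=1e-12)

    def test_unit_reynolds(self, geometry, fluid):
        omega_re1 = fluid.kinematic_viscosity / geometry.radius**2
        assert smooth_disc_moment_coefficient(omega_re1, geometry, fluid) == pytest.approx(
            1.935, rel=1e-12)

    def test_branch_boundary_uses_laminar(self, geometry, fluid):
        omega_star = 3e5 * fluid.kinematic_viscosity / geometry.radius**2
        cm = smooth_disc_moment_coefficient(omega_star, geometry, fluid)
        assert cm == pytest.approx(1.935 / np.sqrt(3e5), rel=1e-12)
        # just above the boundary, the turbulent branch takes over
        cm_above = smooth_disc_moment_coefficient(omega_star * 1.001, geometry, fluid)
        assert cm_above == pytest.approx(0.0365 * (3e5 * 1.001) ** -0.2, rel=1e-12)

    def test_nonpositive_omega_rejected(self, geometry, fluid):
        with pytest.raises(DomainError):
            smooth_disc_moment_coefficient(0.0, geometry, fluid)


class TestMomentumCoefficient:
    def _curve(self, omega, torque):
        return TorqueVelocityCurve(omega=np.asarray(omega), torque=np.asarray(torque))

    def test_hand_substitution(self, geometry, fluid):
        curve = self._curve([1.0, 10.0, 100.0], [1e-6, 1e-4, 1e-2])
        cm = momentum_coefficient_curve(curve, geometry, fluid)
        assert cm[1] == pytest.approx(1e-4 / 1.5968e-4, rel=1e-4)

    def test_zero_torque_gives_zero(self, geometry, fluid):
        curve = self._curve([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert np.all(momentum_coefficient_curve(curve, geometry, fluid) == 0)

    def test_radius_fifth_power_scaling(self, fluid):
        curve = self._curve([1.0, 2.0, 3.0], [1e-5, 2e-5, 3e-5])
        small = momentum_coefficient_curve(curve, DiscGeometry(radius=0.02), fluid)
        big = momentum_coefficient_curve(curve, DiscGeometry(radius=0.04), fluid)
        np.testing.assert_allclose(small / big, 32.0, rtol=1e-12)

    @pytest.mark.parametrize("cf_true", [0.05, 0.063])
    def test_generator_inverse_noise_free(self, cf_true, geometry, fluid):
        curve, _ = generate_torque_curve(cf_true, noise_sd=0.0)
        cf = biofilm_momentum_coefficient(curve, geometry, fluid)
        assert cf == pytest.approx(cf_true, abs=1e-10)

    def test_smooth_disc_baseline_recovers_zero(self, geometry, fluid):
        curve, _ = generate_torque_curve(0.0, noise_sd=0.0)
        assert biofilm_momentum_coefficient(curve, geometry, fluid) == pytest.approx(
            0.0, abs=1e-10)

    def test_noisy_recovery_within_five_percent(self, geometry, fluid):
        for seed in range(20):
            curve, _ = generate_torque_curve(0.05, noise_sd=0.01, seed=seed)
            cf = biofilm_momentum_coefficient(curve, geometry, fluid)
            assert cf == pytest.approx(0.05, rel=0.05)

    def test_empty_window_rejected(self, geometry, fluid):
        curve, _ = generate_torque_curve(0.05)
        with pytest.raises(DomainError):
            biofilm_momentum_coefficient(curve, geometry, fluid, window=(400.0, 500.0))


class TestSlopeTransform:
    def test_linear_torque_gives_zero_slopes(self):
        omega = np.linspace(1, 100, 50)
        curve = TorqueVelocityCurve(omega=omega, torque=3e-6 + 2e-7 * omega)
        slopes = linearized_slope_transform(curve)
        np.testing.assert_allclose(slopes.slope, 0.0, atol=1e-18)
        assert slopes.slope.size == 49

    def test_step_drop_yields_single_negative_spike(self):
        omega = np.linspace(1, 100, 100)
        torque = 1e-6 * omega.copy()
        torque[omega >= 50] -= 2e-5
        curve = TorqueVelocityCurve(omega=omega, torque=torque)
        slopes = linearized_slope_transform(curve)
        k = int(np.argmin(slopes.slope))
        assert slopes.omega_mid[k] == pytest.approx(50.0, abs=1.0)
        # the spike dwarfs every other slope
        rest = np.delete(slopes.slope, k)
        assert np.min(slopes.slope) < 10 * np.min(rest)

    def test_quadratic_matches_brute_force_differencing(self):
        omega = np.linspace(1, 100, 60)
        torque = 1e-8 * omega**2
        curve = TorqueVelocityCurve(omega=omega, torque=torque)
        slopes = linearized_slope_transform(curve)
        b, a = np.polyfit(omega, torque, 1)
        corrected = torque - (a + b * omega)
        expected = [(corrected[i + 1] - corrected[i]) / (omega[i + 1] - omega[i])
                    for i in range(59)]
        np.testing.assert_allclose(slopes.slope, expected, rtol=1e-9)


class TestEventDetection:
    def test_all_zero_slopes_no_events(self):
        s = SlopeSeries(omega_mid=np.linspace(1, 10, 20), slope=np.zeros(20))
        assert detect_detachment_events(s) == []

    def test_single_spike_single_event(self):
        rng = np.random.default_rng(1)
        slope = rng.normal(0, 1e-7, 50)
        sd = slope.std()
        slope[25] = -10 * sd
        s = SlopeSeries(omega_mid=np.linspace(1, 100, 50), slope=slope)
        events = detect_detachment_events(s)
        assert len(events) == 1
        assert events[0].omega == pytest.approx(s.omega_mid[25])
        assert events[0].slope < 0

    def test_two_separated_spikes_two_events(self):
        slope = np.zeros(50)
        noise = np.random.default_rng(2).normal(0, 1e-8, 50)
        slope += noise
        slope[10] = -1e-5
        slope[30] = -2e-5
        s = SlopeSeries(omega_mid=np.linspace(1, 100, 50), slope=slope)
        events = detect_detachment_events(s)
        assert len(events) == 2

    def test_consecutive_flagged_points_merged(self):
        slope = np.zeros(50)
        slope += np.random.default_rng(3).normal(0, 1e-8, 50)
        slope[20] = -1e-5
        slope[21] = -3e-5
        slope[22] = -1e-5
        s = SlopeSeries(omega_mid=np.linspace(1, 100, 50), slope=slope)
        events = detect_detachment_events(s)
        assert len(events) == 1
        assert events[0].omega == pytest.approx(s.omega_mid[21])


class TestWallShearStress:
    def test_zero_at_rest(self, geometry, fluid):
        assert wall_shear_stress(0.0, geometry, fluid) == 0.0

    @pytest.mark.parametrize("omega,expected", [(100.0, 15.968), (1.0, 0.015968)])
    def test_hand_values(self, omega, expected, geometry, fluid):
        assert wall_shear_stress(omega, geometry, fluid) == pytest.approx(
            expected, rel=1e-4)

    @settings(deadline=None, derandomize=True)
    @given(o1=st.floats(0.1, 300), o2=st.floats(0.1, 300))
    def test_strictly_increasing_in_omega(self, o1, o2):
        if o1 == o2:
            return
        lo, hi = sorted((o1, o2))
        assert wall_shear_stress(lo) < wall_shear_stress(hi)

    def test_increasing_in_radius(self, fluid):
        taus = [wall_shear_stress(100.0, DiscGeometry(radius=r), fluid)
                for r in (0.01, 0.02, 0.04)]
        assert taus == sorted(taus) and len(set(taus)) == 3

    def test_negative_omega_rejected(self, geometry, fluid):
        with pytest.raises(DomainError):
            wall_shear_stress(-1.0, geometry, fluid)


class TestCriticalShearStress:
    def test_lowest_event_omega_used(self, geometry, fluid):
        curve, _ = generate_torque_curve(0.05)
        from biofilmmech.rheometry import DetachmentEvent

        events = [
            DetachmentEvent(omega=120.0, slope=-1e-5,
                            shear_stress=wall_shear_stress(120.0, geometry, fluid)),
            DetachmentEvent(omega=50.0, slope=-1e-5,
                            shear_stress=wall_shear_stress(50.0, geometry, fluid)),
        ]
        tau = critical_detachment_shear_stress(curve, events, geometry, fluid)
        assert tau == pytest.approx(wall_shear_stress(50.0, geometry, fluid))

    def test_no_events_is_missing(self, geometry, fluid):
        curve, _ = generate_torque_curve(0.05)
        assert critical_detachment_shear_stress(curve, [], geometry, fluid) is None

    def test_single_event_chains_wall_shear(self, geometry, fluid):
        curve, _ = generate_torque_curve(0.05)
        from biofilmmech.rheometry import DetachmentEvent

        ev = DetachmentEvent(omega=100.0, slope=-1e-5,
                             shear_stress=wall_shear_stress(100.0, geometry, fluid))
        assert critical_detachment_shear_stress(curve, [ev], geometry, fluid) == (
            pytest.approx(15.968, rel=1e-4))


class TestAUC:
    def test_triangle(self):
        curve = TorqueVelocityCurve(omega=np.array([0.0, 1.0, 2.0]),
                                    torque=np.array([0.0, 1.0, 2.0]))
        assert torque_auc(curve) == pytest.approx(2.0)

    def test_constant_torque(self):
        omega = np.linspace(0.1, 300, 100)
        curve = TorqueVelocityCurve(omega=omega, torque=np.full(100, 3e-4))
        assert torque_auc(curve) == pytest.approx(3e-4 * 299.9, rel=1e-12)

    def test_quadratic_against_analytic_integral(self):
        omega = np.linspace(0.0, 2.0, 512)
        curve = TorqueVelocityCurve(omega=omega, torque=omega**2)
        assert torque_auc(curve) == pytest.approx(8.0 / 3.0, rel=1e-3)

    def test_dominated_curve_has_smaller_auc(self):
        rng = np.random.default_rng(4)
        omega = np.sort(rng.uniform(0.1, 300, 40))
        lower = rng.uniform(0, 1e-4, 40)
        upper = lower + rng.uniform(0, 1e-4, 40)
        auc_lo = torque_auc(TorqueVelocityCurve(omega=omega, torque=lower))
        auc_hi = torque_auc(TorqueVelocityCurve(omega=omega, torque=upper))
        assert auc_lo <= auc_hi
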