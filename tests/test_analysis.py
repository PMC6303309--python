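"""Performance metrics: robustness, QIC conditions, memory law, sweeps."""

from dataclasses import replace

import numpy as np
import pytest

from qicsim import (
    DeviceParams,
    RobustnessResult,
    adaptation_error,
    competitor_to_disturbance,
    memory_residual,
    qic_check,
    robustness,
    silencing_dose_response,
    simulate,
    steady_state,
    sweep,
)
from qicsim.model import SteadyStateError


class TestRobustness:
    def test_ratio_arithmetic(self):
        assert RobustnessResult(1.0, 0.5, 0.5).robustness == pytest.approx(50.0)
        assert RobustnessResult(7.0, 7.0, 0.5).robustness == pytest.approx(100.0)

    def test_unregulated_equals_ribosome_fraction(self, strong_high_unreg):
        for d in np.linspace(0.05, 0.9, 8):
            r = robustness(strong_high_unreg, "unregulated", d)
            assert r.robustness == pytest.approx((1 - d) * 100.0, rel=1e-9)

    def test_ideal_variant_is_perfectly_robust(self, strong_high):
        for d in np.arange(0.1, 0.95, 0.1):
            assert robustness(strong_high, "ideal", d).robustness == pytest.approx(
                100.0, abs=1e-9
            )

    def test_zero_nominal_output_rejected(self, strong_high):
        dead = replace(strong_high, T=0.0)
        with pytest.raises(SteadyStateError, match="nominal"):
            robustness(dead, "regulated", 0.5)


class TestQicCheck:
    def test_ratio_arithmetic(self):
        p = DeviceParams(T=100, D=1, kappa_gfp=10, kappa_ecf=1, Ts=10,
                         delta=1, lam=100, beta=1, R=1, gamma=1)
        rep = qic_check(p, epsilon=0.1)
        assert (rep.r_lambda, rep.r_T, rep.r_gain) == pytest.approx((0.01, 0.01, 0.01))
        assert rep.passes

    def test_low_gain_fails_condition_three(self):
        p = DeviceParams(T=100, D=1, kappa_gfp=1, kappa_ecf=10, Ts=1,
                         delta=1, lam=100, beta=1, R=1, gamma=1)
        rep = qic_check(p, epsilon=0.1)
        assert rep.r_gain == pytest.approx(10.0)
        assert rep.flags == (True, True, False)
        assert not rep.passes

    def test_ideal_limit_trivially_passes(self, strong_high):
        rep = qic_check(replace(strong_high, delta=0.0))
        assert (rep.r_lambda, rep.r_T, rep.r_gain) == (0.0, 0.0, 0.0)
        assert rep.passes

    def test_fixture_gain_ordering_controls_condition_three(self):
        from qicsim import fixtures

        low = qic_check(fixtures("strong-low-regulated"))
        high = qic_check(fixtures("strong-high-regulated"))
        assert not low.flags[2] and high.flags[2]


class TestMemoryLaw:
    def test_leaky_integrator_identity_on_trajectories(self, strong_high):
        # dz/dt = k·Ts·e − δ·z is an algebraic consequence of the RNA
        # balances; the residual bounds implementation error only
        traj = simulate(strong_high, "regulated", 0.5, t_span=(0.0, 5.0))
        assert memory_residual(traj) < 1e-6

    def test_ideal_memory_integrates_the_error(self, strong_high):
        # δ = 0: z(t) − z(0) = k·Ts ∫ e dτ, along a genuine transient
        # (equilibrated at d = 0, then held at d = 0.5)
        p = replace(strong_high, delta=0.0)
        start = steady_state(p, 0.0, variant="ideal")
        traj = simulate(strong_high, "ideal", 0.5, t_span=(0.0, 5.0),
                        initial=start, points_per_segment=4000)
        integral = np.concatenate(
            ([0.0], np.cumsum(np.diff(traj.times) *
                              (traj.e[1:] + traj.e[:-1]) / 2.0))
        )
        np.testing.assert_allclose(
            traj.z - traj.z[0], p.k * p.Ts * integral,
            atol=1e-3 * np.max(np.abs(traj.z - traj.z[0])),
        )

    def test_unregulated_trajectory_rejected(self, strong_high_unreg):
        traj = simulate(strong_high_unreg, "unregulated", 0.5, t_span=(0.0, 1.0))
        with pytest.raises(ValueError, match="regulated"):
            memory_residual(traj)

    def test_steady_state_error_identity(self, strong_high):
        # at equilibrium Eq. dz/dt = 0 forces e_ss = δ·z_ss/(k·Ts)
        p = strong_high
        for d in (0.0, 0.4, 0.8):
            ss = steady_state(p, d)
            setpoint = p.T * p.D / (p.k * p.Ts)
            e_ss = setpoint - ss.y1
            z_ss = ss.m1 - ss.s1
            assert e_ss == pytest.approx(p.delta * z_ss / (p.k * p.Ts), rel=1e-6)


class TestAdaptationError:
    def test_vanishes_in_ideal_limit(self, strong_high):
        p0 = replace(strong_high, delta=0.0)
        for d in (0.0, 0.5, 0.9):
            assert adaptation_error(p0, d) == pytest.approx(0.0, abs=1e-12)

    def test_decreases_with_gain(self, strong_high):
        errs = [adaptation_error(strong_high.with_gain(k), 0.5)
                for k in [0.5, 1.0, 2.0, 4.0, 8.0]]
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_small_in_quasi_integral_regime(self, strong_high):
        rep = qic_check(strong_high)
        assert rep.passes
        assert adaptation_error(strong_high, 0.0) < 5 * rep.r_gain


class TestSweep:
    def test_disturbance_sweep_unregulated_linearity(self, strong_high_unreg):
        ds = np.linspace(0.0, 0.9, 10)
        res = sweep(strong_high_unreg, "unregulated", "disturbance", ds)
        y = res.frame.y1.to_numpy()
        np.testing.assert_allclose(y / y[0], 1.0 - ds, rtol=1e-9)

    def test_gain_sweep_robustness_non_decreasing(self, strong_high):
        # monotone where integrator leak dominates the residual
        # uncoupled-decay floor (see docs/methods.md on the high-gain limit)
        ks = np.geomspace(0.5, 4.0, 20)
        res = sweep(strong_high, "regulated", "gain", ks, d_active=0.5)
        rob = res.frame.robustness_pct.to_numpy()
        assert np.all(np.diff(rob) >= -1e-9)

    def test_fixture_gain_levels_order_robustness(self):
        from qicsim import fixtures

        for prom in ("strong", "weak"):
            robs = [robustness(fixtures(f"{prom}-{g}-regulated"), "regulated",
                               0.5).robustness
                    for g in ("low", "medium", "high")]
            assert robs[0] < robs[1] < robs[2]

    def test_gain_sweep_nominal_output_tracks_set_point(self, strong_high):
        # in the QIC regime y1* ≈ T·D/(k·Ts), so output ∝ 1/k
        ks = np.array([2.0, 4.0, 8.0])
        res = sweep(strong_high, "regulated", "gain", ks, d_active=0.5)
        y = res.frame.y1.to_numpy()
        setpoints = strong_high.T * strong_high.D / (ks * strong_high.Ts)
        np.testing.assert_allclose(y, setpoints, rtol=0.05)

    def test_failure_annotated_with_axis_value(self, strong_high):
        with pytest.raises(ValueError, match="disturbance=1.5"):
            sweep(strong_high, "regulated", "disturbance", [0.2, 1.5])


class TestCompetitorMapping:
    def test_hill_endpoints_and_midpoint(self):
        assert competitor_to_disturbance(0.0, 0.5, 100.0) == 0.0
        assert competitor_to_disturbance(100.0, 0.5, 100.0) == pytest.approx(0.25)
        assert competitor_to_disturbance(1e9, 0.5, 100.0) == pytest.approx(0.5, rel=1e-6)

    def test_saturation_must_stay_below_one(self):
        with pytest.raises(ValueError):
            competitor_to_disturbance(1.0, 1.0, 100.0)


class TestSilencing:
    def test_uninduced_level_matches_closed_form(self, strong_high):
        p = strong_high
        df = silencing_dose_response([0.0], p)
        expected = p.R * p.T * p.D / (p.delta * p.gamma * p.kappa_gfp)
        assert df.y1.iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_monotone_non_increasing_in_dose(self, strong_high):
        doses = [0, 1, 3, 10, 30, 100, 300, 1000]
        y = silencing_dose_response(doses, strong_high).y1.to_numpy()
        assert np.all(np.diff(y) <= 1e-12 * y[0])

    def test_strong_induction_approaches_complete_silencing(self, strong_high):
        y = silencing_dose_response([0.0, 1e6], strong_high).y1.to_numpy()
        assert y[1] < 0.01 * y[0]
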