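"""Closed-form skin-transport models: values, limits and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from dermakin.core_models import (
    CONFLUENT_RTOL,
    DiffusionParams,
    InvalidParameterError,
    SkinTransportParams,
    fick_cumulative_infinite,
    fick_flux_fraction,
    finite_dose_profile,
    infinite_dose_profile,
    peak_flux,
    steady_state_metrics,
    time_to_flux_fraction,
)

DP = DiffusionParams(Kp=0.0046, CD=50000.0, Tlag=10.0)

# frozen oracle: 10^4-term series sum (30-digit arithmetic) at t = 30 h
FICK_QR_30H = 4620.1118458344097


class TestDiffusionParams:
    def test_consistent_kdh_accepted(self):
        D, h = 0.01, 0.05
        dp = DiffusionParams(Kp=2.0 * D / h, CD=100.0, Tlag=h**2 / (6 * D), K=2.0, D=D, h=h)
        assert dp.Jss == pytest.approx(dp.Kp * dp.CD)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(Kp=0.4, CD=100.0, Tlag=0.0417, K=2.0, D=0.01, h=0.05),  # Kp != K*D/h
            dict(Kp=0.0, CD=100.0, Tlag=1.0),
            dict(Kp=0.1, CD=100.0, Tlag=0.0),
            dict(Kp=0.1, CD=-1.0, Tlag=1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            DiffusionParams(**kwargs)


class TestFickCumulative:
    def test_zero_at_time_zero(self):
        assert fick_cumulative_infinite(DP, 0.0, 200) == 0.0

    def test_late_time_asymptote(self):
        t = 20 * DP.Tlag
        expected = DP.Kp * DP.CD * (t - DP.Tlag)
        assert fick_cumulative_infinite(DP, t, 200) == pytest.approx(expected, rel=1e-9)

    def test_truncated_series_matches_high_order_oracle(self):
        assert fick_cumulative_infinite(DP, 30.0, 200) == pytest.approx(
            FICK_QR_30H, rel=1e-12
        )
        assert fick_cumulative_infinite(DP, 30.0, 10_000) == pytest.approx(
            FICK_QR_30H, rel=1e-12
        )

    def test_monotone_non_decreasing(self):
        t = np.linspace(0, 60, 301)
        qr = fick_cumulative_infinite(DP, t, 200)
        assert np.all(np.diff(qr) >= -1e-9)
        assert np.all(qr >= 0)

    def test_pseudo_steady_state_line(self):
        # late-time regression recovers slope Kp*CD and t-intercept Tlag
        # (series terms are ~exp(-pi^2 t / 6 Tlag); beyond 15 lag times
        # the curve is linear to well below the 1e-6 target)
        t = np.linspace(15 * DP.Tlag, 25 * DP.Tlag, 50)
        slope, intercept = np.polyfit(t, fick_cumulative_infinite(DP, t, 400), 1)
        assert slope == pytest.approx(DP.Kp * DP.CD, rel=1e-6)
        assert -intercept / slope == pytest.approx(DP.Tlag, rel=1e-6)

    def test_rejects_bad_arguments(self):
        with pytest.raises(InvalidParameterError):
            fick_cumulative_infinite(DP, -1.0, 200)
        with pytest.raises(InvalidParameterError):
            fick_cumulative_infinite(DP, 1.0, 0)


class TestFickFluxFraction:
    def test_published_value_at_2p7_lag_times(self):
        assert fick_flux_fraction(2.7, 200) == pytest.approx(0.975, abs=0.005)

    def test_zero_at_time_zero(self):
        assert fick_flux_fraction(0.0, 200) == 0.0

    def test_saturates_to_one(self):
        assert fick_flux_fraction(10.0, 200) == pytest.approx(1.0, abs=1e-6)
        assert fick_flux_fraction(10.0, 200) == pytest.approx(
            fick_flux_fraction(10.0, 10_000), abs=1e-12
        )

    def test_monotone_and_bounded(self):
        x = np.linspace(0, 8, 200)
        f = fick_flux_fraction(x, 400)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(np.diff(f) >= -1e-12)

    def test_consistent_with_cumulative_derivative(self):
        # numerical d(QR)/dt / Jss equals the flux fraction
        t, dt = 18.0, 1e-4
        dq = (
            fick_cumulative_infinite(DP, t + dt, 400)
            - fick_cumulative_infinite(DP, t - dt, 400)
        ) / (2 * dt)
        assert dq / DP.Jss == pytest.approx(fick_flux_fraction(t / DP.Tlag, 400), rel=1e-6)


class TestInfiniteDoseProfile:
    def test_everything_zero_at_start(self, invitro_params):
        prof = infinite_dose_profile(invitro_params, [0.0])
        assert prof.QM[0] == prof.QR[0] == prof.J[0] == 0.0

    def test_steady_state_limits(self, invitro_params):
        prof = infinite_dose_profile(invitro_params, [500.0])
        assert prof.QM[0] == pytest.approx(229.0 / 0.10, rel=1e-9)  # 2290 µg/cm²
        assert prof.J[0] == pytest.approx(229.0, rel=1e-9)

    def test_mass_balance_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            r0 = rng.uniform(1, 1000)
            kout = 10 ** rng.uniform(-3, 1)
            t = rng.uniform(0, 100)
            sp = SkinTransportParams(R0=r0, kout=kout)
            prof = infinite_dose_profile(sp, [t])
            assert prof.QR[0] + prof.QM[0] == pytest.approx(r0 * t, rel=1e-9, abs=1e-12)

    def test_cumulative_equals_flux_quadrature(self, invitro_params):
        sp = invitro_params
        j = lambda t: sp.R0 * -math.expm1(-sp.kout * t)
        for t_end in (5.0, 30.0):
            integral, _ = quad(j, 0, t_end, epsabs=1e-12, epsrel=1e-10)
            prof = infinite_dose_profile(sp, [t_end])
            assert prof.QR[0] == pytest.approx(integral, rel=1e-6)

    def test_onset_delay_shifts_profile(self, invitro_params):
        sp = SkinTransportParams(R0=229.0, kout=0.10, t0=2.0)
        ref = infinite_dose_profile(invitro_params, [10.0])
        shifted = infinite_dose_profile(sp, [12.0])
        assert shifted.QR[0] == pytest.approx(ref.QR[0], rel=1e-12)
        assert infinite_dose_profile(sp, [1.0]).QR[0] == 0.0


class TestFiniteDoseProfile:
    def test_initial_state(self, finite_params):
        prof = finite_dose_profile(finite_params, [0.0])
        assert prof.QD[0] == finite_params.Q0
        assert prof.QM[0] == prof.QR[0] == prof.J[0] == 0.0

    def test_skin_residual_at_54h(self, finite_params):
        prof = finite_dose_profile(finite_params, [54.0])
        assert prof.QM[0] / finite_params.Q0 == pytest.approx(0.047, abs=5e-4)

    def test_confluent_limit(self):
        sp = SkinTransportParams(kin=0.1, kout=0.1, Q0=1.0)
        prof = finite_dose_profile(sp, [10.0])
        assert prof.QM[0] == pytest.approx(0.1 * 10 * math.exp(-1.0), rel=1e-12)
        # general formula just outside the confluence window agrees
        near = SkinTransportParams(kin=0.1, kout=0.1 * (1 + 10 * CONFLUENT_RTOL), Q0=1.0)
        assert finite_dose_profile(near, [10.0]).QM[0] == pytest.approx(
            prof.QM[0], rel=1e-6
        )

    def test_mass_balance_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            kin, kout = 10 ** rng.uniform(-3, 1, size=2)
            q0 = rng.uniform(1, 1e4)
            t = rng.uniform(0, 200)
            sp = SkinTransportParams(kin=kin, kout=kout, Q0=q0)
            prof = finite_dose_profile(sp, [t])
            total = prof.QD[0] + prof.QM[0] + prof.QR[0]
            assert total == pytest.approx(q0, rel=1e-9)
            assert min(prof.QD[0], prof.QM[0], prof.QR[0]) >= -1e-12

    def test_cumulative_equals_flux_quadrature(self, finite_params):
        sp = finite_params
        def j(t):
            return float(finite_dose_profile(sp, [t]).J[0])
        integral, _ = quad(j, 0, 30.0, epsabs=1e-12, epsrel=1e-10, limit=200)
        assert finite_dose_profile(sp, [30.0]).QR[0] == pytest.approx(integral, rel=1e-6)

    def test_converges_to_infinite_dose_as_q0_grows(self):
        # Q0 -> inf with kin*Q0 fixed at R0: first-order entry becomes zero-order
        r0, kout = 229.0, 0.10
        t = np.linspace(0.5, 30, 20)
        j_inf = infinite_dose_profile(SkinTransportParams(R0=r0, kout=kout), t).J
        # deviation from the zero-order limit is O(kin*t) = O(R0*t/Q0)
        for q0, tol in [(1e6, 8e-3), (1e8, 8e-5)]:
            sp = SkinTransportParams(kin=r0 / q0, kout=kout, Q0=q0)
            j_fin = finite_dose_profile(sp, t).J
            assert np.max(np.abs(j_fin - j_inf) / j_inf) < tol

    def test_missing_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            SkinTransportParams(kin=0.1, kout=0.1)  # no Q0
        with pytest.raises(InvalidParameterError):
            SkinTransportParams(kout=0.1)  # no input mechanism


class TestPeakFlux:
    def test_reference_rates(self):
        sp = SkinTransportParams(kin=0.065, kout=0.10, Q0=100.0)
        t_jmax, j_max = peak_flux(sp)
        assert t_jmax == pytest.approx(12.308, abs=5e-3)
        # numeric argmax oracle on a fine grid
        grid = np.linspace(0.01, 60, 240_000)
        j = finite_dose_profile(sp, grid).J
        g_argmax = grid[np.argmax(j)]
        assert abs(t_jmax - g_argmax) < 2 * (grid[1] - grid[0])
        assert j_max == pytest.approx(np.max(j), rel=1e-8)

    def test_symmetric_under_rate_exchange(self):
        a = peak_flux(SkinTransportParams(kin=0.065, kout=0.10, Q0=100.0))[0]
        b = peak_flux(SkinTransportParams(kin=0.10, kout=0.065, Q0=100.0))[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_confluent_limit_is_reciprocal_rate(self):
        t_jmax, _ = peak_flux(SkinTransportParams(kin=0.1, kout=0.1, Q0=1.0))
        assert t_jmax == pytest.approx(10.0, rel=1e-9)

    def test_flux_unimodal_with_peak_at_tjmax(self):
        sp = SkinTransportParams(kin=0.03, kout=0.25, Q0=50.0)
        t_jmax, _ = peak_flux(sp)
        grid = np.linspace(0, 100, 5000)
        j = finite_dose_profile(sp, grid).J
        peak_idx = int(np.argmax(j))
        assert np.all(np.diff(j[: peak_idx + 1]) >= -1e-12)
        assert np.all(np.diff(j[peak_idx:]) <= 1e-12)
        assert grid[peak_idx] == pytest.approx(t_jmax, abs=grid[1] - grid[0])


class TestTimeToFluxFraction:
    def test_published_multiplier(self):
        for kout in (0.05, 0.10, 1.0):
            t = time_to_flux_fraction(0.975, kout)
            assert t * kout == pytest.approx(3.689, abs=1e-3)

    @pytest.mark.parametrize(
        "fraction,kout,expected",
        [(0.0, 0.1, 0.0), (0.5, 0.1, math.log(2) / 0.1)],
    )
    def test_known_values(self, fraction, kout, expected):
        assert time_to_flux_fraction(fraction, kout) == pytest.approx(expected, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            time_to_flux_fraction(1.0, 0.1)
        with pytest.raises(InvalidParameterError):
            time_to_flux_fraction(0.5, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        fraction=st.floats(0.0, 0.999),
        kout=st.floats(1e-3, 10.0),
    )
    def test_inverts_flux_rise(self, fraction, kout):
        t = time_to_flux_fraction(fraction, kout)
        assert -math.expm1(-kout * t) == pytest.approx(fraction, abs=1e-9)


class TestSteadyStateMetrics:
    def test_permeability_worked_example(self):
        assert steady_state_metrics(229.0, 50000.0).Kp == pytest.approx(0.00458)

    def test_plasma_steady_state(self):
        ss = steady_state_metrics(229.0, 50000.0, S=1.45, CL=1580.0)
        assert ss.Css_ug_per_mL == pytest.approx(0.2102, abs=1e-4)
        assert ss.Css_ng_per_mL == pytest.approx(210.2, abs=0.1)

    def test_zero_flux_means_zero_css(self):
        ss = steady_state_metrics(0.0, 50000.0, S=1.45, CL=1580.0)
        assert ss.Css_ng_per_mL == 0.0

    def test_division_guards(self):
        with pytest.raises(InvalidParameterError):
            steady_state_metrics(229.0, 0.0)
        with pytest.raises(InvalidParameterError):
            steady_state_metrics(229.0, 50000.0, S=1.45, CL=0.0)
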