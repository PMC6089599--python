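"""Unit and property tests for the three-pool kinetic model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ldbuffer as lb
from ldbuffer.model import CONSERVATION_RTOL

HALF_LIFE = math.log(2) / 0.005  # of the reference calibration, ~138.63 s


class TestEquilibriumConstant:
    def test_ratio(self, params):
        assert lb.khl(params) == pytest.approx(2.0)

    def test_zero_off_rate_means_infinitely_tight_binding(self, params):
        assert lb.khl(params.with_(k1_off=0.0)) == 0.0

    def test_undefined_without_on_rate(self, params):
        with pytest.raises(lb.UndefinedEquilibriumError):
            lb.khl(params.with_(k1_on=0.0))

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            lb.KineticParams(L=-1.0)


class TestEffectiveRate:
    def test_reference_value(self, params):
        # (2 / 20) * 5 * 0.01
        assert lb.effective_rate(params) == pytest.approx(0.005)

    def test_no_droplets_gives_maximal_import(self, params):
        assert lb.effective_rate(params.with_(L=0.0)) == pytest.approx(0.05)

    def test_doubling_sites_slows_import(self, params):
        k18 = lb.effective_rate(params)
        k36 = lb.effective_rate(params.with_(L=36.0))
        assert k36 == pytest.approx(2.0 / 38.0 * 0.05)
        assert k36 < k18

    @given(st.floats(0.1, 1000.0), st.floats(0.2, 500.0))
    def test_strictly_decreasing_in_site_concentration(self, L, dL):
        p = lb.KineticParams(L=L)
        assert lb.effective_rate(p.with_(L=L + dL)) < lb.effective_rate(p)


class TestAnalyticCurves:
    def test_nuclear_pool_starts_empty(self, params):
        assert lb.hd_analytic(params, 0.0) == 0.0

    def test_half_life_identity(self, params):
        assert lb.hd_analytic(params, HALF_LIFE) == pytest.approx(50.0)
        assert lb.nonnuclear_analytic(params, HALF_LIFE) == pytest.approx(50.0)

    def test_asymptote_is_total_abundance(self, params):
        assert lb.hd_analytic(params, 2000.0) == pytest.approx(
            100.0 * (1 - math.exp(-10.0))
        )
        assert lb.hd_analytic(params, 1e7) == pytest.approx(100.0)

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            lb.hd_analytic(params, -1.0)
        with pytest.raises(ValueError):
            lb.nonnuclear_analytic(params, -1.0)

    @given(st.floats(0.0, 5000.0))
    def test_pools_complement_to_total(self, t):
        p = lb.KineticParams()
        assert lb.hd_analytic(p, t) + lb.nonnuclear_analytic(p, t) == pytest.approx(
            p.H_tot, rel=1e-12
        )

    @given(st.floats(1e-3, 1e4), st.floats(0.0, 5000.0))
    def test_exactly_linear_in_total_abundance(self, H, t):
        p = lb.KineticParams(H_tot=H)
        assert lb.hd_analytic(p.with_(H_tot=2 * H), t) == pytest.approx(
            2 * lb.hd_analytic(p, t), rel=1e-12, abs=0.0
        )

    @given(st.floats(0.0, 4000.0), st.floats(1.0, 1000.0))
    def test_nondecreasing_in_time(self, t, dt):
        p = lb.KineticParams()
        assert lb.hd_analytic(p, t + dt) >= lb.hd_analytic(p, t)

    def test_early_time_import_rate_nearly_constant(self, params):
        """For k_eff*t << 1 the nuclear-accumulation rate is flat (<5% drift):
        nuclear levels keep rising steadily through a prolonged interphase."""
        k = lb.effective_rate(params)
        t = np.linspace(0.0, 0.05 / k, 50)
        rate = k * np.asarray(lb.nonnuclear_analytic(params, t))  # d/dt hd_analytic
        assert (rate.max() - rate.min()) / rate.max() < 0.05


class TestEquilibriumPartition:
    def test_droplet_dominated_partition(self, params):
        assert lb.equilibrium_partition(params, 100.0) == pytest.approx((10.0, 90.0))

    def test_no_droplets_all_free(self, params):
        assert lb.equilibrium_partition(params.with_(L=0.0), 100.0) == (100.0, 0.0)

    def test_infinitely_tight_binding_all_on_droplets(self, params):
        assert lb.equilibrium_partition(params.with_(k1_off=0.0), 100.0) == (0.0, 100.0)

    def test_negative_amount_rejected(self, params):
        with pytest.raises(ValueError):
            lb.equilibrium_partition(params, -1.0)

    @given(st.floats(0.0, 1e4))
    def test_partition_sums_to_whole(self, H_nn):
        f, l = lb.equilibrium_partition(lb.KineticParams(), H_nn)
        assert f + l == pytest.approx(H_nn, rel=1e-15, abs=0.0)


class TestRateEquations:
    def test_quasi_equilibrium_stationary_exchange(self, params):
        state = lb.PoolState(t=0.0, H_free=10.0, H_LD=90.0, H_DNA=0.0)
        df, dl, dd = lb.rhs(params, state)
        assert dl == pytest.approx(0.0, abs=1e-14)
        assert dd == pytest.approx(0.5)
        assert df == pytest.approx(-0.5)

    def test_no_import_without_free_pool(self, params):
        df, dl, dd = lb.rhs(params, lb.PoolState(t=0.0, H_free=0.0, H_LD=50.0, H_DNA=0.0))
        assert dd == 0.0

    @given(
        st.floats(0.0, 100.0),
        st.floats(0.0, 100.0),
        st.floats(0.0, 100.0),
        st.floats(1e-4, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.0, 0.01),
    )
    def test_derivatives_sum_to_zero(self, hf, hl, hd, k1_on, k1_off, k2_off):
        p = lb.KineticParams(k1_on=k1_on, k1_off=k1_off, k2_off=k2_off)
        df, dl, dd = lb.rhs(p, lb.PoolState(t=0.0, H_free=hf, H_LD=hl, H_DNA=hd))
        assert df + dl + dd == pytest.approx(0.0, abs=1e-12)


class TestIntegration:
    def test_no_droplet_limit_matches_single_exponential(self, params, times_20min):
        p = params.with_(L=0.0)
        init = lb.PoolState(t=0.0, H_free=p.H_tot, H_LD=0.0, H_DNA=0.0)
        traj = lb.integrate(p, init, times_20min)
        expected = p.H_tot * (1 - np.exp(-p.D * p.k2_on * times_20min))
        assert np.max(np.abs(traj.H_DNA - expected)) < 1e-3 * p.H_tot

    def test_quasi_equilibrium_matches_analytic_within_2pct(self, params):
        # separation ratio k1_on*L/(k2_on*D) = 18 >= the >=100 regime via scaling
        p = params.with_(k1_on=0.5, k1_off=1.0)  # same K_HL, separation 180
        k = lb.effective_rate(p)
        t = np.linspace(0.0, 5 * math.log(2) / k, 100)
        traj = lb.integrate(p, lb.equilibrium_initial_state(p), t)
        err = np.max(np.abs(traj.H_DNA - lb.hd_analytic(p, t)))
        assert err < 0.02 * p.H_tot

    def test_frozen_chromatin_exchange_relaxes_to_partition(self, params, times_20min):
        p = params.with_(k2_on=0.0)
        init = lb.PoolState(t=0.0, H_free=100.0, H_LD=0.0, H_DNA=0.0)
        traj = lb.integrate(p, init, times_20min)
        assert np.all(traj.H_DNA == traj.H_DNA[0])
        f_eq, l_eq = lb.equilibrium_partition(p, 100.0)
        assert traj.H_free[-1] == pytest.approx(f_eq, rel=1e-6)
        assert traj.H_LD[-1] == pytest.approx(l_eq, rel=1e-6)

    def test_conservation_along_trajectory(self, params, times_20min):
        traj = lb.integrate(params, lb.equilibrium_initial_state(params), times_20min)
        assert traj.conservation_error() < CONSERVATION_RTOL

    def test_nonmonotone_times_rejected(self, params):
        with pytest.raises(ValueError):
            lb.integrate(params, lb.equilibrium_initial_state(params), [0.0, 120.0, 60.0])

    def test_inconsistent_initial_state_rejected(self, params):
        bad = lb.PoolState(t=0.0, H_free=10.0, H_LD=10.0, H_DNA=0.0)
        with pytest.raises(ValueError):
            lb.integrate(params, bad, [0.0, 60.0])

    def test_trajectory_frame_columns(self, params, times_20min):
        df = lb.integrate(params, lb.equilibrium_initial_state(params), times_20min).to_frame()
        assert list(df.columns) == ["t_s", "H_free", "H_LD", "H_DNA"]


class TestDemandIndependence:
    def test_initial_exchange_flux_invariant_to_chromatin_sites(self, params):
        """Off-flux from LDs at quasi-equilibrium contains no [D]: loss of
        histone from droplets does not respond to chromatin demand."""
        ref = lb.initial_exchange_flux(params)
        assert ref == pytest.approx(0.1 * 90.0)
        for D in (0.0, 1.0, 5.0, 50.0, 5000.0):
            assert lb.initial_exchange_flux(params.with_(D=D)) == ref


class TestRegimeValidation:
    def test_reference_calibration_holds(self, params):
        diag = lb.validate_regime(params)
        assert diag.separation_ratio == pytest.approx(18.0)
        assert diag.partition_ratio == pytest.approx(9.0)
        assert diag.reversibility_ratio == 0.0
        assert diag.assumptions_hold

    def test_slow_droplet_binding_flagged(self, params):
        diag = lb.validate_regime(params.with_(k1_on=0.001, k1_off=0.002))
        assert diag.separation_ratio < 10
        assert not diag.separation_ok and not diag.assumptions_hold

    def test_strong_nuclear_export_flagged(self, params):
        diag = lb.validate_regime(params.with_(k2_off=params.k2_on * params.D))
        assert not diag.reversibility_ok and not diag.assumptions_hold

    def test_zero_denominator_is_an_error(self, params):
        with pytest.raises(lb.UndefinedRatioError):
            lb.validate_regime(params.with_(D=0.0))


class TestParamsIO:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_round_trip(self, params, tmp_path, suffix):
        path = tmp_path / f"params{suffix}"
        params.with_(L=27.0).save(path)
        assert lb.KineticParams.load(path) == params.with_(L=27.0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            lb.KineticParams.from_dict({"k1_on": 0.1, "bogus": 1.0})
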