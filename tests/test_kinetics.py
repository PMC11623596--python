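"""Rates, Eyring fits, bootstrap errors and allosteric energetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phototherm import (
    DegenerateDataError,
    KineticTrace,
    RateMeasurement,
    TooFewPointsError,
    TrueParams,
    allostery_energetics,
    bootstrap_eyring,
    eyring_kcat,
    fit_eyring,
    fit_one_phase_association,
    initial_velocity,
    kcat_from_trace,
    kcat_from_velocity,
    predicted_fold_change,
    simulate_absorbance_trace,
    simulate_kcat_dataset,
    simulate_relaxation_trace,
)
from phototherm.constants import R_CAL, celsius_to_kelvin

from helpers import make_eyring_fit
from oracles import grid_search_eyring, profile_scan_one_phase


def linear_trace(slope, a0=0.5, duration=30.0, dt=0.5):
    t = np.arange(0.0, duration + dt / 2, dt)
    return KineticTrace(time=t, absorbance=a0 + slope * t)


class TestInitialVelocity:
    def test_exact_linear_trace(self):
        # slope -0.001 AU/s with eps=13.2/cm/mM, l=1 cm -> 7.576e-8 M/s
        v0 = initial_velocity(linear_trace(-0.001))
        assert v0 == pytest.approx(0.001 / 13.2 / 1000.0, rel=1e-12)

    def test_flat_trace_zero_velocity(self):
        assert initial_velocity(linear_trace(0.0)) == pytest.approx(0.0, abs=1e-15)

    def test_too_few_points_rejected(self):
        trace = KineticTrace(time=[0, 20, 40, 60], absorbance=[1, 0.9, 0.8, 0.7])
        with pytest.raises(TooFewPointsError):
            initial_velocity(trace)

    def test_negative_velocity_not_clamped(self):
        assert initial_velocity(linear_trace(+0.001)) < 0

    def test_roundtrip_recovers_turnover(self):
        trace = simulate_absorbance_trace(kcat_true=0.58, enzyme_conc=100e-9, noise_sd=0.0)
        assert kcat_from_trace(trace) == pytest.approx(0.58, rel=1e-9)


def test_kcat_from_velocity_arithmetic():
    assert kcat_from_velocity(7.576e-8, 100e-9) == pytest.approx(0.7576, rel=1e-9)
    assert kcat_from_velocity(0.0, 1e-7) == 0.0
    with pytest.raises(ValueError):
        kcat_from_velocity(1e-8, 0.0)


class TestEyringRate:
    def test_prefactor_at_25C(self):
        # with zero barrier the rate is the bare TST frequency kB*T/h
        assert eyring_kcat(0.0, 0.0, 298.15) == pytest.approx(6.212e12, rel=1e-3)

    def test_vanishes_at_large_barrier(self):
        assert eyring_kcat(1e7, 0.0, 298.15) == 0.0

    def test_monotone_in_temperature_for_positive_barrier(self):
        grid = np.linspace(274.0, 320.0, 47)
        rates = eyring_kcat(14000.0, -12.0, grid)
        assert np.all(np.diff(rates) > 0)


class TestEyringFit:
    def test_noiseless_recovery_exact(self):
        params = TrueParams(dh_act=12000.0, ds_act=-20.0, kcat_cv=0.0)
        fit = fit_eyring(simulate_kcat_dataset(params))
        assert fit.dh_act == pytest.approx(12000.0, rel=1e-8)
        assert fit.ds_act == pytest.approx(-20.0, rel=1e-8)
        assert fit.n_points == 21

    def test_high_temperature_filter(self):
        params = TrueParams(dh_act=14000.0, ds_act=-12.0, kcat_cv=0.0)
        data = simulate_kcat_dataset(params, temps=(5, 10, 15, 20, 25, 30, 35, 40))
        fit = fit_eyring(data, t_max=35.0)
        assert fit.n_points == 21 and fit.n_excluded == 3
        kept = [m for m in data if m.temperature <= 35.0]
        assert fit.dh_act == pytest.approx(fit_eyring(kept, t_max=None).dh_act)

    def test_single_temperature_degenerate(self):
        data = [RateMeasurement(25.0, 0.5, replicate=i) for i in range(3)]
        with pytest.raises(DegenerateDataError):
            fit_eyring(data)

    def test_nonpositive_rate_rejected_at_construction(self):
        with pytest.raises(ValueError):
            RateMeasurement(25.0, 0.0)

    def test_agrees_with_grid_search_oracle(self):
        # noisy 3-temperature toy set: the OLS solution must match a
        # brute-force SSE minimization over (dH, dS) refined to <1 cal/mol
        rng = np.random.default_rng(42)
        temps_c = np.repeat([5.0, 20.0, 35.0], 3)
        true = eyring_kcat(13000.0, -15.0, celsius_to_kelvin(temps_c))
        kcats = true * np.exp(rng.normal(0, 0.05, temps_c.size))
        data = [
            RateMeasurement(t, k, replicate=i)
            for i, (t, k) in enumerate(zip(temps_c, kcats))
        ]
        fit = fit_eyring(data)
        dh_oracle, ds_oracle = grid_search_eyring(celsius_to_kelvin(temps_c), kcats)
        assert fit.dh_act == pytest.approx(dh_oracle, abs=2.0)
        assert fit.ds_act == pytest.approx(ds_oracle, abs=0.01)


class TestBootstrapEyring:
    def test_zero_noise_collapse(self):
        params = TrueParams(dh_act=14000.0, ds_act=-12.0, kcat_cv=0.0)
        fit = bootstrap_eyring(simulate_kcat_dataset(params), n_boot=200, seed=3)
        # every resample of exact Eyring data refits the same line
        assert fit.se_dh < 1e-6 and fit.se_ds < 1e-9
        np.testing.assert_allclose(fit.boot_dh, fit.dh_act, atol=1e-6)

    def test_seeded_bitwise_reproducibility(self):
        params = TrueParams(dh_act=14000.0, ds_act=-12.0, kcat_cv=0.05, seed=9)
        data = simulate_kcat_dataset(params)
        a = bootstrap_eyring(data, n_boot=500, seed=7)
        b = bootstrap_eyring(data, n_boot=500, seed=7)
        assert np.array_equal(a.boot_dh, b.boot_dh)
        assert np.array_equal(a.boot_ds, b.boot_ds)

    def test_point_estimate_from_full_data_not_bootstrap_mean(self):
        params = TrueParams(dh_act=14000.0, ds_act=-12.0, kcat_cv=0.05, seed=5)
        data = simulate_kcat_dataset(params)
        fit = bootstrap_eyring(data, n_boot=5000, seed=1)
        assert fit.dh_act == fit_eyring(data).dh_act
        # bootstrap distribution is centred on the point estimate
        assert abs(np.mean(fit.boot_dh) - fit.dh_act) < 0.1 * fit.se_dh

    def test_stratified_resampling_option(self):
        params = TrueParams(dh_act=14000.0, ds_act=-12.0, kcat_cv=0.05, seed=5)
        data = simulate_kcat_dataset(params)
        pooled = bootstrap_eyring(data, n_boot=2000, seed=1)
        strat = bootstrap_eyring(data, n_boot=2000, seed=1, stratified=True)
        assert strat.n_redrawn == 0
        assert strat.se_dh == pytest.approx(pooled.se_dh, rel=0.5)

    def test_ci_coverage_over_repeated_simulations(self):
        # 95% bootstrap CI for the activation enthalpy should cover the
        # generating value in at least 90% of seeded simulations
        params = TrueParams(dh_act=14000.0, ds_act=-12.667, kcat_cv=0.05)
        rng = np.random.default_rng(2024)
        covered = 0
        n_runs = 1000  # Monte-Carlo sd of the coverage estimate ~0.9%
        for _ in range(n_runs):
            s1, s2 = rng.integers(0, 2**31 - 1, size=2)
            data = simulate_kcat_dataset(params, seed=int(s1))
            fit = bootstrap_eyring(data, n_boot=1000, seed=int(s2))
            lo, hi = fit.ci95_dh
            covered += lo <= 14000.0 <= hi
        assert covered / n_runs >= 0.90


class TestAllosteryEnergetics:
    def test_identical_fits_give_exact_zero(self):
        fit = make_eyring_fit(14000.0, -12.0, spread_dh=200.0, spread_ds=1.0)
        e = allostery_energetics(fit, fit)
        assert e.ddh == 0.0 and e.dds == 0.0 and e.ddg_at_ref == 0.0
        assert e.fold_change_at_ref == 1.0
        assert e.ci95_ddh == (0.0, 0.0)

    def test_thermodynamic_identities_hold_exactly(self):
        lit = make_eyring_fit(12335.0, -17.7, spread_dh=150.0, seed=1)
        dark = make_eyring_fit(14000.0, -12.7, spread_dh=150.0, seed=2)
        e = allostery_energetics(lit, dark, t_ref=303.15)
        assert e.ddg_at_ref == e.ddh - e.t_ref * e.dds
        assert e.fold_change_at_ref == np.exp(-e.ddg_at_ref / (R_CAL * e.t_ref))
        np.testing.assert_array_equal(e.boot_ddg, e.boot_ddh - e.t_ref * e.boot_dds)

    def test_printed_value_arithmetic(self):
        # ddH = -1665 cal/mol with T*ddS = -1536 cal/mol at 303.15 K gives
        # ddG = -129 cal/mol and a ~1.24x catalytic fold change
        t_ref = 303.15
        dds = -1536.0 / t_ref
        lit = make_eyring_fit(-1665.0 + 14000.0, -12.0 + dds)
        dark = make_eyring_fit(14000.0, -12.0)
        e = allostery_energetics(lit, dark, t_ref=t_ref)
        assert e.ddh == pytest.approx(-1665.0, abs=1e-9)
        assert e.t_dds_at_ref == pytest.approx(-1536.0, abs=1e-9)
        assert e.ddg_at_ref == pytest.approx(-129.0, abs=1e-9)
        assert e.fold_change_at_ref == pytest.approx(
            np.exp(129.0 / (R_CAL * t_ref)), rel=1e-12
        )
        assert e.fold_change_at_ref == pytest.approx(1.24, abs=0.005)

    def test_mismatched_n_boot_rejected(self):
        lit = make_eyring_fit(12000.0, -15.0, n_boot=100)
        dark = make_eyring_fit(14000.0, -12.0, n_boot=200)
        with pytest.raises(ValueError):
            allostery_energetics(lit, dark)


class TestPredictedFoldChange:
    def test_zero_differences_flat(self):
        e = allostery_energetics(
            make_eyring_fit(14000.0, -12.0), make_eyring_fit(14000.0, -12.0)
        )
        for t in (278.15, 298.15, 308.15):
            assert predicted_fold_change(e, t) == 1.0

    def test_allostery_stronger_in_the_cold(self):
        lit = make_eyring_fit(12335.0, -17.067)
        dark = make_eyring_fit(14000.0, -12.0)
        e = allostery_energetics(lit, dark)
        assert predicted_fold_change(e, 278.15) > predicted_fold_change(e, 308.15)

    def test_unity_at_compensation_temperature(self):
        t_comp = 303.15
        lit = make_eyring_fit(14000.0 - 1500.0, -12.0 - 1500.0 / t_comp)
        dark = make_eyring_fit(14000.0, -12.0)
        e = allostery_energetics(lit, dark, t_ref=t_comp)
        assert predicted_fold_change(e, t_comp) == pytest.approx(1.0, rel=1e-12)

    @given(
        ddh=st.floats(-5000.0, -10.0),
        dds=st.floats(-20.0, 20.0),
        t1=st.floats(270.0, 310.0),
        dt=st.floats(0.5, 40.0),
    )
    def test_monotone_decreasing_in_temperature_when_enthalpy_driven(
        self, ddh, dds, t1, dt
    ):
        lit = make_eyring_fit(14000.0 + ddh, -12.0 + dds)
        dark = make_eyring_fit(14000.0, -12.0)
        e = allostery_energetics(lit, dark)
        assert predicted_fold_change(e, t1) > predicted_fold_change(e, t1 + dt)


class TestOnePhaseAssociation:
    def test_noiseless_recovery(self):
        trace = simulate_relaxation_trace(k_rel=0.02, noise_sd=0.0)
        fit = fit_one_phase_association(trace)
        assert fit.k_rel == pytest.approx(0.02, rel=1e-6)
        assert fit.a0 == pytest.approx(0.012, rel=1e-6)
        assert fit.plateau == pytest.approx(0.048, rel=1e-6)

    def test_constant_trace_degenerate(self):
        trace = KineticTrace(time=np.arange(10.0), absorbance=np.full(10, 0.5))
        with pytest.raises(DegenerateDataError):
            fit_one_phase_association(trace)

    def test_matches_profile_scan_oracle(self):
        trace = simulate_relaxation_trace(k_rel=0.015, noise_sd=5e-4, seed=8)
        fit = fit_one_phase_association(trace)
        k_oracle = profile_scan_one_phase(trace.time, trace.absorbance)
        assert fit.k_rel == pytest.approx(k_oracle, rel=1e-3)
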