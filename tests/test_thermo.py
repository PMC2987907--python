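"""Van't Hoff model, melting-curve fits, fluctuation heat capacities, block errors."""

import numpy as np
import pytest

from foldtherm.constants import R_KCAL
from foldtherm.io import TemperatureSeries
from foldtherm.remd import geometric_ladder
from foldtherm.synth import TwoStateParams, generate_remd_dataset, occupancy_truth
from foldtherm.thermo import (
    CpProfile,
    MeltingCurve,
    VantHoffParams,
    block_errors,
    excess_heat_capacity,
    find_peak_windows,
    fit_vant_hoff,
    folded_fraction_model,
    heat_capacity_profile,
    melting_curve,
    peak_enthalpy,
    stability_curve,
)

CD_PARAMS = VantHoffParams(t_m=315.0, dh_m=10.4, dcp=0.1207)


def closed_form_mixture_cp(T, p: TwoStateParams):
    """Oracle: heat capacity of the two-state Gaussian energy mixture,
    Var(E)/(RT²) with Var = f(1−f)Δμ² + fσ_N² + (1−f)σ_D²."""
    f = occupancy_truth(T, p)
    dmu = p.dh_m + p.dcp * (np.asarray(T) - p.t_m)
    var = f * (1 - f) * dmu**2 + f * p.sigma_n**2 + (1 - f) * p.sigma_d**2
    return var / (R_KCAL * np.asarray(T) ** 2)


class TestStabilityCurve:
    def test_zero_at_midpoint(self):
        assert stability_curve(315.0, CD_PARAMS) == pytest.approx(0.0, abs=1e-12)

    def test_linear_when_dcp_zero(self):
        p = VantHoffParams(t_m=315.0, dh_m=10.4, dcp=0.0)
        T = np.array([280.0, 300.0, 340.0])
        np.testing.assert_allclose(stability_curve(T, p), 10.4 * (1 - T / 315.0))

    def test_term_by_term_evaluation(self):
        # independent term-by-term arithmetic at T = 305 K
        T, tm, dh, dcp = 305.0, 315.0, 10.4, 0.1207
        expected = dh * (1 - T / tm) + dcp * ((T - tm) - T * np.log(T / tm))
        assert stability_curve(T, CD_PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            stability_curve(0.0, CD_PARAMS)


class TestFoldedFractionModel:
    def test_half_at_midpoint(self):
        assert folded_fraction_model(315.0, CD_PARAMS) == pytest.approx(0.5)

    def test_monotone_decreasing_for_dcp_zero(self):
        p = VantHoffParams(t_m=315.0, dh_m=10.4)
        T = np.linspace(160.0, 470.0, 200)
        f = folded_fraction_model(T, p)
        assert np.all(np.diff(f) < 0)

    def test_fractions_sum_to_one(self):
        f = folded_fraction_model(np.array([290.0, 315.0, 350.0]), CD_PARAMS)
        np.testing.assert_allclose(f + (1 - f), 1.0)


class TestFitVantHoff:
    def test_noiseless_round_trip_recovers_cd_row(self):
        ladder = geometric_ladder(271.0, 465.0, 16)
        f = folded_fraction_model(ladder, CD_PARAMS)
        fit = fit_vant_hoff(MeltingCurve(ladder, f))
        assert fit.t_m == pytest.approx(315.0, rel=1e-3)
        assert fit.dh_m == pytest.approx(10.4, rel=1e-3)
        assert fit.dcp == pytest.approx(0.1207, rel=1e-3)
        assert fit.ds_m == pytest.approx(10.4 / 315.0, rel=1e-3)

    def test_noiseless_dcp_zero_recovered(self):
        p = VantHoffParams(t_m=310.0, dh_m=12.0, dcp=0.0)
        ladder = geometric_ladder(271.0, 465.0, 16)
        fit = fit_vant_hoff(MeltingCurve(ladder, folded_fraction_model(ladder, p)))
        assert fit.dcp == pytest.approx(0.0, abs=1e-6)

    def test_noisy_binomial_recovery_within_2K(self):
        rng = np.random.default_rng(0)
        ladder = geometric_ladder(271.0, 465.0, 16)
        f = folded_fraction_model(ladder, CD_PARAMS)
        n = 1000
        counts = rng.binomial(n, f)
        obs = counts / n
        err = np.sqrt(np.clip(obs * (1 - obs), 1e-4, None) / n)
        fit = fit_vant_hoff(MeltingCurve(ladder, obs, err))
        assert abs(fit.t_m - 315.0) < 2.0
        assert fit.t_m_err > 0

    def test_no_crossing_flags_extrapolation(self):
        ladder = np.linspace(271.0, 300.0, 6)
        p = VantHoffParams(t_m=400.0, dh_m=15.0)
        curve = MeltingCurve(ladder, folded_fraction_model(ladder, p))
        fit = fit_vant_hoff(curve)
        assert "extrapolated_tm" in fit.flags

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_vant_hoff(MeltingCurve(np.array([280.0, 300, 320, 340]),
                                       np.full(4, 0.7)))


class TestMeltingCurve:
    def test_all_folded_is_one(self):
        series = [
            TemperatureSeries(T, 0.1, np.ones(100), "indicator")
            for T in (280.0, 300.0)
        ]
        curve = melting_curve(series)
        np.testing.assert_array_equal(curve.folded_fraction, [1.0, 1.0])

    def test_alternating_is_half(self):
        values = np.tile([1.0, 0.0], 50)
        series = [TemperatureSeries(T, 0.1, values, "indicator") for T in (280.0, 300.0)]
        np.testing.assert_allclose(melting_curve(series).folded_fraction, 0.5)

    def test_synthetic_within_three_block_errors_of_truth(self):
        from foldtherm.orderparams import indicator_series

        p = TwoStateParams()
        ladder = geometric_ladder(271.0, 465.0, 8)
        ds = generate_remd_dataset(ladder, p, n_per_t=20_000, seed=11)
        inds = [indicator_series(s, 4.0) for s in ds.order_series]
        curve = melting_curve(inds)
        truth = occupancy_truth(curve.temperatures, p)
        # misclassification from the emission tails is below ~0.03
        slack = 3 * np.maximum(curve.errors, 0.01) + 0.03
        assert np.all(np.abs(curve.folded_fraction - truth) < slack)


class TestHeatCapacity:
    def test_constant_energy_zero(self):
        s = TemperatureSeries(300.0, 0.1, np.full(100, -50.0), "energy")
        prof = heat_capacity_profile([s])
        assert prof.cp[0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        s = TemperatureSeries(300.0, 0.1, rng.normal(-100.0, 2.0, 100_000), "energy")
        prof = heat_capacity_profile([s])
        expected = 4.0 / (R_KCAL * 300.0**2)  # 0.02237 kcal/mol/K
        assert expected == pytest.approx(0.02237, abs=1e-5)
        assert prof.cp[0] == pytest.approx(expected, rel=0.05)

    def test_estimator_error_shrinks_with_n(self):
        expected = 4.0 / (R_KCAL * 300.0**2)
        errors = []
        for n in (500, 50_000):
            devs = []
            for seed in range(8):
                rng = np.random.default_rng(seed)
                s = TemperatureSeries(300.0, 0.1, rng.normal(0.0, 2.0, n), "energy")
                devs.append(abs(heat_capacity_profile([s]).cp[0] - expected))
            errors.append(np.mean(devs))
        assert errors[1] < errors[0] / 3  # ~1/sqrt(100) scaling

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            heat_capacity_profile([TemperatureSeries(300.0, 0.1, np.array([1.0]), "energy")])

    def test_two_state_peak_matches_closed_form_scan(self):
        p = TwoStateParams()
        ladder = geometric_ladder(271.0, 465.0, 16)
        ds = generate_remd_dataset(ladder, p, n_per_t=100_000, seed=5)
        prof = heat_capacity_profile(ds.energy_series)
        peak_T = prof.temperatures[np.argmax(prof.cp)]
        dense = np.arange(271.0, 465.0, 0.1)
        oracle_T = dense[np.argmax(closed_form_mixture_cp(dense, p))]
        ladder_step = ladder[np.searchsorted(ladder, oracle_T)] - ladder[
            np.searchsorted(ladder, oracle_T) - 1
        ]
        assert abs(peak_T - oracle_T) <= ladder_step


class TestExcessAndPeaks:
    def test_flat_profile_all_zero(self):
        prof = excess_heat_capacity(
            CpProfile(np.linspace(280, 380, 6), np.full(6, 0.3))
        )
        np.testing.assert_allclose(prof.excess_cp, 0.0)
        assert prof.baseline == pytest.approx(0.3)

    def test_monotone_profile_monotone_excess(self):
        T = np.linspace(280, 380, 6)
        prof = excess_heat_capacity(CpProfile(T, np.linspace(0.1, 0.6, 6)))
        assert np.all(np.diff(prof.excess_cp) > 0)
        assert prof.excess_cp[0] == 0.0

    def test_rectangle_enthalpy(self):
        T = np.linspace(300.0, 340.0, 41)
        prof = CpProfile(T, np.zeros(41), excess_cp=np.full(41, 0.5), baseline=0.0)
        prof.excess_cp[0] = 0.49  # make the maximum interior
        prof.excess_cp[-1] = 0.49
        pk = peak_enthalpy(prof, (300.0, 340.0))
        assert pk.dh_d == pytest.approx(0.5 * 40.0, rel=0.01)

    def test_triangle_enthalpy(self):
        T = np.linspace(300.0, 340.0, 81)
        tri = 0.8 * (1 - np.abs(T - 320.0) / 20.0)
        prof = CpProfile(T, np.zeros(81), excess_cp=tri, baseline=0.0)
        pk = peak_enthalpy(prof, (300.0, 340.0))
        assert pk.dh_d == pytest.approx(0.8 * 40.0 / 2, rel=0.01)
        assert pk.peak_temperature == pytest.approx(320.0)

    def test_no_interior_maximum_rejected(self):
        T = np.linspace(300.0, 340.0, 21)
        prof = CpProfile(T, np.zeros(21), excess_cp=np.linspace(0, 1, 21), baseline=0.0)
        with pytest.raises(ValueError):
            peak_enthalpy(prof, (300.0, 340.0))

    def test_synthetic_enthalpy_matches_quadrature_oracle(self):
        p = TwoStateParams()
        ladder = geometric_ladder(271.0, 465.0, 16)
        ds = generate_remd_dataset(ladder, p, n_per_t=100_000, seed=9)
        prof = excess_heat_capacity(heat_capacity_profile(ds.energy_series))
        windows = find_peak_windows(prof)
        assert windows, "no peak window found on the synthetic profile"
        lo, hi = windows[0]
        pk = peak_enthalpy(prof, (lo, hi))
        dense = np.linspace(lo, hi, 2000)
        base = closed_form_mixture_cp(271.0, p)
        oracle = np.trapezoid(closed_form_mixture_cp(dense, p) - base, dense)
        assert pk.dh_d == pytest.approx(oracle, rel=0.15)


class TestBlockErrors:
    def test_constant_series_zero_error(self):
        mean, err = block_errors(np.full(100, 2.5), 2)
        assert mean == pytest.approx(2.5)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_two_block_closed_form(self):
        values = np.concatenate([np.full(10, 1.0), np.full(10, 3.0)])
        mean, err = block_errors(values, 2)
        assert mean == pytest.approx(2.0)
        assert err == pytest.approx(abs(1.0 - 3.0) / 2)

    def test_iid_gaussian_matches_sampling_theory(self):
        sigma, n = 1.0, 40_000
        target = sigma / np.sqrt(n)
        errs = [
            block_errors(np.random.default_rng(seed).normal(0, sigma, n), 5)[1]
            for seed in range(10)
        ]
        assert np.mean(errs) == pytest.approx(target, rel=0.5)

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_errors(np.arange(3), 4)
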