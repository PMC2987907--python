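"""Free-energy profiles, folding-time estimators, event detection, committor."""

import numpy as np
import pytest

from foldtherm.constants import R_KCAL
from foldtherm.io import TemperatureSeries
from foldtherm.kinetics import (
    barrier_height,
    cmd_folding_time,
    detect_folding_event,
    free_energy_profile,
    friction_correct,
    kramers_estimate,
    kramers_time,
    pearson_corr,
    pfold_estimate,
    scale_prefactor,
)
from foldtherm.synth import TwoStateParams, rates, simulate_order_series


class TestFreeEnergyProfile:
    def test_uniform_samples_flat(self):
        rng = np.random.default_rng(0)
        prof = free_energy_profile(rng.uniform(0, 10, 200_000),
                                   bins=np.linspace(0, 10, 11), temperature=300.0)
        assert np.nanmax(prof.free_energy) < 0.02

    def test_two_well_population_ratio_closed_form(self):
        values = np.concatenate([np.full(800, 1.0), np.full(200, 5.0)])
        prof = free_energy_profile(values, bins=np.array([0.0, 2.0, 4.0, 6.0]),
                                   temperature=300.0)
        df = prof.free_energy[2] - prof.free_energy[0]
        assert df == pytest.approx(-R_KCAL * 300.0 * np.log(0.2 / 0.8), rel=1e-9)
        assert np.isnan(prof.free_energy[1])  # empty bin marked, not zero

    def test_bin_doubling_preserves_well_difference(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(1, 0.3, 80_000), rng.normal(5, 0.3, 20_000)])
        diffs = []
        for nbins in (40, 20):
            prof = free_energy_profile(values, bins=np.linspace(0, 6, nbins + 1),
                                       temperature=300.0)
            well1 = np.nanmin(prof.free_energy[prof.bin_centers < 3])
            well2 = np.nanmin(prof.free_energy[prof.bin_centers > 3])
            diffs.append(well2 - well1)
        assert diffs[0] == pytest.approx(diffs[1], abs=0.05)

    def test_min_is_zero(self):
        prof = free_energy_profile(np.random.default_rng(2).normal(3, 1, 1000),
                                   bins=20, temperature=300.0)
        assert np.nanmin(prof.free_energy) == 0.0


class TestBarrierHeight:
    def test_v_shaped_profile_rejected(self):
        from foldtherm.kinetics import FreeEnergyProfile

        q = np.linspace(0, 10, 21)
        F = np.abs(q - 5.0)  # single minimum, no interior barrier
        prof = FreeEnergyProfile(q, F - F.min(), 300.0, q[1] - q[0])
        with pytest.raises(ValueError):
            barrier_height(prof, (4.0, 6.0), (9.0, 10.0))

    def test_plateau_barrier_takes_first_maximum(self):
        from foldtherm.kinetics import FreeEnergyProfile

        q = np.arange(7, dtype=float)
        F = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.5])
        prof = FreeEnergyProfile(q, F, 300.0, 1.0)
        dg, loc = barrier_height(prof, (0.0, 1.0), (5.0, 6.0))
        assert dg == pytest.approx(2.0)
        assert loc == pytest.approx(2.0)  # first bin of the plateau

    def test_double_well_langevin_recovery(self, toy_remd_run):
        from foldtherm.io import demux_replicas

        potential, result = toy_remd_run
        demuxed = demux_replicas(result.records, result.coordinate_series)
        coldest = demuxed[min(demuxed)]
        prof = free_energy_profile(coldest.values, bins=np.linspace(-2, 2, 41),
                                   temperature=coldest.temperature)
        dg, loc = barrier_height(prof, (-1.5, -0.5), (0.5, 1.5))
        assert dg == pytest.approx(potential.barrier, abs=0.2)
        assert abs(loc) < 0.2  # barrier top at x = 0


class TestFoldingTimeEstimators:
    def test_kramers_zero_barrier_is_prefactor(self):
        assert kramers_time(0.0, 323.0, 0.56) == pytest.approx(0.56)

    def test_kramers_worked_example(self):
        # ΔG* = 0.9 kcal/mol, A = 0.56 µs, T = 323 K -> ~2.28 µs
        assert kramers_time(0.9, 323.0, 0.56) == pytest.approx(2.2, abs=0.15)

    def test_kramers_exponent_law(self):
        tau = kramers_time(1.3, 310.0, 0.5)
        doubled = kramers_time(1.3 + R_KCAL * 310.0 * np.log(2), 310.0, 0.5)
        assert doubled == pytest.approx(2 * tau, rel=1e-12)

    def test_kramers_error_propagation(self):
        res = kramers_estimate(0.9, 323.0, 0.56, barrier_err=0.1)
        assert res.tau_err == pytest.approx(res.tau * 0.1 / (R_KCAL * 323.0), rel=1e-12)

    @pytest.mark.parametrize("n,expected", [(40, 0.80), (28, 0.56), (20, 0.40)])
    def test_prefactor_linear_scaling(self, n, expected):
        assert scale_prefactor(n) == pytest.approx(expected, abs=1e-12)

    def test_count_estimator_worked_example(self):
        res = cmd_folding_time(20, 1.0, 2)
        assert res.tau == pytest.approx(10.0)
        assert res.tau_err == pytest.approx(10.0 / np.sqrt(2))  # printed ±7
        assert not res.lower_bound

    def test_all_folded_gives_duration(self):
        assert cmd_folding_time(10, 0.5, 10).tau == pytest.approx(0.5)

    def test_censored_lower_bound(self):
        res = cmd_folding_time(20, 1.0, 0)
        assert res.lower_bound
        assert res.tau == pytest.approx(20.0)

    def test_friction_correction_worked_example(self):
        res = friction_correct(cmd_folding_time(20, 1.0, 2), 60.0)
        assert res.tau == pytest.approx(600.0)

    def test_friction_composition_and_identity(self):
        base = cmd_folding_time(20, 1.0, 2)
        assert friction_correct(base, 1.0).tau == pytest.approx(base.tau)
        ab = friction_correct(friction_correct(base, 3.0), 5.0)
        assert ab.tau == pytest.approx(friction_correct(base, 15.0).tau)

    def test_censoring_flag_survives_correction(self):
        res = friction_correct(cmd_folding_time(20, 1.0, 0), 60.0)
        assert res.lower_bound

    def test_count_estimator_consistent_with_kramers_on_chain_data(self):
        """Consistency loop: folding events generated by the detailed-balance
        chain reproduce the Kramers time within a factor of two."""
        p = TwoStateParams()
        T = 300.0
        k_f, _ = rates(T, p)
        tau_kramers = kramers_time(p.barrier_fold, T, p.prefactor)
        assert tau_kramers == pytest.approx(1.0 / k_f, rel=1e-12)

        M, t_us = 40, 1.0
        n_folded = 0
        for k in range(M):
            s = simulate_order_series(T, duration=t_us * 1e3, dt=0.5, p=p,
                                      seed=100 + k, start_state=0)
            if detect_folding_event(s, cutoff=3.0, min_dwell=30.0) is not None:
                n_folded += 1
        est = cmd_folding_time(M, t_us, n_folded)
        assert tau_kramers / 2 < est.tau < tau_kramers * 2


class TestEventDetection:
    def _series(self, values, dt=1.0):
        return TemperatureSeries(300.0, dt, np.asarray(values, float), "rmsd")

    def test_always_folded_event_at_zero(self):
        s = self._series(np.full(40, 2.0))
        assert detect_folding_event(s, 3.0, 30.0) == pytest.approx(0.0)

    def test_short_dip_is_no_event(self):
        values = np.full(100, 7.0)
        values[10:31] = 2.0  # below cutoff for only 20 ns
        assert detect_folding_event(self._series(values), 3.0, 30.0) is None

    def test_late_long_dip_detected_at_onset(self):
        values = np.full(200, 7.0)
        values[100:151] = 2.0  # 50 ns below cutoff starting at t = 100 ns
        assert detect_folding_event(self._series(values), 3.0, 30.0) == pytest.approx(100.0)

    def test_value_at_cutoff_breaks_dwell(self):
        values = np.full(60, 2.0)
        values[15] = 3.0  # exactly at the cutoff -> not folded
        assert detect_folding_event(self._series(values), 3.0, 30.0) == pytest.approx(16.0)

    def test_dwell_shorter_than_dt_rejected(self):
        with pytest.raises(ValueError):
            detect_folding_event(self._series(np.zeros(10), dt=2.0), 3.0, 1.0)


class TestPfold:
    def test_worked_example_23_of_40(self):
        res = pfold_estimate(23, 17)
        assert res.p_fold == pytest.approx(0.575)
        assert res.is_transition_state
        assert res.ci_low <= res.p_fold <= res.ci_high

    def test_even_split(self):
        res = pfold_estimate(20, 20)
        assert res.p_fold == pytest.approx(0.5)
        assert res.is_transition_state

    def test_all_folded_not_transition_state(self):
        res = pfold_estimate(40, 0)
        assert res.p_fold == pytest.approx(1.0)
        assert not res.is_transition_state

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pfold_estimate(0, 0)

    def test_wilson_interval_coverage_at_half(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(500):
            n_folded = rng.binomial(40, 0.5)
            if pfold_estimate(int(n_folded), 40 - int(n_folded)).is_transition_state:
                hits += 1
        assert hits / 500 >= 0.90


class TestPearson:
    def test_self_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert pearson_corr(x, x) == pytest.approx(1.0)

    def test_negated_series(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_formula_on_toy_table(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        # direct product-moment arithmetic, independent of the implementation
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert pearson_corr(x, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))
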