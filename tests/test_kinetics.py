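"""Gating-scheme simulation, dwell-time MLE, equilibrium constants,
thermodynamic conversions, phi-values and mode segmentation."""

import math

import numpy as np
import pytest

from sitecraft.errors import UsageError
from sitecraft.kinetics import (
    DwellDataset,
    GatingScheme,
    PhiInput,
    additivity_ledger,
    correct_background,
    energy_from_kd,
    estimate_E_from_cluster,
    fold_from_energy,
    kd_from_equilibrium,
    kd_from_rates,
    log_likelihood,
    mle_fit,
    percent_swap,
    phi_value,
    rt_kcal,
    segment_modes,
    simulate_dwells,
)
from sitecraft.synthetic import make_bimodal_dwells, make_dwell_data

SCHEME = GatingScheme(k_on=1e8, k_off=1e4, f_open=1e3, b_close=1e3)


class TestSimulateDwells:
    def test_deterministic_given_seed(self):
        a = simulate_dwells(SCHEME, 1e-4, 200, seed=42)
        b = simulate_dwells(SCHEME, 1e-4, 200, seed=42)
        assert a.clusters == b.clusters

    def test_alternation_and_counts(self):
        ds = simulate_dwells(SCHEME, 1e-4, 100, seed=0)
        states = [s for s, _ in ds.clusters[0]]
        assert states[::2] == ["closed"] * 100
        assert states[1::2] == ["open"] * 100

    def test_mean_open_duration_is_inverse_closing_rate(self):
        ds = simulate_dwells(SCHEME, 1e-4, 10_000, seed=1)
        opens = ds.durations("open")
        mean, sem = opens.mean(), opens.std(ddof=1) / math.sqrt(opens.size)
        assert abs(mean - 1.0 / SCHEME.b_close) < 3 * sem

    def test_saturating_concentration_closed_dwells_exponential_in_f(self):
        # k_on*conc >> k_off: closed class collapses onto AC, dwells ~ Exp(f)
        ds = simulate_dwells(SCHEME, 1.0, 10_000, seed=2)
        closed = ds.durations("closed")
        mean, sem = closed.mean(), closed.std(ddof=1) / math.sqrt(closed.size)
        assert abs(mean - 1.0 / SCHEME.f_open) < 4 * sem

    def test_occupancies_match_stationary_distribution(self):
        """Time fractions per state class agree with the analytic
        stationary distribution of the 3-state generator."""
        conc = 1e-4
        ds = simulate_dwells(SCHEME, conc, 20_000, seed=3)
        pi_c = 1.0
        pi_ac = SCHEME.k_on * conc / SCHEME.k_off
        pi_ao = pi_ac * SCHEME.f_open / SCHEME.b_close
        z = pi_c + pi_ac + pi_ao
        open_frac = ds.durations("open").sum() / (
            ds.durations("open").sum() + ds.durations("closed").sum()
        )
        assert open_frac == pytest.approx(pi_ao / z, rel=0.02)

    def test_dead_time_warns_uncorrected(self):
        with pytest.warns(UserWarning, match="uncorrected|idealized"):
            simulate_dwells(SCHEME, 1e-4, 10, seed=0, dead_time_s=25e-6)

    def test_bad_inputs(self):
        with pytest.raises(UsageError):
            simulate_dwells(SCHEME, 1e-4, 0)
        with pytest.raises(UsageError):
            GatingScheme(k_on=-1, k_off=1, f_open=1, b_close=1)


class TestMleFit:
    def test_single_concentration_rejected(self):
        ds = simulate_dwells(SCHEME, 1e-4, 200, seed=0)
        with pytest.raises(UsageError, match="2 distinct"):
            mle_fit([ds])

    def test_recovers_generating_rates(self):
        datasets, truth = make_dwell_data(
            SCHEME, concs_M=[3e-5, 1e-4, 3e-4], n_events=5000, seed=10
        )
        fit = mle_fit(datasets)
        for name in ("k_on", "k_off", "f_open", "b_close"):
            assert getattr(fit.scheme, name) == pytest.approx(
                truth[name], rel=0.10
            )
        assert fit.standard_errors["b_close"] > 0
        assert fit.scheme.kd_M == pytest.approx(truth["kd_M"], rel=0.10)

    def test_likelihood_peaks_near_truth(self):
        datasets, _ = make_dwell_data(
            SCHEME, concs_M=[3e-5, 3e-4], n_events=3000, seed=4
        )
        ll_true = log_likelihood(datasets, SCHEME)
        perturbed = GatingScheme(
            SCHEME.k_on * 2, SCHEME.k_off * 2, SCHEME.f_open * 2,
            SCHEME.b_close * 2,
        )
        assert ll_true > log_likelihood(datasets, perturbed)

    def test_few_events_warn(self):
        datasets, _ = make_dwell_data(SCHEME, [3e-5, 3e-4], n_events=20, seed=0)
        with pytest.warns(UserWarning, match="events"):
            mle_fit(datasets)


class TestEquilibriumAndEnergies:
    def test_kd_from_rates(self):
        assert kd_from_rates(1e3, 1e8) == pytest.approx(1e-5)
        assert kd_from_rates(123.0, 123.0) == 1.0

    def test_kd_proxy_arithmetic(self):
        assert kd_from_equilibrium(1.0, 1.0) == 1.0
        assert kd_from_equilibrium(7.4e-7, 7.4) == pytest.approx(1e-7)

    def test_ddg_from_proxy_equals_ddg_from_molar_kd(self):
        # the omitted open-state constant cancels in differences
        c = 3.7e4  # shared unknown constant linking proxy to molar Kd
        proxy_a, proxy_b = 2.0e-7, 6.3e-6
        ddg_proxy = energy_from_kd(proxy_a) - energy_from_kd(proxy_b)
        ddg_molar = energy_from_kd(proxy_a / c) - energy_from_kd(proxy_b / c)
        assert ddg_proxy == pytest.approx(ddg_molar, rel=1e-12)

    def test_estimate_E_closed_form_and_recovery(self):
        ds = DwellDataset(
            clusters=[[("closed", 1e-3), ("open", 2e-3)] * 10],
            conc_M=0.1,
        )
        assert estimate_E_from_cluster(ds) == pytest.approx(2.0)
        sat = simulate_dwells(SCHEME, 1.0, 5000, seed=6)
        assert estimate_E_from_cluster(sat) == pytest.approx(
            SCHEME.e1, rel=0.05
        )

    def test_background_correction_round_trip(self):
        assert correct_background(7.4e-4, [10.0, 100.0]) == pytest.approx(7.4e-7)
        assert correct_background(0.5, []) == 0.5
        applied = 7.4e-7 * 10 * 100
        assert correct_background(applied, [10.0, 100.0]) == pytest.approx(7.4e-7)
        with pytest.raises(UsageError):
            correct_background(1.0, [0.0])

    def test_rt_and_energy_identities(self):
        assert energy_from_kd(1.0) == 0.0
        assert round(rt_kcal(), 2) == 0.59
        x = -3.7
        assert energy_from_kd(fold_from_energy(x)) == pytest.approx(x, abs=1e-10)
        assert fold_from_energy(0.0) == 1.0

    def test_mle_to_kd_end_to_end(self):
        datasets, truth = make_dwell_data(
            SCHEME, concs_M=[3e-5, 1e-4, 3e-4], n_events=4000, seed=17
        )
        fit = mle_fit(datasets)
        kd = kd_from_rates(fit.scheme.k_off, fit.scheme.k_on)
        assert kd == pytest.approx(truth["kd_M"], rel=0.10)


class TestAdditivity:
    def test_two_site_totals(self):
        ledger = additivity_ledger({"ad": -5.1, "ag": -7.1})
        assert ledger["total"] == pytest.approx(-12.2)
        ledger2 = additivity_ledger({"ad": -5.1, "ae": -5.1})
        assert ledger2["total"] == pytest.approx(-10.2)
        assert additivity_ledger({})["total"] == 0.0

    def test_permutation_invariance(self):
        a = additivity_ledger({"x": -1.0, "y": -2.0, "z": -3.0})
        b = additivity_ledger({"z": -3.0, "x": -1.0, "y": -2.0})
        assert a == b

    def test_percent_swap(self):
        assert percent_swap(-7.1, -5.1, -7.1) == pytest.approx(100.0)
        assert percent_swap(-5.1, -5.1, -7.1) == pytest.approx(0.0)
        with pytest.raises(UsageError):
            percent_swap(0.0, 1.0, 1.0)


class TestPhiValue:
    def test_slope_one_when_rate_tracks_equilibrium(self):
        pts = [PhiInput(f"c{i}", opening_rate=10.0 * e, gating_E=e)
               for i, e in enumerate([0.1, 1.0, 10.0, 100.0])]
        slope, _, r = phi_value(pts)
        assert slope == pytest.approx(1.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_slope_zero_for_constant_rate(self):
        pts = [PhiInput(f"c{i}", opening_rate=500.0, gating_E=e)
               for i, e in enumerate([0.1, 1.0, 10.0])]
        slope, _, _ = phi_value(pts)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_two_point_slope_arithmetic(self):
        pts = [PhiInput("a", 10**3, 10.0), PhiInput("b", 10**2.43, 1.0)]
        slope, _, _ = phi_value(pts)
        assert slope == pytest.approx(0.57, abs=1e-9)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(UsageError):
            phi_value([PhiInput("a", 1.0, 1.0)])


class TestSegmentModes:
    HA = GatingScheme(k_on=1e8, k_off=1e5, f_open=1e4, b_close=1e4)
    LA = GatingScheme(k_on=1e8, k_off=1e5, f_open=1e4, b_close=1e3)

    def test_balanced_mixture_prevalence_and_tau(self):
        ds, truth = make_bimodal_dwells(
            self.HA, self.LA, switch_tau_s=0.020, n_clusters=500,
            events_per_cluster=5, conc_M=1e-3, seed=7,
        )
        report = segment_modes(ds)
        assert report.n_modes == 2
        # time-weighted prevalences approximately isoenergetic
        assert report.prevalence[0] == pytest.approx(0.5, abs=0.1)
        assert report.prevalence[1] == pytest.approx(0.5, abs=0.1)
        assert report.switching_tau_s == pytest.approx(0.020, rel=0.20)
        # labels agree with generator truth up to a small error rate
        agree = np.mean(np.array(report.labels) == np.array(truth["mode_labels"]))
        assert max(agree, 1 - agree) > 0.9

    def test_unimodal_not_force_split(self):
        ds, _ = make_bimodal_dwells(
            self.HA, self.HA, switch_tau_s=0.020, n_clusters=100,
            events_per_cluster=5, conc_M=1e-3, seed=3,
        )
        report = segment_modes(ds)
        assert report.n_modes == 1
        assert report.prevalence[0] == 1.0

    def test_too_few_clusters_rejected(self):
        ds, _ = make_bimodal_dwells(
            self.HA, self.LA, switch_tau_s=0.02, n_clusters=5,
            events_per_cluster=3, seed=0,
        )
        with pytest.raises(UsageError):
            segment_modes(ds)
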