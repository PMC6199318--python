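import math

import numpy as np
import pandas as pd
import pytest

from twometal import (
    DisorderSpec,
    FretTrace,
    LogVHistogram,
    ModelSpec,
    ModelVariant,
    RateConstants,
    VelocityDataset,
    compute_fret,
    estimate_kAoff,
    estimate_sigma,
    fit_velocity_curve,
    first_passage_pdf,
    logV_transform,
    mean_velocity,
    measure_velocity_from_trace,
    pause_statistics,
    predict_logV_histogram,
    simulate_trajectory,
    synth_velocity_dataset,
    tau1,
    trajectory_to_fret,
)
from twometal.inference import FitError, PauseSummary
from twometal.stochastic_simulator import DEFAULT_CONCENTRATION_GRID, PauseRecord

LOG10E = math.log10(math.e)


def noiseless_dataset(rates, concentrations=DEFAULT_CONCENTRATION_GRID, n_sites=20):
    spec = ModelSpec(ModelVariant.MODEL1, rates, n_sites)
    rows = [
        {"mg_mM": c, "velocity_nt_s": mean_velocity(spec, c), "trace_id": f"t{i}"}
        for i, c in enumerate(concentrations)
    ]
    return VelocityDataset(records=pd.DataFrame(rows))


class TestComputeFret:
    def test_symmetric_intensities(self):
        assert compute_fret(100.0, 100.0) == pytest.approx(0.5)

    def test_boundaries(self):
        assert compute_fret(250.0, 0.0) == 0.0
        assert compute_fret(0.0, 250.0) == 1.0

    def test_crosstalk_correction(self):
        assert compute_fret(300.0, 300.0, crosstalk=0.1) == pytest.approx(0.4737, abs=1e-4)

    def test_both_zero_marks_undefined(self):
        assert math.isnan(compute_fret(0.0, 0.0))

    def test_vectorized(self):
        eff = compute_fret(np.array([100.0, 0.0]), np.array([100.0, 0.0]))
        assert eff[0] == pytest.approx(0.5)
        assert math.isnan(eff[1])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            compute_fret(-1.0, 5.0)


class TestMeasureVelocity:
    def _ramp_trace(self):
        # plateau at e_min until t=1, linear rise to e_max at t=3, then plateau
        times = np.round(np.arange(0.0, 5.0, 0.1), 10)
        fret = np.interp(times, [0.0, 1.0, 3.0], [0.26, 0.26, 0.53])
        return FretTrace(frame_dt=0.1, times=times, fret=fret,
                         metadata={"n_sites": 20, "e_min": 0.26, "e_max": 0.53})

    def test_noise_free_fixture_gives_exact_velocity(self):
        v = measure_velocity_from_trace(
            self._ramp_trace(), low_frac=0.0, high_frac=1.0, smooth_frames=1
        )
        assert v == pytest.approx(10.0, rel=1e-9)  # 20 nt / 2 s

    def test_trace_stuck_at_minimum_gives_no_event(self):
        times = np.arange(0.0, 5.0, 0.1)
        trace = FretTrace(frame_dt=0.1, times=times, fret=np.full_like(times, 0.26),
                          metadata={"n_sites": 20})
        assert math.isnan(measure_velocity_from_trace(trace))

    def test_mean_over_noisy_traces_within_10_percent(self, spec1):
        rng = np.random.default_rng(7)
        vs = []
        for _ in range(300):
            traj = simulate_trajectory(spec1, 3.0, rng)
            v = measure_velocity_from_trace(trajectory_to_fret(traj, seed=rng))
            if math.isfinite(v):
                vs.append(v)
        assert len(vs) > 250
        expected = 20 / (20 * tau1(spec1, 3.0))
        assert np.mean(vs) == pytest.approx(expected, rel=0.10)

    def test_invalid_fracs(self):
        with pytest.raises(ValueError):
            measure_velocity_from_trace(self._ramp_trace(), 0.9, 0.1)


class TestFitVelocityCurve:
    def test_model1_noiseless_round_trip(self, concluded_rates):
        data = noiseless_dataset(concluded_rates)
        fit = fit_velocity_curve(data, "model1")
        assert fit.converged
        assert fit.params["k_B_off"] == pytest.approx(18.0, rel=1e-3)
        assert fit.params["K_B"] == pytest.approx(0.71, rel=1e-3)
        assert fit.params["K_A"] == pytest.approx(0.30, rel=1e-3)
        assert fit.rss < 1e-10

    def test_hill_fit_to_model1_data_is_supra_linear(self, concluded_rates):
        data = noiseless_dataset(concluded_rates)
        fit = fit_velocity_curve(data, "hill")
        assert 1.0 < fit.params["n"] < 2.0

    def test_hill_cooperativity_over_random_scan(self):
        # 30 random (K_A, K_B) pairs on a log-spaced concentration grid
        # (the full 100-pair scan runs in the acceptance suite)
        rng = np.random.default_rng(31)
        grid = np.geomspace(0.01, 10.0, 20)
        for _ in range(30):
            K_A, K_B = np.exp(rng.uniform(np.log(0.05), np.log(2.0), size=2))
            rates = RateConstants(18.0, 18.0 / K_B, 0.1, 0.1 / K_A)
            fit = fit_velocity_curve(noiseless_dataset(rates, grid), "hill")
            assert 1.0 < fit.params["n"] < 2.0

    def test_mm_equals_model1_in_nested_limit(self):
        rates = RateConstants(18.0, 25.35, 1e-6, 1.0)  # K_A ~ 0
        data = noiseless_dataset(rates)
        rss_mm = fit_velocity_curve(data, "mm").rss
        rss_m1 = fit_velocity_curve(data, "model1").rss
        assert rss_mm < 1e-8
        assert abs(rss_mm - rss_m1) < 1e-8

    def test_scale_consistency(self, concluded_rates):
        data = noiseless_dataset(concluded_rates)
        scaled = VelocityDataset(
            records=data.records.assign(velocity_nt_s=data.records.velocity_nt_s * 3.0)
        )
        for model, vmax_key in (("model1", "k_B_off"), ("mm", "v_max"), ("hill", "v_max")):
            base = fit_velocity_curve(data, model)
            up = fit_velocity_curve(scaled, model)
            assert up.params[vmax_key] == pytest.approx(3 * base.params[vmax_key], rel=1e-5)
            for key in base.params:
                if key != vmax_key:
                    assert up.params[key] == pytest.approx(base.params[key], rel=1e-4)

    def test_refit_bias_small_under_noise(self, concluded_rates):
        rng = np.random.default_rng(2)
        truth = {"k_B_off": 18.0, "K_B": 0.71, "K_A": 0.30}
        estimates = {k: [] for k in truth}
        base = noiseless_dataset(concluded_rates)
        v0 = base.records["velocity_nt_s"].to_numpy()
        for _ in range(100):
            noisy = base.records.assign(
                velocity_nt_s=v0 * (1 + rng.normal(0, 0.03, size=len(v0)))
            )
            try:
                fit = fit_velocity_curve(VelocityDataset(records=noisy), "model1")
            except FitError:
                continue
            for k in truth:
                estimates[k].append(fit.params[k])
        for k, val in truth.items():
            med = np.median(estimates[k])
            assert abs(med - val) / val < 0.05

    def test_too_few_conditions(self, concluded_rates):
        data = noiseless_dataset(concluded_rates, concentrations=(0.5, 3.0))
        with pytest.raises(ValueError):
            fit_velocity_curve(data, "model1")


class TestEstimateSigma:
    def test_pure_lognormal_recovery(self):
        rng = np.random.default_rng(6)
        sigma = 0.5
        zeta = rng.normal(1.0, sigma * LOG10E, size=5000)
        est = estimate_sigma(10.0**zeta)
        assert est.sigma_kbt == pytest.approx(sigma, rel=0.05)
        assert est.sigma_zeta == pytest.approx(sigma * LOG10E, rel=0.05)

    def test_degenerate_input(self):
        with pytest.warns(UserWarning):
            est = estimate_sigma([2.0] * 25)
        assert est.sigma_kbt == 0.0

    def test_requires_20_velocities(self):
        with pytest.raises(ValueError):
            estimate_sigma([1.0] * 19)

    def test_disorder_free_width_is_positive(self, spec1):
        data = synth_velocity_dataset(spec1, [3.0], 100, None, seed=5)
        est = estimate_sigma(data.velocities_at(3.0))
        assert est.sigma_kbt > 0

    def test_intrinsic_correction(self):
        rng = np.random.default_rng(6)
        zeta = rng.normal(1.0, 0.2, size=1000)
        est = estimate_sigma(10.0**zeta, intrinsic_sigma_zeta=0.1)
        expected = math.sqrt(est.sigma_zeta**2 - 0.01) / LOG10E
        assert est.sigma_kbt_corrected == pytest.approx(expected)


class TestLogVHistogram:
    def test_from_velocities_sums_to_one_with_covering_edges(self):
        v = np.array([1.0, 2.0, 4.0, 8.0])
        h = LogVHistogram.from_velocities(v, np.linspace(-0.5, 1.5, 21))
        assert h.probs.sum() == pytest.approx(1.0)
        assert h.count == 4

    def test_validation(self):
        with pytest.raises(ValueError):
            LogVHistogram(edges=np.array([0.0, 0.0, 1.0]), probs=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            LogVHistogram(edges=np.array([0.0, 1.0]), probs=np.array([1.5]))


class TestPredictLogVHistogram:
    def test_bin_probabilities_sum_to_density_mass(self, spec1):
        d = DisorderSpec(sigma=0.2, n_draws=200, seed=3)
        z = logV_transform(first_passage_pdf(spec1, 1.0), 20)
        edges = np.linspace(z.grid[0], z.grid[-1], 60)
        hist = predict_logV_histogram(spec1, 1.0, d, edges)
        from twometal.master_equation import disorder_average_pdf

        zpdf = logV_transform(disorder_average_pdf(spec1, 1.0, d), 20)
        assert hist.probs.sum() == pytest.approx(min(1.0, zpdf.mass()), abs=1e-6)

    def test_sharp_distribution_falls_in_one_bin(self, spec1):
        d = DisorderSpec(sigma=0.0, n_draws=1, seed=0)
        # bins much wider than the distribution: all mass lands in one bin
        mode = math.log10(1 / tau1(spec1, 3.0))
        edges = np.array([mode - 5.0, mode - 1.0, mode + 1.0, mode + 5.0])
        hist = predict_logV_histogram(spec1, 3.0, d, edges)
        assert hist.probs[1] == pytest.approx(1.0, abs=5e-3)


@pytest.fixture(scope="module")
def kaoff_search_setup():
    rates = RateConstants(18.0, 18.0 / 0.71, 0.1, 0.1 / 0.30)
    spec = ModelSpec(ModelVariant.MODEL1, rates, 20)
    disorder = DisorderSpec(sigma=0.25, n_draws=1, seed=0)
    observed = {}
    for i, c in enumerate((0.03, 0.3)):
        data = synth_velocity_dataset(
            spec, [c], 150, DisorderSpec(sigma=0.25, n_draws=1, seed=0), seed=100 + i
        )
        v = data.velocities_at(c)
        zeta = np.log10(v)
        edges = LogVHistogram.default_edges(zeta.min() - 0.3, zeta.max() + 0.3, 0.1)
        observed[c] = LogVHistogram.from_velocities(v, edges)
    prediction_disorder = DisorderSpec(sigma=0.25, n_draws=300, seed=42)
    return rates, observed, prediction_disorder


class TestEstimateKAoff:
    def test_recovers_generating_value_with_u_shaped_mse(self, kaoff_search_setup):
        rates, observed, d = kaoff_search_setup
        candidates = [0.001, 0.01, 0.1, 1.0, 10.0]
        result = estimate_kAoff(candidates, observed, rates, d)
        assert result.best == pytest.approx(0.1)
        mse = [result.mse[k] for k in candidates]
        k_star = mse.index(min(mse))
        assert candidates[k_star] == pytest.approx(0.1)
        assert all(mse[i] > mse[i + 1] for i in range(k_star))
        assert all(mse[i] < mse[i + 1] for i in range(k_star, len(mse) - 1))

    def test_permutation_invariant_and_deterministic(self, kaoff_search_setup):
        rates, observed, d = kaoff_search_setup
        a = estimate_kAoff([0.01, 0.1, 1.0], observed, rates, d)
        b = estimate_kAoff([1.0, 0.01, 0.1], observed, rates, d)
        assert a.best == b.best
        assert a.mse == b.mse

    def test_needs_two_candidates(self, kaoff_search_setup):
        rates, observed, d = kaoff_search_setup
        with pytest.raises(ValueError):
            estimate_kAoff([0.1], observed, rates, d)


class TestPauseStatistics:
    def _record(self, duration, state="E", position=3):
        occ = {"E": 0.0, "EM": 0.0, "EMM": 0.0}
        occ[state] = 1.0
        return PauseRecord(start=0.0, duration=duration, position=position, occupancy=occ)

    def test_empty_input(self):
        summary = pause_statistics([])
        assert summary.n_pauses == 0
        assert math.isnan(summary.mean_duration)

    def test_threshold_filtering_and_fractions(self):
        per_trace = [
            [self._record(12.0, "E"), self._record(4.0, "EM")],
            [self._record(25.0, "E")],
            [],
        ]
        summary = pause_statistics(per_trace, report_threshold=10.0)
        assert summary.n_pauses == 2
        assert summary.mean_duration == pytest.approx(18.5)
        assert summary.state_fractions["E"] == 1.0
        assert summary.fraction_traces_with_pause == pytest.approx(2 / 3)

    def test_histogram(self):
        summary = pause_statistics([self._record(12.0), self._record(14.0)], 10.0)
        edges, counts = summary.histogram(bin_width=5.0)
        assert counts.sum() == 2


class TestMeanVsLogMeanCaveat:
    def test_arithmetic_and_log_means_differ_on_skewed_data(self, concluded_rates):
        spec = ModelSpec(ModelVariant.MODEL1, concluded_rates, 20)
        data = synth_velocity_dataset(spec, [0.3], 250, None, seed=13)
        v = data.velocities_at(0.3)
        zeta_mean = np.mean(np.log10(v))
        assert abs(zeta_mean - math.log10(v.mean())) > 0.01
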