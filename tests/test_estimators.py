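"""Unit tests for the count-matrix and raster estimators."""

import math

import numpy as np
import pytest

import docksim as dk
from conftest import mc_se, protocol
from oracles import binomial_sample_from_pmf, enumerate_rsds, joint_cov_profile


def _as_cm(counts, n_stim=None, freq_hz=100.0):
    counts = np.asarray(counts)
    proto = dk.TrainProtocol(
        n_stim=counts.shape[1], freq_hz=freq_hz, n_trains=counts.shape[0]
    )
    return dk.CountMatrix(counts=counts, protocol=proto)


class TestSummarize:
    def test_identical_trains_have_zero_variance(self):
        cm = _as_cm(np.tile([2, 1, 0], (5, 1)))
        stats = dk.summarize(cm)
        np.testing.assert_array_equal(stats.var_si, 0.0)
        np.testing.assert_array_equal(stats.cum_Si, [2, 3, 3])

    def test_hand_computed_moments(self):
        stats = dk.summarize(np.array([[0, 1], [2, 1]]))
        assert stats.mean_si[0] == 1.0
        assert stats.var_si[0] == 1.0  # population normalisation

    def test_binomial_moments(self):
        rng = np.random.default_rng(0)
        counts = rng.binomial(4, 0.5, size=(10_000, 2))
        stats = dk.summarize(counts)
        assert stats.mean_si[0] == pytest.approx(2.0, abs=0.05)
        assert stats.var_si[0] == pytest.approx(1.0, abs=0.05)

    def test_single_train_rejected(self):
        with pytest.raises(dk.DataError):
            dk.summarize(np.array([[1, 2]]))


class TestBinomialN:
    def test_recovers_generating_n_from_exact_frequencies(self):
        sample = binomial_sample_from_pmf(4, 0.7)
        est = dk.fit_binomial_N(sample)
        assert est.n_int == 4
        assert est.p_hat == pytest.approx(0.7, abs=0.02)

    def test_candidate_range_below_max_count_rejected(self):
        counts = np.array([0, 1, 6, 2])
        with pytest.raises(dk.DataError):
            dk.fit_binomial_N(counts, n_range=range(1, 6))

    def test_all_zero_counts_indeterminate(self):
        est = dk.fit_binomial_N(np.zeros(50, dtype=int))
        assert est.indeterminate
        assert est.n_int is None

    def test_joint_fit_over_two_stimuli(self):
        rng = np.random.default_rng(1)
        s1 = rng.binomial(4, 0.9, size=200)
        s2 = rng.binomial(4, 0.6, size=200)
        est = dk.fit_binomial_N([s1, s2])
        assert est.n_int == 4

    def test_likelihood_objective_recovers_n(self):
        rng = np.random.default_rng(2)
        counts = rng.binomial(6, 0.7, size=60)
        est = dk.fit_binomial_N(counts, objective="likelihood")
        assert est.n_int == 6
        with pytest.raises(dk.ParameterError):
            dk.fit_binomial_N(counts, objective="bogus")

    def test_simulated_synapse_recovery_rate(self):
        # high-p_r condition, 60 trains per replicate, fit on s_1
        params = dk.ModelParams(n_sites=4, delta=0.8, p_r=0.9)
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            cm = dk.simulate_trains(params, protocol(n_trains=60, seed=100 + rep))
            est = dk.fit_binomial_N(cm.counts[:, 0])
            hits += est.n_int == 4
        assert hits / n_reps >= 0.9


class TestVarianceMeanN:
    def test_exact_parabola_points(self):
        m = np.array([0.4, 1.2, 2.0, 2.8])
        stats = dk.StimulusStats(
            mean_si=m, var_si=m * (1 - m / 4), cum_Si=np.cumsum(m), n_trains=100
        )
        est = dk.fit_variance_mean(stats)
        assert est.n_real == pytest.approx(4.0, abs=1e-6)
        assert est.n_int == 4

    def test_zero_variances_flagged(self):
        m = np.array([0.5, 1.5, 2.5])
        stats = dk.StimulusStats(
            mean_si=m, var_si=np.zeros(3), cum_Si=np.cumsum(m), n_trains=50
        )
        est = dk.fit_variance_mean(stats)
        assert est.failed
        assert est.n_real == pytest.approx(2.5)

    def test_too_few_points_rejected(self):
        stats = dk.StimulusStats(
            mean_si=np.array([1.0, 1.0]), var_si=np.array([0.5, 0.5]),
            cum_Si=np.array([1.0, 2.0]), n_trains=50,
        )
        with pytest.raises(dk.DataError):
            dk.fit_variance_mean(stats)

    def test_simulated_synapse_recovery(self, fourap_params):
        cm = dk.simulate_trains(fourap_params, protocol(n_trains=5000, seed=21))
        est = dk.fit_variance_mean(dk.summarize(cm))
        assert 3.5 <= est.n_real <= 4.5
        assert est.n_int == 4


class TestCovarianceProfile:
    def test_constant_counts_zero_covariance(self):
        prof = dk.covariance_profile(np.tile([1, 2, 1], (6, 1)))
        np.testing.assert_array_equal(prof.cov, 0.0)

    def test_hand_computed_two_trains(self):
        prof = dk.covariance_profile(np.array([[1, 0], [0, 1]]))
        assert prof.cov[0] == pytest.approx(-0.25)

    def test_single_train_rejected(self):
        with pytest.raises(dk.DataError):
            dk.covariance_profile(np.array([[1, 2, 3]]))

    def test_matches_enumeration_oracle(self):
        pars = dict(delta=0.65, rho=1.0, p_r=0.6, r=0.7, s=0.35)
        exact = joint_cov_profile(enumerate_rsds(n_stim=3, **pars))
        cm = dk.simulate_trains(
            dk.ModelParams(n_sites=1, **pars), protocol(n_stim=3, n_trains=100_000, seed=8)
        )
        got = dk.covariance_profile(cm).cov
        # SE of a covariance estimate, approximated from the product moments
        S = np.cumsum(cm.counts, axis=1)
        for i in range(2):
            prod = (S[:, i] - S[:, i].mean()) * (cm.counts[:, i + 1] - cm.counts[:, i + 1].mean())
            se = prod.std(ddof=1) / np.sqrt(len(prod))
            assert abs(got[i] - exact[i]) < 3 * se

    def test_depletion_implies_anticorrelation(self):
        for kind in ("rsds", "lsts"):
            params = dk.ModelParams(model_kind=kind, n_sites=4, delta=0.8, p_r=0.9, s=0.0)
            cm = dk.simulate_trains(params, protocol(n_trains=20_000, seed=13))
            prof = dk.covariance_profile(cm)
            assert np.all(prof.cov <= 1e-3)


class TestBackExtrapolation:
    def test_constant_release_recovers_per_ap_amount(self):
        cm = _as_cm(np.tile([3] * 8, (4, 1)))
        back = dk.smn_backextrapolate(cm, fit_range=(5, 8))
        assert back.p_back == pytest.approx(3.0)
        assert back.slope_per_ap == pytest.approx(3.0)

    def test_full_pool_release_limit(self):
        # per-site limiting pattern: the whole RRP of 2 goes out in two APs
        row = [1, 1, 0, 0, 0, 0, 0, 0]
        back = dk.smn_backextrapolate(_as_cm(np.tile(row, (3, 1))), fit_range=(5, 8))
        assert back.p_back == pytest.approx(2.0)
        assert back.slope_per_ap == pytest.approx(0.0)

    def test_short_fit_range_rejected(self):
        cm = _as_cm(np.tile([1] * 8, (3, 1)))
        with pytest.raises(dk.DataError):
            dk.smn_backextrapolate(cm, fit_range=(8, 8))

    def test_underestimates_rrp_with_incomplete_depression(self, control_params):
        params = dk.ModelParams(n_sites=1, delta=0.65)
        cm = dk.simulate_trains(params, protocol(n_trains=20_000, seed=31))
        back = dk.smn_backextrapolate(cm, fit_range=(5, 8))
        # true pool per site is rho + delta = 1.65; nonzero steady-state release biases low
        assert back.p_back < 1.65


class TestDepressionMetrics:
    def test_tau_interval_to_ms_conversion(self):
        m = 2.0 * np.exp(-(np.arange(8) - 2) / 1.66)
        m[:2] = [2.0, 1.9]
        stats = dk.StimulusStats(
            mean_si=m, var_si=np.ones(8), cum_Si=np.cumsum(m), n_trains=50,
            protocol=dk.TrainProtocol(n_stim=8, freq_hz=200.0, n_trains=50),
        )
        dep = dk.depression_metrics(stats)
        assert dep.decay_tau_intervals == pytest.approx(1.66, rel=1e-3)
        assert dep.decay_tau_ms == pytest.approx(8.3, rel=1e-3)

    def test_exact_exponential_tail(self):
        m = np.concatenate(([3.0, 2.5], 2.0 * np.exp(-np.arange(6) / 1.0)))
        stats = dk.StimulusStats(
            mean_si=m, var_si=np.ones(8), cum_Si=np.cumsum(m), n_trains=50,
            protocol=dk.TrainProtocol(n_stim=8, freq_hz=100.0, n_trains=50),
        )
        dep = dk.depression_metrics(stats)
        assert dep.decay_tau_intervals == pytest.approx(1.0, rel=1e-6)
        assert dep.ppr == pytest.approx(2.5 / 3.0)

    def test_constant_train_flags_infinite_tau(self):
        m = np.full(8, 2.0)
        stats = dk.StimulusStats(
            mean_si=m, var_si=np.ones(8), cum_Si=np.cumsum(m), n_trains=50,
            protocol=dk.TrainProtocol(n_stim=8, freq_hz=100.0, n_trains=50),
        )
        dep = dk.depression_metrics(stats)
        assert dep.depression_ratio == pytest.approx(1.0)
        assert math.isinf(dep.decay_tau_intervals)
        assert dep.flagged

    def test_zero_first_response_flagged(self):
        m = np.array([0.0, 1.0, 0.5, 0.2])
        stats = dk.StimulusStats(
            mean_si=m, var_si=np.ones(4), cum_Si=np.cumsum(m), n_trains=50,
            protocol=dk.TrainProtocol(n_stim=4, freq_hz=100.0, n_trains=50),
        )
        dep = dk.depression_metrics(stats)
        assert math.isnan(dep.ppr)
        assert dep.flagged


class TestSyncAsyncClassification:
    def test_window_rule(self):
        import pandas as pd

        events = pd.DataFrame(
            {"train": [0, 0], "stimulus": [1, 1], "latency_ms": [0.5, 7.0], "pathway": "fast"}
        )
        raster = dk.EventRaster(events=events, protocol=protocol(n_trains=1))
        tagged = dk.classify_sync_async(raster, window_ms=5.0)
        assert tagged.events["synchronous"].tolist() == [True, False]

    def test_negative_latency_rejected(self):
        import pandas as pd

        events = pd.DataFrame(
            {"train": [0], "stimulus": [1], "latency_ms": [-0.1], "pathway": "fast"}
        )
        raster = dk.EventRaster(events=events, protocol=protocol(n_trains=1))
        with pytest.raises(dk.DataError):
            dk.classify_sync_async(raster)

    def test_mixture_async_fraction_matches_tail_mass(self):
        # constant 30% slow pathway; async fraction = mixture mass beyond 5 ms
        params = dk.ModelParams(n_sites=4, delta=0.8, p_r=0.9)
        proto = protocol(n_trains=4000, seed=17)
        latency = dk.LatencyModel(slow_fraction_by_stimulus={i: 0.3 for i in range(1, 9)})
        _, raster = dk.generate_condition_dataset(params, proto, latency=latency)
        tagged = dk.classify_sync_async(raster, window_ms=5.0)
        async_frac = 1.0 - tagged.events["synchronous"].mean()

        def trunc_tail(tau, w=5.0, L=10.0):
            return (math.exp(-w / tau) - math.exp(-L / tau)) / (1 - math.exp(-L / tau))

        expected = 0.3 * trunc_tail(4.0) + 0.7 * trunc_tail(0.47)
        n = len(tagged.events)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(async_frac - expected) < 4 * se


class TestLatencyFit:
    def test_pure_exponential(self):
        rng = np.random.default_rng(5)
        lat = rng.exponential(0.47, size=5000)
        fit = dk.fit_latency_biexp(lat)
        assert fit.tau_fast_ms == pytest.approx(0.47, rel=0.1)
        assert fit.slow_fraction < 0.15 or fit.degenerate

    def test_mixture_recovery(self):
        rng = np.random.default_rng(6)
        n = 10_000
        slow = rng.random(n) < 0.5
        lat = np.where(slow, rng.exponential(4.0, n), rng.exponential(0.47, n))
        fit = dk.fit_latency_biexp(lat)
        assert fit.tau_fast_ms == pytest.approx(0.47, rel=0.1)
        assert fit.tau_slow_ms == pytest.approx(4.0, rel=0.1)
        assert fit.slow_fraction == pytest.approx(0.5, abs=0.05)
        assert not fit.degenerate

    def test_empty_and_small_inputs_rejected(self):
        with pytest.raises(dk.DataError):
            dk.fit_latency_biexp(np.array([]))
        with pytest.raises(dk.DataError):
            dk.fit_latency_biexp(np.ones(10))


class TestReplenishmentArithmetic:
    def test_two_step_ratio_window_limits(self):
        assert dk.two_step_ratio(0.2, window_ms=0.0, tau_ms=4.0) == 0.0
        assert dk.two_step_ratio(0.2, window_ms=1e6, tau_ms=4.0) == pytest.approx(0.2)
        with pytest.raises(dk.ParameterError):
            dk.two_step_ratio(0.2, tau_ms=0.0)

    def test_printed_chain(self):
        ratio = dk.two_step_ratio(0.2, 5.0, 4.0)
        assert round(ratio, 2) == 0.14
        b = dk.ReplenishmentBreakdown(rho2_total=0.460, rho2_replenishment=0.097)
        share, percent = dk.replenishment_contribution(b, P1=0.88, P2=0.67)
        assert round(share, 2) == 0.03
        assert round(percent, 1) == 1.3

    def test_zero_replenishment(self):
        b = dk.ReplenishmentBreakdown(rho2_total=0.5, rho2_replenishment=0.0)
        share, percent = dk.replenishment_contribution(b, P1=0.5, P2=0.5)
        assert share == 0.0 and percent == 0.0

    def test_zero_total_occupancy_rejected(self):
        b = dk.ReplenishmentBreakdown(rho2_total=0.0, rho2_replenishment=0.0)
        with pytest.raises(dk.ParameterError):
            dk.replenishment_contribution(b, P1=0.5, P2=0.5)


class TestNEstimateInvariance:
    def test_estimate_invariant_across_release_regimes(self):
        # same synapse under control-like and potentiated parameters
        hits = []
        for name in ("control", "4ap", "ptp"):
            params = dk.ModelParams(n_sites=4, **{
                "control": dict(delta=0.65, p_r=0.6),
                "4ap": dict(delta=0.8, p_r=0.9),
                "ptp": dict(delta=0.9, p_r=0.9),
            }[name])
            cm = dk.simulate_trains(params, protocol(n_trains=5000, seed=77))
            est = dk.fit_variance_mean(dk.summarize(cm))
            hits.append(est.n_int)
        assert hits == [4, 4, 4]
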