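"""Significance machinery: thresholded integrals, permutation envelopes,
latency rules, contextual modulation."""

import itertools

import numpy as np
import pytest

from amsurround.preprocess import ResponseWaveform, build_pstw
from amsurround.stats import (
    contextual_modulation,
    onset_latency,
    peak_ratio,
    permutation_envelope,
    screen_responsive,
    significant_runs,
    ztest_threshold_integral,
)
from amsurround.synth import ou_noise


def _wf(tb, mean, n=4):
    mean = np.asarray(mean, float)
    return ResponseWaveform(tb, mean, np.zeros_like(mean), n)


class TestZtestIntegral:
    tb = np.arange(-100.0, 251.0)

    def test_flat_trace_has_zero_integral(self):
        rng = np.random.default_rng(0)
        wf = _wf(self.tb, rng.normal(0, 1e-9, len(self.tb)))
        assert ztest_threshold_integral(wf) == pytest.approx(0.0, abs=1e-6)

    def test_rectangle_2mv_100ms_above_bound(self):
        # noiseless baseline -> bound ~ 0; rectangle 2 mV x 100 ms = 200 mV*ms
        rng = np.random.default_rng(1)
        mean = rng.normal(0, 1e-6, len(self.tb))
        mean[(self.tb >= 50) & (self.tb < 150)] += 2.0
        assert ztest_threshold_integral(_wf(self.tb, mean)) == pytest.approx(200.0, rel=0.01)

    def test_window_outside_trace_rejected(self):
        wf = _wf(np.arange(0.0, 100.0), np.zeros(100))
        with pytest.raises(ValueError):
            ztest_threshold_integral(wf, baseline_window=(0, 50), window=(0, 500))

    def test_translation_equivariance(self):
        """Baseline is re-estimated, so adding a constant leaves the
        thresholded integral unchanged."""
        rng = np.random.default_rng(2)
        mean = rng.normal(0, 0.3, len(self.tb))
        mean[(self.tb >= 20) & (self.tb < 80)] += 3.0
        a = ztest_threshold_integral(_wf(self.tb, mean))
        b = ztest_threshold_integral(_wf(self.tb, mean + 11.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_noise_only_positive_in_about_5_percent(self):
        """Monte-Carlo calibration of the one-sided 95% baseline bound: on
        white-noise waveforms the integral is positive whenever any sample
        clears the bound; the *pointwise* exceedance rate is ~5%."""
        rng = np.random.default_rng(3)
        hits = 0
        n_runs, n_pts = 400, 351
        for _ in range(n_runs):
            mean = rng.normal(0, 1.0, n_pts)
            base = mean[self.tb < 0]
            bound = base.mean() + 1.645 * base.std(ddof=1)
            hits += int(mean[self.tb >= 0][100] > bound)
        assert 0.02 < hits / n_runs < 0.08


class TestPermutationEnvelope:
    def test_exhaustive_3v3_matches_enumeration(self):
        """Oracle: with 3 vs 3 trials the null distribution is the full set
        of C(6,3)=20 label assignments, enumerated independently here."""
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(3, 30)), rng.normal(size=(3, 30))
        tb = np.arange(30.0)
        env = permutation_envelope(A, B, tb, n_permutations=100, alpha=0.2)
        assert env.n_permutations == 20
        pooled = np.vstack([A, B])
        null = []
        for idx in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in idx]
            null.append(pooled[list(idx)].mean(axis=0) - pooled[rest].mean(axis=0))
        null = np.array(null)
        assert np.allclose(env.upper, np.quantile(null, 0.8, axis=0, method="higher"))
        assert np.allclose(env.lower, np.quantile(null, 0.2, axis=0, method="lower"))

    def test_strong_offset_yields_long_significant_run(self):
        rng = np.random.default_rng(1)
        tb = np.arange(200.0)
        B = rng.normal(0, 1.0, size=(10, 200))
        A = rng.normal(0, 1.0, size=(10, 200))
        A[:, 100:150] += 5.0  # +5 sigma for 50 ms
        env = permutation_envelope(A, B, tb, n_permutations=500, alpha=0.05,
                                   min_consecutive_ms=5.0, seed=0)
        assert env.mask[100:150].sum() >= 45

    def test_relabel_invariance(self):
        """Swapping the roles of the pools mirrors the envelope."""
        rng = np.random.default_rng(2)
        A, B = rng.normal(size=(5, 40)), rng.normal(size=(5, 40))
        tb = np.arange(40.0)
        e1 = permutation_envelope(A, B, tb, n_permutations=300, alpha=0.1, seed=3)
        e2 = permutation_envelope(B, A, tb, n_permutations=300, alpha=0.1, seed=3)
        assert np.allclose(e1.observed, -e2.observed)

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            permutation_envelope(
                rng.normal(size=(4, 10)), rng.normal(size=(4, 10)),
                np.arange(10.0), n_permutations=10, alpha=0.05,
            )

    def test_pointwise_type_one_error_calibrated(self):
        """Null OU trials in both pools: pointwise exceedance of the upper
        bound occurs at ~alpha (binomial CI over Monte-Carlo runs)."""
        hits, runs = 0, 200
        for r in range(runs):
            g = np.random.default_rng([11, r])
            A = np.vstack([ou_noise(120, 1.0, 1.0, 15.0, g) for _ in range(8)])
            B = np.vstack([ou_noise(120, 1.0, 1.0, 15.0, g) for _ in range(8)])
            env = permutation_envelope(A, B, np.arange(120.0),
                                       n_permutations=400, alpha=0.05, seed=r)
            hits += int(env.observed[60] > env.upper[60])
        # exact binomial 95% CI at p=0.05, n=200: (0.024, 0.090)
        assert 0.015 <= hits / runs <= 0.10

    def test_min_consecutive_filter(self):
        mask = np.array([1, 1, 0, 1, 1, 1, 1, 0, 1], dtype=bool)
        out = significant_runs(mask, 3)
        assert list(out.astype(int)) == [0, 0, 0, 1, 1, 1, 1, 0, 0]


class TestScreenResponsive:
    tb = np.arange(-50.0, 200.0)

    def _trials(self, seed, amp=0.0):
        g = np.random.default_rng(seed)
        X = np.vstack([ou_noise(len(self.tb), 1.0, 1.0, 15.0, g) for _ in range(12)])
        X[:, (self.tb >= 30) & (self.tb <= 90)] += amp
        return X

    def test_strong_response_detected(self):
        assert screen_responsive(
            self._trials(0, amp=4.0), self._trials(1), self.tb, seed=0
        )

    def test_noise_only_rarely_passes(self):
        hits = sum(
            screen_responsive(self._trials(2 * r), self._trials(2 * r + 1), self.tb,
                              n_permutations=300, seed=r)
            for r in range(40)
        )
        # pointwise p<0.01 with a 1 ms duration criterion over 120 correlated
        # samples: familywise rate is inflated but must stay far below chance
        assert hits <= 10

    def test_detection_rate_monotone_in_amplitude(self):
        rates = []
        for amp in (0.0, 0.6, 3.0):
            hits = sum(
                screen_responsive(self._trials(100 + 2 * r, amp=amp),
                                  self._trials(101 + 2 * r), self.tb,
                                  n_permutations=300, seed=r)
                for r in range(15)
            )
            rates.append(hits)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] == 15


class TestOnsetLatency:
    def test_half_height_of_linear_ramp(self):
        tb = np.arange(0.0, 21.0)
        ramp = np.clip(tb / 10.0, 0, 1)  # 0 -> 1 mV over 0-10 ms
        wf = _wf(tb, ramp)
        assert onset_latency(wf, "half_height", reference_peak=1.0) == pytest.approx(5.0)

    def test_three_sigma_crossing(self):
        tb = np.arange(0.0, 30.0)
        y = np.where(tb >= 12, 3.5, 0.0)
        wf = _wf(tb, y)
        lat = onset_latency(wf, "three_sigma", blank_mean=0.0, blank_sigma=1.0)
        assert 11.0 <= lat <= 12.0

    def test_no_crossing_returns_nan(self):
        tb = np.arange(0.0, 30.0)
        wf = _wf(tb, np.zeros_like(tb))
        assert np.isnan(onset_latency(wf, "three_sigma", blank_mean=0.0, blank_sigma=1.0))

    def test_pre_stimulus_blip_ignored(self):
        """The onset anchors to the excursion containing the peak."""
        tb = np.arange(0.0, 100.0)
        y = np.zeros_like(tb)
        y[5:8] = 3.2  # brief noise blip
        y[50:90] = 6.0  # the response
        wf = _wf(tb, y)
        lat = onset_latency(wf, "three_sigma", blank_mean=0.0, blank_sigma=1.0)
        assert 49.0 <= lat <= 50.0


class TestContextualModulation:
    tb = np.arange(-100.0, 251.0)

    def _pulse_trials(self, onset, amp, n=10, seed=0, sigma=0.3):
        g = np.random.default_rng(seed)
        X = g.normal(0, sigma, size=(n, len(self.tb)))
        rise = np.clip((self.tb - onset) / 20.0, 0, 1) * np.exp(
            -np.clip(self.tb - onset, 0, None) / 80.0
        )
        return X + amp * rise

    def test_identity_gives_zero_delta_and_unit_ratio(self):
        C = self._pulse_trials(20.0, 5.0, seed=1)
        T = self._pulse_trials(20.0, 5.0, seed=2)
        mod = contextual_modulation(T, C, self.tb, n_permutations=300, seed=0)
        assert mod.delta_latency == pytest.approx(0.0, abs=2.0)
        assert mod.delta_integral_ratio == pytest.approx(1.0, rel=0.15)

    def test_advanced_and_amplified_response_detected(self):
        C = self._pulse_trials(30.0, 5.0, seed=3)
        T = self._pulse_trials(18.0, 7.0, seed=4)
        mod = contextual_modulation(T, C, self.tb, n_permutations=500, seed=0)
        assert mod.delta_latency > 5.0
        assert mod.delta_integral_ratio > 1.2
        assert mod.significant_latency and mod.significant_integral

    def test_delta_latency_antisymmetric_for_identical_shapes(self):
        C = self._pulse_trials(30.0, 5.0, seed=5, sigma=1e-9)
        T = self._pulse_trials(20.0, 5.0, seed=6, sigma=1e-9)
        m1 = contextual_modulation(T, C, self.tb, n_permutations=300, seed=0)
        m2 = contextual_modulation(C, T, self.tb, n_permutations=300, seed=0)
        assert m1.delta_latency == pytest.approx(-m2.delta_latency, abs=1e-6)


def test_peak_ratio_from_printed_amplitudes():
    """The worked-example peak ratios are pure amplitude ratios."""
    tb = np.arange(0.0, 100.0)
    bump = np.exp(-0.5 * ((tb - 50) / 10.0) ** 2)
    surround = _wf(tb, 4.4 * bump)
    center = _wf(tb, 7.4 * bump)
    assert 100 * peak_ratio(surround, center) == pytest.approx(59.0, abs=0.5)
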