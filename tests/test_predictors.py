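"""Surround linear predictor, center-subtraction predictor, non-linearity test."""

import numpy as np
import pytest

from amsurround.preprocess import ResponseWaveform, condition_trace
from amsurround.predictors import (
    center_subtraction_predictor,
    nonlinearity_test,
    slp_trial_ensemble,
    surround_linear_predictor,
)
from amsurround.synth import GeneratorParams, ou_noise, simulate_trial


def _wf(tb, mean):
    mean = np.asarray(mean, float)
    return ResponseWaveform(np.asarray(tb, float), mean, np.zeros_like(mean), 4)


class TestSurroundLinearPredictor:
    def test_zero_components_give_zero_slp(self, radial_protocol):
        chrono = radial_protocol.entries("CP-ISO", "surround_only")[0]
        tb = np.arange(-150.0, 300.0)
        iso = {f"D{k}": _wf(tb, np.zeros_like(tb)) for k in range(1, 6)}
        slp = surround_linear_predictor(iso, chrono, tb)
        assert np.allclose(slp.value, 0.0)

    def test_two_pulses_match_brute_force_shift(self, radial_protocol):
        """Oracle: direct shifted addition of unit pulses."""
        chrono = radial_protocol.entries("CP-ISO", "surround_only")[0]
        tb = np.arange(-200.0, 300.0)
        iso = {}
        for k in range(1, 6):
            y = np.zeros_like(tb)
            y[(tb >= 40 + k) & (tb < 50 + k)] = 1.0  # pulse at its own delay
            iso[f"D{k}"] = _wf(tb, y)
        slp = surround_linear_predictor(iso, chrono, tb)
        expected = np.zeros_like(tb)
        for onset, group in chrono.stroke_groups():
            k = int(group[0].node_label[1])
            shift = onset - chrono.expected_center_onset_ms
            src = iso[f"D{k}"].mean
            expected += np.interp(tb - shift, tb, src, left=0, right=0)
        assert np.allclose(slp.value, expected)

    def test_linearity_in_component_scaling(self, radial_protocol):
        chrono = radial_protocol.entries("CP-ISO", "surround_only")[0]
        tb = np.arange(-150.0, 300.0)
        rng = np.random.default_rng(0)
        iso = {f"D{k}": _wf(tb, rng.normal(size=len(tb))) for k in range(1, 6)}
        slp1 = surround_linear_predictor(iso, chrono, tb)
        iso3 = {k: _wf(tb, 3.0 * w.mean) for k, w in iso.items()}
        slp3 = surround_linear_predictor(iso3, chrono, tb)
        assert np.allclose(slp3.value, 3.0 * slp1.value)

    def test_missing_node_reported(self, radial_protocol):
        chrono = radial_protocol.entries("CP-ISO", "surround_only")[0]
        tb = np.arange(-150.0, 300.0)
        iso = {f"D{k}": _wf(tb, np.zeros_like(tb)) for k in (1, 2, 3)}
        with pytest.raises(KeyError, match="D4"):
            surround_linear_predictor(iso, chrono, tb)

    def test_matches_additive_generator_surround_only(self, rf, quiet_params, radial_protocol):
        """Generator ground truth: with interaction_gain = 0 the SLP equals
        the simulated Surround-Only response pointwise (noise-free)."""
        chrono = radial_protocol.entries("CP-ISO", "surround_only")[0]
        dur = 900.0
        rec = simulate_trial(chrono, rf, quiet_params, seed=0, duration_ms=dur)
        y_obs = condition_trace(rec.vm, 10000) - quiet_params.v_rest
        tb = np.arange(len(y_obs)) - rec.expected_center_onset_ms
        iso = {}
        for ring in range(1, 6):
            lab = f"ISOLATED-ISO-D{ring}|SECTOR"
            entry = [e for e in radial_protocol.condition_set if e.label == lab][0]
            r = simulate_trial(entry, rf, quiet_params, seed=0, duration_ms=dur)
            y = condition_trace(r.vm, 10000) - quiet_params.v_rest
            tbi = np.arange(len(y)) - r.expected_center_onset_ms
            stroke_rel = entry.events[0].onset_time - entry.expected_center_onset_ms
            iso[f"D{ring}"] = _wf(tbi - stroke_rel, y)
        slp = surround_linear_predictor(iso, chrono, tb)
        m = (tb >= -150) & (tb <= 250)
        assert np.max(np.abs(slp.value[m] - y_obs[m])) < 0.02


class TestCenterSubtraction:
    def test_identical_waveforms_give_zero(self):
        tb = np.arange(100.0)
        wf = _wf(tb, np.sin(tb / 10))
        assert np.allclose(center_subtraction_predictor(wf, wf).value, 0.0)

    def test_recovers_surround_component_in_additive_generator(
        self, rf, quiet_params, radial_protocol
    ):
        full = radial_protocol.entries("CP-ISO", "full")[0]
        so = radial_protocol.entries("CP-ISO", "surround_only")[0]
        co = radial_protocol.entries("CENTER_ONLY")[0]
        dur = 900.0
        common = np.arange(-150.0, 300.0)
        waves = {}
        for name, e in (("full", full), ("so", so), ("co", co)):
            r = simulate_trial(e, rf, quiet_params, seed=0, duration_ms=dur)
            y = condition_trace(r.vm, 10000) - quiet_params.v_rest
            tb = np.arange(len(y)) - r.expected_center_onset_ms
            waves[name] = _wf(common, np.interp(common, tb, y))
        pred = center_subtraction_predictor(waves["full"], waves["co"])
        assert np.max(np.abs(pred.value - waves["so"].mean)) < 0.02

    def test_gated_generator_exceeds_additive_prediction(self, rf, radial_protocol):
        """With the supra-linear gate on, the full-sequence response exceeds
        Center-Only + Surround-Only, so the center-subtraction predictor
        exceeds the simulated Surround-Only component."""
        p = GeneratorParams(
            noise_sigma=1e-12, spike_amplitude=0.0, spike_threshold=1e9,
            interaction_gain=1.5,
        )
        full = radial_protocol.entries("CP-ISO", "full")[0]
        so = radial_protocol.entries("CP-ISO", "surround_only")[0]
        co = radial_protocol.entries("CENTER_ONLY")[0]
        dur = 900.0
        common = np.arange(-150.0, 300.0)
        waves = {}
        for name, e in (("full", full), ("so", so), ("co", co)):
            r = simulate_trial(e, rf, p, seed=0, duration_ms=dur)
            y = condition_trace(r.vm, 10000) - p.v_rest
            tb = np.arange(len(y)) - r.expected_center_onset_ms
            waves[name] = _wf(common, np.interp(common, tb, y))
        pred = center_subtraction_predictor(waves["full"], waves["co"])
        m = (common >= -20) & (common <= 100)  # window of FF/lateral interaction
        assert np.max(pred.value[m] - waves["so"].mean[m]) > 0.5

    def test_time_base_mismatch_rejected(self):
        tb = np.arange(100.0)
        with pytest.raises(ValueError):
            center_subtraction_predictor(_wf(tb, tb), _wf(tb + 1.0, tb))


class TestNonlinearityTest:
    tb = np.arange(-50.0, 200.0)

    def _ou_trials(self, seed, n=12):
        g = np.random.default_rng(seed)
        return np.vstack([ou_noise(len(self.tb), 1.0, 0.8, 15.0, g) for _ in range(n)])

    def test_strong_excess_detected(self):
        obs = self._ou_trials(0)
        obs[:, (self.tb >= 20) & (self.tb <= 60)] += 4.0  # 5 sigma for 40 ms
        slp = self._ou_trials(1)
        v = nonlinearity_test(obs, slp, self.tb, n_permutations=500, seed=0)
        assert v.significant
        assert v.excess_ms >= 25.0

    def test_null_calibration(self):
        hits = 0
        runs = 40
        for r in range(runs):
            v = nonlinearity_test(
                self._ou_trials(10 + 2 * r), self._ou_trials(11 + 2 * r),
                self.tb, n_permutations=300, seed=r,
            )
            hits += int(v.significant)
        # 7 ms duration criterion keeps the false-positive rate near alpha
        assert hits <= 8

    def test_detection_rate_rises_with_interaction_gain(self, rf, radial_protocol):
        """Generator sweep: supra-linearity detection rate is monotone in
        interaction_gain."""
        chrono = radial_protocol.entries("CP-ISO", "surround_only")[0]
        iso_entries = {
            f"D{k}": [e for e in radial_protocol.condition_set
                      if e.label == f"ISOLATED-ISO-D{k}|SECTOR"][0]
            for k in range(1, 6)
        }
        dur, n_trials = 700.0, 12
        rates = []
        for gain in (0.0, 1.0, 3.0):
            p = GeneratorParams(
                noise_sigma=1.0, spike_amplitude=0.0, spike_threshold=1e9,
                interaction_gain=gain,
            )
            hits = 0
            runs = 6
            for run in range(runs):
                obs, comp = [], {f"D{k}": [] for k in range(1, 6)}
                tb = None
                for j in range(n_trials):
                    r = simulate_trial(chrono, rf, p, seed=[run, j], duration_ms=dur)
                    y = condition_trace(r.vm, 10000) - p.v_rest
                    tb = np.arange(len(y)) - r.expected_center_onset_ms
                    obs.append(y)
                    for k in range(1, 6):
                        e = iso_entries[f"D{k}"]
                        ri = simulate_trial(e, rf, p, seed=[run, j, k], duration_ms=dur)
                        yi = condition_trace(ri.vm, 10000) - p.v_rest
                        tbi = np.arange(len(yi)) - ri.expected_center_onset_ms
                        stroke_rel = e.events[0].onset_time - e.expected_center_onset_ms
                        comp[f"D{k}"].append(np.interp(tb, tbi - stroke_rel, yi, left=0, right=0))
                slp = slp_trial_ensemble(
                    {k: np.vstack(v) for k, v in comp.items()}, tb, chrono, tb, seed=run
                )
                v = nonlinearity_test(np.vstack(obs), slp, tb,
                                      n_permutations=400, seed=run)
                hits += int(v.significant)
            rates.append(hits / runs)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.8
        assert rates[0] <= 0.35
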