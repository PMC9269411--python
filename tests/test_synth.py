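"""Generator correctness: kernels, additivity, noise statistics, datasets."""

import numpy as np
import pytest

from amsurround.stimuli import build_radial_protocol, scale_speed, sequence_speed
from amsurround.synth import (
    GeneratorParams,
    generate_dataset,
    lateral_kernel,
    ou_noise,
    psp_kernel,
    simulate_trial,
)

from conftest import make_isolated_entry


class TestLateralKernel:
    def test_latency_is_linear_in_eccentricity(self):
        # base 30 ms + 4 deg * 1 mm/deg / 0.2 mm/ms = 50 ms
        p = GeneratorParams(base_latency=30.0, magnification=1.0, ashp_true=0.2)
        lat, _ = lateral_kernel(4.0, p)
        assert lat == pytest.approx(50.0)

    def test_amplitude_decays_by_e_at_space_constant(self):
        p = GeneratorParams(a0=4.0, lambda_decay=6.0)
        _, amp = lateral_kernel(6.0, p)
        assert amp == pytest.approx(4.0 / np.e)

    def test_latencies_recover_slope_exactly(self):
        """Closed-form oracle: noise-free latencies at 4 eccentricities fit a
        line of slope M/ashp exactly."""
        from amsurround.propagation import fit_latency_basin

        p = GeneratorParams(base_latency=35.0, magnification=1.0, ashp_true=0.25)
        pts = [(e, lateral_kernel(e, p)[0]) for e in (0.0, 2.0, 4.0, 6.0)]
        fit = fit_latency_basin(pts, magnification=p.magnification)
        assert fit.ashp == pytest.approx(0.25, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_rejects_negative_eccentricity(self):
        with pytest.raises(ValueError):
            lateral_kernel(-1.0, GeneratorParams())


class TestSimulateTrial:
    def test_blank_noise_free_is_flat_resting(self, rf, quiet_params, blank_entry):
        rec = simulate_trial(blank_entry, rf, quiet_params, seed=0, duration_ms=400)
        assert np.allclose(rec.vm, quiet_params.v_rest, atol=1e-9)
        assert rec.spike_times.size == 0

    def test_center_only_single_psp_at_base_latency(self, rf, quiet_params, radial_protocol):
        co = radial_protocol.entries("CENTER_ONLY")[0]
        rec = simulate_trial(co, rf, quiet_params, seed=0)
        dep = rec.vm - quiet_params.v_rest
        t = rec.time_ms
        onset = rec.stim_offset_ms + quiet_params.base_latency
        assert np.allclose(dep[t <= onset], 0.0, atol=1e-9)
        assert dep.max() == pytest.approx(
            quiet_params.ff_amplitude * co.events[0].gabor.contrast, rel=1e-3
        )

    def test_cp_iso_at_matched_speed_synchronizes_all_inputs(self, rf, quiet_params):
        """At AM speed = ashp * 1000 / M deg/s every lateral onset coincides
        with the feedforward onset and the peak equals the sum of the
        individual peaks (direct summation oracle of shifted kernels)."""
        proto = build_radial_protocol(rf)
        cp = proto.entries("CP-ISO", "full")[0]
        v = sequence_speed(cp)  # deg/s
        p = GeneratorParams(
            noise_sigma=1e-12, spike_amplitude=0.0, spike_threshold=1e9,
            ashp_true=v * 1.0 / 1000.0,
        )
        rec = simulate_trial(cp, rf, p, seed=0)
        dep = rec.vm - p.v_rest
        # oracle: sum of individually simulated strokes
        total_peak_expected = 0.0
        for onset, group in cp.stroke_groups():
            center = [e for e in group if e.node_label == "D0"]
            if center:
                total_peak_expected += p.ff_amplitude * center[0].gabor.contrast
            lateral = [e for e in group if e.node_label != "D0"]
            if lateral:
                ecc = np.mean([e.eccentricity for e in lateral])
                total_peak_expected += lateral_kernel(ecc, p)[1] * lateral[0].gabor.contrast
        assert dep.max() == pytest.approx(total_peak_expected, rel=1e-4)

    def test_linearity_switch(self, rf, quiet_params, radial_protocol):
        """With interaction_gain = 0 the Surround-Only response equals the
        pointwise sum of isolated-GP responses (noise-free)."""
        so = radial_protocol.entries("CP-ISO", "surround_only")[0]
        dur = 900.0
        rec = simulate_trial(so, rf, quiet_params, seed=0, duration_ms=dur)
        total = np.zeros_like(rec.vm)
        for ring in range(1, 6):
            lab = f"ISOLATED-ISO-D{ring}|SECTOR"
            entry = [e for e in radial_protocol.condition_set if e.label == lab][0]
            # place the isolated stroke at its chronogram onset
            chrono_onset = [t for t, g in so.stroke_groups() if g[0].node_label == f"D{ring}"][0]
            from dataclasses import replace

            shifted = replace(
                entry,
                events=tuple(replace(e, onset_time=chrono_onset) for e in entry.events),
            )
            r = simulate_trial(shifted, rf, quiet_params, seed=0, duration_ms=dur)
            total += r.vm - quiet_params.v_rest
        assert np.allclose(rec.vm - quiet_params.v_rest, total, atol=1e-9)

    def test_cf_iso_leaves_ff_onset_unchanged(self, rf, quiet_params, radial_protocol):
        """In the additive noise-free model every CF lateral onset follows the
        feedforward onset, so the early rising phase matches Center-Only."""
        cf = radial_protocol.entries("CF-ISO", "full")[0]
        co = radial_protocol.entries("CENTER_ONLY")[0]
        dur = 1200.0
        r_cf = simulate_trial(cf, rf, quiet_params, seed=0, duration_ms=dur)
        r_co = simulate_trial(co, rf, quiet_params, seed=0, duration_ms=dur)
        t = r_cf.time_ms
        # identical up to the earliest lateral onset
        first_lateral = min(
            onset + lateral_kernel(np.mean([e.eccentricity for e in g]), quiet_params)[0]
            for onset, g in cf.stroke_groups()
            if g[0].node_label != "D0"
        )
        m = t <= r_cf.stim_offset_ms + first_lateral
        assert np.allclose(r_cf.vm[m], r_co.vm[m], atol=1e-9)

    def test_speed_tuning_ordering(self, rf, quiet_params, radial_protocol):
        """Peak contextual depolarization is strictly ordered
        100% > 70% > 50% > 30% of the matched speed (additive generator)."""
        cp = radial_protocol.entries("CP-ISO", "full")[0]
        co = radial_protocol.entries("CENTER_ONLY")[0]
        v = sequence_speed(cp)
        p = GeneratorParams(
            noise_sigma=1e-12, spike_amplitude=0.0, spike_threshold=1e9,
            ashp_true=v / 1000.0,
        )
        dur = 1600.0
        rc = simulate_trial(co, rf, p, seed=0, duration_ms=dur)
        peaks = []
        for f in (1.0, 0.7, 0.5, 0.3):
            seq = scale_speed(cp, f)
            r = simulate_trial(seq, rf, p, seed=0, duration_ms=dur)
            # align on the expected center onset before contrasting
            shift = int(round(r.expected_center_onset_ms - rc.expected_center_onset_ms) * 10)
            ctx = (r.vm[shift:] - rc.vm[: len(r.vm) - shift]) if shift > 0 else r.vm - rc.vm
            peaks.append(ctx.max())
        assert peaks[0] > peaks[1] > peaks[2] > peaks[3]

    def test_deterministic_given_seed(self, rf, radial_protocol):
        cp = radial_protocol.entries("CP-ISO", "full")[0]
        p = GeneratorParams()
        a = simulate_trial(cp, rf, p, seed=42)
        b = simulate_trial(cp, rf, p, seed=42)
        assert np.array_equal(a.vm, b.vm)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_supralinear_gate_boosts_surround_only(self, rf, radial_protocol):
        so = radial_protocol.entries("CP-ISO", "surround_only")[0]
        base = dict(noise_sigma=1e-12, spike_amplitude=0.0, spike_threshold=1e9)
        peaks = []
        for gain in (0.0, 0.5, 1.0, 2.0):
            p = GeneratorParams(interaction_gain=gain, **base)
            r = simulate_trial(so, rf, p, seed=0, duration_ms=900)
            peaks.append(r.vm.max() - p.v_rest)
        assert np.all(np.diff(peaks) > 0)


class TestOUNoise:
    def test_variance_and_autocorrelation_time(self):
        rng = np.random.default_rng(7)
        sigma, tau, dt = 1.5, 20.0, 0.1
        x = ou_noise(1_000_000, dt, sigma, tau, rng)
        assert x.var() == pytest.approx(sigma**2, rel=0.1)
        lag = int(round(tau / dt))
        rho = np.corrcoef(x[:-lag], x[lag:])[0, 1]
        assert rho == pytest.approx(1.0 / np.e, rel=0.1)


class TestGenerateDataset:
    def test_counts_and_determinism(self, rf):
        proto = build_radial_protocol(rf)
        ds = generate_dataset(proto, n_cells=1, n_blocks=2, seed=5)
        assert len(ds.recordings) == 2 * proto.n_conditions
        ds2 = generate_dataset(proto, n_cells=1, n_blocks=2, seed=5)
        k = sorted(ds.recordings)[0]
        assert np.array_equal(ds.recordings[k].vm, ds2.recordings[k].vm)

    def test_priors_respected(self, rf):
        proto = build_radial_protocol(rf)
        ds = generate_dataset(
            proto, n_cells=5, n_blocks=1,
            param_priors={"ashp_true": (0.1, 0.3)}, seed=1,
        )
        for _, _, p in ds.cells:
            assert 0.1 <= p.ashp_true <= 0.3

    def test_every_cell_has_blanks(self, rf):
        proto = build_radial_protocol(rf)
        ds = generate_dataset(proto, n_cells=2, n_blocks=1, seed=0)
        for cid in ds.cell_ids():
            assert ds.trials(cid, lambda l: l.startswith("BLANK"))


def test_psp_kernel_unit_peak():
    t = np.linspace(0, 300, 30001)
    k = psp_kernel(t, 5.0, 30.0)
    assert k.max() == pytest.approx(1.0, abs=1e-6)
    assert np.all(k[t <= 0] == 0.0)
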