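# amsurround

Stimulus design and intracellular analysis for **dynamic center–surround
apparent-motion (AM) integration in primary visual cortex (V1)**.

## The scientific problem

A V1 neuron's receptive field (RF) has a spiking core (the minimal discharge
field, MDF), a broader subthreshold depolarizing field (SRF), and a "silent"
surround that influences the cell only through long-range horizontal
connectivity. Stimulating the surround with a sequence of collinear Gabor
patches sweeping centripetally toward the RF center (a CP-ISO apparent-motion
flow) can *synchronize* the lateral synaptic volleys with the feedforward
drive of the final center stroke — provided the flow speed matches the
propagation speed of horizontal axons. Under that condition the cell's
response to the center stimulus is facilitated: its onset latency shortens
and its depolarizing integral grows.

The quantitative skeleton is a pair of laws for the lateral ("horizontal")
input evoked by a surround stimulus at eccentricity *x* (degrees) from the RF
center:

- onset latency grows linearly: `L(x) = L0 + x·M / v`, where `M` is the
  retino-cortical magnification (mm/deg) and `v` the apparent speed of
  horizontal propagation (**ASHP**, mm/ms);
- peak amplitude decays exponentially: `A(x) = A0 · exp(−x/λ)`.

The inverse regression — fitting surround-response onset latency against
eccentricity (the "latency basin") and reading off `v = M / slope` — is how
the ASHP is inferred from recordings. A flow at visual speed `s` deg/s
corresponds to a cortical speed `s·M/1000` mm/ms, which is why facilitation
peaks at 150–250 deg/s when `v ≈ 0.15–0.25` mm/ms.

No recordings from this preparation are public, so the package ships a
**synthetic membrane-potential generator** that embodies this working model
(Ornstein–Uhlenbeck background noise, alpha-shaped PSPs obeying the two laws,
optional gated supra-linear interaction, threshold spiking). Every analysis
stage — spike removal and filtering, peristimulus averaging, permutation
significance envelopes, latency and gain measures, surround linear
predictors, latency-basin and bilinear phase regressions, population
averaging and speed tuning — can therefore be exercised and validated
end-to-end on data with known ground truth.

## What is in the package

| module | contents |
| --- | --- |
| `amsurround.stimuli` | cardinal (18/10-condition) and radial (43-entry) AM protocols, condition enumeration, geometry, speed scaling, seeded randomization, CSV event tables |
| `amsurround.synth` | `GeneratorParams`, `simulate_trial`, `generate_dataset` — trial-resolved Vm + spikes at 10 kHz |
| `amsurround.preprocess` | spike removal by alpha-function splicing, 0.1–300 Hz zero-phase conditioning to 1 kHz, PSTW/PSTH with SEM, blank subtraction |
| `amsurround.stats` | Z-thresholded response integrals, pointwise permutation envelopes with consecutive-duration criteria, responsiveness screening, onset latencies, contextual Δ-latency / Δ-integral |
| `amsurround.predictors` | surround linear predictor (shifted sum of isolated responses), center-subtraction predictor, supra-linearity test |
| `amsurround.propagation` | latency-basin OLS → `AshpFit.summary()`, input phase, two-connex-segment (`fit_bilinear`) regression, Gaussian KDE, speed unit conversions |
| `amsurround.population` | peak normalization, onset realignment, population averages, speed-tuning tables, overlay plots |
| `amsurround.io` / `pipeline` / `cli` | dataset container (npz + JSON), four-stage pipeline, `amsurround` command line (`simulate`, `preprocess`, `analyze`, `run`, `report`) |

## Worked example

Recover the generator's propagation speed from the latency basin of isolated
surround Gabors, then measure the contextual effect of a full CP-ISO flow
(20 trials per condition, moderate noise):

```python
import numpy as np
from amsurround import (
    GeneratorParams, RFGeometry, build_radial_protocol, fit_latency_basin,
)
from amsurround.preprocess import ResponseWaveform, build_pstw, condition_trace
from amsurround.stats import contextual_modulation, onset_latency
from amsurround.synth import simulate_condition

rf = RFGeometry(mdf_length=2.0, mdf_width=1.0, srf_extent=5.0)
protocol = build_radial_protocol(rf)        # 43 stimulation entries per block
params = GeneratorParams(                   # ground-truth propagation: 0.2 mm/ms
    ashp_true=0.2, a0=4.0, lambda_decay=20.0, noise_sigma=1.0,
)

def conditioned(entry, n, seed, window=(-150.0, 300.0)):
    """Simulate, condition to 1 kHz and realign on the expected center onset."""
    recs = simulate_condition(entry, rf, params, n, seed=seed, duration_ms=900)
    trials = np.vstack([condition_trace(r.vm, r.sampling_rate) for r in recs])
    tb = np.arange(trials.shape[1]) - recs[0].expected_center_onset_ms
    m = (tb >= window[0]) & (tb <= window[1])
    return tb[m], trials[:, m]

# ongoing activity from the interleaved blank trials
_, blanks = conditioned(protocol.entries("BLANK")[0], 20, seed=0)
rest_level = float(blanks.mean())
sigma_blank = float(np.std(blanks.mean(axis=0), ddof=1))

# 1) latency basin of the isolated surround Gabors -> propagation speed
points = []
for ring in (1, 2, 3, 4, 5):                # rings at 5..25 deg eccentricity
    entry = [e for e in protocol.condition_set
             if e.label == f"ISOLATED-ISO-D{ring}|SECTOR"][0]
    rel = entry.events[0].onset_time - entry.expected_center_onset_ms
    tb, trials = conditioned(entry, 20, seed=ring, window=(rel - 150, rel + 350))
    wf = build_pstw(trials - rest_level, tb - rel)   # rebase on the stroke onset
    wf = ResponseWaveform(wf.time_base, wf.mean - wf.crop((-150, 0)).mean.mean(),
                          wf.sem, wf.n_trials)
    lat = onset_latency(wf, "three_sigma", blank_mean=0.0,
                        blank_sigma=sigma_blank, window=(0, 350))
    points.append((entry.events[0].eccentricity, lat))
fit = fit_latency_basin(points, magnification=1.0)
print(fit.summary())

# 2) contextual modulation: CP-ISO apparent motion vs Center-Only
tb, cp = conditioned(protocol.entries("CP-ISO", "full")[0], 20, seed=10)
_,  co = conditioned(protocol.entries("CENTER_ONLY")[0], 20, seed=11)
mod = contextual_modulation(cp - rest_level, co - rest_level, tb,
                            n_permutations=1000, seed=0)
print(f"\nCP-ISO latency advance : {mod.delta_latency:+.1f} ms (p = {mod.p_latency:.3f})")
print(f"CP-ISO integral ratio  : {mod.delta_integral_ratio:.2f} (p = {mod.p_integral:.3f})")
```

Output:

```
Latency-basin regression (latency ~ eccentricity)
  n points          : 5
  slope             : 5.207 ms/deg (SE 0.0729)
  intercept         : 34.01 ms
  R^2               : 0.9994
  magnification     : 1 mm/deg
  ASHP              : 0.1921 mm/ms

CP-ISO latency advance : +14.5 ms (p = 0.001)
CP-ISO integral ratio  : 3.00 (p = 0.001)
```

The regression slope of 5.2 ms/deg recovers the generator's 0.2 mm/ms
propagation speed to within 4%, and the centripetal collinear flow — whose
nominal speed matches the horizontal propagation speed — both advances the
center response (half-height latency 14.5 ms earlier) and triples its
supra-threshold depolarizing integral, with permutation p-values at the
resolution floor of 1000 permutations.

The same analysis over a whole simulated dataset (3 cells × 20 blocks × 43
conditions) runs from the shell:

```bash
amsurround run --outdir demo_run --seed 7 --n-permutations 1000
```

which writes `results.csv` (per cell × condition Δ-latency, Δ-integral and
p-values), `ashp.csv`, `phases.csv`, population CSVs, an overlay figure and
a reproducibility manifest.

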