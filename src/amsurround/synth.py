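"""Synthetic intracellular recordings under the lateral-propagation hypothesis.

The generator embodies the working model of dynamic center-surround
integration: every surround Gabor stroke launches a horizontal (lateral)
synaptic volley whose postsynaptic onset latency grows *linearly* with the
stroke's eccentricity from the RF center, and whose amplitude decays
*exponentially* with that eccentricity; a stroke in the RF center (D0)
evokes a feedforward PSP at a fixed base latency. The membrane potential of
a trial is

    Vm(t) = v_rest + OU(t) + sum_k A_k * K(t - o_k)

where K is a two-exponential (alpha-like) PSP kernel with unit peak, o_k the
synaptic onset of PSP k, OU an Ornstein-Uhlenbeck background-noise process,
and A_k the PSP amplitude (contrast-scaled, eccentricity-attenuated for
lateral volleys). An optional gated supra-linear interaction multiplies each
PSP's amplitude by ``1 + interaction_gain * V_lat(o_k)/a0`` where V_lat is
the depolarization accumulated from lateral volleys that lead this PSP by
more than ``interaction_lag_threshold`` (default 5.5 ms); with
``interaction_gain = 0`` the model is exactly additive. Spikes are emitted
at upward threshold crossings with an absolute refractory period and a
stereotyped spike waveform is superimposed on the trace.

Everything is deterministic given a seed; traces are sampled at 10 kHz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .stimuli import AMSequence, ProtocolSpec, RFGeometry, randomize_sequence

__all__ = [
    "GeneratorParams",
    "TrialRecording",
    "Dataset",
    "lateral_kernel",
    "psp_kernel",
    "ou_noise",
    "simulate_trial",
    "simulate_condition",
    "generate_dataset",
    "trial_duration_for_protocol",
    "DEFAULT_STIM_OFFSET_MS",
]

#: silent pre-stimulus interval at the head of every simulated trial (ms)
DEFAULT_STIM_OFFSET_MS = 200.0


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one simulated cell.

    Units: latencies and time constants in ms, amplitudes in mV, eccentricity
    space constants in visual degrees, propagation speed in mm/ms,
    magnification in cortical mm per visual degree.
    """

    ashp_true: float = 0.2          # apparent horizontal propagation speed
    base_latency: float = 35.0      # feedforward onset latency at D0
    magnification: float = 1.0      # mm of cortex per degree
    a0: float = 3.5                 # lateral PSP peak at zero eccentricity
    lambda_decay: float = 10.0      # exponential space constant (deg)
    ff_amplitude: float = 18.0      # feedforward PSP peak per unit contrast
    psp_rise: float = 5.0
    psp_decay: float = 30.0
    v_rest: float = -67.0
    noise_sigma: float = 2.0
    noise_tau: float = 20.0
    spike_threshold: float = -57.0
    refractory: float = 3.0
    interaction_gain: float = 0.0
    interaction_lag_threshold: float = 5.5
    cross_orientation_gain: float = 0.3  # lateral gain for cross-oriented inducers
    soft_clip_reversal: float | None = None  # optional sub-linear saturation (mV)
    spike_amplitude: float = 45.0
    spike_width: float = 1.0        # ms (total spike waveform support ~2x this)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ashp_true):
            raise ValueError("ashp_true must be positive")
        if self.lambda_decay <= 0 or self.noise_tau <= 0 or self.noise_sigma < 0:
            raise ValueError("decay/noise parameters must be positive")
        if self.interaction_gain < 0:
            raise ValueError("interaction_gain must be >= 0")


@dataclass
class TrialRecording:
    """One trial: Vm trace (mV) at ``sampling_rate`` plus spike times (ms)."""

    vm: np.ndarray
    spike_times: np.ndarray
    condition: str
    block: int
    cell: str
    sampling_rate: float = 10000.0
    stim_offset_ms: float = DEFAULT_STIM_OFFSET_MS
    expected_center_onset_ms: float = 0.0  # absolute, within the trial

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, dtype=float)
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if not np.all(np.isfinite(self.vm)):
            raise ValueError("Vm trace contains non-finite samples")
        dur = len(self.vm) / self.sampling_rate * 1000.0
        if self.spike_times.size and (
            self.spike_times.min() < 0 or self.spike_times.max() > dur
        ):
            raise ValueError("spike times outside the trial window")

    @property
    def duration_ms(self) -> float:
        return len(self.vm) / self.sampling_rate * 1000.0

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.vm)) * 1000.0 / self.sampling_rate


@dataclass
class Dataset:
    """Many cells x blocks x conditions of simulated (or loaded) trials."""

    protocol: ProtocolSpec | None
    cells: list[tuple[str, RFGeometry, GeneratorParams]]
    recordings: dict[tuple[str, int, str], TrialRecording]
    meta: dict = field(default_factory=dict)

    def cell_ids(self) -> list[str]:
        return [c[0] for c in self.cells]

    def trials(self, cell: str, label_predicate) -> list[TrialRecording]:
        """All trials of one cell whose entry label satisfies the predicate."""
        if isinstance(label_predicate, str):
            want = label_predicate
            label_predicate = lambda lab: lab == want  # noqa: E731
        return [
            rec
            for (cid, _, lab), rec in sorted(self.recordings.items())
            if cid == cell and label_predicate(lab)
        ]


# ---------------------------------------------------------------------------
# elementary kernels
# ---------------------------------------------------------------------------

def lateral_kernel(eccentricity: float, p: GeneratorParams) -> tuple[float, float]:
    """Onset latency (ms) and peak amplitude (mV) of a lateral volley.

    latency = base_latency + eccentricity * magnification / ashp_true
    amplitude = a0 * exp(-eccentricity / lambda_decay)
    """
    if eccentricity < 0:
        raise ValueError("eccentricity must be >= 0")
    latency = p.base_latency + eccentricity * p.magnification / p.ashp_true
    amplitude = p.a0 * np.exp(-eccentricity / p.lambda_decay)
    return float(latency), float(amplitude)


def psp_kernel(t_ms: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak double-exponential PSP kernel, zero for t < 0."""
    t = np.asarray(t_ms, dtype=float)
    if rise >= decay:
        rise = 0.999 * decay
    tp = rise * decay / (decay - rise) * np.log(decay / rise)  # time of peak
    peak = np.exp(-tp / decay) - np.exp(-tp / rise)
    out = np.where(t > 0, np.exp(-np.maximum(t, 0) / decay) - np.exp(-np.maximum(t, 0) / rise), 0.0)
    return out / peak


def ou_noise(
    n: int, dt_ms: float, sigma: float, tau_ms: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise (exact discretization)."""
    if sigma == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    rho = np.exp(-dt_ms / tau_ms)
    innov = sigma * np.sqrt(1.0 - rho**2)
    drive = innov * rng.standard_normal(n)
    drive[0] = sigma * rng.standard_normal()  # stationary start
    # AR(1): x[k] = rho x[k-1] + drive[k]
    x = lfilter([1.0], [1.0, -rho], drive)
    return x


def _spike_waveform(fs: float, width_ms: float, amplitude: float) -> np.ndarray:
    """Stereotyped spike shape (alpha function, ~width_ms half-width)."""
    tau = width_ms / 1.35  # alpha half-width ~= 1.35 tau above half-height... empirical
    t = np.arange(0.0, 6.0 * tau, 1000.0 / fs)
    w = (t / tau) * np.exp(1.0 - t / tau)
    return amplitude * w


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

def _psp_schedule(entry: AMSequence, rf: RFGeometry, p: GeneratorParams):
    """Synaptic onsets/amplitudes for one sequence (interaction applied).

    One lateral PSP per surround stroke group (amplitude scaled by stroke
    contrast and down-weighted for cross-oriented inducers), one feedforward
    PSP per D0 stroke. Returns a list of (onset_ms, amplitude_mV).
    """
    cx, cy = rf.center_position
    psps: list[tuple[float, float, bool]] = []  # (onset, amplitude, is_lateral)
    for onset, group in entry.stroke_groups():
        center_events = [e for e in group if e.node_label == "D0"]
        if center_events:
            e = center_events[0]
            psps.append((onset + p.base_latency, p.ff_amplitude * e.gabor.contrast, False))
            group = tuple(e for e in group if e.node_label != "D0")
        if group:
            ecc = float(np.mean([e.eccentricity for e in group]))
            lat, amp = lateral_kernel(ecc, p)
            e0 = group[0]
            amp *= e0.gabor.contrast
            d_ori = abs((e0.gabor.orientation - rf.preferred_orientation + 90.0) % 180.0 - 90.0)
            if d_ori > 45.0:
                amp *= p.cross_orientation_gain
            psps.append((onset + lat, amp, True))
    psps.sort(key=lambda x: x[0])
    if p.interaction_gain > 0 and psps:
        rise, decay = p.psp_rise, p.psp_decay
        boosted: list[tuple[float, float]] = []
        for k, (o_k, a_k, is_lat) in enumerate(psps):
            v_lat = 0.0
            for o_j, a_j, lat_j in psps[:k]:
                if lat_j and o_k - o_j > p.interaction_lag_threshold:
                    v_lat += a_j * psp_kernel(np.array([o_k - o_j]), rise, decay)[0]
            boost = 1.0 + p.interaction_gain * max(v_lat, 0.0) / p.a0
            boosted.append((o_k, a_k * boost))
        return boosted
    return [(o, a) for o, a, _ in psps]


def simulate_trial(
    entry: AMSequence,
    rf: RFGeometry,
    p: GeneratorParams,
    seed: int | Sequence[int],
    duration_ms: float | None = None,
    fs: float = 10000.0,
    stim_offset_ms: float = DEFAULT_STIM_OFFSET_MS,
    block: int = 0,
    cell: str = "cell0",
) -> TrialRecording:
    """Simulate one trial of one stimulation entry. Deterministic per seed."""
    for e in entry.events:
        if e.eccentricity > 60.0:
            raise ValueError(
                f"event at eccentricity {e.eccentricity:g} deg lies outside the "
                "generator's geometry"
            )
    if duration_ms is None:
        last = max((e.onset_time for e in entry.events), default=0.0)
        duration_ms = stim_offset_ms + last + p.base_latency + 350.0
    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) * 1000.0 / fs
    rng = np.random.default_rng(seed)
    vm = np.full(n, p.v_rest) + ou_noise(n, 1000.0 / fs, p.noise_sigma, p.noise_tau, rng)
    for onset, amp in _psp_schedule(entry, rf, p):
        vm += amp * psp_kernel(t - (stim_offset_ms + onset), p.psp_rise, p.psp_decay)
    if p.soft_clip_reversal is not None:
        # soft saturation toward a reversal potential (sub-linear summation)
        head = p.soft_clip_reversal - p.v_rest
        dep = vm - p.v_rest
        vm = p.v_rest + head * np.tanh(dep / head)
    # threshold spiking with absolute refractory
    spike_times: list[float] = []
    above = vm >= p.spike_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    last_spike = -np.inf
    for idx in crossings:
        ts = t[idx]
        if ts - last_spike >= p.refractory:
            spike_times.append(ts)
            last_spike = ts
    if spike_times and p.spike_amplitude > 0:
        w = _spike_waveform(fs, p.spike_width, p.spike_amplitude)
        for ts in spike_times:
            i0 = int(round(ts * fs / 1000.0))
            i1 = min(i0 + len(w), n)
            vm[i0:i1] += w[: i1 - i0]
    return TrialRecording(
        vm=vm,
        spike_times=np.array(spike_times),
        condition=entry.label or entry.condition,
        block=block,
        cell=cell,
        sampling_rate=fs,
        stim_offset_ms=stim_offset_ms,
        expected_center_onset_ms=stim_offset_ms + entry.expected_center_onset_ms,
    )


def simulate_condition(
    entry: AMSequence,
    rf: RFGeometry,
    p: GeneratorParams,
    n_trials: int,
    seed: int,
    **kwargs,
) -> list[TrialRecording]:
    """Convenience wrapper: ``n_trials`` independent trials of one entry."""
    return [
        simulate_trial(entry, rf, p, seed=[seed, k], block=k, **kwargs)
        for k in range(n_trials)
    ]


def trial_duration_for_protocol(
    protocol: ProtocolSpec, p: GeneratorParams, stim_offset_ms: float = DEFAULT_STIM_OFFSET_MS
) -> float:
    """Common trial duration long enough for every entry of a protocol."""
    last = 0.0
    for seq in protocol.condition_set:
        events_last = max((e.onset_time for e in seq.events), default=0.0)
        last = max(last, events_last, seq.expected_center_onset_ms)
    return stim_offset_ms + last + p.base_latency + 350.0


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _draw_params(
    priors: Mapping[str, object] | None, base: GeneratorParams, rng: np.random.Generator
) -> GeneratorParams:
    if not priors:
        return base
    updates = {}
    for name, spec in priors.items():
        if callable(spec):
            updates[name] = spec(rng)
        elif isinstance(spec, tuple) and len(spec) == 2:
            lo, hi = spec
            updates[name] = float(rng.uniform(lo, hi))
        else:
            updates[name] = spec
    return dataclasses.replace(base, **updates)


def generate_dataset(
    protocol: ProtocolSpec,
    n_cells: int,
    n_blocks: int,
    param_priors: Mapping[str, object] | None = None,
    seed: int = 0,
    base_params: GeneratorParams | None = None,
    stim_offset_ms: float = DEFAULT_STIM_OFFSET_MS,
    fs: float = 10000.0,
) -> Dataset:
    """Simulate a full dataset: each block presents each condition once.

    ``param_priors`` maps GeneratorParams field names to either a
    ``(low, high)`` uniform range, a constant, or a callable ``f(rng)``;
    per-cell parameters are drawn independently. RND-ISO entries are
    re-randomized in every block (pseudo-randomization of all other entries
    is protocol-level). Full provenance (master seed, per-cell parameters)
    is stored in ``Dataset.meta``.
    """
    base = base_params or GeneratorParams()
    master = np.random.default_rng([seed, 0x5EED])
    cells: list[tuple[str, RFGeometry, GeneratorParams]] = []
    for c in range(n_cells):
        p = _draw_params(param_priors, base, master)
        p = dataclasses.replace(p, rng_seed=int(master.integers(2**31)))
        cells.append((f"cell{c:02d}", protocol.rf, p))
    duration = max(
        trial_duration_for_protocol(protocol, p, stim_offset_ms) for _, _, p in cells
    )
    recordings: dict[tuple[str, int, str], TrialRecording] = {}
    for ci, (cid, rf, p) in enumerate(cells):
        for block in range(n_blocks):
            for seq in protocol.block_order(block):
                if seq.condition == "RND-ISO":
                    seq = randomize_sequence(seq, [seed, 0xA11D, ci, block, hash(seq.label) % 2**16])
                rec = simulate_trial(
                    seq,
                    rf,
                    p,
                    seed=[p.rng_seed, block, abs(hash(seq.label)) % 2**31],
                    duration_ms=duration,
                    fs=fs,
                    stim_offset_ms=stim_offset_ms,
                    block=block,
                    cell=cid,
                )
                recordings[(cid, block, seq.label)] = rec
    meta = {
        "master_seed": seed,
        "n_cells": n_cells,
        "n_blocks": n_blocks,
        "stim_offset_ms": stim_offset_ms,
        "sampling_rate": fs,
        "protocol_hash": protocol.content_hash(),
        "cell_params": {
            cid: dataclasses.asdict(p) for cid, _, p in cells
        },
    }
    return Dataset(protocol=protocol, cells=cells, recordings=recordings, meta=meta)
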