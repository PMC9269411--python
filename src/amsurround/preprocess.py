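"""Raw-trial conditioning: spike removal, filtering, PSTW/PSTH construction.

The conditioning chain mirrors standard intracellular practice: spikes are
excised from the Vm trace and replaced by alpha functions
``alpha(t) = a * t * exp(-t/tau)`` (``a`` estimated from the slope at the
peak of the second derivative of the rising phase, ``tau`` from the spike
half-width); the resulting trace is band-pass filtered (0.1-300 Hz,
zero-phase so latency measurements are unbiased), down-sampled to 1 kHz and
smoothed with a 7 ms sliding average. Trial-averaged peristimulus waveforms
(PSTW, mV) carry mean +/- SEM; peristimulus time histograms (PSTH, spikes/s)
are Gaussian-smoothed (sigma = 3 ms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseWaveform",
    "alpha_function",
    "detect_spikes",
    "remove_spikes",
    "condition_trace",
    "build_pstw",
    "build_psth",
    "subtract_blank",
    "subtract_block_mean",
]


@dataclass
class ResponseWaveform:
    """A trial-averaged response: mean +/- SEM on a millisecond time base.

    ``time_base`` is in ms (1 kHz after conditioning), usually relative to
    the (expected) center-stimulus onset. ``kind`` is "PSTW" (mV) or "PSTH"
    (spikes/s).
    """

    time_base: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    kind: str = "PSTW"

    def __post_init__(self) -> None:
        self.time_base = np.asarray(self.time_base, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.time_base) == len(self.mean) == len(self.sem)):
            raise ValueError("time_base, mean and sem must have equal length")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_base)))

    def crop(self, window: tuple[float, float]) -> "ResponseWaveform":
        m = (self.time_base >= window[0]) & (self.time_base <= window[1])
        return replace(self, time_base=self.time_base[m], mean=self.mean[m], sem=self.sem[m])

    def peak(self, window: tuple[float, float] | None = None) -> float:
        w = self if window is None else self.crop(window)
        return float(np.max(w.mean))

    def shifted(self, dt_ms: float) -> "ResponseWaveform":
        return replace(self, time_base=self.time_base + dt_ms)


def alpha_function(t_ms: np.ndarray, a: float, tau: float) -> np.ndarray:
    """``a * t * exp(-t/tau)``, zero for t < 0; peaks at t = tau with a*tau/e."""
    t = np.asarray(t_ms, dtype=float)
    return np.where(t > 0, a * t * np.exp(-t / tau), 0.0)


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    threshold: float | None = None,
    dvdt_threshold: float = 20.0,
    refractory_ms: float = 2.0,
) -> np.ndarray:
    """Threshold-detect spikes; returns spike times in ms.

    Default criterion is on dV/dt (mV/ms), which is robust to slow
    depolarizations; an absolute-voltage criterion is available via
    ``threshold``.
    """
    x = np.asarray(trace, dtype=float)
    if threshold is not None:
        above = x >= threshold
    else:
        dvdt = np.gradient(x) * fs / 1000.0
        above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = crossings * 1000.0 / fs
    keep: list[float] = []
    for t in times:
        if not keep or t - keep[-1] >= refractory_ms:
            keep.append(float(t))
    return np.array(keep)


def remove_spikes(
    trace: np.ndarray,
    spike_times: np.ndarray,
    fs: float,
    window_pre_ms: float = 0.5,
    window_post_ms: float = 6.0,
    blend_ms: float = 1.0,
) -> np.ndarray:
    """Excise spike waveforms and splice in alpha functions.

    For each spike, the rising phase inside the excision window is analysed:
    ``a`` is the Vm slope (mV/ms) at the peak of the second derivative of the
    rising phase and ``tau`` the spike half-width. The excised segment is
    replaced by ``v0 + alpha(t; a, tau)`` anchored at the window start and
    linearly blended into the trace over ``blend_ms`` at the window end.
    Spikes closer than their half-width are merged into a single replacement
    (logged). Spike-free traces are returned unchanged.
    """
    x = np.asarray(trace, dtype=float).copy()
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size == 0:
        return x
    n = len(x)
    pre = int(round(window_pre_ms * fs / 1000.0))
    post = int(round(window_post_ms * fs / 1000.0))
    windows: list[list[int]] = []
    n_merged = 0
    for t in st:
        i = int(round(t * fs / 1000.0))
        w = [max(i - pre, 0), min(i + post, n - 1)]
        if windows and w[0] <= windows[-1][1]:
            windows[-1][1] = w[1]
            n_merged += 1
        else:
            windows.append(w)
    if n_merged:
        logger.warning(
            "%d overlapping spike(s) merged into wider replacements", n_merged
        )
    dt = 1000.0 / fs
    for i0, i1 in windows:
        seg = x[i0 : i1 + 1]
        ip = int(np.argmax(seg))
        v0 = seg[0]
        vpeak = seg[ip]
        # half-width of the spike above half-height
        half = v0 + 0.5 * (vpeak - v0)
        above = seg >= half
        tau = max(np.count_nonzero(above) * dt, dt)
        # slope at the peak of the 2nd derivative of the rising phase
        rising = seg[: max(ip, 2) + 1]
        d1 = np.gradient(rising, dt)
        d2 = np.gradient(d1, dt)
        a = max(float(d1[int(np.argmax(d2))]), 0.0)
        t_rel = np.arange(i1 + 1 - i0) * dt
        repl = v0 + alpha_function(t_rel, a, tau)
        nb = min(int(round(blend_ms * fs / 1000.0)), len(repl))
        if nb > 0:
            wts = np.linspace(0.0, 1.0, nb)
            repl[-nb:] = (1 - wts) * repl[-nb:] + wts * x[i1 + 1 - nb : i1 + 1]
        x[i0 : i1 + 1] = repl
    return x


def condition_trace(
    trace: np.ndarray,
    fs_in: float,
    out_fs: float = 1000.0,
    band: tuple[float, float] = (0.1, 300.0),
    smooth_ms: float = 7.0,
    filter_order: int = 4,
) -> np.ndarray:
    """Band-pass (zero-phase), decimate to 1 kHz, 7 ms sliding average.

    The band-pass acts on the mean-removed trace and the mean is restored
    afterwards, so absolute Vm levels (and any additive constant) survive
    conditioning while in-trace drift outside the band is removed.
    """
    x = np.asarray(trace, dtype=float)
    if fs_in < 2000.0:
        raise ValueError("condition_trace expects an input rate of at least 2 kHz")
    # separate HP/LP sections: a single band-pass spanning 0.1-300 Hz at
    # 10 kHz is numerically ill-conditioned
    sos_lp = signal.butter(filter_order, band[1], btype="lowpass", fs=fs_in, output="sos")
    padlen = 3 * (2 * filter_order + 1)
    if len(x) <= 3 * padlen:
        raise ValueError("trace shorter than the filter warm-up")
    mean = float(np.mean(x))
    y = x - mean
    if len(x) >= fs_in / band[0]:
        # the HP corner is resolvable only when the trace spans one period;
        # on shorter trials the mean removal above implements it
        sos_hp = signal.butter(2, band[0], btype="highpass", fs=fs_in, output="sos")
        y = signal.sosfiltfilt(sos_hp, y, padlen=min(len(x) - 1, int(fs_in / band[0])))
    y = signal.sosfiltfilt(sos_lp, y)
    q = int(round(fs_in / out_fs))
    if q > 1:
        y = signal.decimate(y, q, ftype="fir", zero_phase=True)
    nsmooth = max(int(round(smooth_ms * out_fs / 1000.0)), 1)
    kernel = np.ones(nsmooth) / nsmooth
    pad = nsmooth // 2
    yp = np.pad(y, pad, mode="edge")
    y = np.convolve(yp, kernel, mode="same")[pad : pad + len(y)]
    return y + mean


def build_pstw(
    trials: np.ndarray, time_base: np.ndarray, kind: str = "PSTW"
) -> ResponseWaveform:
    """Mean +/- SEM across conditioned trials sharing a common time base."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[1] != len(time_base):
        raise ValueError("trials and time_base lengths do not match")
    n = trials.shape[0]
    mean = trials.mean(axis=0)
    sem = trials.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ResponseWaveform(time_base=np.asarray(time_base, float), mean=mean, sem=sem, n_trials=n, kind=kind)


def spike_trains_to_rates(
    spike_trains: list[np.ndarray],
    time_base: np.ndarray,
    sigma_ms: float = 3.0,
) -> np.ndarray:
    """Per-trial instantaneous firing rate (spikes/s), Gaussian-smoothed."""
    time_base = np.asarray(time_base, dtype=float)
    dt = float(np.median(np.diff(time_base)))
    edges = np.concatenate([time_base - dt / 2.0, [time_base[-1] + dt / 2.0]])
    rates = np.empty((len(spike_trains), len(time_base)))
    for i, train in enumerate(spike_trains):
        counts, _ = np.histogram(np.asarray(train, dtype=float), bins=edges)
        rates[i] = gaussian_filter1d(counts.astype(float), sigma_ms / dt, mode="constant")
        rates[i] *= 1000.0 / dt
    return rates


def build_psth(
    spike_trains: list[np.ndarray],
    time_base: np.ndarray,
    sigma_ms: float = 3.0,
) -> ResponseWaveform:
    """Trial-averaged PSTH in spikes/s (Gaussian window, sigma = 3 ms)."""
    if len(spike_trains) < 1:
        raise ValueError("need at least one spike train")
    rates = spike_trains_to_rates(spike_trains, time_base, sigma_ms)
    return build_pstw(rates, time_base, kind="PSTH")


def subtract_blank(resp: ResponseWaveform, blank: ResponseWaveform) -> ResponseWaveform:
    """Pointwise blank subtraction (evoked = response - blank).

    Blank-subtracted blanks are centred on zero by construction, which is
    also why permutation null envelopes are centred on zero (and why a PSTH
    can go negative). SEMs combine in quadrature.
    """
    if len(resp.time_base) != len(blank.time_base) or not np.allclose(
        resp.time_base, blank.time_base
    ):
        raise ValueError("response and blank are on different time bases")
    return replace(
        resp,
        mean=resp.mean - blank.mean,
        sem=np.hypot(resp.sem, blank.sem),
    )


def subtract_block_mean(trials: np.ndarray, block_ids: np.ndarray) -> np.ndarray:
    """Remove each block's mean activity level from its trials.

    ``trials`` is (n_trials, n_samples); for every block, the scalar mean
    over all of that block's trials and samples is subtracted, removing slow
    excitability drift common to all conditions of the block.
    """
    trials = np.asarray(trials, dtype=float).copy()
    block_ids = np.asarray(block_ids)
    for b in np.unique(block_ids):
        m = block_ids == b
        trials[m] -= trials[m].mean()
    return trials
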