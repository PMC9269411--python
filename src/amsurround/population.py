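"""Across-cell normalization, realignment and averaging.

Cells differ in absolute response amplitude, feedforward latency and
preferred orientation, so population averages are built in a common frame:
each cell's waveforms are divided by the peak of its own Center-Only
response, shifted so that the Center-Only 3-sigma onset sits at relative
time 0 (the orientation frame is already cell-centric by construction of
the protocols: the preferred orientation defines the 0 deg axis). Because
onset-to-peak rise times vary across cells, the peak of the average
normalized response can legitimately be below 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ResponseWaveform, build_pstw
from .stats import onset_latency

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedPopulation",
    "normalize_and_realign",
    "population_average",
    "speed_tuning_profile",
    "plot_population_overlay",
]

#: figure colors used across the flow conditions
CONDITION_COLORS = {
    "CP-ISO": "tab:red",
    "CF-ISO": "tab:green",
    "CP-CROSS": "goldenrod",
    "CF-CROSS": "saddlebrown",
    "RND-ISO": "tab:blue",
    "CENTER_ONLY": "black",
}

SPEED_FRACTIONS = (1.0, 0.7, 0.5, 0.3)


@dataclass
class AlignedPopulation:
    """Per-cell normalized waveforms on a common relative-time base."""

    time_base: np.ndarray  # ms, 0 = each cell's Center-Only onset
    waveforms: np.ndarray  # (n_cells, T), peak-normalized
    cell_ids: list[str]
    alignment_onsets: dict[str, float]  # per-cell onset used for the shift (ms)
    condition: str = ""

    @property
    def n_cells(self) -> int:
        return self.waveforms.shape[0]


def normalize_and_realign(
    cell_waveforms: dict[str, ResponseWaveform],
    center_only_waveforms: dict[str, ResponseWaveform],
    blank_stats: dict[str, tuple[float, float]],
    condition: str = "",
    out_dt_ms: float = 1.0,
) -> AlignedPopulation:
    """Normalize each cell to its Center-Only peak and realign onsets to 0.

    ``blank_stats[cell] = (blank_mean, blank_sigma)`` supplies the 3-sigma
    onset criterion for the Center-Only response. Cells with a non-positive
    Center-Only peak or an undefined onset are excluded (logged). The
    common time base is the intersection of the shifted windows, resampled
    at ``out_dt_ms``.
    """
    shifted: dict[str, ResponseWaveform] = {}
    onsets: dict[str, float] = {}
    for cell, wf in cell_waveforms.items():
        co = center_only_waveforms[cell]
        peak = co.peak()
        if peak <= 0:
            logger.warning("cell %s excluded: non-positive Center-Only peak", cell)
            continue
        mean_b, sigma_b = blank_stats[cell]
        onset = onset_latency(co, rule="three_sigma", blank_mean=mean_b, blank_sigma=sigma_b)
        if not np.isfinite(onset):
            logger.warning("cell %s excluded: undefined Center-Only onset", cell)
            continue
        onsets[cell] = onset
        shifted[cell] = ResponseWaveform(
            time_base=wf.time_base - onset,
            mean=wf.mean / peak,
            sem=wf.sem / peak,
            n_trials=wf.n_trials,
            kind=wf.kind,
        )
    if not shifted:
        raise ValueError("no cell survived normalization/realignment")
    lo = max(w.time_base[0] for w in shifted.values())
    hi = min(w.time_base[-1] for w in shifted.values())
    if hi <= lo:
        raise ValueError("shifted waveforms share no overlapping window")
    common = np.arange(np.ceil(lo), np.floor(hi) + 1e-9, out_dt_ms)
    cells = sorted(shifted)
    mat = np.vstack(
        [np.interp(common, shifted[c].time_base, shifted[c].mean) for c in cells]
    )
    return AlignedPopulation(
        time_base=common,
        waveforms=mat,
        cell_ids=cells,
        alignment_onsets=onsets,
        condition=condition,
    )


def population_average(pop: AlignedPopulation) -> ResponseWaveform:
    """Pointwise mean +/- SEM across cells of an aligned population."""
    if pop.n_cells < 1:
        raise ValueError("empty population")
    return build_pstw(pop.waveforms, pop.time_base)


def speed_tuning_profile(
    contextual_peaks: dict[tuple[str, float], float],
    fractions=SPEED_FRACTIONS,
) -> pd.DataFrame:
    """Speed-tuning summary across cells.

    ``contextual_peaks[(cell, fraction)]`` is the peak contextual amplitude
    (AM response minus Center-Only, at that cell's normalization) measured
    at one nominal-speed fraction. Cells missing a fraction are excluded
    from that row. Returns one row per fraction with the population mean,
    SEM and n, plus an ``is_max`` flag marking whether the full-speed (1.0)
    row has the largest mean peak.
    """
    present = sorted({f for (_, f) in contextual_peaks}, reverse=True)
    fractions = [f for f in fractions if f in present] or present
    rows = []
    for f in fractions:
        vals = np.array(
            [v for (c, ff), v in contextual_peaks.items() if ff == f], dtype=float
        )
        rows.append(
            dict(
                speed_fraction=f,
                mean_peak=float(vals.mean()),
                sem_peak=float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                n_cells=int(len(vals)),
            )
        )
    df = pd.DataFrame(rows)
    df["is_max"] = df["mean_peak"] == df["mean_peak"].max()
    return df


def plot_population_overlay(
    populations: dict[str, ResponseWaveform],
    path,
    title: str = "Population averages (mean +/- SEM)",
) -> None:
    """Overlay per-condition population averages with SEM shading.

    ``populations`` maps condition labels to averaged waveforms on a common
    relative-time base (0 = Center-Only onset). The figure is written to
    ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, wf in sorted(populations.items()):
        cond = label.split("|")[0]
        color = CONDITION_COLORS.get(cond)
        ax.plot(wf.time_base, wf.mean, label=label, color=color, lw=1.5)
        ax.fill_between(
            wf.time_base, wf.mean - wf.sem, wf.mean + wf.sem,
            alpha=0.25, color=color, linewidth=0,
        )
    ax.axvline(0.0, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("time from Center-Only onset (ms)")
    ax.set_ylabel("normalized response")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
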