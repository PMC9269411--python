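"""Four-stage analysis pipeline: simulate -> preprocess -> analyze -> report.

This is the plumbing that strings the library modules together on a whole
dataset: every trial is conditioned and realigned on the (expected) center
stimulus onset, per-cell statistics are computed for every AM condition
against the Center-Only reference, isolated-Gabor latencies are regressed
into a per-cell ASHP estimate, and population summaries are exported as CSV
tables with a JSON run manifest carrying full provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import (
    ResponseWaveform,
    build_pstw,
    condition_trace,
    remove_spikes,
)
from .predictors import nonlinearity_test, slp_trial_ensemble, surround_linear_predictor
from .propagation import fit_latency_basin, input_phase
from .stats import (
    contextual_modulation,
    onset_latency,
    permutation_envelope,
    screen_responsive,
)
from .stimuli import ProtocolSpec, RFGeometry, build_cardinal_protocol, build_radial_protocol
from .synth import Dataset, GeneratorParams, generate_dataset
from .population import normalize_and_realign, population_average

__all__ = ["RunConfig", "preprocess_dataset", "analyze_dataset", "run_pipeline"]

ANALYSIS_WINDOW = (-150.0, 300.0)  # ms, relative to expected center onset


@dataclass
class RunConfig:
    """Configuration of one end-to-end run (all seeds flow from ``seed``)."""

    outdir: str = "amsurround_run"
    protocol: str = "radial"
    n_cells: int = 3
    n_blocks: int = 20
    seed: int = 0
    alpha: float = 0.05
    n_permutations: int = 1000
    min_consecutive_ms: float = 1.0
    magnification: float = 1.0
    dataset_path: str | None = None  # analyze an existing dataset instead of simulating
    rf: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if 1.0 / self.n_permutations > self.alpha:
            raise ValueError(
                f"n_permutations={self.n_permutations} cannot resolve alpha={self.alpha}: "
                "increase n_permutations or relax alpha"
            )

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()


def build_protocol(config: RunConfig) -> ProtocolSpec:
    rf = RFGeometry(**{**config.rf, "center_position": tuple(config.rf.get("center_position", (0.0, 0.0)))})
    if config.protocol == "radial":
        return build_radial_protocol(rf, seed=config.seed)
    if config.protocol == "cardinal":
        return build_cardinal_protocol(rf, variant="center_surround", block_order_seed=config.seed)
    raise ValueError(f"unknown protocol family {config.protocol!r}")


# ---------------------------------------------------------------------------
# preprocessing stage
# ---------------------------------------------------------------------------

def preprocess_dataset(
    dataset: Dataset, window: tuple[float, float] = ANALYSIS_WINDOW
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Condition every trial and realign on the expected center onset.

    Returns ``{cell: {entry_label: (time_base, trials)}}`` where ``trials``
    is (n_trials, T) at 1 kHz on the common relative time base. Spikes are
    removed before filtering; each block's scalar mean activity is
    subtracted from its trials.
    """
    import logging

    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    per_cell_block_sums: dict[tuple[str, int], list[float]] = {}
    conditioned: dict[tuple[str, int, str], tuple[np.ndarray, np.ndarray]] = {}
    prep_logger = logging.getLogger("amsurround.preprocess")
    prev_level = prep_logger.level
    prep_logger.setLevel(logging.ERROR)  # per-trial merge notices would flood the log
    try:
        for (cid, block, label), rec in dataset.recordings.items():
            trace = rec.vm
            if rec.spike_times.size:
                trace = remove_spikes(trace, rec.spike_times, rec.sampling_rate)
            y = condition_trace(trace, rec.sampling_rate)
            tb = np.arange(len(y)) - rec.expected_center_onset_ms  # 1 kHz -> 1 sample/ms
            m = (tb >= window[0]) & (tb <= window[1])
            conditioned[(cid, block, label)] = (tb[m], y[m])
            per_cell_block_sums.setdefault((cid, block), []).append(float(np.mean(y[m])))
    finally:
        prep_logger.setLevel(prev_level)
    block_mean = {k: float(np.mean(v)) for k, v in per_cell_block_sums.items()}
    for (cid, block, label), (tb, y) in conditioned.items():
        cell_map = out.setdefault(cid, {})
        tb_y = cell_map.get(label)
        y = y - block_mean[(cid, block)]
        if tb_y is None:
            cell_map[label] = (tb, [y])
        else:
            cell_map[label][1].append(y)
    final: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for cid, cell_map in out.items():
        final[cid] = {}
        for label, (tb, rows) in cell_map.items():
            tlen = min(len(r) for r in rows)
            final[cid][label] = (tb[:tlen], np.vstack([r[:tlen] for r in rows]))
    return final


# ---------------------------------------------------------------------------
# analysis stage
# ---------------------------------------------------------------------------

def _pool(cell_map, predicate) -> tuple[np.ndarray, np.ndarray] | None:
    labs = [lab for lab in cell_map if predicate(lab)]
    if not labs:
        return None
    tb = cell_map[labs[0]][0]
    trials = np.vstack([cell_map[lab][1] for lab in labs])
    return tb, trials


def analyze_dataset(
    dataset: Dataset,
    preprocessed=None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    min_consecutive_ms: float = 1.0,
    magnification: float = 1.0,
    seed: int = 0,
) -> dict:
    """Per-cell and population statistics for a (simulated or loaded) dataset.

    Returns a dict with DataFrames ``results`` (one row per cell x AM
    condition), ``ashp`` (per-cell latency-basin fits), ``phases`` (input
    phase points), ``screening``, and per-condition population averages.
    """
    protocol = dataset.protocol
    if preprocessed is None:
        preprocessed = preprocess_dataset(dataset)
    rng = np.random.default_rng([seed, 0xA7A])
    results_rows, ashp_rows, phase_rows, screen_rows = [], [], [], []
    pop_inputs: dict[str, dict[str, ResponseWaveform]] = {}
    center_wfs: dict[str, ResponseWaveform] = {}
    blank_stats: dict[str, tuple[float, float]] = {}

    entries_by_label = (
        {e.label: e for e in protocol.condition_set} if protocol is not None else {}
    )
    for cid, cell_map in preprocessed.items():
        blanks = _pool(cell_map, lambda l: l.startswith("BLANK"))
        center = _pool(cell_map, lambda l: l == "CENTER_ONLY")
        if blanks is None or center is None:
            continue
        tb = center[0]
        blank_mean_wave = blanks[1].mean(axis=0)
        blank_mean = float(np.mean(blank_mean_wave))
        blank_sigma = float(np.std(blanks[1].mean(axis=0), ddof=1))
        blank_stats[cid] = (blank_mean, blank_sigma)

        def evoked(trials):
            return trials - blank_mean_wave[None, : trials.shape[1]]

        center_trials = evoked(center[1])
        blank_trials = evoked(blanks[1])
        responsive = screen_responsive(
            center_trials, blank_trials, tb,
            n_permutations=max(n_permutations, 200),
            seed=int(rng.integers(2**31)),
        )
        screen_rows.append(dict(cell=cid, responsive=bool(responsive)))
        center_wf = build_pstw(center_trials, tb)
        center_wfs[cid] = center_wf
        center_onset = onset_latency(
            center_wf, "three_sigma", blank_mean=0.0, blank_sigma=blank_sigma,
            window=(0.0, 200.0),
        )
        if not responsive:
            continue

        # contextual modulation for every full AM entry
        for label, (tb_e, trials) in sorted(cell_map.items()):
            entry = entries_by_label.get(label)
            if entry is None or entry.trajectory != "full":
                continue
            trials_e = evoked(trials)
            mod = contextual_modulation(
                trials_e, center_trials, tb,
                n_permutations=n_permutations, alpha=alpha,
                seed=int(rng.integers(2**31)),
            )
            so_label = label.replace("|full", "|surround_only")
            so_sig = np.nan
            so_onset = np.nan
            if so_label in cell_map:
                so_trials = evoked(cell_map[so_label][1])
                env = permutation_envelope(
                    so_trials, blank_trials, tb,
                    n_permutations=n_permutations, alpha=0.01,
                    min_consecutive_ms=min_consecutive_ms,
                    seed=int(rng.integers(2**31)),
                )
                win = (tb >= 0) & (tb <= 120)
                so_sig = bool(np.any(env.mask[win]))
                so_wf = build_pstw(so_trials, tb)
                so_onset = onset_latency(
                    so_wf, "three_sigma", blank_mean=0.0, blank_sigma=blank_sigma,
                    window=(-120.0, 200.0),
                )
                phase_rows.append(
                    dict(
                        cell=cid, condition=entry.condition,
                        configuration=entry.configuration,
                        phase_ms=input_phase(so_onset, center_onset),
                        delta_latency_ms=mod.delta_latency,
                    )
                )
            results_rows.append(
                dict(
                    cell=cid, condition=entry.condition,
                    configuration=entry.configuration,
                    speed_fraction=entry.speed_fraction,
                    delta_latency_ms=mod.delta_latency,
                    delta_integral_ratio=mod.delta_integral_ratio,
                    p_latency=mod.p_latency, p_integral=mod.p_integral,
                    surround_only_significant=so_sig,
                )
            )
            pop_inputs.setdefault(f"{entry.condition}|{entry.configuration}", {})[cid] = build_pstw(trials_e, tb)

        # latency basin from isolated-Gabor responses (radial protocol)
        iso_points = []
        for label, (tb_e, trials) in sorted(cell_map.items()):
            entry = entries_by_label.get(label)
            if entry is None or entry.trajectory != "isolated":
                continue
            if "ISOLATED-ISO" not in label or "|SECTOR" not in label:
                continue
            wf = build_pstw(evoked(trials), tb)
            # rebase on the stroke's own onset
            stroke_rel = entry.events[0].onset_time - entry.expected_center_onset_ms
            wf_rebased = ResponseWaveform(
                time_base=tb - stroke_rel, mean=wf.mean, sem=wf.sem, n_trials=wf.n_trials
            )
            lat = onset_latency(
                wf_rebased, "three_sigma", blank_mean=0.0, blank_sigma=blank_sigma,
                window=(0.0, 250.0),
            )
            iso_points.append((entry.events[0].eccentricity, lat))
        if len([p for p in iso_points if np.isfinite(p[1])]) >= 3:
            fit = fit_latency_basin(iso_points, magnification=magnification)
            ashp_rows.append(
                dict(
                    cell=cid, slope_ms_per_deg=fit.slope, intercept_ms=fit.intercept,
                    ashp_mm_per_ms=fit.ashp, r2=fit.r2, n_points=len(fit.points),
                )
            )

        # non-linearity vs the Surround linear predictor (CP-ISO SECTOR)
        chrono_label = "CP-ISO|SECTOR|surround_only"
        if chrono_label in cell_map and protocol is not None:
            chrono = entries_by_label[chrono_label]
            iso_trials = {}
            for ring in range(1, 6):
                lab = f"ISOLATED-ISO-D{ring}|SECTOR"
                if lab in cell_map:
                    entry = entries_by_label[lab]
                    stroke_rel = entry.events[0].onset_time - entry.expected_center_onset_ms
                    iso_trials[f"D{ring}"] = (evoked(cell_map[lab][1]), stroke_rel)
            needed = {e.node_label for e in chrono.events}
            if needed <= set(iso_trials):
                comp_tb = tb
                comp = {
                    lab: np.array(
                        [np.interp(comp_tb, tb - rel, row, left=0.0, right=0.0) for row in trials]
                    )
                    for lab, (trials, rel) in iso_trials.items()
                }
                slp_trials = slp_trial_ensemble(
                    comp, comp_tb, chrono, tb, seed=int(rng.integers(2**31))
                )
                verdict = nonlinearity_test(
                    evoked(cell_map[chrono_label][1]), slp_trials, tb,
                    alpha=alpha, n_permutations=n_permutations,
                    seed=int(rng.integers(2**31)),
                )
                for row in results_rows:
                    if row["cell"] == cid and row["condition"] == "CP-ISO" and row["configuration"] == "SECTOR":
                        row["slp_supralinear"] = bool(verdict.significant)

    populations = {}
    for key, wfs in pop_inputs.items():
        usable = {c: w for c, w in wfs.items() if c in center_wfs}
        if usable:
            try:
                pop = normalize_and_realign(usable, center_wfs, blank_stats, condition=key)
                populations[key] = population_average(pop)
            except ValueError:
                pass
    return {
        "results": pd.DataFrame(results_rows),
        "ashp": pd.DataFrame(ashp_rows),
        "phases": pd.DataFrame(phase_rows),
        "screening": pd.DataFrame(screen_rows),
        "populations": populations,
    }


# ---------------------------------------------------------------------------
# report stage / end-to-end driver
# ---------------------------------------------------------------------------

def write_report(outdir: str | Path, config: RunConfig, analysis: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {}
    for name in ("results", "ashp", "phases", "screening"):
        df = analysis[name]
        f = outdir / f"{name}.csv"
        df.to_csv(f, index=False)
        tables[name] = hashlib.sha256(f.read_bytes()).hexdigest()
    for key, wf in analysis["populations"].items():
        safe = key.replace("|", "_").replace("/", "_")
        pd.DataFrame(
            {"time_ms": wf.time_base, "mean": wf.mean, "sem": wf.sem}
        ).to_csv(outdir / f"population_{safe}.csv", index=False)
    if analysis["populations"]:
        from .population import plot_population_overlay

        plot_population_overlay(
            analysis["populations"], outdir / "population_overlay.png"
        )
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "config_hash": config.content_hash(),
        "table_hashes": tables,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir


def run_pipeline(config: RunConfig) -> Path:
    """simulate -> preprocess -> analyze -> report; returns the output dir."""
    from .io import load_dataset, save_dataset

    if config.dataset_path is not None:
        dataset = load_dataset(config.dataset_path)
        if dataset.protocol is None:
            dataset.protocol = build_protocol(config)
    else:
        protocol = build_protocol(config)
        base = GeneratorParams(**config.generator) if config.generator else GeneratorParams()
        priors = {k: tuple(v) if isinstance(v, list) else v for k, v in config.priors.items()}
        dataset = generate_dataset(
            protocol, config.n_cells, config.n_blocks,
            param_priors=priors or None, seed=config.seed, base_params=base,
        )
        save_dataset(dataset, Path(config.outdir) / "dataset")
    pre = preprocess_dataset(dataset)
    analysis = analyze_dataset(
        dataset, pre,
        alpha=config.alpha, n_permutations=config.n_permutations,
        min_consecutive_ms=config.min_consecutive_ms,
        magnification=config.magnification, seed=config.seed,
    )
    return write_report(config.outdir, config, analysis)
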