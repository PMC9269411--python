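"""Dataset container I/O: per-trial arrays plus JSON sidecar metadata.

A dataset directory holds ``traces.npz`` (stacked Vm traces, concatenated
spike times with offsets, and the record keys) and ``meta.json`` (cell
parameters, seeds, protocol hash and any user metadata, preserved verbatim
on round trip). The stimulus event table is written beside them as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from pathlib import Path

import numpy as np

from .stimuli import RFGeometry
from .synth import Dataset, GeneratorParams, TrialRecording

__all__ = ["DatasetIOError", "save_dataset", "load_dataset"]


class DatasetIOError(RuntimeError):
    """Raised when a dataset directory is missing, truncated or malformed."""


FORMAT_VERSION = 1


def save_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write a dataset to a directory (lossless round trip)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    keys = sorted(dataset.recordings)
    recs = [dataset.recordings[k] for k in keys]
    vm = np.stack([r.vm for r in recs]) if recs else np.empty((0, 0))
    spikes = np.concatenate([r.spike_times for r in recs]) if recs else np.empty(0)
    offsets = np.cumsum([0] + [len(r.spike_times) for r in recs])
    blocks = np.array([r.block for r in recs], dtype=int)
    fs = np.array([r.sampling_rate for r in recs])
    stim_off = np.array([r.stim_offset_ms for r in recs])
    center_on = np.array([r.expected_center_onset_ms for r in recs])
    np.savez_compressed(
        path / "traces.npz",
        vm=vm, spikes=spikes, spike_offsets=offsets, blocks=blocks,
        sampling_rate=fs, stim_offset_ms=stim_off,
        expected_center_onset_ms=center_on,
    )
    meta = dict(dataset.meta)
    meta.setdefault("format_version", FORMAT_VERSION)
    meta["record_keys"] = [list(k) for k in keys]
    meta["cells"] = [
        {
            "cell_id": cid,
            "rf": dataclasses.asdict(rf),
            "params": dataclasses.asdict(p),
        }
        for cid, rf, p in dataset.cells
    ]
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if dataset.protocol is not None:
        from .stimuli import protocol_to_table

        protocol_to_table(dataset.protocol).to_csv(path / "events.csv", index=False)
    return path


def load_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory written by :func:`save_dataset`.

    Unknown metadata keys are preserved verbatim in ``Dataset.meta``.
    """
    path = Path(path)
    meta_file = path / "meta.json"
    traces_file = path / "traces.npz"
    if not meta_file.exists() or not traces_file.exists():
        raise DatasetIOError(f"{path} is not a dataset directory")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as err:
        raise DatasetIOError(f"corrupt metadata in {meta_file}: {err}") from err
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise DatasetIOError(f"unsupported dataset format version {version!r}")
    try:
        with np.load(traces_file) as z:
            vm = z["vm"]
            spikes = z["spikes"]
            offsets = z["spike_offsets"]
            blocks = z["blocks"]
            fs = z["sampling_rate"]
            stim_off = z["stim_offset_ms"]
            center_on = z["expected_center_onset_ms"]
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as err:
        raise DatasetIOError(f"corrupt trace container {traces_file}: {err}") from err
    keys = [tuple(k) for k in meta.pop("record_keys")]
    if len(keys) != len(vm):
        raise DatasetIOError("trace container and metadata disagree on record count")
    recordings = {}
    for i, key in enumerate(keys):
        cid, block, label = key[0], int(key[1]), key[2]
        recordings[(cid, block, label)] = TrialRecording(
            vm=vm[i],
            spike_times=spikes[offsets[i] : offsets[i + 1]],
            condition=label,
            block=int(blocks[i]),
            cell=cid,
            sampling_rate=float(fs[i]),
            stim_offset_ms=float(stim_off[i]),
            expected_center_onset_ms=float(center_on[i]),
        )
    cells = []
    for c in meta.pop("cells"):
        cells.append(
            (
                c["cell_id"],
                RFGeometry(**{**c["rf"], "center_position": tuple(c["rf"]["center_position"])}),
                GeneratorParams(**c["params"]),
            )
        )
    return Dataset(protocol=None, cells=cells, recordings=recordings, meta=meta)
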