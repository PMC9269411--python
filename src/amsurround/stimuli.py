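"""Apparent-motion (AM) stimulus protocols for center-surround studies in V1.

Two protocol families are built here as fully enumerated event tables:

* the **cardinal** protocol: 2/3-stroke AM sequences of Gabor patches flashed
  along the two cardinal receptive-field (RF) axes (orientation-preference
  "main" axis and the orthogonal "width" axis), one side of the RF at a time;
* the **radial** protocol: 5-6 stroke AM flows over 5 concentric rings of
  increasing eccentricity centred on the RF, either restricted to angular
  sectors around an axis (SECTOR) or covering all motion axes (FULL).

Geometry is anchored on each cell's receptive field: the spiking minimal
discharge field (MDF) sets patch size and spacing in the cardinal protocol,
the broader subthreshold depolarizing field (SRF) sets them in the radial
protocol, so that no radial surround node overlaps the SRF.

All coordinates are visual-field degrees (x rightward, y upward); orientations
are degrees in [0, 180), measured so the cell's preferred orientation defines
the "main" axis. Times are milliseconds from sequence start.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RFGeometry",
    "GaborSpec",
    "StimulusEvent",
    "AMSequence",
    "ProtocolSpec",
    "InvalidGeometryError",
    "build_cardinal_protocol",
    "build_radial_protocol",
    "sequence_speed",
    "scale_speed",
    "randomize_sequence",
    "protocol_to_table",
    "CARDINAL_FRAME_MS",
    "DEFAULT_SURROUND_CONTRAST",
    "DEFAULT_CENTER_CONTRAST",
]

#: one frame of the 60 Hz CRT used for the cardinal protocol (ms)
CARDINAL_FRAME_MS = 1000.0 / 60.0
#: mean surround / center contrasts used across cells
DEFAULT_SURROUND_CONTRAST = 0.925
DEFAULT_CENTER_CONTRAST = 0.406


class InvalidGeometryError(ValueError):
    """Raised when RF geometry cannot support the requested protocol."""


@dataclass(frozen=True)
class RFGeometry:
    """One cell's receptive-field parameters anchoring all stimulus geometry.

    Parameters
    ----------
    center_position : (x, y) in visual-field degrees.
    preferred_orientation : degrees in [0, 180); defines the RF "main" axis.
    mdf_length, mdf_width : extents (deg) of the spiking minimal discharge
        field along the main / width axes.
    srf_extent : radius (deg) of the subthreshold depolarizing receptive
        field; must contain the MDF.
    eccentricity_from_area_centralis : deg, >= 0.
    """

    center_position: tuple[float, float] = (0.0, 0.0)
    preferred_orientation: float = 0.0
    mdf_length: float = 2.0
    mdf_width: float = 1.0
    srf_extent: float = 2.5
    eccentricity_from_area_centralis: float = 4.0

    def __post_init__(self) -> None:
        if min(self.mdf_length, self.mdf_width, self.srf_extent) <= 0:
            raise InvalidGeometryError("RF extents must be strictly positive")
        if self.srf_extent < max(self.mdf_length, self.mdf_width) / 2.0:
            raise InvalidGeometryError(
                "SRF radius must contain the MDF (srf_extent >= max MDF half-extent)"
            )
        if self.eccentricity_from_area_centralis < 0:
            raise InvalidGeometryError("eccentricity_from_area_centralis must be >= 0")
        if not (0.0 <= self.preferred_orientation < 180.0):
            raise InvalidGeometryError("preferred_orientation must lie in [0, 180)")


@dataclass(frozen=True)
class GaborSpec:
    """A flashed Gabor patch (the local AM "inducer")."""

    orientation: float = 0.0  # deg
    spatial_frequency: float = 1.0  # cycles/deg
    phase: float = 0.0  # deg
    contrast: float = DEFAULT_SURROUND_CONTRAST  # (0, 1]
    mask_length: float = 3.0  # deg
    envelope_sigma: float = 0.6  # deg
    duration: float = CARDINAL_FRAME_MS  # ms

    def __post_init__(self) -> None:
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class StimulusEvent:
    """A single timed Gabor stroke."""

    onset_time: float  # ms from sequence start
    position: tuple[float, float]  # deg
    gabor: GaborSpec
    node_label: str  # eccentricity ring index D0..D5
    eccentricity: float  # deg from the RF center

    def __post_init__(self) -> None:
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")


@dataclass(frozen=True)
class AMSequence:
    """An ordered flow of Gabor strokes forming one stimulation entry.

    ``label`` is unique within a protocol (condition + configuration + axis /
    direction tags). ``expected_center_onset_ms`` is the time at which the
    center (D0) stroke occurs, or -- for Surround-Only sequences -- the time at
    which it *would* have occurred; every analysis realigns on this reference.
    """

    condition: str  # CP-ISO, CF-ISO, CP-CROSS, CF-CROSS, RND-ISO, CENTER_ONLY, BLANK, ISOLATED
    configuration: str  # SECTOR | FULL | CARDINAL_AXIS
    events: tuple[StimulusEvent, ...]
    nominal_speed: float  # deg/s (0 for degenerate entries)
    speed_fraction: float = 1.0
    trajectory: str = "full"  # full | surround_only | center_only | isolated | blank
    label: str = ""
    expected_center_onset_ms: float = 0.0

    def __post_init__(self) -> None:
        onsets = [e.onset_time for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be ordered by onset_time")
        if self.condition == "BLANK" and self.events:
            raise ValueError("BLANK sequences carry no events")
        eccs = self.stroke_eccentricities()
        if self.condition.startswith("CP") and np.any(np.diff(eccs) > 1e-9):
            raise ValueError("centripetal sequences must have non-increasing eccentricity")
        if self.condition.startswith("CF") and np.any(np.diff(eccs) < -1e-9):
            raise ValueError("centrifugal sequences must have non-decreasing eccentricity")
        if self.condition == "RND-ISO" and self.trajectory == "full" and self.events:
            if self.events[-1].node_label != "D0":
                raise ValueError("RND-ISO full sequences must end at the RF center (D0)")

    # -- stroke structure ---------------------------------------------------
    def stroke_onsets(self) -> np.ndarray:
        """Unique stroke onset times (several events may share one onset)."""
        return np.unique([e.onset_time for e in self.events])

    def stroke_groups(self) -> list[tuple[float, tuple[StimulusEvent, ...]]]:
        """Events grouped by onset, in temporal order."""
        groups: dict[float, list[StimulusEvent]] = {}
        for e in self.events:
            groups.setdefault(e.onset_time, []).append(e)
        return [(t, tuple(groups[t])) for t in sorted(groups)]

    def stroke_eccentricities(self) -> np.ndarray:
        """Mean eccentricity of each stroke group, in temporal order."""
        return np.array([np.mean([e.eccentricity for e in g]) for _, g in self.stroke_groups()])


@dataclass(frozen=True)
class ProtocolSpec:
    """The full interleaved condition set presented once per block."""

    protocol_family: str  # cardinal | radial
    condition_set: tuple[AMSequence, ...]
    blanks_per_block: int
    block_order_seed: int
    rf: RFGeometry
    gabor_template: GaborSpec

    def __post_init__(self) -> None:
        labels = [s.label for s in self.condition_set]
        if len(labels) != len(set(labels)):
            raise ValueError("sequence labels within a protocol must be unique")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_set)

    def entries(self, condition: str | None = None, trajectory: str | None = None):
        out = self.condition_set
        if condition is not None:
            out = tuple(s for s in out if s.condition == condition)
        if trajectory is not None:
            out = tuple(s for s in out if s.trajectory == trajectory)
        return out

    def block_order(self, block: int) -> list[AMSequence]:
        """Seeded random presentation order for one block.

        Every block presents each condition exactly once; blanks are ordinary
        interleaved entries.
        """
        rng = np.random.default_rng([self.block_order_seed, int(block)])
        idx = rng.permutation(len(self.condition_set))
        return [self.condition_set[i] for i in idx]

    def content_hash(self) -> str:
        """Stable hash of the full event table (provenance)."""
        text = protocol_to_table(self).to_csv(index=False)
        return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(angle_deg: float) -> tuple[float, float]:
    a = math.radians(angle_deg)
    return (math.cos(a), math.sin(a))


def _node_position(rf: RFGeometry, angle_deg: float, distance: float) -> tuple[float, float]:
    ux, uy = _unit(angle_deg)
    cx, cy = rf.center_position
    return (cx + distance * ux, cy + distance * uy)


def _seq_events(
    rf: RFGeometry,
    gabor: GaborSpec,
    angle: float,
    distances: Sequence[float],
    labels: Sequence[str],
    isi_ms: float,
    orientation: float,
    contrast: float,
) -> list[StimulusEvent]:
    events = []
    for k, (d, lab) in enumerate(zip(distances, labels)):
        g = replace(gabor, orientation=orientation % 180.0, contrast=contrast)
        events.append(
            StimulusEvent(
                onset_time=k * isi_ms,
                position=_node_position(rf, angle, d),
                gabor=g,
                node_label=lab,
                eccentricity=abs(d),
            )
        )
    return events


# ---------------------------------------------------------------------------
# cardinal protocol
# ---------------------------------------------------------------------------

def build_cardinal_protocol(
    rf: RFGeometry,
    variant: str = "surround_only",
    gabor: GaborSpec | None = None,
    stroke_duration_ms: float = CARDINAL_FRAME_MS,
    surround_contrast: float = DEFAULT_SURROUND_CONTRAST,
    center_contrast: float = DEFAULT_CENTER_CONTRAST,
    block_order_seed: int = 0,
) -> ProtocolSpec:
    """Build the cardinal AM protocol as a fully enumerated condition set.

    ``variant="surround_only"`` yields the 2-stroke Surround-Only study:
    8 flow configurations (CP/CF x ISO/CROSS x main/width axis) x 2 directions
    + Center-Only + Blank = 18 conditions. ``variant="center_surround"``
    yields the 3-stroke full-AM study: 4 configurations x 2 directions +
    Center-Only + Blank = 10 conditions.

    Patch mask length is 150% of the MDF length, the Gaussian envelope sigma
    20% of the mask, and the inter-node distance 120% of the mask length.
    Strokes are frame-locked back to back (one 60 Hz frame each by default).
    """
    if variant not in ("surround_only", "center_surround"):
        raise ValueError(f"unknown cardinal variant {variant!r}")
    mask = 1.5 * rf.mdf_length
    sigma = 0.2 * mask
    spacing = 1.2 * mask
    if gabor is None:
        gabor = GaborSpec()
    gabor = replace(
        gabor, mask_length=mask, envelope_sigma=sigma, duration=stroke_duration_ms
    )
    isi = stroke_duration_ms
    speed = spacing / (isi / 1000.0)

    main = rf.preferred_orientation
    axes = {"main": main, "width": main + 90.0}

    if variant == "surround_only":
        flows = [(f, o) for f in ("CP", "CF") for o in ("ISO", "CROSS")]
        n_surround_strokes = 2
        with_center = False
    else:
        # CP-ISO & CF-ISO along the main axis, CP-CROSS & CF-CROSS along width
        flows = None
        n_surround_strokes = 2
        with_center = True

    sequences: list[AMSequence] = []

    def _make(flow: str, ori_cond: str, axis_name: str, direction: int) -> AMSequence:
        angle = axes[axis_name] + (0.0 if direction > 0 else 180.0)
        # surround nodes D2, D1 at 2x / 1x the inter-node spacing from center
        dists_out_in = [2 * spacing, 1 * spacing]
        labels_out_in = ["D2", "D1"]
        if flow == "CP":
            dists, labels = dists_out_in, labels_out_in
        else:
            dists, labels = dists_out_in[::-1], labels_out_in[::-1]
        # ISO / CROSS defined relative to the chosen AM axis
        ori = axes[axis_name] if ori_cond == "ISO" else axes[axis_name] + 90.0
        if with_center:
            if flow == "CP":
                dists = dists + [0.0]
                labels = labels + ["D0"]
            else:
                dists = [0.0] + dists
                labels = ["D0"] + labels
        events = _seq_events(
            rf, gabor, angle, dists, labels, isi, ori, surround_contrast
        )
        # center stroke uses the preferred orientation at center contrast
        events = [
            replace(
                e,
                gabor=replace(e.gabor, orientation=main % 180.0, contrast=center_contrast),
            )
            if e.node_label == "D0"
            else e
            for e in events
        ]
        cond = f"{flow}-{ori_cond}"
        if with_center:
            center_onset = next(e.onset_time for e in events if e.node_label == "D0")
            traj = "full"
        else:
            traj = "surround_only"
            if flow == "CP":
                center_onset = len(events) * isi  # where the center stroke would follow
            else:
                # centrifugal: the omitted center stroke would have led the flow
                events = [replace(e, onset_time=e.onset_time + isi) for e in events]
                center_onset = 0.0
        return AMSequence(
            condition=cond,
            configuration="CARDINAL_AXIS",
            events=tuple(events),
            nominal_speed=speed,
            trajectory=traj,
            label=f"{cond}|{axis_name}|{'+' if direction > 0 else '-'}|{traj}",
            expected_center_onset_ms=center_onset,
        )

    if variant == "surround_only":
        for flow, ori_cond in flows:
            for axis_name in ("main", "width"):
                for direction in (+1, -1):
                    sequences.append(_make(flow, ori_cond, axis_name, direction))
    else:
        for flow, ori_cond, axis_name in (
            ("CP", "ISO", "main"),
            ("CP", "CROSS", "width"),
            ("CF", "ISO", "main"),
            ("CF", "CROSS", "width"),
        ):
            for direction in (+1, -1):
                sequences.append(_make(flow, ori_cond, axis_name, direction))

    sequences.append(_center_only(rf, gabor, center_contrast, speed))
    sequences.append(_blank("BLANK"))
    return ProtocolSpec(
        protocol_family="cardinal",
        condition_set=tuple(sequences),
        blanks_per_block=1,
        block_order_seed=block_order_seed,
        rf=rf,
        gabor_template=gabor,
    )


def _center_only(rf: RFGeometry, gabor: GaborSpec, contrast: float, speed: float) -> AMSequence:
    g = replace(gabor, orientation=rf.preferred_orientation % 180.0, contrast=contrast)
    ev = StimulusEvent(0.0, rf.center_position, g, "D0", 0.0)
    return AMSequence(
        condition="CENTER_ONLY",
        configuration="CARDINAL_AXIS",
        events=(ev,),
        nominal_speed=speed,
        trajectory="center_only",
        label="CENTER_ONLY",
        expected_center_onset_ms=0.0,
    )


def _blank(label: str, configuration: str = "CARDINAL_AXIS") -> AMSequence:
    return AMSequence(
        condition="BLANK",
        configuration=configuration,
        events=(),
        nominal_speed=0.0,
        trajectory="blank",
        label=label,
        expected_center_onset_ms=0.0,
    )


# ---------------------------------------------------------------------------
# radial protocol
# ---------------------------------------------------------------------------

def build_radial_protocol(
    rf: RFGeometry,
    gabor: GaborSpec | None = None,
    rings: int = 5,
    sector_halfwidth: float = 30.0,
    angular_offsets: Sequence[float] = (-30.0, -15.0, 0.0, 15.0, 30.0),
    stroke_duration_ms: float = 30.0,
    ring_spacing: float | None = None,
    surround_contrast: float = DEFAULT_SURROUND_CONTRAST,
    center_contrast: float = DEFAULT_CENTER_CONTRAST,
    n_blanks: int = 6,
    seed: int = 0,
) -> ProtocolSpec:
    """Build the radial AM protocol (43 stimulation entries per block).

    The visual field is paved with ``rings`` concentric rings of increasing
    eccentricity, spaced by the SRF extent so no peripheral node overlaps the
    SRF. The block content is 16 AM sequences (4 conditions x 2 trajectories
    x 2 configurations), 21 isolated-GP stimulations (5 peripheral ring
    locations x 2 inducer-orientation conditions x 2 configurations + 1
    center GP), and 6 blanks.
    """
    if rings < 2:
        raise InvalidGeometryError("radial protocol needs at least 2 rings")
    spacing = rf.srf_extent if ring_spacing is None else ring_spacing
    if spacing < rf.srf_extent - 1e-9:
        raise InvalidGeometryError(
            f"ring spacing {spacing:g} deg would place D1 inside the SRF "
            f"(extent {rf.srf_extent:g} deg)"
        )
    mask = rf.srf_extent
    if gabor is None:
        gabor = GaborSpec()
    gabor = replace(
        gabor, mask_length=mask, envelope_sigma=0.2 * mask, duration=stroke_duration_ms
    )
    isi = stroke_duration_ms
    speed = spacing / (isi / 1000.0)
    main = rf.preferred_orientation

    offs = [o for o in angular_offsets if abs(o) <= sector_halfwidth + 1e-9]
    sector_angles = [main + o for o in offs] + [main + 180.0 + o for o in offs]
    full_angles = [30.0 * k for k in range(12)]
    config_angles = {"SECTOR": sector_angles, "FULL": full_angles}

    def _ring_stroke(
        config: str, ring: int, onset: float, ori_cond: str
    ) -> list[StimulusEvent]:
        events = []
        for ang in config_angles[config]:
            # ISO: inducer co-aligned with its radial motion axis; CROSS: orthogonal
            ori = ang if ori_cond == "ISO" else ang + 90.0
            g = replace(gabor, orientation=ori % 180.0, contrast=surround_contrast)
            events.append(
                StimulusEvent(
                    onset_time=onset,
                    position=_node_position(rf, ang, ring * spacing),
                    gabor=g,
                    node_label=f"D{ring}",
                    eccentricity=ring * spacing,
                )
            )
        return events

    def _center_event(onset: float) -> StimulusEvent:
        g = replace(gabor, orientation=main % 180.0, contrast=center_contrast)
        return StimulusEvent(onset, rf.center_position, g, "D0", 0.0)

    sequences: list[AMSequence] = []
    ring_ids = list(range(rings, 0, -1))  # D5 .. D1 (centripetal order)
    rng = np.random.default_rng([seed, 0xAD])

    for config in ("SECTOR", "FULL"):
        for cond in ("CP-ISO", "CF-ISO", "CP-CROSS", "RND-ISO"):
            ori_cond = "CROSS" if cond.endswith("CROSS") else "ISO"
            for traj in ("full", "surround_only"):
                if cond.startswith("CP") or cond == "RND-ISO":
                    order = ring_ids
                else:  # CF: time-reversal of the centripetal flow
                    order = ring_ids[::-1]
                events: list[StimulusEvent] = []
                if cond == "CF-ISO":
                    # center (shown or omitted) leads the centrifugal flow
                    if traj == "full":
                        events.append(_center_event(0.0))
                    offset = isi
                    center_onset = 0.0
                else:
                    offset = 0.0
                    center_onset = len(order) * isi
                for k, ring in enumerate(order):
                    events.extend(_ring_stroke(config, ring, offset + k * isi, ori_cond))
                if traj == "full" and cond != "CF-ISO":
                    events.append(_center_event(offset + len(order) * isi))
                seq = AMSequence(
                    condition=cond,
                    configuration=config,
                    events=tuple(events),
                    nominal_speed=speed,
                    trajectory=traj,
                    label=f"{cond}|{config}|{traj}",
                    expected_center_onset_ms=center_onset,
                )
                if cond == "RND-ISO":
                    seq = randomize_sequence(seq, int(rng.integers(2**31)))
                sequences.append(seq)

    # isolated Gabor stimulations: 5 peripheral ring locations x ISO/CROSS x config
    for config in ("SECTOR", "FULL"):
        for ori_cond in ("ISO", "CROSS"):
            for ring in range(1, rings + 1):
                events = tuple(_ring_stroke(config, ring, 0.0, ori_cond))
                sequences.append(
                    AMSequence(
                        condition="ISOLATED",
                        configuration=config,
                        events=events,
                        nominal_speed=speed,
                        trajectory="isolated",
                        label=f"ISOLATED-{ori_cond}-D{ring}|{config}",
                        expected_center_onset_ms=ring * isi,
                    )
                )
    sequences.append(
        AMSequence(
            condition="CENTER_ONLY",
            configuration="SECTOR",
            events=(_center_event(0.0),),
            nominal_speed=speed,
            trajectory="center_only",
            label="CENTER_ONLY",
            expected_center_onset_ms=0.0,
        )
    )
    for b in range(n_blanks):
        sequences.append(_blank(f"BLANK-{b + 1}", configuration="SECTOR"))
    return ProtocolSpec(
        protocol_family="radial",
        condition_set=tuple(sequences),
        blanks_per_block=n_blanks,
        block_order_seed=seed,
        rf=rf,
        gabor_template=gabor,
    )


# ---------------------------------------------------------------------------
# speed operations
# ---------------------------------------------------------------------------

def sequence_speed(seq: AMSequence) -> float:
    """AM flow speed in deg/s: inter-node distance over inter-stroke interval."""
    groups = seq.stroke_groups()
    eccs = seq.stroke_eccentricities()
    onsets = np.array([t for t, _ in groups])
    if len(groups) < 2 or np.allclose(eccs, eccs[0]):
        raise ValueError("sequence needs >= 2 strokes at distinct positions")
    d_ecc = np.abs(np.diff(eccs))
    d_t = np.diff(onsets) / 1000.0
    keep = d_ecc > 1e-12
    return float(np.mean(d_ecc[keep] / d_t[keep]))


def scale_speed(seq: AMSequence, fraction: float) -> AMSequence:
    """Replay a sequence at ``fraction`` of its nominal speed.

    Inter-stroke delays are stretched by 1/fraction while stroke durations
    are left unchanged (slow-motion chronograms). ``fraction`` must lie in
    (0, 1]; ``fraction=1.0`` is the identity on onset times.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("speed fraction must lie in (0, 1]")
    if fraction == 1.0:
        return replace(seq, speed_fraction=1.0)
    t0 = seq.events[0].onset_time if seq.events else 0.0
    events = tuple(
        replace(e, onset_time=t0 + (e.onset_time - t0) / fraction) for e in seq.events
    )
    return replace(
        seq,
        events=events,
        speed_fraction=fraction,
        label=f"{seq.label}@{int(round(fraction * 100))}%",
        expected_center_onset_ms=t0 + (seq.expected_center_onset_ms - t0) / fraction,
    )


def randomize_sequence(seq: AMSequence, seed: int) -> AMSequence:
    """Scramble the spatial order of the surround strokes of an AM sequence.

    Each surround location is visited exactly once, on the original onset
    grid, so stroke count, stroke durations and the total stimulus energy all
    match the template; in full sequences the last event stays at the RF
    center (D0). Deterministic for a given ``seed``.
    """
    groups = seq.stroke_groups()
    if not groups:
        raise ValueError("cannot randomize an empty sequence")
    surround = [(t, g) for t, g in groups if not any(e.node_label == "D0" for e in g)]
    center = [(t, g) for t, g in groups if any(e.node_label == "D0" for e in g)]
    rng = np.random.default_rng(seed)
    onsets = [t for t, _ in surround]
    perm = rng.permutation(len(surround))
    events: list[StimulusEvent] = []
    for slot, j in enumerate(perm):
        _, group = surround[j]
        events.extend(replace(e, onset_time=onsets[slot]) for e in group)
    for t, group in center:
        events.extend(group)
    events.sort(key=lambda e: e.onset_time)
    return replace(seq, condition="RND-ISO", events=tuple(events))


# ---------------------------------------------------------------------------
# event-table export
# ---------------------------------------------------------------------------

def protocol_to_table(protocol: ProtocolSpec, n_blocks: int = 1) -> pd.DataFrame:
    """Flatten a protocol into the standard stimulus event table.

    Columns: trial, block, condition, configuration, stroke_index, node_label,
    onset_ms, duration_ms, x_deg, y_deg, orientation_deg, sf_cpd, phase_deg,
    contrast.
    """
    rows = []
    trial = 0
    for block in range(n_blocks):
        for seq in protocol.block_order(block):
            if not seq.events:
                rows.append(
                    dict(
                        trial=trial, block=block, condition=seq.condition,
                        configuration=seq.configuration, stroke_index=-1,
                        node_label="", onset_ms=np.nan, duration_ms=np.nan,
                        x_deg=np.nan, y_deg=np.nan, orientation_deg=np.nan,
                        sf_cpd=np.nan, phase_deg=np.nan, contrast=np.nan,
                    )
                )
            stroke_of_onset = {t: k for k, t in enumerate(seq.stroke_onsets())}
            for e in seq.events:
                rows.append(
                    dict(
                        trial=trial, block=block, condition=seq.condition,
                        configuration=seq.configuration,
                        stroke_index=stroke_of_onset[e.onset_time],
                        node_label=e.node_label, onset_ms=e.onset_time,
                        duration_ms=e.gabor.duration, x_deg=e.position[0],
                        y_deg=e.position[1], orientation_deg=e.gabor.orientation,
                        sf_cpd=e.gabor.spatial_frequency, phase_deg=e.gabor.phase,
                        contrast=e.gabor.contrast,
                    )
                )
            trial += 1
    return pd.DataFrame(rows)
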