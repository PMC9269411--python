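import numpy as np
import pytest

from amsurround.stimuli import (
    AMSequence,
    GaborSpec,
    RFGeometry,
    StimulusEvent,
    build_radial_protocol,
)
from amsurround.synth import GeneratorParams


@pytest.fixture(scope="session")
def rf() -> RFGeometry:
    return RFGeometry(mdf_length=2.0, mdf_width=1.0, srf_extent=5.0)


@pytest.fixture(scope="session")
def radial_protocol(rf):
    return build_radial_protocol(rf)


@pytest.fixture(scope="session")
def quiet_params() -> GeneratorParams:
    """Noise-free, non-spiking generator (deterministic subthreshold limit)."""
    return GeneratorParams(
        noise_sigma=1e-12, spike_amplitude=0.0, spike_threshold=1e9
    )


@pytest.fixture
def blank_entry() -> AMSequence:
    return AMSequence(
        condition="BLANK", configuration="SECTOR", events=(), nominal_speed=0.0,
        trajectory="blank", label="BLANK-1",
    )


def make_isolated_entry(ecc: float, duration_ms: float = 30.0) -> AMSequence:
    """Single surround Gabor flashed in isolation at a given eccentricity."""
    g = GaborSpec(duration=duration_ms, contrast=0.925)
    ev = StimulusEvent(0.0, (ecc, 0.0), g, "D1", ecc)
    return AMSequence(
        condition="ISOLATED", configuration="SECTOR", events=(ev,),
        nominal_speed=100.0, trajectory="isolated", label=f"iso-{ecc}",
        expected_center_onset_ms=0.0,
    )
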