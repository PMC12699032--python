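import numpy as np
import pytest

from amodehmi.io_core import (
    AcquisitionConfig,
    CircleFrame,
    MarkerTrajectory,
    RawFrame,
    Recording,
    RecordingMeta,
)

# A small acquisition geometry for fast unit tests: 40 samples per line,
# same structure as the full 5500-sample configuration.
SMALL = dict(sampling_rate=4.0e6, window=10e-6, trim_samples=8,
             band=(0.4e6, 1.6e6), decimation=2)


@pytest.fixture(scope="session")
def small_config() -> AcquisitionConfig:
    return AcquisitionConfig(**SMALL)


@pytest.fixture(scope="session")
def default_config() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture()
def unique_frame() -> CircleFrame:
    """16x16x4 frame whose every element is distinct (index oracles)."""
    amps = np.arange(16 * 16 * 4).reshape(16, 16, 4).astype(np.int16)
    return CircleFrame(amps, ring_id=0, timestamp=0.5)


@pytest.fixture()
def raw_frame(rng) -> RawFrame:
    amps = rng.integers(-2048, 2048, size=(32, 32, 8), dtype=np.int16)
    return RawFrame(amps, timestamp=0.0)


@pytest.fixture()
def small_recording(rng, small_config) -> Recording:
    S = small_config.samples_per_line
    meta = RecordingMeta(participant_id="P01", session=1, position=2,
                         rotation=90, video_set="wrist",
                         rom={"flexion_extension": (-60.0, 60.0)})
    frames = [
        CircleFrame(rng.integers(-2048, 2048, size=(16, 16, S), dtype=np.int16),
                    ring_id=0, timestamp=0.1 * i)
        for i in range(3)
    ]
    return Recording(meta=meta, frames=frames)


def straight_line_trajectory(T: int = 50, velocity=(1.0, -2.0, 0.5)) -> MarkerTrajectory:
    """All 10 markers translating uniformly (for gap-fill oracles)."""
    t = np.arange(T) / 200.0
    base = np.arange(10)[None, :, None] * 10.0
    pos = base + np.asarray(velocity)[None, None, :] * t[:, None, None] * 100.0
    return MarkerTrajectory(positions=pos, missing_mask=np.zeros((T, 10), bool))
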