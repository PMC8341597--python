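import numpy as np
import pytest

from ivusseg import LabelMask, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sim_config():
    """Desk-scale simulation: few patients, 64x64 frames, 5.12-mm field of view."""
    return SimConfig(
        n_patients=4,
        frames_per_patient=8,
        image_size=64,
        pixel_spacing=0.08,
        rng_seed=42,
    )


def random_mask(rng: np.random.Generator, size: int = 64, spacing: float = 0.02) -> LabelMask:
    """Uniformly random five-class mask (no geometric structure)."""
    return LabelMask(rng.integers(0, 5, size=(size, size), dtype=np.int64).astype(np.uint8), spacing)
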