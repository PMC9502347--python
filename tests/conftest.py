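import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from dermaquant.synthgen import GeneratorParams, generate_section_image


@pytest.fixture
def clean_params() -> GeneratorParams:
    """Noise-free, dye-free, flat-surface render parameters."""
    return GeneratorParams(
        surface_roughness_px=0.0,
        noise_sd=0.0,
        dye_amount=0.0,
        hotspot_density=0.0,
        background_level=0.0,
    )


@pytest.fixture
def default_image():
    """One default dye-laden render plus its ground truth."""
    return generate_section_image(GeneratorParams(), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
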