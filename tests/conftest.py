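import numpy as np
import pytest

from sgscreen import simulate


@pytest.fixture
def small_field():
    """A 10-cell noiseless field with one punctum per positive cell."""
    spec = simulate.ImageSpec(
        width_px=256,
        height_px=256,
        n_cells=10,
        read_noise_sd=0.0,
        sg_positive_fraction=0.5,
        puncta_per_positive_cell=(1, 1),
        seed=42,
    )
    return simulate.generate_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
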