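import numpy as np
import pytest

from mirnca import (
    TimeGrid,
    generate_expression,
    generate_ground_truth,
)


@pytest.fixture
def small_truth():
    """Tiny noiseless planted system (L=3, N=12, M=8)."""
    grid = TimeGrid(tuple(float(t) for t in np.linspace(0, 4320, 8)))
    return generate_ground_truth(
        n_regulators=3, n_targets=12, grid=grid, noise_sd=0.0, seed=42
    )


@pytest.fixture
def small_expression(small_truth):
    return generate_expression(small_truth)


@pytest.fixture
def default_truth():
    """Default-scale system (L=10, N=120, M=17), noiseless."""
    return generate_ground_truth(noise_sd=0.0, seed=7)
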