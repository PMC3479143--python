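import numpy as np
import pytest

from mrsisep import (
    Ellipse,
    PhantomConfig,
    SpectralAxis,
    VoxelGrid,
    generate_phantom,
    nontumor_template,
    render_source,
    tumor_template,
)


def min_normalized_peak_amplitude(axis: SpectralAxis | None = None) -> float:
    """Smallest template peak amplitude expressed in the unit-norm
    intensity scale the phantom mixes in."""
    axis = axis or SpectralAxis.default()
    amp = np.inf
    for tpl in (tumor_template(), nontumor_template()):
        norm = np.linalg.norm(render_source(tpl, axis))
        amp = min(amp, tpl.min_abs_amplitude / norm)
    return float(amp)


@pytest.fixture(scope="session")
def phantom_clean():
    """Default noiseless 10x10, 692-point LTE phantom."""
    return generate_phantom()


@pytest.fixture(scope="session")
def phantom_noisy():
    """Default phantom with noise at 10% of the minimum peak amplitude."""
    sd = 0.1 * min_normalized_peak_amplitude()
    return generate_phantom(PhantomConfig(noise_sd=sd, seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced phantom (8x8 grid, 200 points) for IO/CLI round trips."""
    return generate_phantom(PhantomConfig(
        grid=VoxelGrid(8, 8),
        axis=SpectralAxis.default(n=200),
        tumor_region=Ellipse(3.5, 3.5, 2.0, 2.5),
        seed=2,
    ))
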