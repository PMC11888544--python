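import numpy as np
import pytest

from elite_mri.phantom import make_phantom, generate_dynamic_phantom
from elite_mri.pkm import standard_aif
from elite_mri.encoding import make_encoding_spec, simulate_kspace
from elite_mri.series import DynamicImageSeries


@pytest.fixture(scope="session")
def small_phantom():
    """Fast 48x48, 2-coil, 12-frame phantom shared across tests."""
    tg = (np.arange(12) + 0.5) * (150.0 / 12)
    return make_phantom(48, 48, time_grid=tg, n_coils=2, seed=3)


@pytest.fixture(scope="session")
def small_aif(small_phantom):
    return standard_aif(small_phantom.time_grid, onset=30.0)


@pytest.fixture(scope="session")
def small_truth(small_phantom, small_aif):
    return generate_dynamic_phantom(small_phantom, small_aif)


@pytest.fixture(scope="session")
def small_spec(small_phantom):
    return make_encoding_spec((48, 48), small_phantom.coils, 48, 4)


@pytest.fixture(scope="session")
def small_kspace(small_truth, small_spec):
    complex_truth = DynamicImageSeries(
        small_truth.data.astype(complex), small_truth.frame_times
    )
    clean = small_spec.forward(complex_truth)
    sigma = 0.02 * float(np.sqrt(np.mean(np.abs(clean.data) ** 2)))
    return simulate_kspace(complex_truth, small_spec, noise_sigma=sigma, seed=7)


@pytest.fixture(scope="session")
def full_benchmark():
    """The fixed-seed 160x160 / 8-coil / 8-spokes-per-frame comparison."""
    from elite_mri.benchmark import run_benchmark

    return run_benchmark(seed=1)
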