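import numpy as np
import pytest

from elite_mri.encoding import (
    GOLDEN_ANGLE_DEG,
    MultiCoilKSpace,
    bin_spokes,
    density_compensation,
    golden_angle_trajectory,
    lowres_subset,
    make_encoding_spec,
    simulate_kspace,
    temporal_resolution,
)
from elite_mri.phantom import simulate_coils
from elite_mri.series import DynamicImageSeries


def test_golden_angle_increment():
    traj = golden_angle_trajectory(10, 64)
    inc = np.rad2deg(np.diff(np.unwrap(traj.angles * 2) / 2))
    # consecutive spokes differ by the golden angle modulo 180 degrees
    assert np.allclose(inc % 180.0, GOLDEN_ANGLE_DEG % 180.0, atol=1e-9)
    assert traj.coords.shape == (10, 64, 2)
    # every spoke passes through k = 0
    assert np.allclose(traj.coords[:, 32, :], 0.0)
    # extreme radius is at the edge of the unit k-space square
    assert np.isclose(np.abs(traj.radii).max(), 0.5)
    with pytest.raises(ValueError):
        golden_angle_trajectory(4, 63)


def test_density_compensation_ramp():
    traj = golden_angle_trajectory(5, 32)
    w = density_compensation(traj)
    assert w.shape == (5, 32)
    assert np.all(w > 0)
    assert np.isclose(w.mean(), 1.0)
    # weights grow linearly with |k| away from the centre
    r = np.abs(traj.radii)
    outer = r > 0.1
    ratio = w[0, outer] / r[outer]
    assert np.allclose(ratio, ratio[0])


def test_bin_spokes_edge_cases():
    assert np.array_equal(bin_spokes(6, 2), [0, 0, 1, 1, 2, 2])
    assert np.array_equal(bin_spokes(7, 2), [0, 0, 1, 1, 2, 2, -1])
    with pytest.raises(ValueError):
        bin_spokes(4, 0)
    with pytest.raises(ValueError):
        bin_spokes(4, 5)
    assert np.isclose(temporal_resolution(150.0, 300, 10), 5.0)


def test_kspace_validation():
    traj = golden_angle_trajectory(4, 16)
    data = np.zeros((1, 4, 16), dtype=complex)
    ksp = MultiCoilKSpace(data, traj, bin_spokes(4, 2))
    assert ksp.n_coils == 1 and ksp.n_frames == 2
    with pytest.raises(ValueError):
        MultiCoilKSpace(np.zeros((4, 16)), traj, bin_spokes(4, 2))
    with pytest.raises(ValueError):
        MultiCoilKSpace(data, traj, np.array([1, 0, 0, 1]))


def _small_spec(h=24, n_spokes=8, spf=4, n_coils=2, seed=0):
    coils = simulate_coils(h, h, n_coils)
    return make_encoding_spec((h, h), coils, n_spokes, spf)


def test_forward_linearity_and_adjoint_shapes():
    spec = _small_spec()
    rng = np.random.default_rng(0)
    x = DynamicImageSeries(rng.standard_normal((2, 24, 24)))
    y = spec.forward(x)
    assert y.data.shape == (2, 8, 48)
    # linearity
    x2 = DynamicImageSeries(2.0 * x.data)
    assert np.allclose(spec.forward(x2).data, 2.0 * y.data)
    back = spec.adjoint(y)
    assert back.data.shape == (2, 24, 24)


def test_simulate_kspace_noise_statistics():
    spec = _small_spec()
    x = DynamicImageSeries(np.ones((2, 24, 24)))
    clean = simulate_kspace(x, spec, noise_sigma=0.0)
    noisy = simulate_kspace(x, spec, noise_sigma=0.5, seed=1)
    resid = noisy.data - clean.data
    assert np.isclose(np.std(resid), 0.5, rtol=0.1)
    # determinism of the seed
    noisy2 = simulate_kspace(x, spec, noise_sigma=0.5, seed=1)
    assert np.array_equal(noisy.data, noisy2.data)
    with pytest.raises(ValueError):
        simulate_kspace(x, spec, noise_sigma=-1.0)


def test_dc_sample_measures_image_sum():
    """The k = 0 sample of a single-coil spoke is proportional to the image
    sum with a gain independent of spoke angle and image content."""
    h = 24
    coils = simulate_coils(h, h, 1)
    coils.maps[:] = 1.0
    spec = make_encoding_spec((h, h), coils, 6, 6)
    rng = np.random.default_rng(2)
    img = rng.standard_normal((1, h, h))
    y = spec.forward(DynamicImageSeries(img))
    centre = y.data.shape[2] // 2
    dc = y.data[0, :, centre] / np.sqrt(y.density_weights[:, centre])
    assert np.allclose(dc, dc[0], rtol=1e-6)
    img2 = rng.standard_normal((1, h, h))
    y2 = spec.forward(DynamicImageSeries(img2))
    dc2 = y2.data[0, 0, centre] / np.sqrt(y2.density_weights[0, centre])
    gain1 = dc[0] / img.sum()
    gain2 = dc2 / img2.sum()
    assert np.isclose(gain1, gain2, rtol=1e-2)


def test_lowres_subset_keeps_centre():
    spec = _small_spec(h=32, n_spokes=12, spf=4)
    rng = np.random.default_rng(3)
    x = DynamicImageSeries(rng.standard_normal((3, 32, 32)))
    ksp = spec.forward(x)
    sub, coils_lr = lowres_subset(ksp, 16, spec.coils)
    assert np.abs(sub.trajectory.radii).max() <= 0.5 + 1e-12
    assert sub.data.shape[2] == np.sum(np.abs(ksp.trajectory.radii) <= 16 / 64 * 0.5 + 1e-12)
    assert coils_lr.maps.shape == (2, 16, 16)
    with pytest.raises(ValueError):
        lowres_subset(ksp, 15)
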