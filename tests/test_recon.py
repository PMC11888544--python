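import numpy as np
import pytest

from elite_mri.encoding import make_encoding_spec, simulate_kspace
from elite_mri.phantom import simulate_coils
from elite_mri.recon import (
    ReconConfig,
    SubspaceCoefficients,
    TemporalBasis,
    compress,
    estimate_basis,
    expand,
    grasp_recon,
    kmeans_partition,
    nufft_recon,
    subspace_recon,
    temporal_diff,
    temporal_diff_adjoint,
)
from elite_mri.regions import partition_blocks, partition_from_labels, whole_image_partition
from elite_mri.series import DynamicImageSeries, nrmse


def test_recon_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(lam=-0.1)
    with pytest.raises(ValueError):
        ReconConfig(n_iter=0)
    with pytest.raises(ValueError):
        ReconConfig(K=0)


def test_temporal_diff_and_adjoint():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((5, 3, 3)) + 1j * rng.standard_normal((5, 3, 3))
    d = temporal_diff(x)
    assert d.shape == (4, 3, 3)
    assert np.allclose(d, x[1:] - x[:-1])
    y = rng.standard_normal(d.shape) + 1j * rng.standard_normal(d.shape)
    lhs = np.vdot(y, temporal_diff(x))
    rhs = np.vdot(temporal_diff_adjoint(y), x)
    assert abs(lhs - rhs) < 1e-10 * abs(lhs)


def test_temporal_basis_requires_orthonormal_columns():
    with pytest.raises(ValueError):
        TemporalBasis(bases=[np.ones((4, 2))])
    q, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((6, 3)))
    TemporalBasis(bases=[q])  # valid


def test_compress_expand_identity_for_low_rank_data():
    """Rank-K Casorati data are represented exactly by a K-component basis."""
    rng = np.random.default_rng(2)
    t, h, w, k = 10, 8, 8, 3
    u = np.linalg.qr(rng.standard_normal((t, k)))[0]
    v = rng.standard_normal((k, h * w))
    data = (u @ v).reshape(t, h, w)
    part = whole_image_partition(h, w)
    basis = estimate_basis(DynamicImageSeries(data), part, ReconConfig(K=k))
    coeffs = compress(DynamicImageSeries(data), basis, part)
    back = expand(basis, coeffs, part)
    assert nrmse(back.data, data) < 1e-10


def test_expand_averages_overlapping_blocks():
    part = partition_blocks(8, 8, block_grid=2, overlap_fraction=0.5)
    t = 4
    # per-block bases whose first column is the constant mode, so a constant
    # image is representable exactly in every block and the overlap averaging
    # in expand() must return it unchanged
    bases = []
    for i in range(part.n_regions):
        m = np.random.default_rng(i).standard_normal((t, 2))
        m[:, 0] = 1.0
        bases.append(np.linalg.qr(m)[0])
    basis = TemporalBasis(bases=bases)
    ones = DynamicImageSeries(np.ones((t, 8, 8)))
    coeffs = compress(ones, basis, part)
    back = expand(basis, coeffs, part)
    assert np.allclose(back.data, 1.0, atol=1e-10)


def test_estimate_basis_region_sizes_and_warning():
    labels = np.zeros((6, 6), dtype=np.int16)
    labels[0, 0] = 1  # one-pixel region, smaller than K
    part = partition_from_labels(labels, ["background", "tiny"])
    data = np.random.default_rng(3).standard_normal((8, 6, 6))
    with pytest.warns(UserWarning):
        basis = estimate_basis(DynamicImageSeries(data), part, ReconConfig(K=4))
    assert basis.bases[0].shape == (8, 1)  # background gets K_background = 1
    assert basis.bases[1].shape == (8, 1)  # reduced to region size


def _toy_problem(seed=0):
    h, t = 24, 3
    coils = simulate_coils(h, h, 2)
    spokes_per_frame = 38  # ~Nyquist for 24 pixels
    spec = make_encoding_spec((h, h), coils, spokes_per_frame * t, spokes_per_frame)
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.standard_normal((h, h)), 1.5)
    truth = np.stack([base * (1 + 0.2 * i) for i in range(t)])
    ksp = simulate_kspace(DynamicImageSeries(truth), spec, noise_sigma=0.0)
    return truth, ksp, spec


def test_nufft_recon_recovers_fully_sampled_object():
    truth, ksp, spec = _toy_problem()
    rec = nufft_recon(ksp, spec)
    assert rec.data.shape == truth.shape
    assert nrmse(np.abs(rec.data), np.abs(truth)) < 0.15


def test_grasp_beats_gridding_and_trace_monotone():
    truth, ksp, spec = _toy_problem()
    grid = nufft_recon(ksp, spec)
    rec, trace = grasp_recon(ksp, spec, ReconConfig(lam=0.001, n_iter=6, n_repeat=2),
                             return_trace=True)
    assert np.all(np.diff(trace) <= 1e-9 * trace[0])
    assert nrmse(np.abs(rec.data), np.abs(truth)) < nrmse(np.abs(grid.data), np.abs(truth))


def test_subspace_recon_glr_matches_grasp_with_full_basis():
    """With K = T the whole-image subspace is unconstrained, so GLR with the
    data-derived basis reaches the same objective as unconstrained GRASP."""
    truth, ksp, spec = _toy_problem()
    cfg = ReconConfig(lam=0.001, n_iter=6, n_repeat=2, K=truth.shape[0])
    part = whole_image_partition(*truth.shape[1:])
    lowres = spec.adjoint(ksp)
    basis = estimate_basis(lowres, part, cfg, background_region="__none__")
    rec_sub, tr_sub = subspace_recon(ksp, spec, basis, part, cfg, return_trace=True)
    _, tr_grasp = grasp_recon(ksp, spec, cfg, return_trace=True)
    assert tr_sub[-1] <= tr_grasp[-1] * 1.05


def test_grasp_rejects_nonfinite_data():
    _, ksp, spec = _toy_problem()
    ksp.data[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        grasp_recon(ksp, spec)


def test_kmeans_partition_separates_distinct_dynamics():
    t = 12
    data = np.zeros((t, 10, 10))
    ramp = np.linspace(0, 1, t)
    data[:, :, :5] = ramp[:, None, None]
    data[:, :, 5:] = 1.0 - ramp[:, None, None]
    part = kmeans_partition(DynamicImageSeries(data), 2, seed=0)
    assert part.n_regions == 2
    a = part.indices(0)
    # each cluster is exactly one half of the image
    assert a.size == 50
    cols = a % 10
    assert np.all(cols < 5) or np.all(cols >= 5)
    with pytest.raises(ValueError):
        kmeans_partition(DynamicImageSeries(data), 1)
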