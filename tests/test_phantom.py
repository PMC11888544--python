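import numpy as np
import pytest

from elite_mri.phantom import (
    RISE_TIME_DICTIONARY,
    TissueKinetics,
    TissueParams,
    default_kinetics,
    generate_dynamic_phantom,
    make_label_map,
    make_phantom,
    sample_rise_times,
    simulate_coils,
    tissue_curve,
)
from elite_mri.pkm import standard_aif


def test_label_map_has_six_regions():
    part = make_label_map(64, 64, seed=0)
    assert part.n_regions == 6
    assert set(part.region_names) == {
        "background",
        "lesion",
        "fibroglandular",
        "muscle",
        "skin",
        "heart",
    }
    # every pixel belongs to exactly one region
    sizes = [part.indices(i).size for i in range(part.n_regions)]
    assert sum(sizes) == 64 * 64
    assert all(s > 0 for s in sizes)
    with pytest.raises(ValueError):
        make_label_map(16, 16)


def test_label_map_seed_moves_lesion():
    a = make_label_map(64, 64, seed=0)
    b = make_label_map(64, 64, seed=5)
    ia = a.region_names.index("lesion")
    ib = b.region_names.index("lesion")
    assert not np.array_equal(a.indices(ia), b.indices(ib))
    # but the same seed reproduces exactly
    c = make_label_map(64, 64, seed=0)
    assert np.array_equal(a.label_map, c.label_map)


def test_tissue_params_validation():
    with pytest.raises(ValueError):
        TissueParams(-1.0, 1.0, 10.0)
    with pytest.raises(ValueError):
        TissueParams(1.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        TissueKinetics({"background": TissueParams(0.0, 1.0, 10.0)})


def test_rise_time_sampling_within_dictionary():
    names = list(RISE_TIME_DICTIONARY)
    rises = sample_rise_times(names, RISE_TIME_DICTIONARY, seed=11)
    for name in names:
        lo, hi = RISE_TIME_DICTIONARY[name]
        assert lo <= rises[name] <= hi
    assert rises == sample_rise_times(names, RISE_TIME_DICTIONARY, seed=11)
    assert rises != sample_rise_times(names, RISE_TIME_DICTIONARY, seed=12)


def test_coil_maps_smooth_and_normalized():
    coils = simulate_coils(48, 48, 6)
    assert coils.n_coils == 6
    rss = coils.rss()
    assert rss.min() > 0.1 and rss.max() < 5.0
    # smoothness: adjacent-pixel variation is small relative to magnitude
    diff = np.abs(np.diff(coils.maps, axis=1)).max()
    assert diff < 0.2


def test_tissue_curve_shape_and_monotone_washin():
    aif = standard_aif(np.linspace(0.0, 150.0, 60), onset=30.0)
    params = default_kinetics().tissues["lesion"]
    curve = tissue_curve(params, aif)
    assert curve.shape == aif.t.shape
    # peak-normalized enhancement: zero before onset, unit maximum
    pre = aif.t < 30.0
    assert np.allclose(curve[pre], 0.0)
    assert np.isclose(curve.max(), 1.0)
    assert np.all(curve >= 0.0)


def test_generate_dynamic_phantom_structure():
    ph = make_phantom(height=48, n_coils=2, seed=3,
                      time_grid=np.linspace(2.0, 150.0, 12))
    aif = standard_aif(ph.time_grid, onset=30.0)
    truth = generate_dynamic_phantom(ph, aif)
    assert truth.data.shape == (12, 48, 48)
    # background stays exactly zero
    bg = ph.partition.region_names.index("background")
    idx = ph.partition.indices(bg)
    flat = truth.data.reshape(12, -1)
    assert np.allclose(flat[:, idx], 0.0)
    # enhancing tissues rise after onset
    lz = ph.partition.indices(ph.partition.region_names.index("lesion"))
    lesion = flat[:, lz].mean(axis=1)
    assert lesion[-1] > 1.5 * lesion[0]
    # deterministic regeneration
    truth2 = generate_dynamic_phantom(ph, aif)
    assert np.array_equal(truth.data, truth2.data)


def test_heterogeneity_adds_intra_tissue_variation():
    grid = np.linspace(2.0, 150.0, 6)
    aif = standard_aif(grid, onset=30.0)
    smooth = make_phantom(height=48, n_coils=1, seed=3, time_grid=grid,
                          heterogeneity=0.0)
    rough = make_phantom(height=48, n_coils=1, seed=3, time_grid=grid,
                         heterogeneity=0.1)
    fz = smooth.partition.indices(
        smooth.partition.region_names.index("fibroglandular"))
    a = generate_dynamic_phantom(smooth, aif).data.reshape(6, -1)[:, fz]
    b = generate_dynamic_phantom(rough, aif).data.reshape(6, -1)[:, fz]
    # heterogeneity perturbs the enhancement amplitude, so variation shows
    # up after contrast arrival, not at baseline
    assert np.std(a[-1]) < 1e-12
    assert np.std(b[0]) < 1e-12
    assert np.std(b[-1]) > 1e-3
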