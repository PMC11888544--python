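import numpy as np
import pytest

from elite_mri.metrics import (
    MetricsReport,
    ROISet,
    background_noise,
    cnr,
    curve_similarity,
    evaluate_series,
    fold_change,
    peak_lesion_frame,
    rois_from_partition,
)
from elite_mri.phantom import make_label_map
from elite_mri.series import DynamicImageSeries


def _toy_rois(h=16):
    lesion = np.zeros((h, h), dtype=bool)
    fibro = np.zeros((h, h), dtype=bool)
    lesion[6:8, 6:8] = True
    fibro[10:12, 10:12] = True
    return ROISet(lesion=lesion, fibroglandular=fibro,
                  background_rects=[(0, 3, 0, 3), (0, 3, 13, 16)])


def test_roiset_validation():
    with pytest.raises(ValueError):
        ROISet(np.zeros((4, 4), bool), np.ones((4, 4), bool), [(0, 1, 0, 1)])
    m = np.zeros((4, 4), bool)
    m[0, 0] = True
    with pytest.raises(ValueError):
        ROISet(m, m, [(0, 1, 0, 1)])  # overlapping masks
    with pytest.raises(ValueError):
        ROISet(m, ~m, [])  # no background rects


def test_cnr_hand_computed():
    rois = _toy_rois()
    img = np.zeros((1, 16, 16))
    img[0][rois.lesion] = 5.0
    img[0][rois.fibroglandular] = 2.0
    s = DynamicImageSeries(img.repeat(2, axis=0))
    assert cnr(s, rois, 0, noise_sd=1.5) == pytest.approx((5.0 - 2.0) / 1.5)
    with pytest.raises(ValueError):
        cnr(s, rois, 0, noise_sd=0.0)


def test_background_noise_unbiased_and_phase_invariant():
    rois = _toy_rois()
    rng = np.random.default_rng(0)
    sigma = 0.3
    # static pedestal well above the noise floor so the magnitude operation
    # inside the estimator is linear in the noise
    base = 10.0 * np.ones((80, 16, 16))
    noisy = base + sigma * rng.standard_normal(base.shape)
    s = DynamicImageSeries(noisy)
    est = background_noise(s, rois)
    assert est == pytest.approx(sigma, rel=0.1)
    # a global complex phase does not change the magnitude-based estimate
    s_phase = DynamicImageSeries(noisy * np.exp(1j * 1.2))
    assert background_noise(s_phase, rois) == pytest.approx(est, rel=1e-10)
    # the static pedestal cancels in frame differences: doubling it does not
    # change the estimate
    assert background_noise(DynamicImageSeries(noisy + base), rois) == pytest.approx(
        est, rel=1e-10)
    with pytest.raises(ValueError):
        background_noise(DynamicImageSeries(noisy[:2]), rois, slice(0, 1))


def test_peak_lesion_frame():
    rois = _toy_rois()
    data = np.zeros((5, 16, 16))
    for t in range(5):
        data[t][rois.lesion] = [0.1, 0.5, 2.0, 1.0, 0.7][t]
    assert peak_lesion_frame(DynamicImageSeries(data), rois) == 2


def test_curve_similarity_properties():
    a = np.array([0.0, 1.0, 2.0, 3.0])
    r, d = curve_similarity(a, 5.0 * a)
    assert r == pytest.approx(1.0)
    assert d == pytest.approx(0.0)  # peak normalization removes scale
    r2, _ = curve_similarity(a, -a)
    assert r2 == pytest.approx(-1.0)
    r3, _ = curve_similarity(a, np.ones(4))
    assert np.isnan(r3)
    with pytest.raises(ValueError):
        curve_similarity(a, a[:3])


def test_fold_change_table():
    reports = [
        MetricsReport("ref", cnr=2.0, noise_sd=0.4),
        MetricsReport("better", cnr=6.0, noise_sd=0.1),
    ]
    table = fold_change(reports, "ref")
    assert table["ref"]["cnr_fold"] == pytest.approx(1.0)
    assert table["better"]["cnr_fold"] == pytest.approx(3.0)
    assert table["better"]["noise_reduction_fold"] == pytest.approx(4.0)
    with pytest.raises(ValueError):
        fold_change(reports, "missing")


def test_rois_from_partition_on_phantom_geometry():
    part = make_label_map(64, 64, seed=0)
    rois = rois_from_partition(part, n_background=4)
    lm = part.label_map
    assert np.array_equal(rois.lesion, lm == part.region_names.index("lesion"))
    bg = lm == part.region_names.index("background")
    assert bg[rois.background_mask()].all()  # rects lie in pure background
    with pytest.raises(ValueError):
        rois_from_partition(part, n_background=10_000)


def test_evaluate_series_end_to_end():
    rois = _toy_rois()
    rng = np.random.default_rng(1)
    # static pedestal keeps the magnitude operation linear in the noise
    data = 5.0 + 0.05 * rng.standard_normal((20, 16, 16))
    data[:, rois.lesion] += np.linspace(0, 4, 20)[:, None]
    data[:, rois.fibroglandular] += 1.0
    rep = evaluate_series(DynamicImageSeries(data), rois, "test")
    assert rep.method == "test"
    assert rep.noise_sd == pytest.approx(0.05, rel=0.2)
    assert rep.cnr > 10.0
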