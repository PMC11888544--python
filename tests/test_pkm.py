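import warnings

import numpy as np
import pytest

from elite_mri.pkm import (
    AIF,
    ConcentrationCurve,
    PKMParams,
    RelaxationSettings,
    bootstrap_fit,
    concentration_to_signal,
    detect_onset,
    fit_pkm,
    ktrans_from,
    population_aif,
    shift_aif_onset,
    signal_to_concentration,
    standard_aif,
    tcxm_forward,
)

SEC_PER_MIN = 60.0


def _rk4_oracle(params, aif, substeps=40):
    """Independent fixed-step RK4 integration of the 2CXM equations."""
    fp = params.fp / SEC_PER_MIN
    ps = params.ps / SEC_PER_MIN
    ve, vp = params.ve, params.vp
    ca = lambda s: np.interp(s, aif.t, aif.ca)  # noqa: E731

    def rhs(s, y):
        cp, ce = y
        return np.array([
            (fp * ca(s) + ps * ce - (fp + ps) * cp) / vp,
            ps * (cp - ce) / ve,
        ])

    y = np.zeros(2)
    out = [0.0]
    for k in range(len(aif.t) - 1):
        t0, t1 = aif.t[k], aif.t[k + 1]
        h = (t1 - t0) / substeps
        s = t0
        for _ in range(substeps):
            k1 = rhs(s, y)
            k2 = rhs(s + h / 2, y + h / 2 * k1)
            k3 = rhs(s + h / 2, y + h / 2 * k2)
            k4 = rhs(s + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            s += h
        out.append(vp * y[0] + ve * y[1])
    return np.array(out)


def test_params_validation_and_ktrans():
    with pytest.raises(ValueError):
        PKMParams(-0.1, 0.1, 1.0, 0.1)
    with pytest.raises(ValueError):
        PKMParams(0.7, 0.5, 1.0, 0.1)  # ve + vp > 1
    assert ktrans_from(0.0, 0.5) == 0.0
    # PS << Fp: Ktrans -> PS; PS >> Fp: Ktrans -> Fp
    assert np.isclose(ktrans_from(10.0, 0.01), 0.01, rtol=1e-3)
    assert np.isclose(ktrans_from(0.01, 10.0), 0.01, rtol=1e-3)
    p = PKMParams(0.4, 0.08, 0.8, 0.3)
    assert np.isclose(p.ktrans, 0.8 * -np.expm1(-0.3 / 0.8))


def test_standard_aif_shape():
    t = np.linspace(0.0, 300.0, 301)
    aif = standard_aif(t, onset=30.0, peak=6.0)
    assert np.all(aif.ca[t < 30.0] == 0.0)
    assert np.isclose(aif.ca.max(), 6.0, rtol=0.01)
    # washout: tail is lower than the peak but still positive
    assert 0.0 < aif.ca[-1] < aif.ca.max()


def test_tcxm_conv_and_ode_match_rk4_oracle():
    t = np.linspace(0.0, 200.0, 201)
    aif = standard_aif(t, onset=20.0)
    for params in [PKMParams(0.40, 0.08, 0.80, 0.30),
                   PKMParams(0.10, 0.30, 3.00, 0.05)]:
        ref = _rk4_oracle(params, aif)
        conv = tcxm_forward(params, aif, method="conv").ct
        ode = tcxm_forward(params, aif, method="ode").ct
        peak = ref.max()
        assert np.max(np.abs(conv - ref)) < 2e-3 * peak
        assert np.max(np.abs(ode - ref)) < 2e-3 * peak


def test_tcxm_degenerate_limits():
    t = np.linspace(0.0, 200.0, 201)
    aif = standard_aif(t, onset=20.0)
    # vp = 0 reduces to a Tofts-like single compartment
    ct = tcxm_forward(PKMParams(0.3, 0.0, 0.5, 0.2), aif).ct
    assert np.all(np.isfinite(ct)) and ct.max() > 0
    # ps = 0: intravascular only, Ct <= vp * max(Cp)
    ct2 = tcxm_forward(PKMParams(0.3, 0.1, 0.5, 0.0), aif).ct
    assert ct2.max() <= 0.1 * aif.ca.max() * 1.01
    with pytest.raises(ValueError):
        tcxm_forward(PKMParams(0.0, 0.0, 0.5, 0.2), aif)


def test_signal_concentration_roundtrip():
    rel = RelaxationSettings()
    t = np.linspace(0.0, 150.0, 40)
    ct_true = np.clip(np.sin(t / 40.0), 0.0, None) * 1.5
    ct_true[:8] = 0.0
    sig = concentration_to_signal(ct_true, rel, m0=3.7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        back = signal_to_concentration(sig, slice(0, 8), rel, t=t)
    assert np.max(np.abs(back.ct - ct_true)) < 1e-8
    # only exactly-zero samples may be clipped by rounding noise
    assert back.n_clipped <= int(np.sum(ct_true == 0.0))
    with pytest.raises(ValueError):
        signal_to_concentration(np.zeros(10), slice(0, 5), rel)


def test_onset_detection_and_population_aif():
    t = np.arange(0.0, 120.0, 2.0)
    a1 = standard_aif(t, onset=20.0)
    a2 = standard_aif(t, onset=40.0)
    i1, i2 = detect_onset(a1), detect_onset(a2)
    assert t[i2] - t[i1] == pytest.approx(20.0, abs=4.0)
    pop = population_aif([a1, a2])
    # aligned average: onset at the start of the grid
    assert detect_onset(pop) <= 2
    shifted = shift_aif_onset(pop, 30.0, t)
    assert np.all(shifted.ca[t < 28.0] == 0.0)
    with pytest.raises(ValueError):
        population_aif([])


def test_fit_recovers_noiseless_parameters():
    t = np.arange(0.0, 180.0, 1.5)
    aif = standard_aif(t, onset=20.0)
    true = PKMParams(0.40, 0.08, 0.80, 0.30)
    ct = tcxm_forward(true, aif, method="conv")
    fit = fit_pkm(ct, aif, seed=0)
    assert fit.converged
    rec = fit.params.as_array()
    assert np.all(np.abs(rec - true.as_array()) / true.as_array() < 0.02)
    assert np.isclose(fit.ktrans, true.ktrans, rtol=0.02)


def test_fit_rejects_mismatched_grids():
    t = np.arange(0.0, 60.0, 2.0)
    aif = standard_aif(t, onset=10.0)
    ct = ConcentrationCurve(t=t + 1.0, ct=np.zeros_like(t))
    with pytest.raises(ValueError):
        fit_pkm(ct, aif)


def test_bootstrap_shapes_and_determinism():
    t = np.arange(0.0, 150.0, 3.0)
    aif = standard_aif(t, onset=20.0)
    true = PKMParams(0.40, 0.08, 0.80, 0.30)
    base = tcxm_forward(true, aif, method="conv").ct
    rng = np.random.default_rng(4)
    curves = base[None, :] * (1.0 + 0.05 * rng.standard_normal((30, 1)))
    results, summary = bootstrap_fit(curves, t, aif, fraction=0.2, n_boot=5,
                                     seed=1, n_starts=1)
    assert len(results) == 5
    assert set(summary) == {"ve", "vp", "fp", "ps", "ktrans"}
    assert np.isclose(summary["ktrans"]["mean"], true.ktrans, rtol=0.1)
    _, summary2 = bootstrap_fit(curves, t, aif, fraction=0.2, n_boot=5,
                                seed=1, n_starts=1)
    assert summary == summary2
    with pytest.raises(ValueError):
        bootstrap_fit(curves[:5], t, aif)
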