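"""Two-compartment exchange model (2CXM) analysis for DCE-MRI.

The model describes the tissue contrast-agent concentration Ct(t) as a mix of
a capillary plasma compartment Cp (volume fraction vp) and the
extravascular-extracellular space Ce (volume fraction ve), fed by an arterial
input function Ca(t) with plasma flow Fp and exchanging across the capillary
wall with permeability-surface-area product PS:

    Ct = vp*Cp + ve*Ce
    vp dCp/dt = Fp*Ca + PS*Ce - (Fp + PS)*Cp
    ve dCe/dt = PS*(Cp - Ce)

The volume transfer constant is Ktrans = Fp * (1 - exp(-PS/Fp)).

Rates (Fp, PS, Ktrans) are fractional and carry units of 1/min; times are in
seconds throughout the package, so rates are converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "PKMParams",
    "AIF",
    "ConcentrationCurve",
    "RelaxationSettings",
    "FitResult",
    "ktrans_from",
    "tcxm_forward",
    "signal_to_concentration",
    "concentration_to_signal",
    "standard_aif",
    "population_aif",
    "shift_aif_onset",
    "detect_onset",
    "fit_pkm",
    "bootstrap_fit",
    "DEFAULT_BOUNDS",
]

SEC_PER_MIN = 60.0


@dataclass
class PKMParams:
    """2CXM parameters. ve, vp are unitless volume fractions; Fp, PS in 1/min."""

    ve: float
    vp: float
    fp: float
    ps: float

    def __post_init__(self) -> None:
        for name in ("ve", "vp", "fp", "ps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ve + self.vp > 1.0 + 1e-9:
            raise ValueError("ve + vp must not exceed 1")

    @property
    def ktrans(self) -> float:
        return ktrans_from(self.fp, self.ps)

    def as_array(self) -> np.ndarray:
        return np.array([self.ve, self.vp, self.fp, self.ps])


@dataclass
class AIF:
    """Arterial input function: concentration Ca(t) in mM on sample times t (s)."""

    t: np.ndarray
    ca: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.t.shape != self.ca.shape:
            raise ValueError("t and ca must have the same shape")
        if np.any(self.ca < -1e-12):
            raise ValueError("Ca must be non-negative")


@dataclass
class ConcentrationCurve:
    """Tissue (Ct), plasma (Cp) and EES (Ce) concentrations in mM over time (s)."""

    t: np.ndarray
    ct: np.ndarray
    cp: np.ndarray = None
    ce: np.ndarray = None
    n_clipped: int = 0


@dataclass
class RelaxationSettings:
    """Spoiled-gradient-echo signal model settings.

    t10: pre-contrast T1 (s); tr: repetition time (s); flip_deg: flip angle
    (degrees); r1: contrast agent longitudinal relaxivity (1/mM/s).
    """

    t10: float = 1.3
    tr: float = 0.00487
    flip_deg: float = 10.0
    r1: float = 4.5

    def __post_init__(self) -> None:
        for name in ("t10", "tr", "flip_deg", "r1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ktrans_from(fp: float, ps: float) -> float:
    """Volume transfer constant Ktrans = Fp * (1 - exp(-PS/Fp)) in 1/min."""
    if fp < 0 or ps < 0:
        raise ValueError("Fp and PS must be non-negative")
    if fp == 0:
        return 0.0
    return float(fp * -np.expm1(-ps / fp))


def _expconv(rate: float, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exact y(t) = int_0^t f(s) exp(-rate (t-s)) ds for piecewise-linear f."""
    y = np.zeros_like(f, dtype=float)
    dt = np.diff(t)
    for k in range(len(t) - 1):
        h = dt[k]
        x = rate * h
        if x > 1e-8:
            e = np.exp(-x)
            i0 = (1.0 - e) / rate          # int exp(-rate (h-s)) ds
            i1 = h / rate - (1.0 - e) / rate**2  # int s exp(-rate (h-s)) ds
        else:  # series expansion for rate*h -> 0
            e = np.exp(-x)
            i0 = h * (1.0 - x / 2.0 + x * x / 6.0)
            i1 = h * h * (0.5 - x / 3.0 + x * x / 8.0)
        df = f[k + 1] - f[k]
        y[k + 1] = y[k] * e + f[k] * i0 + (df / h) * i1
    return y


def _tcxm_conv(params: PKMParams, aif: AIF) -> ConcentrationCurve:
    """2CXM via eigen-decomposition and exact exponential convolution."""
    ve, vp = params.ve, params.vp
    fp = params.fp / SEC_PER_MIN
    ps = params.ps / SEC_PER_MIN
    m = np.array([[-(fp + ps) / vp, ps / vp], [ps / ve, -ps / ve]])
    b = np.array([fp / vp, 0.0])
    evals, q = np.linalg.eig(m)
    qinv_b = np.linalg.solve(q, b)
    states = np.zeros((2, len(aif.t)))
    for j in range(2):
        rate = -float(np.real(evals[j]))
        states[j] = _expconv(rate, aif.t, aif.ca)
    xz = q @ (qinv_b[:, None] * states)
    cp, ce = np.real(xz[0]), np.real(xz[1])
    ct = vp * cp + ve * ce
    return ConcentrationCurve(t=aif.t.copy(), ct=ct, cp=cp, ce=ce)


def tcxm_forward(
    params: PKMParams, aif: AIF, method: str = "ode", rtol: float = 1e-8
) -> ConcentrationCurve:
    """Integrate the 2CXM driven by the AIF from Cp = Ce = 0.

    method "ode" uses an adaptive stiff-capable solver (LSODA); method "conv"
    evaluates the closed-form solution by eigen-decomposition and exact
    exponential convolution of the piecewise-linear AIF (fast, used inside
    fitting). Degenerate vp = 0 or ve = 0 reduce to one-compartment limits;
    both zero is invalid.
    """
    if params.vp == 0 and params.ve == 0:
        raise ValueError("vp and ve cannot both be zero")
    t = aif.t
    fp = params.fp / SEC_PER_MIN
    ps = params.ps / SEC_PER_MIN

    if params.vp == 0:
        # plasma equilibrates instantly: Cp = (Fp Ca + PS Ce) / (Fp + PS),
        # leaving ve dCe/dt = PS Fp/(Fp+PS) (Ca - Ce)
        rate = (ps / params.ve) * fp / (fp + ps) if (fp + ps) > 0 else 0.0
        ce = rate * _expconv(rate, t, aif.ca) if rate > 0 else np.zeros_like(t)
        cp = (fp * aif.ca + ps * ce) / (fp + ps) if (fp + ps) > 0 else np.zeros_like(t)
        return ConcentrationCurve(t=t.copy(), ct=params.ve * ce, cp=cp, ce=ce)
    if params.ve == 0 or ps == 0:
        # one-compartment: vp dCp/dt = Fp (Ca - Cp); Ce carries no signal
        rate = fp / params.vp
        cp = _expconv(rate, t, aif.ca) * rate
        ce = cp.copy() if params.ve == 0 and ps > 0 else np.zeros_like(t)
        return ConcentrationCurve(t=t.copy(), ct=params.vp * cp + params.ve * ce, cp=cp, ce=ce)

    if method == "conv":
        return _tcxm_conv(params, aif)
    if method != "ode":
        raise ValueError("method must be 'ode' or 'conv'")

    ca_interp = lambda s: np.interp(s, t, aif.ca)  # noqa: E731
    ve, vp = params.ve, params.vp

    def rhs(s, y):
        cp, ce = y
        dcp = (fp * ca_interp(s) + ps * ce - (fp + ps) * cp) / vp
        dce = ps * (cp - ce) / ve
        return [dcp, dce]

    scale = max(float(np.max(aif.ca)), 1e-12)
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [0.0, 0.0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=rtol * scale,
        max_step=float(np.min(np.diff(t))) if len(t) > 1 else np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    cp, ce = sol.y
    return ConcentrationCurve(t=t.copy(), ct=vp * cp + ve * ce, cp=cp, ce=ce)


# ---------------------------------------------------------------------------
# signal <-> concentration (spoiled gradient echo, steady state)
# ---------------------------------------------------------------------------

def concentration_to_signal(
    ct: np.ndarray, rel: RelaxationSettings, m0: float = 1.0
) -> np.ndarray:
    """SPGR steady-state signal for tissue concentration ct (mM)."""
    r1 = 1.0 / rel.t10 + rel.r1 * np.asarray(ct)
    e1 = np.exp(-rel.tr * r1)
    a = np.deg2rad(rel.flip_deg)
    return m0 * np.sin(a) * (1 - e1) / (1 - np.cos(a) * e1)


def signal_to_concentration(
    signal: np.ndarray,
    baseline_window: slice,
    rel: RelaxationSettings,
    t: np.ndarray = None,
) -> ConcentrationCurve:
    """Invert the SPGR signal equation to a tissue concentration curve.

    The equilibrium magnetization M0 is estimated from the baseline window
    using the known pre-contrast T1; each sample is then mapped to R1(t) and
    Ct = (R1 - 1/T10) / r1. Samples implying R1 below the pre-contrast rate
    are clipped to zero concentration (count reported on the result).
    """
    signal = np.asarray(signal, dtype=float)
    s0 = float(np.mean(signal[baseline_window]))
    if s0 <= 0:
        raise ValueError("baseline signal must be positive")
    a = np.deg2rad(rel.flip_deg)
    e10 = np.exp(-rel.tr / rel.t10)
    m0 = s0 * (1 - np.cos(a) * e10) / (np.sin(a) * (1 - e10))
    sn = signal / (m0 * np.sin(a))
    e1 = (1 - sn) / (1 - sn * np.cos(a))
    e1 = np.clip(e1, 1e-12, 1 - 1e-12)
    r1 = -np.log(e1) / rel.tr
    ct = (r1 - 1.0 / rel.t10) / rel.r1
    n_clipped = int(np.sum(ct < 0))
    if n_clipped:
        warnings.warn(f"{n_clipped} samples implied negative concentration; clipped to 0")
    ct = np.maximum(ct, 0.0)
    if t is None:
        t = np.arange(len(signal), dtype=float)
    return ConcentrationCurve(t=np.asarray(t, dtype=float), ct=ct, n_clipped=n_clipped)


# ---------------------------------------------------------------------------
# AIF utilities
# ---------------------------------------------------------------------------

def standard_aif(t: np.ndarray, onset: float = 30.0, peak: float = 6.0) -> AIF:
    """Synthetic population-style AIF: gamma-variate bolus plus washout tail.

    Zero before the injection onset; scaled so the peak concentration equals
    `peak` mM on a fine internal grid.
    """
    t = np.asarray(t, dtype=float)

    def shape(tau):
        tau = np.maximum(tau, 0.0)
        bolus = (tau / 12.0) ** 3 * np.exp(-tau / 6.0)
        tail = 0.20 * (1 - np.exp(-tau / 30.0)) * np.exp(-tau / 400.0)
        return bolus + tail

    fine = np.linspace(0, 600, 6001)
    norm = shape(fine).max()
    ca = peak * shape(t - onset) / norm
    ca[t < onset] = 0.0
    return AIF(t=t, ca=ca)


def detect_onset(aif: AIF, threshold_frac: float = 0.1) -> int:
    """Index of the first sample exceeding threshold_frac of the peak."""
    peak = float(np.max(aif.ca))
    if peak <= 0:
        raise ValueError("AIF has no enhancement")
    above = np.flatnonzero(aif.ca > threshold_frac * peak)
    return int(above[0])


def population_aif(aif_set: list, threshold_frac: float = 0.1) -> AIF:
    """Average a set of AIFs after aligning each to its own bolus onset.

    Each input is shifted so its onset (first sample above threshold_frac of
    its peak) sits at index 0; aligned curves are averaged over the common
    length, padding the tail with the last value. AIFs with no enhancement
    are excluded with a warning. All inputs must share the sampling interval.
    """
    if not aif_set:
        raise ValueError("need at least one AIF")
    aligned = []
    dt = None
    for aif in aif_set:
        if np.max(aif.ca) <= 0:
            warnings.warn("excluding AIF with no enhancement")
            continue
        d = float(np.median(np.diff(aif.t)))
        if dt is None:
            dt = d
        elif abs(d - dt) > 1e-6 * dt:
            raise ValueError("AIFs must share a common sampling interval")
        onset = detect_onset(aif, threshold_frac)
        aligned.append(aif.ca[onset:])
    if not aligned:
        raise ValueError("no AIF with enhancement")
    length = max(len(a) for a in aligned)
    stack = np.stack(
        [np.pad(a, (0, length - len(a)), mode="edge") for a in aligned]
    )
    ca = stack.mean(axis=0)
    return AIF(t=dt * np.arange(length), ca=ca)


def shift_aif_onset(pop: AIF, onset_time: float, t: np.ndarray) -> AIF:
    """Place a population AIF at a case-specific onset time on grid t."""
    t = np.asarray(t, dtype=float)
    ca = np.interp(t - onset_time, pop.t, pop.ca, left=0.0, right=float(pop.ca[-1]))
    return AIF(t=t, ca=np.maximum(ca, 0.0))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

DEFAULT_BOUNDS = {
    "ve": (1e-4, 1.0),
    "vp": (1e-4, 1.0),
    "fp": (1e-4, 10.0),
    "ps": (1e-4, 10.0),
}


@dataclass
class FitResult:
    params: PKMParams
    residual_norm: float
    converged: bool
    cost: float = 0.0
    n_starts: int = 1

    @property
    def ktrans(self) -> float:
        return self.params.ktrans


def _clip_params(x, bounds_lo, bounds_hi):
    x = np.clip(x, bounds_lo, bounds_hi)
    # keep ve + vp feasible
    s = x[0] + x[1]
    if s > 1.0:
        x[0], x[1] = x[0] / s, x[1] / s
    return x


def fit_pkm(
    ct: ConcentrationCurve,
    aif: AIF,
    init: PKMParams = None,
    bounds: dict = None,
    n_starts: int = 5,
    seed: int = 0,
    method: str = "conv",
) -> FitResult:
    """Nonlinear least-squares fit of (ve, vp, Fp, PS) to a tissue curve.

    Multi-start (n_starts seeded log-uniform draws within bounds, plus the
    supplied init) mitigates local minima. Non-convergence is flagged on the
    result, not raised. Ktrans is derived from the fitted Fp and PS.
    """
    if not np.allclose(ct.t, aif.t):
        raise ValueError("Ct and AIF must share the same time grid")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[k][0] for k in ("ve", "vp", "fp", "ps")])
    hi = np.array([b[k][1] for k in ("ve", "vp", "fp", "ps")])
    target = np.asarray(ct.ct, dtype=float)
    scale = max(float(np.max(np.abs(target))), 1e-12)

    def resid(x):
        p = PKMParams(*_clip_params(x.copy(), lo, hi))
        model = tcxm_forward(p, aif, method=method).ct
        return (model - target) / scale

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(init.as_array())
    starts.append(np.array([0.3, 0.05, 0.5, 0.2]))
    while len(starts) < n_starts:
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(np.minimum(hi, 2.0)))))

    best = None
    for x0 in starts:
        x0 = _clip_params(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = least_squares(
                resid, x0, bounds=(lo, hi), method="trf", x_scale="jac", ftol=1e-12,
                xtol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitResult(PKMParams(*lo), np.inf, converged=False)
    params = PKMParams(*_clip_params(best.x.copy(), lo, hi))
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun) * scale),
        converged=bool(best.status > 0),
        cost=float(best.cost),
        n_starts=len(starts),
    )


def bootstrap_fit(
    voxel_curves: np.ndarray,
    t: np.ndarray,
    aif: AIF,
    fraction: float = 0.10,
    n_boot: int = 100,
    seed: int = 0,
    **fit_kwargs,
):
    """Bootstrap PK fitting over voxels.

    Each replicate draws ceil(fraction * n_voxels) voxels without replacement,
    averages their concentration curves, and fits the 2CXM. Returns the list
    of n_boot FitResults and a mean/SD summary per parameter.
    """
    voxel_curves = np.asarray(voxel_curves, dtype=float)
    if voxel_curves.ndim != 2:
        raise ValueError("voxel_curves must be (n_voxels, T)")
    n_vox = voxel_curves.shape[0]
    if n_vox < 10:
        raise ValueError("need at least 10 voxels")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_draw = int(np.ceil(fraction * n_vox))
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_boot):
        idx = rng.choice(n_vox, size=n_draw, replace=False)
        mean_curve = ConcentrationCurve(t=np.asarray(t, float), ct=voxel_curves[idx].mean(axis=0))
        results.append(fit_pkm(mean_curve, aif, seed=seed, **fit_kwargs))
    names = ("ve", "vp", "fp", "ps", "ktrans")
    arr = np.array(
        [[r.params.ve, r.params.vp, r.params.fp, r.params.ps, r.ktrans] for r in results]
    )
    summary = {
        name: {"mean": float(arr[:, j].mean()), "sd": float(arr[:, j].std(ddof=1)) if n_boot > 1 else 0.0}
        for j, name in enumerate(names)
    }
    return results, summary
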