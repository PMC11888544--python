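"""Synthetic breast digital reference object (DRO).

Builds a 2D breast slice with six tissue classes (background, lesion,
fibroglandular, pectoral muscle, skin, heart), per-tissue contrast-enhancement
dynamics driven by the two-compartment exchange model with tissue-specific
rise times, and smooth complex coil sensitivity maps. Everything is seeded and
deterministic, so phantoms double as test fixtures and as training data for
the streak-artifact denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .pkm import AIF, PKMParams, tcxm_forward
from .regions import RegionPartition, partition_from_labels
from .series import DynamicImageSeries

TISSUE_NAMES = ["background", "lesion", "fibroglandular", "muscle", "skin", "heart"]

# Rise-time dictionary (seconds): plausible per-tissue wash-in ranges with the
# blood-pool heart fastest and lesion faster than normal parenchyma. Package
# defaults used for augmentation draws.
RISE_TIME_DICTIONARY = {
    "lesion": (15.0, 40.0),
    "fibroglandular": (40.0, 90.0),
    "muscle": (60.0, 120.0),
    "skin": (60.0, 120.0),
    "heart": (5.0, 15.0),
}


@dataclass
class TissueParams:
    """Per-tissue signal model: baseline (a.u.), multiplicative enhancement
    amplitude, wash-in rise time (s), and the ground-truth 2CXM parameters
    used to synthesize the enhancement curve."""

    baseline: float
    amplitude: float
    rise_time: float
    pkm: PKMParams = None

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.amplitude < 0:
            raise ValueError("baseline and amplitude must be non-negative")
        if self.rise_time <= 0:
            raise ValueError("rise time must be positive")


@dataclass
class TissueKinetics:
    tissues: dict

    def __post_init__(self) -> None:
        bg = self.tissues.get("background")
        if bg is not None and bg.amplitude != 0:
            raise ValueError("background must not enhance")


def default_kinetics(rise_times: dict = None) -> TissueKinetics:
    """Reference kinetics table; rise_times overrides per-tissue rise times."""
    base = {
        "background": TissueParams(0.0, 0.0, 1.0),
        "lesion": TissueParams(0.5, 2.0, 27.5, PKMParams(0.40, 0.08, 0.80, 0.30)),
        "fibroglandular": TissueParams(0.6, 0.8, 65.0, PKMParams(0.30, 0.03, 0.20, 0.08)),
        "muscle": TissueParams(0.7, 0.4, 90.0, PKMParams(0.15, 0.02, 0.10, 0.05)),
        "skin": TissueParams(0.8, 0.5, 90.0, PKMParams(0.20, 0.03, 0.12, 0.06)),
        "heart": TissueParams(0.9, 3.0, 10.0, PKMParams(0.10, 0.85, 5.00, 0.01)),
    }
    if rise_times:
        for name, rt in rise_times.items():
            base[name] = replace(base[name], rise_time=float(rt))
    return TissueKinetics(tissues=base)


# midpoints of the dictionary ranges; the synthesized curve's wash-in speed is
# scaled by base_rise / drawn_rise (see generate_dynamic_phantom)
_BASE_RISE = {name: 0.5 * (lo + hi) for name, (lo, hi) in RISE_TIME_DICTIONARY.items()}


@dataclass
class CoilSensitivities:
    """Smooth complex coil maps, shape (C, H, W)."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 3:
            raise ValueError("maps must have shape (C, H, W)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class DROPhantom:
    partition: RegionPartition
    kinetics: TissueKinetics
    coils: CoilSensitivities
    time_grid: np.ndarray
    heterogeneity: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if len(self.time_grid) < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.diff(self.time_grid) > 0):
            raise ValueError("time_grid must be strictly increasing")


def make_label_map(height: int, width: int, seed: int = 0) -> RegionPartition:
    """Six-region breast slice geometry.

    Background frame, elliptical breast with a skin rim, fibroglandular
    interior, an embedded ellipsoidal lesion (position jittered by the seed),
    a posterior pectoral-muscle band, and a small heart disc.
    """
    if height < 32 or width < 32:
        raise ValueError("dimensions must be at least 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    labels = np.zeros((height, width), dtype=np.int16)

    def ellipse(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    breast = ellipse(0.50 * height, 0.40 * width, 0.40 * height, 0.33 * width)
    rim = max(2, int(round(height / 80)))
    interior = binary_erosion(breast, iterations=rim)
    labels[breast] = TISSUE_NAMES.index("skin")
    labels[interior] = TISSUE_NAMES.index("fibroglandular")

    # lesion inside the fibroglandular interior, jittered by the seed
    ly = (0.50 + 0.08 * rng.uniform(-1, 1)) * height
    lx = (0.38 + 0.06 * rng.uniform(-1, 1)) * width
    lry = max(2.0, (0.075 + 0.02 * rng.uniform(-1, 1)) * height)
    lrx = max(2.0, (0.060 + 0.02 * rng.uniform(-1, 1)) * width)
    lesion = ellipse(ly, lx, lry, lrx) & interior
    labels[lesion] = TISSUE_NAMES.index("lesion")

    muscle = (
        (xx >= 0.80 * width)
        & (xx < 0.95 * width)
        & (yy >= 0.12 * height)
        & (yy < 0.88 * height)
        & ~breast
    )
    labels[muscle] = TISSUE_NAMES.index("muscle")
    heart = ellipse(0.50 * height, 0.875 * width, 0.09 * height, 0.055 * width) & muscle
    labels[heart] = TISSUE_NAMES.index("heart")
    return partition_from_labels(labels, TISSUE_NAMES)


def sample_rise_times(tissue_names: list, dictionary: dict, seed: int = 0) -> dict:
    """One uniform rise-time draw per tissue within its dictionary range."""
    if not dictionary:
        raise ValueError("rise-time dictionary must not be empty")
    rng = np.random.default_rng(seed)
    out = {}
    for name in tissue_names:
        lo, hi = dictionary[name]
        if not (0 < lo <= hi):
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        out[name] = float(rng.uniform(lo, hi))
    return out


def simulate_coils(height: int, width: int, n_coils: int) -> CoilSensitivities:
    """Smooth complex Gaussian-lobe coil model on a ring around the image.

    With a single coil the map is identically one. Multi-coil maps have a
    Gaussian magnitude lobe centred outside the FOV and a gentle linear phase
    ramp per coil; the root-sum-of-squares is positive everywhere.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return CoilSensitivities(np.ones((1, height, width), dtype=np.complex128))
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    cy0, cx0 = (height - 1) / 2.0, (width - 1) / 2.0
    radius = 0.55 * max(height, width)
    sigma = 0.55 * max(height, width)
    maps = np.empty((n_coils, height, width), dtype=np.complex128)
    for c in range(n_coils):
        phi = 2 * np.pi * c / n_coils
        cy, cx = cy0 + radius * np.sin(phi), cx0 + radius * np.cos(phi)
        mag = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
        phase = 0.5 * np.pi * ((xx - cx0) * np.cos(phi) + (yy - cy0) * np.sin(phi)) / max(height, width)
        maps[c] = mag * np.exp(1j * (phase + phi / 3.0))
    return CoilSensitivities(maps)


def tissue_curve(params: TissueParams, aif: AIF, base_rise: float = None) -> np.ndarray:
    """Peak-normalized 2CXM enhancement curve for one tissue.

    The drawn rise time acts through a joint rescaling of (Fp, PS) by
    base_rise / rise_time, so shorter rise times give proportionally faster
    wash-in while the volume fractions are untouched.
    """
    if params.pkm is None or params.amplitude == 0:
        return np.zeros_like(aif.t)
    scale = (base_rise / params.rise_time) if base_rise else 1.0
    p = PKMParams(params.pkm.ve, params.pkm.vp, params.pkm.fp * scale, params.pkm.ps * scale)
    ct = tcxm_forward(p, aif, method="conv").ct
    peak = float(np.max(ct))
    return ct / peak if peak > 0 else ct


def generate_dynamic_phantom(phantom: DROPhantom, aif: AIF) -> DynamicImageSeries:
    """Ground-truth dynamic magnitude object (coil-free), shape (T, H, W).

    Pixel value at frame t is baseline * (1 + amplitude * e(t)) with e the
    peak-normalized 2CXM tissue curve; background stays at zero. A smooth
    multiplicative Gaussian field (sd = phantom.heterogeneity) perturbs the
    amplitude per pixel so region Casorati matrices are not exactly rank 1.
    """
    if aif.t.shape != phantom.time_grid.shape or not np.allclose(aif.t, phantom.time_grid):
        raise ValueError("AIF must be defined on the phantom time grid")
    part = phantom.partition
    h, w = part.shape
    tgrid = phantom.time_grid
    data = np.zeros((len(tgrid), h, w), dtype=np.float64)
    rng = np.random.default_rng(phantom.seed + 7919)
    if phantom.heterogeneity > 0:
        field_ = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 20.0)
        field_ = field_ / max(field_.std(), 1e-12) * phantom.heterogeneity
    else:
        field_ = np.zeros((h, w))
    flat = data.reshape(len(tgrid), -1)
    ffield = field_.ravel()
    for i, name in enumerate(part.region_names):
        par = phantom.kinetics.tissues[name]
        idx = part.indices(i)
        if idx.size == 0 or par.baseline == 0 and par.amplitude == 0:
            continue
        curve = tissue_curve(par, aif, base_rise=_BASE_RISE.get(name))
        amp = par.amplitude * (1.0 + ffield[idx])
        flat[:, idx] = par.baseline * (1.0 + curve[:, None] * amp[None, :])
    return DynamicImageSeries(data, tgrid.copy())


def make_phantom(
    height: int = 160,
    width: int = None,
    time_grid: np.ndarray = None,
    n_coils: int = 8,
    seed: int = 0,
    rise_dictionary: dict = None,
    heterogeneity: float = 0.05,
) -> DROPhantom:
    """Convenience constructor: geometry + sampled rise times + coils."""
    width = width or height
    if time_grid is None:
        time_grid = np.arange(36) * (150.0 / 36) + 0.5 * (150.0 / 36)
    dictionary = rise_dictionary or RISE_TIME_DICTIONARY
    partition = make_label_map(height, width, seed=seed)
    rises = sample_rise_times(list(dictionary), dictionary, seed=seed)
    kinetics = default_kinetics(rise_times=rises)
    coils = simulate_coils(height, width, n_coils)
    return DROPhantom(
        partition=partition,
        kinetics=kinetics,
        coils=coils,
        time_grid=np.asarray(time_grid, dtype=float),
        heterogeneity=heterogeneity,
        seed=seed,
    )
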