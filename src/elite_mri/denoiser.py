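"""Residual CNN for streak-artifact suppression in 2-spokes-per-frame images.

A plain convolutional residual network (default ten convolutional layers,
3x3 kernels, ReLU, global skip connection) maps undersampled 2-spoke
magnitude frames to artifact-reduced frames. It is trained with Adam on an
L2 loss against fully sampled reference frames simulated from the digital
reference object, with rise-time-dictionary augmentation. The forward pass,
backpropagation and the Adam update are implemented directly on numpy
arrays; training is deterministic for a fixed seed.

The denoised low-resolution series feeds temporal-basis estimation for
high-temporal-resolution (2 spokes/frame) subspace reconstruction; the
network is not applied to the final high-resolution images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import make_encoding_spec, simulate_kspace
from .phantom import DROPhantom, default_kinetics, generate_dynamic_phantom, sample_rise_times
from .recon import nufft_recon
from .series import DynamicImageSeries

__all__ = [
    "TrainingPair",
    "DenoiserSpec",
    "ResidualDenoiser",
    "augment_training_set",
    "make_training_pairs",
    "train_denoiser",
    "denoise",
    "save_denoiser",
    "load_denoiser",
]


@dataclass
class TrainingPair:
    """Undersampled input frame and its fully sampled reference target."""

    input: np.ndarray
    target: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input = np.asarray(self.input, dtype=np.float64)
        self.target = np.asarray(self.target, dtype=np.float64)
        if self.input.shape != self.target.shape:
            raise ValueError("input and target must have the same shape")


@dataclass
class DenoiserSpec:
    n_conv_layers: int = 10
    channels: int = 64
    kernel_size: int = 3
    residual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_layers < 2:
            raise ValueError("need at least two convolutional layers")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")


# ---------------------------------------------------------------------------
# convolution primitives (NHWC layout, stride 1, same padding)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patches with zero same-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = np.moveaxis(win, 3, -1)
    n, h, w = x.shape[:3]
    return win.reshape(n, h, w, k * k * x.shape[3])


def _col2im(dcols: np.ndarray, k: int, c_in: int) -> np.ndarray:
    """Adjoint of _im2col: scatter patch gradients back onto the input grid."""
    n, h, w, _ = dcols.shape
    p = k // 2
    dx = np.zeros((n, h + 2 * p, w + 2 * p, c_in))
    d = dcols.reshape(n, h, w, k, k, c_in)
    for i in range(k):
        for j in range(k):
            dx[:, i : i + h, j : j + w, :] += d[:, :, :, i, j, :]
    return dx[:, p : p + h, p : p + w, :]


class _ConvLayer:
    def __init__(self, c_in, c_out, k, rng, final=False):
        fan_in = c_in * k * k
        self.w = rng.standard_normal((k * k * c_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in
        self.relu = not final
        self._adam = [np.zeros_like(self.w), np.zeros_like(self.w),
                      np.zeros_like(self.b), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        cols = _im2col(x, self.k)
        z = cols @ self.w + self.b
        if train:
            self._cache = (cols, z)
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout):
        cols, z = self._cache
        if self.relu:
            dout = dout * (z > 0)
        self.dw = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dout.sum(axis=(0, 1, 2))
        return _col2im(dout @ self.w.T, self.k, self.c_in)

    def adam_step(self, lr, t, beta1=0.9, beta2=0.999, eps=1e-8):
        mw, vw, mb, vb = self._adam
        for p, g, m, v in ((self.w, self.dw, mw, vw), (self.b, self.db, mb, vb)):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


class ResidualDenoiser:
    """Global-residual CNN: output = input + correction(input)."""

    def __init__(self, spec: DenoiserSpec, norm_scale: float = 1.0):
        self.spec = spec
        self.norm_scale = float(norm_scale)
        rng = np.random.default_rng(spec.seed)
        ch, k, n = spec.channels, spec.kernel_size, spec.n_conv_layers
        self.layers = [_ConvLayer(1, ch, k, rng)]
        for _ in range(n - 2):
            self.layers.append(_ConvLayer(ch, ch, k, rng))
        self.layers.append(_ConvLayer(ch, 1, k, rng, final=True))

    def zero_correction(self) -> None:
        """Zero all weights, making the residual network exactly the identity."""
        for layer in self.layers:
            layer.w[:] = 0.0
            layer.b[:] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, H, W) normalized magnitude frames."""
        h = x[..., None]
        for layer in self.layers:
            h = layer.forward(h, train=train)
        out = h[..., 0]
        return x + out if self.spec.residual else out

    def train_step(self, x, target, lr, t):
        pred = self.forward(x)
        diff = pred - target
        loss = float(np.mean(diff**2))
        d = ((2.0 / diff.size) * diff)[..., None]
        for layer in reversed(self.layers):
            d = layer.backward(d)
        for layer in self.layers:
            layer.adam_step(lr, t)
        return loss

    def apply(self, frames: np.ndarray, chunk: int = 4,
              flip_average: bool = True) -> np.ndarray:
        """Denoise magnitude frames (N, H, W) given in original units.

        Frames are processed in chunks without layer caches to bound memory.
        With flip_average the prediction is averaged over the four axis-flip
        orientations, which symmetrizes the learned correction and reduces
        orientation-dependent bias.
        """
        x = np.asarray(frames, dtype=float) / self.norm_scale
        flips = [(False, False)]
        if flip_average:
            flips += [(True, False), (False, True), (True, True)]
        out = np.zeros_like(x)
        for start in range(0, x.shape[0], chunk):
            sl = slice(start, start + chunk)
            for ud, lr in flips:
                xi = x[sl]
                if ud:
                    xi = xi[:, ::-1, :]
                if lr:
                    xi = xi[:, :, ::-1]
                yi = self.forward(np.ascontiguousarray(xi), train=False)
                if lr:
                    yi = yi[:, :, ::-1]
                if ud:
                    yi = yi[:, ::-1, :]
                out[sl] += yi
        return out * (self.norm_scale / len(flips))


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def augment_training_set(
    cases: list,
    n_aug_per_case: int,
    rise_dictionary: dict,
    seed: int = 0,
) -> list:
    """Rise-time augmentation of phantom cases.

    Each variant shares the case geometry and coils but has all tissue rise
    times redrawn from the dictionary. The returned list contains
    len(cases) * n_aug_per_case phantoms.
    """
    if not cases:
        raise ValueError("case list must not be empty")
    if n_aug_per_case < 1:
        raise ValueError("n_aug_per_case must be >= 1")
    out = []
    counter = 0
    for case in cases:
        for _ in range(n_aug_per_case):
            rises = sample_rise_times(
                list(rise_dictionary), rise_dictionary, seed=seed + counter
            )
            kin = default_kinetics(rise_times=rises)
            out.append(replace(case, kinetics=kin, seed=case.seed + 1000 * (counter + 1)))
            counter += 1
    return out


def make_training_pairs(
    phantom: DROPhantom,
    aif,
    spokes_per_frame: int = 2,
    frame_indices=None,
    noise_rel: float = 0.02,
    seed: int = 0,
) -> list:
    """Simulate (2-spoke input, fully sampled reference) frame pairs.

    The input is the gridding reconstruction of a golden-angle acquisition
    binned at spokes_per_frame; the reference is the gridding reconstruction
    of a Nyquist-sampled (pi/2 * matrix spokes) acquisition of the same frame.
    """
    truth = generate_dynamic_phantom(phantom, aif)
    t, h = truth.data.shape[:2]
    n_spokes = spokes_per_frame * t
    spec_u = make_encoding_spec((h, h), phantom.coils, n_spokes, spokes_per_frame)
    complex_truth = DynamicImageSeries(truth.data.astype(complex), truth.frame_times)
    clean = spec_u.forward(complex_truth)
    sigma = noise_rel * float(np.sqrt(np.mean(np.abs(clean.data) ** 2)))
    ksp = simulate_kspace(complex_truth, spec_u, noise_sigma=sigma, seed=seed)
    inputs = nufft_recon(ksp, spec_u, truth.frame_times)

    n_full = int(np.ceil(np.pi / 2 * h))
    spec_f = make_encoding_spec((h, h), phantom.coils, n_full, n_full)
    if frame_indices is None:
        frame_indices = range(t)
    pairs = []
    for fi in frame_indices:
        static = DynamicImageSeries(truth.data[fi][None].astype(complex))
        kf = simulate_kspace(static, spec_f, noise_sigma=0.0)
        ref = nufft_recon(kf, spec_f)
        pairs.append(
            TrainingPair(
                input=inputs.data[fi],
                target=ref.data[0],
                meta={"frame": int(fi), "phantom_seed": phantom.seed},
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def train_denoiser(
    pairs: list,
    spec: DenoiserSpec = None,
    epochs: int = 50,
    learning_rate: float = 1e-3,
    batch_size: int = 8,
):
    """Train the residual denoiser with Adam on an MSE loss.

    Inputs and targets are jointly normalized by the global peak so the
    network sees values in roughly [0, 1]; the scale is stored in the model
    and undone at inference. Deterministic for a fixed spec.seed. Returns the
    trained model and the per-epoch mean training loss.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    shape = pairs[0].input.shape
    for p in pairs:
        if p.input.shape != shape:
            raise ValueError("all pairs must share one frame shape")
    spec = spec or DenoiserSpec()
    scale = max(max(float(p.target.max()), float(p.input.max())) for p in pairs)
    scale = scale if scale > 0 else 1.0
    x = np.stack([p.input for p in pairs]) / scale
    y = np.stack([p.target for p in pairs]) / scale
    model = ResidualDenoiser(spec, norm_scale=scale)
    rng = np.random.default_rng(spec.seed + 1)
    n = len(pairs)
    trace = []
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            step += 1
            losses.append(model.train_step(x[idx], y[idx], learning_rate, step))
        trace.append(float(np.mean(losses)))
    return model, trace


def denoise(model: ResidualDenoiser, series: DynamicImageSeries) -> DynamicImageSeries:
    """Frame-wise application of the trained denoiser to a magnitude series."""
    out = model.apply(np.abs(series.data))
    return DynamicImageSeries(out, series.frame_times.copy())


def save_denoiser(path, model: ResidualDenoiser) -> None:
    """Serialize weights, biases, architecture and the normalization scale."""
    arrays = {"norm_scale": np.array(model.norm_scale)}
    s = model.spec
    arrays["spec"] = np.array(
        [s.n_conv_layers, s.channels, s.kernel_size, int(s.residual), s.seed]
    )
    for i, layer in enumerate(model.layers):
        arrays[f"w{i}"] = layer.w
        arrays[f"b{i}"] = layer.b
    np.savez(path, **arrays)


def load_denoiser(path) -> ResidualDenoiser:
    with np.load(path) as f:
        n, ch, k, res, seed = (int(v) for v in f["spec"])
        spec = DenoiserSpec(n, ch, k, bool(res), seed)
        model = ResidualDenoiser(spec, norm_scale=float(f["norm_scale"]))
        for i, layer in enumerate(model.layers):
            layer.w = f[f"w{i}"].copy()
            layer.b = f[f"b{i}"].copy()
    return model
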