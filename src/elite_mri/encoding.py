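"""Golden-angle radial encoding: trajectory, density compensation, and the
multi-coil non-uniform Fourier operator E with its exact adjoint.

The non-uniform FFT is implemented by Kaiser-Bessel gridding on a 2x
oversampled Cartesian grid: the image is deapodized, zero-padded, transformed
with a centred unitary FFT, and interpolated onto the radial sample positions
with a precomputed sparse matrix. The adjoint applies the transposed
interpolation, inverse FFT, crop and deapodization, so <Ex, y> = <x, E^H y>
holds to machine precision by construction.

Conventions: k-space coordinates are stored in cycles/pixel in [-0.5, 0.5)
with the DC sample at the k-space centre; image pixel (0, 0) is the array
corner and the object centre maps to the array centre (fftshift convention).
Density-compensation square roots are folded into both E and E^H so the
normal operator is symmetrically preconditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import i0

from .phantom import CoilSensitivities
from .series import DynamicImageSeries

GOLDEN_ANGLE_DEG = 111.246  # standard golden-angle increment


# ---------------------------------------------------------------------------
# trajectory and frame binning
# ---------------------------------------------------------------------------

@dataclass
class RadialTrajectory:
    """Radial k-space trajectory: per-spoke angles and sample coordinates."""

    angles: np.ndarray          # radians, one per spoke
    coords: np.ndarray          # (n_spokes, n_readout, 2) in cycles/pixel
    radii: np.ndarray           # (n_readout,) signed radius of each readout sample

    @property
    def n_spokes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_readout(self) -> int:
        return self.coords.shape[1]


def golden_angle_trajectory(n_spokes: int, n_readout: int) -> RadialTrajectory:
    """Golden-angle radial trajectory.

    Spoke i has angle (i * 111.246 deg) mod 180 deg; each spoke's readout
    samples span the k-space diameter uniformly, passing exactly through k=0.
    """
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    if n_readout < 2 or n_readout % 2 != 0:
        raise ValueError("n_readout must be even and >= 2")
    angles = np.deg2rad((np.arange(n_spokes) * GOLDEN_ANGLE_DEG) % 180.0)
    radii = (np.arange(n_readout) - n_readout // 2) / n_readout  # [-0.5, 0.5)
    kx = radii[None, :] * np.cos(angles)[:, None]
    ky = radii[None, :] * np.sin(angles)[:, None]
    coords = np.stack([ky, kx], axis=-1)
    return RadialTrajectory(angles=angles, coords=coords, radii=radii)


def bin_spokes(n_spokes: int, spokes_per_frame: int) -> np.ndarray:
    """Sequential frame assignment; trailing remainder spokes get frame -1.

    floor(n_spokes / spokes_per_frame) frames are formed; leftover spokes at
    the end of the acquisition are discarded.
    """
    if spokes_per_frame < 1:
        raise ValueError("spokes_per_frame must be >= 1")
    if spokes_per_frame > n_spokes:
        raise ValueError("spokes_per_frame exceeds n_spokes")
    frame = np.arange(n_spokes) // spokes_per_frame
    n_frames = n_spokes // spokes_per_frame
    frame[frame >= n_frames] = -1
    return frame


def temporal_resolution(scan_time: float, n_spokes: int, spokes_per_frame: int) -> float:
    """Seconds per frame: scan_time * spokes_per_frame / n_spokes."""
    if scan_time <= 0 or n_spokes <= 0 or spokes_per_frame <= 0:
        raise ValueError("all arguments must be positive")
    return scan_time * spokes_per_frame / n_spokes


def density_compensation(trajectory: RadialTrajectory) -> np.ndarray:
    """Ramp density-compensation weights, one per (spoke, readout) sample.

    Proportional to |k| with the centre sample floored at half a k-space cell,
    normalized to unit mean.
    """
    r = np.abs(trajectory.radii)
    cell = 1.0 / trajectory.n_readout
    w = np.maximum(r, 0.5 * cell)
    w = w / w.mean()
    return np.broadcast_to(w, (trajectory.n_spokes, trajectory.n_readout)).copy()


@dataclass
class MultiCoilKSpace:
    """Radial k-space data: (C, n_spokes, n_readout) complex samples plus the
    trajectory, frame assignment and density weights. The stored data live in
    the weighted domain of the encoding operator (sqrt(w) applied)."""

    data: np.ndarray
    trajectory: RadialTrajectory
    frame_of_spoke: np.ndarray
    density_weights: np.ndarray = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (C, n_spokes, n_readout)")
        if self.density_weights is None:
            self.density_weights = density_compensation(self.trajectory)
        self.frame_of_spoke = np.asarray(self.frame_of_spoke)
        kept = self.frame_of_spoke[self.frame_of_spoke >= 0]
        if kept.size and np.any(np.diff(kept) < 0):
            raise ValueError("frame_of_spoke must be non-decreasing")
        if np.any(self.density_weights <= 0):
            raise ValueError("density weights must be positive")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return int(self.frame_of_spoke.max()) + 1


# ---------------------------------------------------------------------------
# Kaiser-Bessel gridding internals
# ---------------------------------------------------------------------------

_KB_WIDTH = 4          # kernel support in oversampled grid cells
_OVERSAMP = 2          # grid oversampling factor
_KB_BETA = float(np.pi * np.sqrt((_KB_WIDTH / _OVERSAMP) ** 2 * (_OVERSAMP - 0.5) ** 2 - 0.8))


def _kb_kernel(u: np.ndarray) -> np.ndarray:
    """Kaiser-Bessel kernel on offsets u (oversampled grid cells)."""
    x = 1.0 - (2.0 * u / _KB_WIDTH) ** 2
    out = np.zeros_like(u, dtype=float)
    inside = x > 0
    out[inside] = i0(_KB_BETA * np.sqrt(x[inside]))
    return out


def _deapodization(size: int, n_grid: int) -> np.ndarray:
    """1D image-domain correction for the KB kernel rolloff (central crop)."""
    t = np.arange(size) - size // 2
    x = _KB_BETA**2 - (np.pi * _KB_WIDTH * t / n_grid) ** 2
    x = np.sqrt(x.astype(complex))
    psi = np.real(np.sinh(x) / x)  # FT of the KB kernel up to a constant
    return 1.0 / psi


def _interp_matrix(coords: np.ndarray, n_grid: int) -> sparse.csr_matrix:
    """Sparse interpolation from an n_grid x n_grid k-space grid to samples.

    coords: (M, 2) in cycles/pixel; rows are samples, columns flat grid index.
    """
    m = coords.shape[0]
    g = coords * n_grid + n_grid // 2  # fractional grid positions (y, x)
    j0 = np.ceil(g - _KB_WIDTH / 2.0).astype(int)  # (M, 2)
    offs = np.arange(_KB_WIDTH)
    jy = j0[:, 0:1] + offs[None, :]
    jx = j0[:, 1:2] + offs[None, :]
    wy = _kb_kernel(jy - g[:, 0:1])
    wx = _kb_kernel(jx - g[:, 1:2])
    w2 = wy[:, :, None] * wx[:, None, :]
    cols = (np.mod(jy[:, :, None], n_grid) * n_grid + np.mod(jx[:, None, :], n_grid))
    rows = np.repeat(np.arange(m), _KB_WIDTH * _KB_WIDTH)
    mat = sparse.coo_matrix(
        (w2.ravel(), (rows, cols.ravel())), shape=(m, n_grid * n_grid)
    )
    return mat.tocsr()


def _fft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


def _ifft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


# ---------------------------------------------------------------------------
# encoding operator
# ---------------------------------------------------------------------------

@dataclass
class EncodingSpec:
    """Frame-resolved multi-coil radial Fourier encoding operator E.

    forward: image series (T, H, W) -> weighted k-space (C, S, R); adjoint is
    the exact conjugate transpose. Each frame only sees its own spokes.
    """

    shape: tuple
    coils: CoilSensitivities
    trajectory: RadialTrajectory
    frame_of_spoke: np.ndarray
    weights: np.ndarray = None
    refine_dcf: bool = True
    _interp: sparse.csr_matrix = field(default=None, repr=False)
    _frame_rows: list = field(default=None, repr=False)
    _scale: float = field(default=None, repr=False)

    def __post_init__(self) -> None:
        h, w = self.shape
        if h != w:
            raise ValueError("square images only")
        if self.coils.maps.shape[1:] != (h, w):
            raise ValueError("coil maps must match image shape")
        if self.weights is None:
            self.weights = density_compensation(self.trajectory)
        self.frame_of_spoke = np.asarray(self.frame_of_spoke)
        self.n_frames = int(self.frame_of_spoke.max()) + 1
        for f in range(self.n_frames):
            if not np.any(self.frame_of_spoke == f):
                raise ValueError(f"frame {f} has no spokes")
        self._n_grid = _OVERSAMP * h
        self._deapod = np.outer(
            _deapodization(h, self._n_grid), _deapodization(w, self._n_grid)
        )
        flat_coords = self.trajectory.coords.reshape(-1, 2)
        self._interp = _interp_matrix(flat_coords, self._n_grid)
        self._frame_rows = [
            np.flatnonzero(np.repeat(self.frame_of_spoke, self.trajectory.n_readout) == f)
            for f in range(self.n_frames)
        ]
        if self.refine_dcf:
            # Pipe-Menon fixed point w <- w / (A A^T w): flattens the effective
            # k-space transfer function beyond the analytic ramp approximation
            wf = self.weights.reshape(-1).astype(float).copy()
            for _ in range(50):
                dens = self._interp @ (self._interp.T @ wf)
                wf = wf / np.maximum(dens, 1e-30 * dens.max())
                wf /= wf.mean()
            self.weights = wf.reshape(self.weights.shape)
        self._sqrt_w = np.sqrt(self.weights).reshape(-1)
        self._scale = 1.0
        self._scale = self._calibrate()
        self._frame_gain_cache = None

    # -- internals ---------------------------------------------------------
    def _grid_forward(self, img: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """(C, H, W) image -> (C, m) samples at the given trajectory rows."""
        h, w = self.shape
        n = self._n_grid
        x = img * self._deapod
        pad = np.zeros(img.shape[:-2] + (n, n), dtype=np.complex128)
        r0, c0 = (n - h) // 2, (n - w) // 2
        pad[..., r0 : r0 + h, c0 : c0 + w] = x
        k = _fft2c(pad)
        kf = k.reshape(-1, n * n)
        samp = self._interp[rows] @ kf.T  # (m, C)
        return samp.T

    def _grid_adjoint(self, samp: np.ndarray, rows: np.ndarray) -> np.ndarray:
        """(C, m) samples -> (C, H, W) image (adjoint of _grid_forward)."""
        h, w = self.shape
        n = self._n_grid
        kf = self._interp[rows].T @ samp.T  # (n*n, C)
        k = kf.T.reshape(-1, n, n)
        img = _ifft2c(k)
        r0, c0 = (n - h) // 2, (n - w) // 2
        crop = img[..., r0 : r0 + h, c0 : c0 + w]
        return crop * self._deapod

    def _calibrate(self) -> float:
        """Scalar fixing the DC gain of E^H E to one at full sampling
        (unit coil, all spokes with their density weights), so smooth objects
        come back at the right intensity."""
        h, w = self.shape
        ones = np.ones((1, h, w), dtype=np.complex128)
        rows = np.arange(self._interp.shape[0])
        samp = self._grid_forward(ones, rows) * self._sqrt_w[rows]
        back = self._grid_adjoint(samp * self._sqrt_w[rows], rows)
        val = float(np.mean(np.real(back)))
        return 1.0 / np.sqrt(val)

    def frame_gains(self) -> np.ndarray:
        """Per-frame DC gain of the weighted gridding normal operator (unit
        coil); divides the plain density-compensated adjoint reconstruction so
        undersampled frames keep quantitative intensity."""
        if self._frame_gain_cache is None:
            h, w = self.shape
            ones = np.ones((1, h, w), dtype=np.complex128)
            gains = np.empty(self.n_frames)
            for f in range(self.n_frames):
                rows = self._frame_rows[f]
                samp = self._grid_forward(ones, rows) * self._sqrt_w[rows]
                back = self._grid_adjoint(samp * self._sqrt_w[rows], rows)
                gains[f] = float(np.mean(np.real(back))) * self._scale**2
            self._frame_gain_cache = gains
        return self._frame_gain_cache

    # -- public operator ---------------------------------------------------
    def forward(self, series: DynamicImageSeries) -> MultiCoilKSpace:
        """E: per-frame coil weighting, NUFFT onto the frame's spokes, sqrt(w)."""
        if series.data.shape[0] != self.n_frames:
            raise ValueError("series frame count must match the binning")
        if series.data.shape[1:] != tuple(self.shape):
            raise ValueError("series spatial shape mismatch")
        c = self.coils.maps
        out = np.zeros(
            (c.shape[0], self.trajectory.n_spokes, self.trajectory.n_readout),
            dtype=np.complex128,
        )
        flat = out.reshape(c.shape[0], -1)
        for f in range(self.n_frames):
            rows = self._frame_rows[f]
            img = c * series.data[f][None]
            samp = self._grid_forward(img, rows)
            flat[:, rows] = samp * (self._sqrt_w[rows] * self._scale)
        return MultiCoilKSpace(
            data=out,
            trajectory=self.trajectory,
            frame_of_spoke=self.frame_of_spoke,
            density_weights=self.weights,
        )

    def adjoint(self, ksp, frame_times: np.ndarray = None) -> DynamicImageSeries:
        """E^H: sqrt(w), transposed gridding, conjugate coil combination."""
        data = ksp.data if isinstance(ksp, MultiCoilKSpace) else np.asarray(ksp)
        c = self.coils.maps
        flat = data.reshape(c.shape[0], -1)
        h, w = self.shape
        out = np.zeros((self.n_frames, h, w), dtype=np.complex128)
        for f in range(self.n_frames):
            rows = self._frame_rows[f]
            samp = flat[:, rows] * (self._sqrt_w[rows] * self._scale)
            img = self._grid_adjoint(samp, rows)
            out[f] = np.sum(np.conj(c) * img, axis=0)
        return DynamicImageSeries(out, frame_times)


def make_encoding_spec(
    shape: tuple,
    coils: CoilSensitivities,
    n_spokes: int,
    spokes_per_frame: int,
    n_readout: int = None,
) -> EncodingSpec:
    """Build the standard golden-angle spec: trajectory + binning + weights."""
    h, _ = shape
    n_readout = n_readout or 2 * h
    traj = golden_angle_trajectory(n_spokes, n_readout)
    frame = bin_spokes(n_spokes, spokes_per_frame)
    return EncodingSpec(
        shape=tuple(shape), coils=coils, trajectory=traj, frame_of_spoke=frame
    )


def simulate_kspace(
    series: DynamicImageSeries,
    spec: EncodingSpec,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> MultiCoilKSpace:
    """y = E(truth) + complex white Gaussian noise (std noise_sigma per sample,
    split evenly between real and imaginary parts)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    ksp = spec.forward(series)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = (noise_sigma / np.sqrt(2.0)) * (
            rng.standard_normal(ksp.data.shape) + 1j * rng.standard_normal(ksp.data.shape)
        )
        ksp.data = ksp.data + noise
    return ksp


def lowres_subset(ksp: MultiCoilKSpace, L: int, coils: CoilSensitivities = None):
    """Retain the densely sampled k-space centre: samples with |k| <= L/(2H).

    Returns a MultiCoilKSpace whose trajectory is rescaled for an L x L grid,
    plus coil maps downsampled consistently (Fourier crop) when provided.
    """
    if L % 2 != 0:
        raise ValueError("L must be even")
    traj = ksp.trajectory
    full = traj.n_readout
    keep = np.abs(traj.radii) <= (L / full) * 0.5 + 1e-12
    new_radii = traj.radii[keep] * (full / L)
    angles = traj.angles
    kx = new_radii[None, :] * np.cos(angles)[:, None]
    ky = new_radii[None, :] * np.sin(angles)[:, None]
    new_traj = RadialTrajectory(
        angles=angles.copy(),
        coords=np.stack([ky, kx], axis=-1),
        radii=new_radii,
    )
    sub = MultiCoilKSpace(
        data=ksp.data[:, :, keep].copy(),
        trajectory=new_traj,
        frame_of_spoke=ksp.frame_of_spoke.copy(),
        density_weights=density_compensation(new_traj),
    )
    if coils is None:
        return sub
    return sub, downsample_coils(coils, L)


def downsample_coils(coils: CoilSensitivities, L: int) -> CoilSensitivities:
    """Fourier-crop smooth coil maps to an L x L grid."""
    c, h, w = coils.maps.shape
    if L > h:
        raise ValueError("L must not exceed the coil map size")
    k = _fft2c(coils.maps)
    r0, c0 = (h - L) // 2, (w - L) // 2
    crop = k[:, r0 : r0 + L, c0 : c0 + L]
    return CoilSensitivities(_ifft2c(crop) * (L / h))
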