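"""Reconstruction algorithms for golden-angle radial DCE-MRI.

Implements the density-compensated NUFFT baseline, the GRASP compressed
sensing reconstruction

    argmin_M  1/2 ||y - E M||^2 + lambda ||S M||_1,

temporal-basis estimation by per-region PCA of the Casorati matrix, and the
subspace-constrained reconstruction over coefficients V with fixed bases U

    argmin_V  1/2 ||y - E sum_i U_i V_i||^2 + lambda ||S sum_i U_i V_i||_1,

where regions are the whole image (globally low rank), overlapping blocks
(locally low rank) or tissue segments with a one-component background (the
ELITE mode). Both problems are solved by nonlinear conjugate gradient with a
smoothed l1 temporal total-variation penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.cluster import KMeans

from .encoding import EncodingSpec, MultiCoilKSpace
from .regions import (
    RegionPartition,
    partition_blocks,
    partition_from_labels,
    whole_image_partition,
)
from .series import DynamicImageSeries

__all__ = [
    "ReconConfig",
    "TemporalBasis",
    "SubspaceCoefficients",
    "nufft_recon",
    "temporal_diff",
    "temporal_diff_adjoint",
    "grasp_recon",
    "estimate_basis",
    "compress",
    "expand",
    "subspace_recon",
    "partition_blocks",
    "kmeans_partition",
    "whole_image_partition",
]


@dataclass
class ReconConfig:
    """Iterative reconstruction settings.

    lam is the TV regularizer weight relative to the peak magnitude of the
    initial (density-compensated adjoint) image; n_iter conjugate-gradient
    iterations are run per repetition and the scheme restarts n_repeat times.
    K components per tissue region and K_background for the background region.
    """

    lam: float = 0.01
    n_iter: int = 7
    n_repeat: int = 3
    K: int = 6
    K_background: int = 1
    block_grid: int = 10
    block_overlap: float = 0.5
    l1_smooth: float = 1e-6
    max_backtracks: int = 20

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.n_iter < 1 or self.n_repeat < 1:
            raise ValueError("n_iter and n_repeat must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class TemporalBasis:
    """Per-region temporal bases U_i, each T x K_i with orthonormal columns."""

    bases: list

    def __post_init__(self) -> None:
        for u in self.bases:
            k = u.shape[1]
            gram = u.conj().T @ u
            if not np.allclose(gram, np.eye(k), atol=1e-8):
                raise ValueError("basis columns must be orthonormal")

    @property
    def n_regions(self) -> int:
        return len(self.bases)


@dataclass
class SubspaceCoefficients:
    """Per-region coefficient matrices V_i, each K_i x M_i."""

    coeffs: list


# ---------------------------------------------------------------------------
# baseline NUFFT reconstruction
# ---------------------------------------------------------------------------

def nufft_recon(ksp: MultiCoilKSpace, spec: EncodingSpec, frame_times=None,
                combine: str = "sensitivity") -> DynamicImageSeries:
    """Per-frame density-compensated adjoint (gridding) reconstruction.

    Coil combination is either sensitivity-weighted (conjugate coil sum
    normalized by the sum-of-squares map) or root-sum-of-squares of per-coil
    gridding images. Output is the magnitude series.
    """
    adj = spec.adjoint(ksp, frame_times)
    gains = spec.frame_gains()
    if combine == "sensitivity":
        sos = np.sum(np.abs(spec.coils.maps) ** 2, axis=0)
        sos = np.maximum(sos, 1e-8 * sos.max() if sos.max() > 0 else 1e-8)
        data = np.abs(adj.data) / sos[None]
    elif combine == "rss":
        data = np.abs(adj.data)
    else:
        raise ValueError("combine must be 'sensitivity' or 'rss'")
    data = data / gains[:, None, None]
    return DynamicImageSeries(data, adj.frame_times)


# ---------------------------------------------------------------------------
# temporal total variation (finite differences along time)
# ---------------------------------------------------------------------------

def temporal_diff(x: np.ndarray) -> np.ndarray:
    """Forward difference along the first (time) axis: length T-1."""
    if x.shape[0] < 2:
        raise ValueError("need at least two frames")
    return x[1:] - x[:-1]


def temporal_diff_adjoint(d: np.ndarray) -> np.ndarray:
    """Exact adjoint of temporal_diff (negative backward difference)."""
    t = d.shape[0] + 1
    out = np.zeros((t,) + d.shape[1:], dtype=d.dtype)
    out[0] = -d[0]
    out[-1] = d[-1]
    if t > 2:
        out[1:-1] = d[:-1] - d[1:]
    return out


# ---------------------------------------------------------------------------
# nonlinear conjugate gradient with smoothed-l1 temporal TV
# ---------------------------------------------------------------------------

def _nlcg(a_fwd, a_adj, y, x0, lam_abs, eps, n_iter, n_repeat, max_backtracks,
          tv_fwd, tv_adj):
    """Minimize 1/2||y - A x||^2 + lam * sum sqrt(|S x|^2 + eps) over complex x.

    Fletcher-Reeves NLCG with Armijo backtracking. A and S are linear, so line
    search objective values reuse cached A d and S d (no extra operator calls).
    Returns (x, objective trace over accepted iterates).
    """

    def l1s(u):
        return float(np.sum(np.sqrt(np.abs(u) ** 2 + eps)))

    x = x0.copy()
    ax = a_fwd(x)
    sx = tv_fwd(x)
    r = ax - y
    trace = []

    def objective(r_, sx_):
        return 0.5 * float(np.vdot(r_, r_).real) + lam_abs * l1s(sx_)

    f = objective(r, sx)
    trace.append(f)

    for _ in range(n_repeat):
        g = a_adj(r)
        if lam_abs > 0:
            g = g + lam_abs * tv_adj(sx / np.sqrt(np.abs(sx) ** 2 + eps))
        d = -g
        g_norm2 = float(np.vdot(g, g).real)
        for _ in range(n_iter):
            if g_norm2 == 0:
                break
            ad = a_fwd(d)
            sd = tv_fwd(d)
            slope = float(np.vdot(g, d).real)
            if slope >= 0:  # not a descent direction: restart
                d = -g
                ad = a_fwd(d)
                sd = tv_fwd(d)
                slope = float(np.vdot(g, d).real)
            denom = float(np.vdot(ad, ad).real)
            alpha = -slope / denom if denom > 0 else 1.0
            accepted = False
            for _bt in range(max_backtracks):
                f_new = objective(r + alpha * ad, sx + alpha * sd)
                if f_new <= f + 1e-4 * alpha * slope:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
            x = x + alpha * d
            r = r + alpha * ad
            sx = sx + alpha * sd
            f = f_new
            trace.append(f)
            g_new = a_adj(r)
            if lam_abs > 0:
                g_new = g_new + lam_abs * tv_adj(sx / np.sqrt(np.abs(sx) ** 2 + eps))
            g_new_norm2 = float(np.vdot(g_new, g_new).real)
            beta = g_new_norm2 / g_norm2 if g_norm2 > 0 else 0.0
            d = -g_new + beta * d
            g = g_new
            g_norm2 = g_new_norm2
    return x, trace


def grasp_recon(
    ksp: MultiCoilKSpace,
    spec: EncodingSpec,
    cfg: ReconConfig = None,
    frame_times=None,
    return_trace: bool = False,
):
    """GRASP: compressed sensing with temporal TV over the full image series.

    Nonlinear CG on 1/2||y - E M||^2 + lam||S M||_1 (smoothed l1), initialized
    at the density-compensated adjoint. lam and the l1 smoothing are scaled by
    the peak magnitude of the initial image.
    """
    cfg = cfg or ReconConfig()
    if not np.all(np.isfinite(ksp.data.real)) or not np.all(np.isfinite(ksp.data.imag)):
        raise ValueError("k-space data must be finite")
    x0 = spec.adjoint(ksp, frame_times).data
    scale = float(np.max(np.abs(x0)))
    lam_abs = cfg.lam * scale
    eps = (cfg.l1_smooth * scale) ** 2

    def a_fwd(x):
        return spec.forward(DynamicImageSeries(x)).data

    def a_adj(r):
        return spec.adjoint(r).data

    x, trace = _nlcg(
        a_fwd, a_adj, ksp.data, x0, lam_abs, eps, cfg.n_iter, cfg.n_repeat,
        cfg.max_backtracks, temporal_diff, temporal_diff_adjoint,
    )
    series = DynamicImageSeries(x, frame_times)
    return (series, trace) if return_trace else series


# ---------------------------------------------------------------------------
# subspace model: basis estimation, compression, expansion
# ---------------------------------------------------------------------------

def _fix_sign(u: np.ndarray) -> np.ndarray:
    """Rotate each column so its largest-magnitude entry is positive real."""
    for j in range(u.shape[1]):
        idx = int(np.argmax(np.abs(u[:, j])))
        pivot = u[idx, j]
        if np.abs(pivot) > 0:
            u[:, j] = u[:, j] * (np.conj(pivot) / np.abs(pivot))
    return u


def estimate_basis(
    lowres: DynamicImageSeries,
    partition: RegionPartition,
    cfg: ReconConfig = None,
    background_region: str = "background",
) -> TemporalBasis:
    """Per-region temporal PCA bases from the Casorati matrix.

    For each region the T x M_i matrix of pixel time-courses is decomposed
    (SVD without mean-centering, the subspace model M = U V has no intercept)
    and the K leading left singular vectors are kept, K_background for the
    region named `background_region`. Regions smaller than K reduce K with a
    warning.
    """
    cfg = cfg or ReconConfig()
    t = lowres.data.shape[0]
    flat = lowres.data.reshape(t, -1)
    bases = []
    for i, name in enumerate(partition.region_names):
        idx = partition.indices(i)
        k = cfg.K_background if name == background_region else cfg.K
        k = min(k, t)
        if idx.size == 0:
            bases.append(np.zeros((t, 0), dtype=lowres.data.dtype))
            continue
        if idx.size < k:
            warnings.warn(
                f"region {name!r} has {idx.size} pixels < K={k}; reducing K"
            )
            k = idx.size
        cas = flat[:, idx]
        # SVD via the T x T Gram matrix (M_i can be large, T is small)
        gram = cas @ cas.conj().T
        evals, evecs = np.linalg.eigh(gram)
        order = np.argsort(evals)[::-1][:k]
        u = evecs[:, order]
        bases.append(_fix_sign(u))
    return TemporalBasis(bases=bases)


def compress(
    series: DynamicImageSeries, basis: TemporalBasis, partition: RegionPartition
) -> SubspaceCoefficients:
    """V_i = U_i^H Casorati_i for each region."""
    if basis.n_regions != partition.n_regions:
        raise ValueError("basis/partition mismatch")
    t = series.data.shape[0]
    flat = series.data.reshape(t, -1)
    coeffs = []
    for i in range(partition.n_regions):
        idx = partition.indices(i)
        coeffs.append(basis.bases[i].conj().T @ flat[:, idx])
    return SubspaceCoefficients(coeffs=coeffs)


def expand(
    basis: TemporalBasis,
    coeffs: SubspaceCoefficients,
    partition: RegionPartition,
    frame_times=None,
) -> DynamicImageSeries:
    """Reassemble Casorati_i = U_i V_i into an image series; overlapping
    blocks are averaged over the blocks covering each pixel."""
    if basis.n_regions != partition.n_regions:
        raise ValueError("basis/partition mismatch")
    t = basis.bases[0].shape[0] if basis.bases else 0
    n_pix = int(np.prod(partition.shape))
    out = np.zeros((t, n_pix), dtype=np.complex128)
    for i in range(partition.n_regions):
        idx = partition.indices(i)
        if idx.size == 0:
            continue
        block = basis.bases[i] @ coeffs.coeffs[i]
        if partition.is_blocks:
            np.add.at(out, (slice(None), idx), block)
        else:
            out[:, idx] = block
    if partition.is_blocks:
        out /= partition.coverage()[None, :]
    return DynamicImageSeries(out.reshape((t,) + tuple(partition.shape)), frame_times)


class _SubspaceVec:
    """Flat-vector view of per-region coefficient matrices."""

    def __init__(self, basis: TemporalBasis, partition: RegionPartition):
        self.basis = basis
        self.partition = partition
        self.sizes = [
            basis.bases[i].shape[1] * partition.indices(i).size
            for i in range(partition.n_regions)
        ]
        self.shapes = [
            (basis.bases[i].shape[1], partition.indices(i).size)
            for i in range(partition.n_regions)
        ]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self._idx = [partition.indices(i) for i in range(partition.n_regions)]
        self._cov = partition.coverage().astype(float) if partition.is_blocks else None

    @property
    def n_unknowns(self) -> int:
        return int(self.offsets[-1])

    def to_vec(self, coeffs: SubspaceCoefficients) -> np.ndarray:
        return np.concatenate([c.ravel() for c in coeffs.coeffs])

    def to_coeffs(self, vec: np.ndarray) -> SubspaceCoefficients:
        return SubspaceCoefficients(
            coeffs=[
                vec[self.offsets[i] : self.offsets[i + 1]].reshape(self.shapes[i])
                for i in range(len(self.sizes))
            ]
        )

    def expand_vec(self, vec: np.ndarray, t: int, shape: tuple) -> np.ndarray:
        out = np.zeros((t, int(np.prod(shape))), dtype=np.complex128)
        for i in range(len(self.sizes)):
            idx = self._idx[i]
            if idx.size == 0:
                continue
            v = vec[self.offsets[i] : self.offsets[i + 1]].reshape(self.shapes[i])
            block = self.basis.bases[i] @ v
            if self.partition.is_blocks:
                np.add.at(out, (slice(None), idx), block)
            else:
                out[:, idx] = block
        if self._cov is not None:
            out /= self._cov[None, :]
        return out.reshape((t,) + tuple(shape))

    def adjoint_vec(self, img: np.ndarray) -> np.ndarray:
        t = img.shape[0]
        flat = img.reshape(t, -1)
        if self._cov is not None:
            flat = flat / self._cov[None, :]
        parts = []
        for i in range(len(self.sizes)):
            idx = self._idx[i]
            parts.append((self.basis.bases[i].conj().T @ flat[:, idx]).ravel())
        return np.concatenate(parts)


def subspace_recon(
    ksp: MultiCoilKSpace,
    spec: EncodingSpec,
    basis: TemporalBasis,
    partition: RegionPartition,
    cfg: ReconConfig = None,
    frame_times=None,
    return_trace: bool = False,
):
    """Subspace-constrained reconstruction over coefficients V (bases fixed).

    Same nonlinear CG scheme and objective as grasp_recon, but the unknowns
    are the per-region subspace coefficients; the solution is expand(V*).
    Region choice selects the mode: whole image (GLR), overlapping blocks
    (LLR) or tissue segments with a single background component (ELITE).
    """
    cfg = cfg or ReconConfig()
    if not np.all(np.isfinite(ksp.data.real)) or not np.all(np.isfinite(ksp.data.imag)):
        raise ValueError("k-space data must be finite")
    t = spec.n_frames
    vec = _SubspaceVec(basis, partition)
    shape = tuple(partition.shape)

    adj0 = spec.adjoint(ksp, frame_times)
    scale = float(np.max(np.abs(adj0.data)))
    lam_abs = cfg.lam * scale
    eps = (cfg.l1_smooth * scale) ** 2
    v0 = vec.to_vec(compress(adj0, basis, partition))

    def a_fwd(v):
        return spec.forward(DynamicImageSeries(vec.expand_vec(v, t, shape))).data

    def a_adj(r):
        return vec.adjoint_vec(spec.adjoint(r).data)

    def tv_fwd(v):
        return temporal_diff(vec.expand_vec(v, t, shape))

    def tv_adj(d):
        return vec.adjoint_vec(temporal_diff_adjoint(d))

    v_opt, trace = _nlcg(
        a_fwd, a_adj, ksp.data, v0, lam_abs, eps, cfg.n_iter, cfg.n_repeat,
        cfg.max_backtracks, tv_fwd, tv_adj,
    )
    series = DynamicImageSeries(vec.expand_vec(v_opt, t, shape), frame_times)
    return (series, trace) if return_trace else series


def kmeans_partition(
    lowres: DynamicImageSeries, n_clusters: int, seed: int = 0
) -> RegionPartition:
    """Cluster pixel time-courses (l2, k-means++ init) into regions."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    t = lowres.data.shape[0]
    x = np.abs(lowres.data.reshape(t, -1)).T
    if n_clusters > x.shape[0]:
        raise ValueError("more clusters than pixels")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(x).astype(np.int16)
    return partition_from_labels(
        labels.reshape(lowres.data.shape[1:]),
        [f"cluster_{i}" for i in range(n_clusters)],
    )
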