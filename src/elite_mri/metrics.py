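"""Quantitative evaluation: CNR, background noise from consecutive-frame
subtraction, and enhancement-curve similarity.

The noise estimate follows the frame-subtraction approach: consecutive
post-injection frames differ only by random noise (and residual artifact
fluctuation), so the pooled standard deviation of difference images over
background ROIs, divided by sqrt(2), estimates the per-frame noise level.
CNR = |mean_lesion - mean_fibroglandular| / noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import RegionPartition
from .series import DynamicImageSeries

__all__ = [
    "ROISet",
    "MetricsReport",
    "background_noise",
    "cnr",
    "curve_similarity",
    "fold_change",
    "rois_from_partition",
    "evaluate_series",
]


@dataclass
class ROISet:
    """Lesion mask, fibroglandular mask and background rectangles.

    Masks are boolean (H, W); background_rects are (row0, row1, col0, col1)
    half-open pixel ranges that must lie outside the object support.
    """

    lesion: np.ndarray
    fibroglandular: np.ndarray
    background_rects: list

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=bool)
        self.fibroglandular = np.asarray(self.fibroglandular, dtype=bool)
        if not self.lesion.any() or not self.fibroglandular.any():
            raise ValueError("lesion and fibroglandular masks must be non-empty")
        if np.any(self.lesion & self.fibroglandular):
            raise ValueError("masks must be disjoint")
        if not self.background_rects:
            raise ValueError("need at least one background rectangle")

    def background_mask(self) -> np.ndarray:
        mask = np.zeros(self.lesion.shape, dtype=bool)
        for r0, r1, c0, c1 in self.background_rects:
            mask[r0:r1, c0:c1] = True
        return mask


@dataclass
class MetricsReport:
    method: str
    cnr: float
    noise_sd: float
    curve_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def rois_from_partition(
    partition: RegionPartition,
    n_background: int = 6,
    rect_size: int = None,
    lesion_name: str = "lesion",
    fibro_name: str = "fibroglandular",
    background_name: str = "background",
) -> ROISet:
    """Derive the standard ROI set from a tissue label map.

    Background rectangles (default size scales with the image, 8 px at
    160 px matrix) are placed greedily in rows of pure-background pixels
    scanning from the image corners inward.
    """
    if partition.is_blocks:
        raise ValueError("need a tissue label map")
    names = partition.region_names
    lm = partition.label_map
    if rect_size is None:
        rect_size = max(3, round(lm.shape[0] / 20))
    lesion = lm == names.index(lesion_name)
    fibro = lm == names.index(fibro_name)
    bg = lm == names.index(background_name)
    h, w = lm.shape
    rects = []
    step = rect_size + 2
    for r0 in range(1, h - rect_size, step):
        for c0 in range(1, w - rect_size, step):
            if len(rects) >= n_background:
                break
            if bg[r0 : r0 + rect_size, c0 : c0 + rect_size].all():
                rects.append((r0, r0 + rect_size, c0, c0 + rect_size))
        if len(rects) >= n_background:
            break
    if len(rects) < n_background:
        raise ValueError("could not place the requested background ROIs")
    return ROISet(lesion=lesion, fibroglandular=fibro, background_rects=rects)


def background_noise(
    series: DynamicImageSeries, rois: ROISet, frame_range: slice = None
) -> float:
    """Noise SD from consecutive-frame differences pooled over background ROIs.

    The difference of two frames that share the underlying object doubles the
    noise variance, hence the sqrt(2) correction.
    """
    data = np.abs(series.data)
    if frame_range is not None:
        data = data[frame_range]
    if data.shape[0] < 2:
        raise ValueError("frame_range must contain at least two frames")
    mask = rois.background_mask()
    if not mask.any():
        raise ValueError("empty background ROI")
    diffs = data[1:] - data[:-1]
    vals = diffs[:, mask].ravel()
    return float(np.std(vals) / np.sqrt(2.0))


def cnr(series: DynamicImageSeries, rois: ROISet, frame: int, noise_sd: float) -> float:
    """|mean_lesion - mean_fibroglandular| at the given frame over noise_sd."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    img = np.abs(series.data[frame])
    return float(
        np.abs(img[rois.lesion].mean() - img[rois.fibroglandular].mean()) / noise_sd
    )


def peak_lesion_frame(series: DynamicImageSeries, rois: ROISet) -> int:
    """Frame index with the highest mean lesion signal."""
    means = np.abs(series.data)[:, rois.lesion].mean(axis=1)
    return int(np.argmax(means))


def curve_similarity(curve_a: np.ndarray, curve_b: np.ndarray):
    """(Pearson r, Euclidean norm of the peak-normalized difference).

    r is computed on the raw curves; for the norm both curves are first
    scaled to unit peak so the score reflects shape, not amplitude. A constant
    curve has undefined correlation, reported as NaN.
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("curves must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    an = a / np.max(np.abs(a)) if np.max(np.abs(a)) > 0 else a
    bn = b / np.max(np.abs(b)) if np.max(np.abs(b)) > 0 else b
    return r, float(np.linalg.norm(an - bn))


def fold_change(reports: list, reference_method: str) -> dict:
    """CNR and inverse-noise fold changes of each method vs the reference."""
    ref = next((m for m in reports if m.method == reference_method), None)
    if ref is None:
        raise ValueError(f"reference method {reference_method!r} not in reports")
    table = {}
    for m in reports:
        entry = {}
        entry["cnr_fold"] = m.cnr / ref.cnr if ref.cnr != 0 else float("nan")
        entry["noise_reduction_fold"] = (
            ref.noise_sd / m.noise_sd if m.noise_sd != 0 else float("nan")
        )
        table[m.method] = entry
    return table


def evaluate_series(
    series: DynamicImageSeries,
    rois: ROISet,
    method: str,
    frame: int = None,
    post_injection: slice = None,
) -> MetricsReport:
    """Noise + CNR report for one reconstruction (peak-lesion frame default)."""
    noise = background_noise(series, rois, post_injection)
    if frame is None:
        frame = peak_lesion_frame(series, rois)
    return MetricsReport(method=method, cnr=cnr(series, rois, frame, noise), noise_sd=noise)
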