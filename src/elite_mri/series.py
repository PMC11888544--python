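"""Dynamic image series container shared by the encoding and reconstruction layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DynamicImageSeries:
    """T frames of a (possibly complex) 2D image with their acquisition times.

    data has shape (T, H, W); frame_times are seconds from the start of the
    scan and must be strictly increasing.
    """

    data: np.ndarray
    frame_times: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (T, H, W)")
        if self.frame_times is None:
            self.frame_times = np.arange(self.data.shape[0], dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.data.shape[0],):
            raise ValueError("frame_times must have one entry per frame")
        if self.data.shape[0] >= 2 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def magnitude(self) -> "DynamicImageSeries":
        return DynamicImageSeries(np.abs(self.data), self.frame_times.copy())


def nrmse(x: np.ndarray, ref: np.ndarray) -> float:
    """Normalized root-mean-square error ||x - ref|| / ||ref||."""
    x = np.asarray(x)
    ref = np.asarray(ref)
    denom = np.linalg.norm(ref)
    if denom == 0:
        return float(np.linalg.norm(x) > 0)
    return float(np.linalg.norm(x - ref) / denom)
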