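"""Core domain containers shared across the pipeline.

Coordinates follow the (x, y) convention — x is the column index, y the
row index — so that converting fragment positions to polar angles with
``atan2(y - cy, x - cx)`` matches the usual mathematical orientation.
Areas are in pixels² unless converted through an :class:`ImageCalibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Invalid input or configuration (CLI exit code 2)."""


@dataclass(frozen=True)
class ImageCalibration:
    """Physical calibration of an image or time-lapse stack.

    Parameters
    ----------
    pixel_size : float
        Lateral sampling in µm per pixel. Default 0.1 µm/px, so a 2 µm
        tubule spans 20 pixels and is comfortably resolvable.
    frame_interval : float
        Seconds per frame for time-lapse stacks. Default 1 s, so a one
        minute video is 60 frames.
    """

    pixel_size: float = 0.1
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be > 0")
        if not (self.frame_interval > 0):
            raise ValidationError("frame_interval must be > 0")

    def px_to_um(self, value_px: float) -> float:
        return float(value_px) * self.pixel_size

    def um_to_px(self, value_um: float) -> float:
        return float(value_um) / self.pixel_size


@dataclass
class Fragment:
    """One detected (or ground-truth) intracellular structure."""

    centroid: tuple[float, float]  # (x, y) in px
    area: float  # px²
    integrated_intensity: float = 0.0


@dataclass
class FragmentSet:
    """Fragments/puncta belonging to one segmented cell."""

    cell_id: int
    fragments: list[Fragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids; empty (0, 2) when no fragments."""
        if not self.fragments:
            return np.empty((0, 2), dtype=float)
        return np.asarray([f.centroid for f in self.fragments], dtype=float)

    @property
    def areas(self) -> np.ndarray:
        return np.asarray([f.area for f in self.fragments], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.asarray([f.integrated_intensity for f in self.fragments], dtype=float)


@dataclass
class CellRecord:
    """One segmented cell with its nucleus."""

    cell_id: int
    cell_mask: np.ndarray  # boolean, full image shape
    cell_centroid: tuple[float, float]  # (x, y) px
    nucleus_centroid: tuple[float, float]  # (x, y) px
    treatment: str = ""

    def contains(self, x: float, y: float) -> bool:
        r, c = int(round(y)), int(round(x))
        h, w = self.cell_mask.shape
        return 0 <= r < h and 0 <= c < w and bool(self.cell_mask[r, c])


def as_float_image(image: np.ndarray, ndim: int | Sequence[int] = 2) -> np.ndarray:
    """Validate dimensionality and return a float64 view/copy of ``image``."""
    arr = np.asarray(image)
    allowed = (ndim,) if isinstance(ndim, int) else tuple(ndim)
    if arr.ndim not in allowed:
        raise ValidationError(f"expected {allowed}-d image, got {arr.ndim}-d")
    return arr.astype(float, copy=False)
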