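"""Shared data containers for the microvessel quantification pipeline.

Conventions used throughout the package: images are 2-D numpy arrays indexed
(row, col), 0-based; physical lengths are micrometres (µm) converted through
``pixel_size`` (µm/pixel); angles are degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiMask", "VesselMask", "SlowTimeStack", "PowerImage"]


@dataclass
class RoiMask:
    """Region of interest (e.g. a manually segmented nodule boundary).

    Parameters
    ----------
    data : bool array, shape (rows, cols)
    pixel_size : float
        µm per pixel.
    provenance : {"manual", "synthetic"}
    """

    data: np.ndarray
    pixel_size: float
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("ROI must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.data.any():
            raise ValueError("ROI must contain at least one pixel")
        if self.provenance not in ("manual", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def area_px(self) -> int:
        return int(self.data.sum())

    @classmethod
    def full(cls, shape: tuple[int, int], pixel_size: float) -> "RoiMask":
        """ROI covering the whole canvas."""
        return cls(np.ones(shape, dtype=bool), pixel_size)


@dataclass
class VesselMask:
    """Binary vessel map restricted to an ROI."""

    data: np.ndarray
    roi: RoiMask
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.roi.data.shape:
            raise ValueError("vessel mask and ROI shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        # restriction invariant: vessels live inside the ROI
        self.data &= self.roi.data

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SlowTimeStack:
    """Slow-time ensemble: (rows, cols, frames) of echo samples.

    ``data`` may be real (synthetic fixtures) or complex (IQ); all power
    computations use the squared magnitude. ``components``, when present,
    holds the separate additive terms a synthetic generator used (tissue,
    blood, noise) so filters can be checked against ground truth.
    """

    data: np.ndarray
    frame_rate: float = 1000.0
    pixel_size: float = 100.0
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must have shape (rows, cols, frames)")
        if self.data.shape[2] < 2:
            raise ValueError("stack needs at least 2 frames")
        if not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def casorati(self) -> np.ndarray:
        """Reshape to the (pixels x frames) Casorati matrix."""
        r, c, t = self.data.shape
        return self.data.reshape(r * c, t)


@dataclass
class PowerImage:
    """Non-negative microvessel intensity (power) image."""

    values: np.ndarray
    pixel_size: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("power image must be 2-D")
        if (self.values < 0).any():
            raise ValueError("power image must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
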