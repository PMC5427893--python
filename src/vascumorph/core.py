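"""Shared containers and exceptions for the vascular-morphometry pipeline.

All raster coordinates in this package are 0-based ``(row, col)`` with the
origin at the top-left corner, row-major — the convention every module shares.
Physical scale is carried alongside rasters as a pixel size in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationError",
    "DegenerateInputError",
    "SchemaError",
    "VesselImage",
    "BinaryVesselMask",
]


class ConfigurationError(ValueError):
    """An analysis or generator configuration is invalid."""


class DegenerateInputError(ValueError):
    """Input is formally valid but degenerate for the requested operation
    (e.g. Otsu thresholding of a constant image)."""


class SchemaError(ValueError):
    """A tabular input is missing required columns."""


@dataclass(frozen=True)
class VesselImage:
    """A 2D grayscale fluorescence-style image with physical pixel size.

    Attributes
    ----------
    data : ndarray
        2D float or integer array; bright pixels are vessel signal.
    pixel_size_um : float
        Physical edge length of one pixel, in micrometres (> 0).
    """

    data: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if np.ndim(self.data) != 2 or np.size(self.data) == 0:
            raise ConfigurationError("VesselImage.data must be a non-empty 2D array")
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryVesselMask:
    """Boolean raster of vessel foreground with physical pixel size."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if np.ndim(self.mask) != 2 or np.size(self.mask) == 0:
            raise ConfigurationError("BinaryVesselMask.mask must be a non-empty 2D array")
        if self.mask.dtype != np.bool_:
            object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2
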