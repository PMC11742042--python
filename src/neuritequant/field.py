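"""Calibrated single-channel image container.

An :class:`ImageField` is one 2D intensity grid for one channel of one
microscope field, together with the pixel calibration (µm/px) that every
derived area in the pipeline depends on.  All physical areas downstream are
``pixel count × pixel_size**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageField"]


@dataclass
class ImageField:
    """One calibrated 2D intensity grid for one channel of one field.

    Parameters
    ----------
    pixels : ndarray
        2D array of non-negative intensities.  Stored as given (integer
        straight off a TIFF, or float mid-pipeline); values must lie within
        the declared bit-depth range.
    pixel_size : float
        Pixel calibration in µm per pixel.  Must be positive.
    bit_depth : int
        8 or 16.  Sets the valid intensity range ``[0, 2**bit_depth - 1]``.
    channel : str
        Channel label, e.g. ``"calcein"``, ``"tmre"``, ``"hoechst"``.
    field_id, well_id, condition_id : str
        Bookkeeping identifiers carried through to output tables.
    """

    pixels: np.ndarray
    pixel_size: float
    bit_depth: int = 16
    channel: str = ""
    field_id: str = ""
    well_id: str = ""
    condition_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size:
            lo = float(self.pixels.min())
            hi = float(self.pixels.max())
            if not np.isfinite([lo, hi]).all():
                raise ValueError("pixels contain non-finite values")
            if lo < 0 or hi > self.max_value:
                raise ValueError(
                    f"intensities [{lo}, {hi}] outside {self.bit_depth}-bit "
                    f"range [0, {self.max_value}]"
                )

    @property
    def max_value(self) -> int:
        """Largest representable intensity for the declared bit depth."""
        return (1 << self.bit_depth) - 1

    @property
    def px_area_um2(self) -> float:
        """Physical area of one pixel in µm²."""
        return self.pixel_size**2

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ImageField":
        """Copy of this field with new pixel data, same calibration and ids."""
        return replace(self, pixels=pixels)
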