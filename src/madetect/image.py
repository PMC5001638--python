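"""Image containers and readers.

Two raster types flow through the pipeline:

``FundusImage``
    The original RGB fundus photograph plus an optional field-of-view (FOV)
    mask and the resolution scale factor ``rho = width / 768``.  768 px is the
    reference width at which vessels and microaneurysms span radii of about
    1-6 pixels.

``IntensityImage``
    A single-channel float raster in [0, 1] carrying ``rho`` and the FOV mask.
    The preprocessed green channel, the K map residuals and every derived map
    use this representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InvalidInputError

REFERENCE_WIDTH = 768.0


@dataclass
class FundusImage:
    """RGB fundus photograph with optional FOV mask."""

    pixels: np.ndarray                      # (H, W, 3) uint8/uint16 or float
    fov_mask: np.ndarray | None = None      # (H, W) bool, True inside FOV

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidInputError(
                f"expected a 3-channel RGB image, got shape {self.pixels.shape}"
            )
        if self.fov_mask is not None:
            if self.fov_mask.shape != self.pixels.shape[:2]:
                raise InvalidInputError(
                    "FOV mask dimensions do not match the image"
                )
            self.fov_mask = self.fov_mask.astype(bool)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def rho(self) -> float:
        return self.width / REFERENCE_WIDTH

    def as_float(self) -> np.ndarray:
        """RGB pixels rescaled once to float64 in [0, 1]."""
        px = self.pixels
        if px.dtype == np.uint8:
            return px.astype(np.float64) / 255.0
        if px.dtype == np.uint16:
            return px.astype(np.float64) / 65535.0
        return np.clip(px.astype(np.float64), 0.0, 1.0)


@dataclass
class IntensityImage:
    """Single-channel float raster in a declared [0, 1] range."""

    values: np.ndarray                      # (H, W) float64
    rho: float = 1.0
    fov_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidInputError("IntensityImage expects a 2-D raster")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("IntensityImage contains non-finite values")
        if self.fov_mask is not None and self.fov_mask.shape != self.values.shape:
            raise InvalidInputError("FOV mask dimensions do not match the raster")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def fov(self) -> np.ndarray:
        """Boolean FOV mask (all-true when none was supplied)."""
        if self.fov_mask is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.fov_mask

    def with_values(self, values: np.ndarray) -> "IntensityImage":
        return IntensityImage(values=values, rho=self.rho, fov_mask=self.fov_mask)


def load_fundus(path: str | Path, fov_path: str | Path | None = None) -> FundusImage:
    """Read a PNG/TIFF/JPEG RGB image, with an optional single-channel FOV mask."""
    px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:      # drop alpha
        px = px[:, :, :3]
    mask = None
    if fov_path is not None:
        m = iio.imread(fov_path)
        if m.ndim == 3:
            m = m[..., 0]
        mask = m > 0
    return FundusImage(pixels=px, fov_mask=mask)


def save_intensity(path: str | Path, img: IntensityImage) -> None:
    """Write a float raster as 32-bit TIFF."""
    tifffile.imwrite(str(path), img.values.astype(np.float32))


def load_intensity(path: str | Path, rho: float | None = None) -> IntensityImage:
    """Read a float TIFF back; ``rho`` defaults to width / 768."""
    values = tifffile.imread(str(path)).astype(np.float64)
    if rho is None:
        rho = values.shape[1] / REFERENCE_WIDTH
    return IntensityImage(values=values, rho=rho)
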