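"""Image container and TIFF I/O.

All physical coordinates in this package are in nanometres, with the origin
at the image's top-left corner, x increasing rightward (columns) and y
increasing downward (rows).  Pixel (i, j) covers the square
[j*p, (j+1)*p) x [i*p, (i+1)*p) where p is the pixel size in nm; the pixel's
sample point (for interpolation) is its centre ((j+0.5)*p, (i+0.5)*p).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class ImageChannel:
    """A single-channel 2D intensity raster with a physical pixel size.

    Attributes
    ----------
    data : np.ndarray
        2D array of intensities (photon counts for rendered scenes).
    pixel_size_nm : float
        Physical edge length of one pixel, in nanometres.
    channel : str
        Role label, conventionally ``"pre"`` or ``"post"``.
    """

    data: np.ndarray
    pixel_size_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("ImageChannel.data must be 2D")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def height_nm(self) -> float:
        return self.data.shape[0] * self.pixel_size_nm

    @property
    def width_nm(self) -> float:
        return self.data.shape[1] * self.pixel_size_nm

    def to_nm(self, row: float, col: float) -> tuple[float, float]:
        """Convert fractional pixel indices (row, col) to (x, y) in nm."""
        return ((col + 0.5) * self.pixel_size_nm, (row + 0.5) * self.pixel_size_nm)

    def to_px(self, x_nm: float, y_nm: float) -> tuple[float, float]:
        """Convert physical (x, y) nm to fractional (row, col) pixel indices."""
        return (y_nm / self.pixel_size_nm - 0.5, x_nm / self.pixel_size_nm - 0.5)


def write_tiff(path: str | Path, image: ImageChannel) -> None:
    """Write a 16-bit grayscale TIFF with pixel size in the resolution tags.

    Resolution is recorded in pixels per centimetre (1 cm = 1e7 nm).
    """
    data = np.clip(np.rint(image.data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    px_per_cm = 1e7 / image.pixel_size_nm
    tifffile.imwrite(
        str(path),
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_nm": image.pixel_size_nm, "channel": image.channel},
    )


def read_tiff(path: str | Path, pixel_size_nm: float | None = None,
              channel: str = "") -> ImageChannel:
    """Read a grayscale TIFF; pixel size from resolution tags unless given."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(np.float64)
        if pixel_size_nm is None:
            try:
                xres = page.tags["XResolution"].value
                unit = page.tags["ResolutionUnit"].value
                px_per_unit = xres[0] / xres[1]
                unit_nm = {2: 2.54e7, 3: 1e7}.get(int(unit))
                if unit_nm is None or px_per_unit <= 0:
                    raise KeyError
                pixel_size_nm = unit_nm / px_per_unit
            except (KeyError, ZeroDivisionError):
                raise ValueError(
                    f"{path}: no usable resolution metadata; pass pixel_size_nm"
                ) from None
    return ImageChannel(data=data, pixel_size_nm=float(pixel_size_nm), channel=channel)
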