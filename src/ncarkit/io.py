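"""Plate-photograph input and red-channel preprocessing.

Plate images are decoded into 8-bit RGB rasters, reduced to their red
channel, and resampled to a constant square working size before any
segmentation.  All downstream area indices are pixel counts on this
standardized raster, so the working size cancels out of the normalized
colony area ratio (NCAR) — it only controls discretization.

Resampling uses nearest-neighbour interpolation on purpose: it never
invents intensity values, so the set of intensities seen by the
thresholding stage is a subset of the original image's and the red
histogram keeps its support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger("ncarkit")

#: Default side length (pixels) of the square working raster.
DEFAULT_STANDARD_SIZE = 1024

#: Minimum admissible working size.
MIN_STANDARD_SIZE = 16


class PlateImageError(ValueError):
    """Raised when a plate photograph cannot be read or is malformed."""


@dataclass(frozen=True)
class RasterImage:
    """An 8-bit RGB plate photograph.

    Attributes
    ----------
    rgb : numpy.ndarray
        ``(height, width, 3)`` uint8 array of red, green, blue intensities.
    path : str
        Origin of the image, for error messages and provenance logs.
    """

    rgb: np.ndarray
    path: str = ""

    def __post_init__(self) -> None:
        a = self.rgb
        if a.ndim != 3 or a.shape[2] != 3:
            raise PlateImageError(f"expected (H, W, 3) RGB array, got shape {a.shape}")
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise PlateImageError("image has zero extent")
        if a.dtype != np.uint8:
            raise PlateImageError(f"expected uint8 channels, got {a.dtype}")

    @property
    def height(self) -> int:
        return int(self.rgb.shape[0])

    @property
    def width(self) -> int:
        return int(self.rgb.shape[1])


@dataclass(frozen=True)
class RedChannelImage:
    """Square raster of per-pixel red intensities on the working grid.

    Attributes
    ----------
    values : numpy.ndarray
        ``(size, size)`` uint8 array of red intensities.
    source_id : str
        Plate/sample label the raster came from.
    day : int
        Imaging day.
    """

    values: np.ndarray
    source_id: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise PlateImageError(f"red-channel raster must be square 2-D, got shape {v.shape}")
        if v.dtype != np.uint8:
            raise PlateImageError(f"red-channel raster must be uint8, got {v.dtype}")

    @property
    def size(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class RedHistogram:
    """Frequency of each red intensity level (256 bins)."""

    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape != (256,):
            raise ValueError(f"histogram must have 256 bins, got shape {c.shape}")
        if (c < 0).any():
            raise ValueError("histogram counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def n_nonzero_levels(self) -> int:
        return int(np.count_nonzero(self.counts))


def load_plate_image(path: str | Path) -> RasterImage:
    """Decode a PNG/JPEG/TIFF plate photograph into an 8-bit RGB raster.

    Grayscale sources are promoted to three identical channels; an alpha
    channel, if present, is dropped.  Sources deeper than 8 bits/channel
    are rescaled to 8-bit with a logged warning.

    Raises
    ------
    PlateImageError
        If the file is missing, truncated, or not a decodable image.
    """
    p = Path(path)
    try:
        with Image.open(p) as im:
            im.load()
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise PlateImageError(f"cannot read plate image {p}: {exc}") from exc

    if arr.ndim == 0 or arr.size == 0:
        raise PlateImageError(f"cannot read plate image {p}: empty raster")

    if arr.dtype != np.uint8:
        # >8-bit sources (e.g. 16-bit TIFF) are linearly rescaled to [0, 255].
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        top = info.max if info is not None else float(arr.max()) or 1.0
        logger.warning("%s: %s bit depth rescaled to 8-bit", p, arr.dtype)
        arr = np.clip(np.rint(arr.astype(np.float64) * (255.0 / top)), 0, 255).astype(np.uint8)

    if arr.ndim == 2:
        arr = np.stack([arr, arr, arr], axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise PlateImageError(f"cannot read plate image {p}: unsupported layout {arr.shape}")

    return RasterImage(rgb=np.ascontiguousarray(arr), path=str(p))


def _nn_indices(n_src: int, n_dst: int) -> np.ndarray:
    """Source indices for nearest-neighbour resampling (pixel-centre mapping)."""
    idx = np.floor((np.arange(n_dst) + 0.5) * (n_src / n_dst)).astype(np.intp)
    return np.clip(idx, 0, n_src - 1)


def to_red_channel(
    img: RasterImage,
    standard_size: int = DEFAULT_STANDARD_SIZE,
    source_id: str = "",
    day: int = 0,
) -> RedChannelImage:
    """Extract the red channel and resample to the square working size.

    Both axes are resampled independently with nearest-neighbour
    interpolation, so non-square inputs are stretched to the square grid
    (aspect distortion does not affect pixel-count ratios).  An image
    already at ``standard_size`` passes through unchanged.
    """
    if standard_size < MIN_STANDARD_SIZE:
        raise ValueError(f"standard_size must be >= {MIN_STANDARD_SIZE}, got {standard_size}")
    red = img.rgb[:, :, 0]
    h, w = red.shape
    if h != w:
        logger.info("%s: non-square %dx%d input stretched to %d^2", img.path, w, h, standard_size)
    if (h, w) == (standard_size, standard_size):
        values = red.copy()
    else:
        values = red[np.ix_(_nn_indices(h, standard_size), _nn_indices(w, standard_size))]
    return RedChannelImage(values=np.ascontiguousarray(values), source_id=source_id, day=day)


def red_histogram(img: RedChannelImage) -> RedHistogram:
    """Tally the frequency of every red intensity level in the raster."""
    counts = np.bincount(img.values.ravel(), minlength=256)
    return RedHistogram(counts=counts)
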