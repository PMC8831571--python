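"""Image container and preparation steps for spot detection.

The detection front end normalizes whatever the microscope produced:
downscale to roughly 500 px on the long side, pick a color channel,
generously pre-mask the (dark) tissue so it cannot seed blob detection,
and shave a few border pixels.  All coordinate bookkeeping needed to map
results back to the full-resolution frame lives on :class:`RasterImage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize


@dataclass
class RasterImage:
    """A 1- or 3-channel intensity raster with frame bookkeeping.

    ``pixels`` holds floats in [0, 1]; shape ``(H, W)`` or ``(H, W, 3)``.
    Coordinates are (x, y) = (column, row), 0-based, origin at the top
    left.  ``scale`` is the processed-per-original pixel factor applied by
    downscaling, ``offset`` the (x, y) position of this raster's pixel
    (0, 0) inside the downscaled-but-uncropped frame, and
    ``original_shape`` the (height, width) of the raster before any
    processing — together they make the processed→original map exact.
    """

    pixels: np.ndarray
    scale: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)
    original_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) or (H, W, 3)")
        if px.size == 0:
            raise ValueError("empty image")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.scale <= 0:
            raise ValueError("scale factor must be positive")
        self.pixels = np.clip(px, 0.0, 1.0)
        if self.original_shape is None:
            self.original_shape = (px.shape[0], px.shape[1])

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def to_original(self, xy: np.ndarray) -> np.ndarray:
        """Map (x, y) coordinates in this raster to the original frame."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (xy + np.asarray(self.offset)) / self.scale

    def from_original(self, xy: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_original`."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy * self.scale - np.asarray(self.offset)


def read_image(path) -> RasterImage:
    """Read a JPEG/PNG/TIFF image into a [0, 1] float raster.

    8- and 16-bit integer images are rescaled by their dtype range; an
    alpha channel, if present, is dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, 0]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    return RasterImage(arr)


def write_image(img: RasterImage, path) -> None:
    """Write a raster as 8-bit PNG/JPEG/TIFF (by extension)."""
    arr = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def downscale_image(img: RasterImage, target_extent: int = 500) -> RasterImage:
    """Shrink so the longest side is at most ``target_extent`` pixels.

    Area-average (anti-aliased) resampling preserves the small dark spots
    at ~10x reduction.  Aspect ratio is kept; images already small enough
    pass through unchanged (no upscaling — the factor is capped at 1).
    """
    if target_extent < 1:
        raise ValueError("target_extent must be >= 1")
    h, w = img.height, img.width
    factor = min(1.0, target_extent / max(h, w))
    if factor == 1.0:
        return replace(img, scale=img.scale * 1.0)
    out_h = max(1, round(h * factor))
    out_w = max(1, round(w * factor))
    shape = (out_h, out_w) if img.channels == 1 else (out_h, out_w, 3)
    px = resize(img.pixels, shape, order=1, anti_aliasing=True, mode="reflect")
    return RasterImage(
        np.clip(px, 0, 1),
        scale=img.scale * factor,
        offset=img.offset,
        original_shape=img.original_shape,
    )


_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def select_channel(img: RasterImage, channel: str = "gray") -> RasterImage:
    """Extract one color plane, or the channel mean for ``gray``."""
    if channel not in ("red", "green", "blue", "gray"):
        raise ValueError(f"unknown channel {channel!r}")
    if img.channels == 1:
        if channel != "gray":
            raise ValueError(
                f"cannot select {channel!r} from a single-channel image"
            )
        return replace(img)
    if channel == "gray":
        plane = img.pixels.mean(axis=2)
    else:
        plane = img.pixels[:, :, _CHANNEL_INDEX[channel]]
    return replace(img, pixels=plane)


def modal_intensity(plane: np.ndarray, bins: int = 256) -> float:
    """Modal intensity of a plane (histogram mode, 256 bins)."""
    hist, edges = np.histogram(plane.ravel(), bins=bins, range=(0.0, 1.0))
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def pre_mask_tissue(gray: RasterImage, quantile: float = 0.10) -> RasterImage:
    """Generously blank the darkest pixels before blob detection.

    Pixels strictly darker than the given intensity quantile (tissue,
    bubbles, heavy stain) are replaced by the image's modal background
    intensity so they can neither seed dark blobs nor leave bright halos.
    ``quantile=0`` is the identity.
    """
    if gray.channels != 1:
        raise ValueError("pre_mask_tissue expects a single-channel image")
    if not 0.0 <= quantile <= 1.0:
        raise ValueError("quantile must be in [0, 1]")
    if quantile == 0.0:
        return replace(gray)
    cut = float(np.quantile(gray.pixels, quantile))
    fill = modal_intensity(gray.pixels)
    px = gray.pixels.copy()
    px[px < cut] = fill
    return replace(gray, pixels=px)


def crop_borders(img: RasterImage, n_px: int = 4) -> RasterImage:
    """Shave ``n_px`` pixels off all four borders, tracking the offset."""
    if n_px < 0:
        raise ValueError("n_px must be nonnegative")
    if n_px == 0:
        return replace(img)
    if img.height <= 2 * n_px or img.width <= 2 * n_px:
        raise ValueError(
            f"image {img.width}x{img.height} too small to crop {n_px} px "
            "from each border"
        )
    px = img.pixels[n_px:-n_px, n_px:-n_px]
    off = (img.offset[0] + n_px, img.offset[1] + n_px)
    return replace(img, pixels=px.copy(), offset=off)
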