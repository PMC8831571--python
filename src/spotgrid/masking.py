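"""Tissue masking on stained array images and under-tissue spot calling.

The mask is built from stain contrast against background statistics taken
from the image border (no tissue is expected within 20 px of the edge):
stained pixels exceeding the background by its standard deviation form a
primary mask, a border-seeded flood fill removes the connected background
(and dark artifacts attached to it), two blur/threshold passes (sigma 10
then 1) close spot-sized holes and recover weak edges, and an optional
bubble mask removes mounting bubbles — pixels that are dark and nearly
equal across all three color channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import flood

from .image import RasterImage, select_channel


@dataclass
class TissueMask:
    """Boolean tissue raster plus the statistics it was built from."""

    mask: np.ndarray
    bubble_mask: np.ndarray | None = None
    background_stats: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.bubble_mask is not None:
            self.bubble_mask = np.asarray(self.bubble_mask, dtype=bool)
            if self.bubble_mask.shape != self.mask.shape:
                raise ValueError("bubble_mask and mask shapes differ")
            if np.any(self.mask & self.bubble_mask):
                raise ValueError("bubble pixels must not be tissue pixels")


def estimate_background(img: RasterImage, border_px: int = 20) -> tuple[float, float]:
    """Mean and sd of intensity over the ``border_px``-wide frame region."""
    plane = img.pixels if img.channels == 1 else img.pixels.mean(axis=2)
    h, w = plane.shape
    if h <= 2 * border_px or w <= 2 * border_px:
        raise ValueError(
            f"image {w}x{h} too small for a {border_px}-px border frame"
        )
    frame = np.ones((h, w), dtype=bool)
    frame[border_px:-border_px, border_px:-border_px] = False
    vals = plane[frame]
    return float(vals.mean()), float(vals.std())


def build_tissue_mask(
    img: RasterImage,
    channel: str = "green",
    use_bubble_mask: bool = False,
    flood_tolerance: float = 0.1,
    k_sd: float = 1.0,
    border_px: int = 20,
    refine_sigmas: tuple[float, float] = (10.0, 1.0),
    refine_threshold: float = 0.5,
    bubble_level: float = 0.35,
    bubble_channel_range: float = 0.08,
) -> TissueMask:
    """Segment the tissue region of a stained 3-channel array image.

    Stain intensity is defined as ``1 − channel value`` (darker stained
    pixels score higher).  Pixels whose stain exceeds the border
    background's mean stain by ``k_sd`` standard deviations seed the
    primary mask; the border-connected background found by flood fill
    (absolute tolerance ``flood_tolerance``) is removed; two Gaussian
    blur + threshold passes refine the result.  With ``use_bubble_mask``
    dark near-gray pixels (all channels below ``bubble_level`` and
    channel spread below ``bubble_channel_range``) are moved into a
    separate bubble mask.  An all-false mask is legal and simply flagged
    downstream in the QC report.
    """
    if img.channels != 3:
        raise ValueError("build_tissue_mask expects a 3-channel image")
    if channel not in ("red", "green"):
        raise ValueError("mask channel must be 'red' or 'green'")
    plane = select_channel(img, channel).pixels
    bg_mean, bg_sd = estimate_background(
        RasterImage(plane, scale=img.scale, offset=img.offset), border_px
    )
    stain = 1.0 - plane
    stain_bg_mean = 1.0 - bg_mean
    mask = stain > stain_bg_mean + k_sd * bg_sd

    # Border-connected background via flood fill from all four corners.
    h, w = plane.shape
    background = np.zeros((h, w), dtype=bool)
    for seed in ((0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)):
        background |= flood(plane, seed, tolerance=flood_tolerance, connectivity=1)
    mask &= ~background

    for sigma in refine_sigmas:
        mask = ndimage.gaussian_filter(mask.astype(float), sigma) > refine_threshold

    bubble = None
    if use_bubble_mask:
        low = np.all(img.pixels < bubble_level, axis=2)
        spread = img.pixels.max(axis=2) - img.pixels.min(axis=2)
        bubble = low & (spread < bubble_channel_range)
        mask &= ~bubble
    return TissueMask(mask=mask, bubble_mask=bubble, background_stats=(bg_mean, bg_sd))


def call_under_tissue(
    spots, mask: TissueMask, warn_counter: dict | None = None
):
    """Flag grid nodes whose rounded centroid pixel lies in the mask.

    ``spots`` is a node table with ``pixel_x``/``pixel_y`` in the mask's
    frame; returns a copy with ``under_tissue`` set.  Nodes falling
    outside the image are flagged False and counted in ``warn_counter``
    under ``"spots_outside_image"``.
    """
    out = spots.copy()
    h, w = mask.mask.shape
    xs = np.round(out["pixel_x"].to_numpy()).astype(int)
    ys = np.round(out["pixel_y"].to_numpy()).astype(int)
    inside = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    flags = np.zeros(len(out), dtype=bool)
    flags[inside] = mask.mask[ys[inside], xs[inside]]
    out["under_tissue"] = flags
    n_outside = int((~inside).sum())
    if warn_counter is not None and n_outside:
        warn_counter["spots_outside_image"] = (
            warn_counter.get("spots_outside_image", 0) + n_outside
        )
    return out
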