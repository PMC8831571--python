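"""Image-based quantification: per-spot fluorescence, lateral diffusion,
and fluorescent-footprint extraction.

Three estimators used to validate in situ reactions on the array:

* per-spot immunofluorescence — sum a small patch (±1% of the image
  extent) around each registered spot centroid;
* lateral diffusion — compare cell-boundary positions between a nuclear
  intensity profile and the fluorescent cDNA footprint profile drawn
  along the same line, boundaries being the local minima of a degree-5
  polynomial fit that flank the main peak;
* footprint extraction — background removal by morphological
  reconstruction, Sobel elevation map, watershed segmentation, and a
  3:1 signal-to-noise advisory rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import sobel
from skimage.morphology import reconstruction
from skimage.segmentation import watershed

from .image import RasterImage
from .masking import TissueMask

#: Default pixel → micrometer conversion for the diffusion estimator.
UM_PER_PX_DIFFUSION = 0.1728


class ProfileError(ValueError):
    """Raised when a line profile has no usable boundary structure."""


@dataclass
class ProfileTrace:
    """Pixel intensities sampled along a drawn line."""

    positions: np.ndarray
    intensities: np.ndarray
    boundaries: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must match in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def quantify_spot_if(
    fluor: RasterImage,
    spots: pd.DataFrame,
    patch_fraction: float = 0.01,
    warn_counter: dict | None = None,
) -> pd.DataFrame:
    """Summed fluorescence in a ±``patch_fraction``-of-image patch per spot.

    The patch half-width is ``floor(patch_fraction · width)`` pixels in x
    and ``floor(patch_fraction · height)`` in y, centered on the rounded
    spot centroid and clipped at the borders.  Spots fully outside the
    image sum to 0 and are counted in ``warn_counter``.  The input is
    expected to be background-subtracted (see :func:`extract_footprint`).
    """
    if not 0.0 < patch_fraction < 0.5:
        raise ValueError("patch_fraction must be in (0, 0.5)")
    plane = fluor.pixels if fluor.channels == 1 else fluor.pixels.mean(axis=2)
    h, w = plane.shape
    hx = int(np.floor(patch_fraction * w))
    hy = int(np.floor(patch_fraction * h))
    sums = np.zeros(len(spots))
    outside = 0
    for i, rec in enumerate(spots.itertuples(index=False)):
        cx = int(round(rec.pixel_x))
        cy = int(round(rec.pixel_y))
        x0, x1 = cx - hx, cx + hx + 1
        y0, y1 = cy - hy, cy + hy + 1
        if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
            outside += 1
            continue
        sums[i] = plane[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)].sum()
    if warn_counter is not None and outside:
        warn_counter["spots_outside_fluorescence_image"] = (
            warn_counter.get("spots_outside_fluorescence_image", 0) + outside
        )
    return pd.DataFrame(
        {"x": spots["x"], "y": spots["y"], "intensity_sum": sums}
    ).reset_index(drop=True)


def _profile_boundaries(trace: ProfileTrace, degree: int = 5,
                        min_rel_intensity: float = 0.10) -> tuple[float, float]:
    """Cell boundaries of one profile: qualifying minima flanking the peak.

    A degree-5 polynomial is fit to the samples; its stationary points
    inside the sampled range are classified by the second derivative.
    The boundary on each side is the local minimum nearest the global
    maximum whose fitted intensity exceeds ``min_rel_intensity`` of the
    maximum's fitted intensity.
    """
    x, y = trace.positions, trace.intensities
    # Center/scale for numerical conditioning of the Vandermonde solve.
    xm, xs = x.mean(), x.std()
    coeffs = np.polynomial.polynomial.polyfit((x - xm) / xs, y, degree)
    poly = np.polynomial.polynomial.Polynomial(coeffs)
    deriv = poly.deriv()
    roots = deriv.roots()
    roots = roots[np.isreal(roots)].real
    lo, hi = (x.min() - xm) / xs, (x.max() - xm) / xs
    roots = np.sort(roots[(roots > lo) & (roots < hi)])
    if roots.size == 0:
        raise ProfileError("no stationary points inside the profile range")
    second = deriv.deriv()
    minima = roots[second(roots) > 0]
    maxima = roots[second(roots) < 0]
    if maxima.size == 0:
        raise ProfileError("profile has no interior peak")
    peak = maxima[np.argmax(poly(maxima))]
    peak_val = float(poly(peak))
    qual = minima[poly(minima) > min_rel_intensity * peak_val]
    left = qual[qual < peak]
    right = qual[qual > peak]
    if left.size == 0 or right.size == 0:
        raise ProfileError(
            "no qualifying boundary minima flanking the peak; the line may "
            "not span a full nucleus"
        )
    # Nearest qualifying minimum on each side of the peak.
    return (
        float(left.max() * xs + xm),
        float(right.min() * xs + xm),
    )


def estimate_lateral_diffusion(
    nuclear: ProfileTrace,
    footprint: ProfileTrace,
    um_per_px: float = UM_PER_PX_DIFFUSION,
) -> tuple[float, float]:
    """Signed boundary displacement (left, right) in micrometers.

    Boundaries are located on each trace by :func:`_profile_boundaries`;
    the per-side offset is the footprint boundary minus the nuclear
    boundary measured *outward* (negative values mean the footprint
    signal is contained within the cell boundary), converted to µm by
    ``um_per_px``.
    """
    nl, nr = _profile_boundaries(nuclear)
    fl, fr = _profile_boundaries(footprint)
    nuclear.boundaries = (nl, nr)
    footprint.boundaries = (fl, fr)
    left_um = (nl - fl) * um_per_px
    right_um = (fr - nr) * um_per_px
    return float(left_um), float(right_um)


def extract_footprint(
    fluor: RasterImage,
    tissue: TissueMask | None = None,
    smoothing_sigma: float | None = None,
    snr_advisory: float = 3.0,
    low_quantile: float = 0.25,
    high_quantile: float = 0.90,
    eps: float = 1e-6,
) -> tuple[np.ndarray, float, float, bool]:
    """Extract the fluorescent cDNA footprint and score its SNR.

    The image is lightly smoothed (sigma defaulting to 1% of the longest
    dimension), its border-connected background estimated by
    morphological reconstruction (dilation from a border-seeded marker)
    and subtracted, and a Sobel gradient elevation map segmented by
    watershed from low/high intensity markers into background and signal
    objects.  Pixels outside the tissue mask, if one is given, are
    excluded.  Returns the background-subtracted signal restricted to
    the detected objects, its mean, ``snr = mean signal / mean residual
    background``, and an advisory flag that is set when the SNR falls
    below ``snr_advisory`` (new tissue optimizations recommended) or no
    objects are found.
    """
    if fluor.channels != 1:
        raise ValueError("extract_footprint expects a single-channel image")
    img = fluor.pixels
    if smoothing_sigma is None:
        smoothing_sigma = 0.01 * max(img.shape)
    smooth = ndimage.gaussian_filter(img, smoothing_sigma)

    # Background: grayscale reconstruction by dilation from a marker that
    # equals the image on the border and its minimum elsewhere.
    seed = np.full_like(smooth, smooth.min())
    seed[0, :], seed[-1, :], seed[:, 0], seed[:, -1] = (
        smooth[0, :], smooth[-1, :], smooth[:, 0], smooth[:, -1],
    )
    background = reconstruction(seed, smooth, method="dilation")
    signal = smooth - background

    rng_lo = float(np.quantile(signal, low_quantile))
    rng_hi = float(np.quantile(signal, high_quantile))
    if rng_hi - rng_lo < eps:  # flat image: nothing to segment
        return np.zeros_like(signal), 0.0, 0.0, True
    markers = np.zeros(signal.shape, dtype=int)
    markers[signal <= rng_lo] = 1
    markers[signal >= rng_hi] = 2
    elevation = sobel(signal)
    labels = watershed(elevation, markers)
    objects = labels == 2
    if tissue is not None:
        objects &= tissue.mask
    if not objects.any():
        return np.zeros_like(signal), 0.0, 0.0, True
    mean_signal = float(signal[objects].mean())
    residual = float(np.abs(signal[~objects]).mean()) if (~objects).any() else 0.0
    snr = mean_signal / max(residual, eps)
    out = np.where(objects, signal, 0.0)
    return out, mean_signal, snr, snr < snr_advisory
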