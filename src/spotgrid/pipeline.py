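"""End-to-end registration: image in, spot table + mask + QC out.

Chains the front end (downscale, channel select, generous pre-mask,
border crop), blob detection and lattice-score filtering, regular-grid
fitting with iterative outlier shedding, tissue masking, and
under-tissue calling.  The result object carries every intermediate
artifact plus a QC summary, statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ArrayDesign, DEFAULT_DESIGN
from .detection import (
    BlobSet,
    KeepRule,
    detect_blobs,
    filter_by_grid_score,
    grid_score,
)
from .gridfit import GridFitResult, enumerate_nodes, fit_regular_grid, iterative_refine
from .image import (
    RasterImage,
    crop_borders,
    downscale_image,
    pre_mask_tissue,
    read_image,
    select_channel,
)
from .io import qc_report
from .masking import TissueMask, build_tissue_mask, call_under_tissue


@dataclass
class RegistrationResult:
    """All artifacts of one registration run.

    ``spots`` carries pixel centroids in the ORIGINAL image frame (the
    convention of the output table; full-resolution viewers want these);
    ``spots_processed`` the same table in the processed (downscaled)
    frame the mask lives in.
    """

    design: ArrayDesign
    image: RasterImage
    prepared: RasterImage
    blobs: BlobSet
    kept_blobs: BlobSet
    fit: GridFitResult
    mask: TissueMask
    spots: pd.DataFrame
    spots_processed: pd.DataFrame
    report: dict
    warn_counter: dict = field(default_factory=dict)

    @property
    def status(self) -> str:
        return self.report["status"]

    def pitch_um(self, um_per_px: float) -> float:
        """Mean fitted center-to-center spacing converted to µm.

        ``um_per_px`` is the scale of the ORIGINAL image; the fitted
        pixel pitch is mapped back through the downscale factor first.
        """
        mean_pitch_px = float(np.mean(self.fit.model.pitch))
        return mean_pitch_px / self.image.scale * um_per_px

    def summary(self) -> str:
        lines = [self.fit.summary(), ""]
        lines.append(f"tissue mask pixels   {int(self.mask.mask.sum()):>10d}")
        lines.append(
            f"under-tissue spots   {int(self.spots['under_tissue'].sum()):>10d}"
            f" / {len(self.spots)}"
        )
        lines.append(f"QC status            {self.status:>10s}")
        for w in self.report["warnings"]:
            lines.append(f"  warn: {w}")
        return "\n".join(lines)


def register(
    image: RasterImage | str | Path,
    design: ArrayDesign = DEFAULT_DESIGN,
    channel: str = "green",
    use_bubble_mask: bool = False,
    target_extent: int = 500,
    pre_mask_quantile: float = 0.10,
    border_crop_px: int = 4,
    blur_sigma: float = 3.0,
    maxima_window: int = 3,
    keep_rule: KeepRule | None = None,
    init_extent: int | None = None,
    drop_fraction: float = 0.001,
    flood_tolerance: float = 0.1,
    k_sd: float = 1.0,
    out_dir=None,
) -> RegistrationResult:
    """Run the full registration pipeline on one stained array image."""
    if not isinstance(image, RasterImage):
        image = read_image(image)
    warn_counter: dict = {}

    down = downscale_image(image, target_extent)
    chan = select_channel(down, channel if down.channels == 3 else "gray")
    masked = pre_mask_tissue(chan, pre_mask_quantile)
    prep = crop_borders(masked, border_crop_px)

    blobs = detect_blobs(prep, blur_sigma=blur_sigma, maxima_window=maxima_window)
    scored = grid_score(blobs)
    kept = filter_by_grid_score(scored, keep_rule)

    rough = fit_regular_grid(
        kept, init_extent=init_extent or design.initial_grid_guess
    )
    fit = iterative_refine(
        rough,
        target_cols=design.n_cols,
        target_rows=design.n_rows,
        drop_fraction=drop_fraction,
    )

    spots_local = enumerate_nodes(fit.model)
    # prep-local → processed (downscaled, uncropped) frame.
    spots_proc = spots_local.copy()
    spots_proc["pixel_x"] += prep.offset[0]
    spots_proc["pixel_y"] += prep.offset[1]

    if down.channels == 3:
        mask = build_tissue_mask(
            down,
            channel=channel if channel in ("red", "green") else "green",
            use_bubble_mask=use_bubble_mask,
            flood_tolerance=flood_tolerance,
            k_sd=k_sd,
        )
    else:
        warn_counter["mask_skipped_single_channel"] = 1
        mask = TissueMask(mask=np.zeros(down.pixels.shape[:2], dtype=bool))
    spots_proc = call_under_tissue(spots_proc, mask, warn_counter)

    spots = spots_proc.copy()
    orig = down.to_original(spots_proc[["pixel_x", "pixel_y"]].to_numpy())
    spots["pixel_x"] = orig[:, 0]
    spots["pixel_y"] = orig[:, 1]

    report = qc_report(
        fit,
        mask,
        spots_proc,
        out_dir=out_dir,
        image=down,
        target_cols=design.n_cols,
        target_rows=design.n_rows,
        warn_counter=warn_counter,
    )
    return RegistrationResult(
        design=design,
        image=down,
        prepared=prep,
        blobs=blobs,
        kept_blobs=kept,
        fit=fit,
        mask=mask,
        spots=spots,
        spots_processed=spots_proc,
        report=report,
        warn_counter=warn_counter,
    )
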