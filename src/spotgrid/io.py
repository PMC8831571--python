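"""Registration outputs: spot table, expression subsetting, crop, QC.

The spot table (``output.tsv``) is the registration contract with the
expression pipeline: one row per grid node with its (x, y) grid indices,
centroid pixel coordinates, and a literal TRUE/FALSE under-tissue flag.
Gene-by-barcode matrices are tab-separated with spot ids keyed
``"{col}x{row}"``; only under-tissue spots enter downstream analysis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gridfit import GridFitResult, GridModel
from .image import RasterImage
from .masking import TissueMask

SPOT_COLUMNS = ["x", "y", "pixel_x", "pixel_y", "under_tissue"]
_SPOT_ID_RE = re.compile(r"^(\d+)x(\d+)$")


def make_spot_id(col: int, row: int) -> str:
    return f"{col}x{row}"


def parse_spot_id(spot_id: str) -> tuple[int, int]:
    m = _SPOT_ID_RE.match(str(spot_id))
    if not m:
        raise ValueError(f"malformed spot id {spot_id!r}; expected '<col>x<row>'")
    return int(m.group(1)), int(m.group(2))


def write_spot_table(spots: pd.DataFrame, path) -> None:
    """Write the registration output table (``output.tsv`` dialect).

    Tab-separated with header ``x y pixel_x pixel_y under_tissue``;
    the flag is serialized as the literal strings TRUE/FALSE.  Floats are
    written with ``repr`` so that ``read_spot_table(write(...))`` is
    bit-exact.
    """
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write("\t".join(SPOT_COLUMNS) + "\n")
        for rec in spots.itertuples(index=False):
            fh.write(
                f"{int(rec.x)}\t{int(rec.y)}\t{rec.pixel_x!r}\t{rec.pixel_y!r}\t"
                f"{'TRUE' if rec.under_tissue else 'FALSE'}\n"
            )


def read_spot_table(path) -> pd.DataFrame:
    """Read a spot table, validating every row (line number on failure)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SPOT_COLUMNS:
            raise ValueError(f"unexpected spot-table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                flag = {"TRUE": True, "FALSE": False}[parts[4]]
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]),
                     float(parts[3]), flag)
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"line {lineno}: malformed row ({exc})") from exc
    df = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    if df.duplicated(subset=["x", "y"]).any():
        raise ValueError("duplicate (x, y) grid indices in spot table")
    return df


def write_expression(matrix: pd.DataFrame, path, transpose: bool = False) -> None:
    """Write a spots × genes count matrix as TSV (``spot`` id column first)."""
    out = matrix.T if transpose else matrix
    out.to_csv(path, sep="\t", index_label="spot")


def read_expression(path, transpose: bool = False) -> pd.DataFrame:
    """Read a tab-separated gene-by-barcode matrix (spots × genes).

    ``transpose=True`` reads the genes × spots orientation, which also
    occurs in the wild.  Spot ids must parse as ``"{col}x{row}"`` and
    counts must be nonnegative integers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    for spot_id in df.index:
        parse_spot_id(spot_id)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric entries")
    if (values < 0).any() or np.any(values != np.round(values)):
        raise ValueError("expression counts must be nonnegative integers")
    return df.astype(int)


def subset_expression(
    matrix: pd.DataFrame, spots: pd.DataFrame, warn_counter: dict | None = None
) -> pd.DataFrame:
    """Retain matrix rows whose spot is flagged under tissue.

    Row order and counts are preserved.  Matrix spots absent from the
    spot table are dropped and tallied in ``warn_counter`` under
    ``"matrix_spots_missing"`` (not fatal).
    """
    flags = {
        make_spot_id(int(r.x), int(r.y)): bool(r.under_tissue)
        for r in spots.itertuples(index=False)
    }
    keep, missing = [], 0
    for spot_id in matrix.index:
        if spot_id not in flags:
            missing += 1
        elif flags[spot_id]:
            keep.append(spot_id)
    if warn_counter is not None and missing:
        warn_counter["matrix_spots_missing"] = (
            warn_counter.get("matrix_spots_missing", 0) + missing
        )
    return matrix.loc[keep]


@dataclass(frozen=True)
class CropTransform:
    """Pixel map applied by :func:`crop_and_orient` (crop then double flip)."""

    x0: int
    y0: int
    width: int
    height: int

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.empty_like(xy)
        out[:, 0] = (self.width - 1) - (xy[:, 0] - self.x0)
        out[:, 1] = (self.height - 1) - (xy[:, 1] - self.y0)
        return out

    def invert(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        out = np.empty_like(xy)
        out[:, 0] = self.x0 + (self.width - 1) - xy[:, 0]
        out[:, 1] = self.y0 + (self.height - 1) - xy[:, 1]
        return out


def crop_and_orient(
    img: RasterImage, model: GridModel, warn_counter: dict | None = None
) -> tuple[RasterImage, CropTransform]:
    """Crop the image to the grid rectangle and flip to display convention.

    The rectangle is spanned by the grid corner nodes — width the
    distance between nodes (1, n_rows) and (n_cols, n_rows), height the
    distance between (n_cols, n_rows) and (n_cols, 1) — then flipped
    horizontally and vertically.  A rectangle exceeding the image is
    clipped and counted in ``warn_counter["crop_clipped"]``.
    """
    corners = model.node(
        [1, model.n_cols, 1, model.n_cols], [1, 1, model.n_rows, model.n_rows]
    )
    width = int(round(np.linalg.norm(corners[3] - corners[2])))
    height = int(round(np.linalg.norm(corners[3] - corners[1])))
    x0 = int(round(corners[:, 0].min()))
    y0 = int(round(corners[:, 1].min()))
    h, w = img.pixels.shape[:2]
    cx0, cy0 = max(0, x0), max(0, y0)
    cx1, cy1 = min(w, x0 + width), min(h, y0 + height)
    if (cx0, cy0, cx1, cy1) != (x0, y0, x0 + width, y0 + height):
        if warn_counter is not None:
            warn_counter["crop_clipped"] = warn_counter.get("crop_clipped", 0) + 1
    cropped = img.pixels[cy0:cy1, cx0:cx1]
    flipped = cropped[::-1, ::-1].copy()
    out = RasterImage(
        flipped,
        scale=img.scale,
        offset=img.offset,
        original_shape=img.original_shape,
    )
    return out, CropTransform(cx0, cy0, cx1 - cx0, cy1 - cy0)


def qc_report(
    fit: GridFitResult,
    mask: TissueMask,
    spots: pd.DataFrame,
    out_dir=None,
    image: RasterImage | None = None,
    target_cols: int | None = None,
    target_rows: int | None = None,
    warn_counter: dict | None = None,
    max_rotation_deg: float = 10.0,
    under_tissue_bounds: tuple[float, float] = (0.02, 0.98),
) -> dict:
    """Summarize a registration run and flag irregularities.

    Returns a machine-readable summary (and writes ``report.json`` plus
    an ``overlay.png`` of grid + mask if ``out_dir`` is given).  Status
    is ``"warn"`` if the grid targets were not reached, the rotation is
    implausibly large, the under-tissue fraction is extreme, the mask is
    empty, or any warning counters fired; otherwise ``"pass"``.
    """
    m = fit.model
    warnings: list[str] = []
    if target_cols is not None and (m.n_cols, m.n_rows) != (target_cols, target_rows):
        warnings.append(
            f"grid targets not reached: {m.n_cols}x{m.n_rows} "
            f"vs {target_cols}x{target_rows}"
        )
    if abs(m.rotation_deg) > max_rotation_deg:
        warnings.append(f"large grid rotation: {m.rotation_deg:.2f} deg")
    frac_under = float(spots["under_tissue"].mean()) if len(spots) else 0.0
    if not under_tissue_bounds[0] <= frac_under <= under_tissue_bounds[1]:
        warnings.append(f"extreme under-tissue fraction: {frac_under:.1%}")
    if not mask.mask.any():
        warnings.append("tissue mask is empty")
    for key, count in (warn_counter or {}).items():
        warnings.append(f"{key}: {count}")

    log = [
        {"n_points": r.n_points, "n_cols": r.n_cols, "n_rows": r.n_rows,
         "objective": r.objective}
        for r in fit.iteration_log
    ]
    removed = [
        log[i - 1]["n_points"] - log[i]["n_points"] for i in range(1, len(log))
    ]
    summary = {
        "status": "warn" if warnings else "pass",
        "warnings": warnings,
        "n_blobs_fitted": int(fit.iteration_log[0].n_points) if log else 0,
        "n_points_final": int(len(fit.points)),
        "n_removed_per_iteration": removed,
        "n_iterations": len(log),
        "final_extents": [m.n_cols, m.n_rows],
        "pitch_px": [m.pitch[0], m.pitch[1]],
        "rotation_deg": m.rotation_deg,
        "rms_residual_px": float(np.sqrt(np.mean(fit.residuals**2)))
        if len(fit.residuals)
        else 0.0,
        "fraction_under_tissue": frac_under,
        "background_mean": mask.background_stats[0],
        "background_sd": mask.background_stats[1],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump({**summary, "iteration_log": log}, fh, indent=2)
        if image is not None:
            _write_overlay(image, fit, mask, spots, out_dir / "overlay.png")
    return summary


def _write_overlay(image, fit, mask, spots, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if image.channels == 1:
        ax.imshow(image.pixels, cmap="gray", vmin=0, vmax=1)
    else:
        ax.imshow(image.pixels)
    ax.contour(mask.mask.astype(float), levels=[0.5], colors="lime", linewidths=0.8)
    under = spots["under_tissue"].to_numpy(dtype=bool)
    ax.scatter(
        spots["pixel_x"][~under], spots["pixel_y"][~under],
        s=4, c="tab:blue", label="grid node",
    )
    ax.scatter(
        spots["pixel_x"][under], spots["pixel_y"][under],
        s=4, c="tab:red", label="under tissue",
    )
    ax.legend(loc="lower right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
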