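"""Synthetic stained-array images with ground truth, and fixtures.

Renders brightfield-like images of a spotted array: dark circular
capture spots on a bright gray-white background at exact lattice
positions, optionally overlaid with an H&E-like tissue blob, uneven
coloration, pink smears and dark mounting bubbles.  Every rendering
returns the matching ground truth (true spot centers, tissue polygon,
artifact inventory), so detection, fitting, masking and registration can
be benchmarked without any downloaded data.  Also provides count-matrix,
line-profile and read-saturation fixtures, and the FP/FN scorer used to
compare recovered spots against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask
from skimage.transform import resize

from .design import ArrayDesign, DEFAULT_DESIGN
from .image import RasterImage
from .quantify import ProfileTrace

# H&E-like palette (RGB in [0, 1]).
BACKGROUND_RGB = (0.92, 0.92, 0.91)
SPOT_RGB = (0.55, 0.55, 0.58)
HEMATOXYLIN_RGB = (0.52, 0.38, 0.62)
EOSIN_RGB = (0.86, 0.58, 0.70)
BUBBLE_RGB = (0.10, 0.10, 0.11)
# Per-channel darkening of "pink" smears: the stain contrast sits almost
# entirely in the red channel, mirroring the artifact class that red-
# channel tissue masking picks up and green-channel masking avoids.
SMEAR_DARKENING = (0.30, 0.04, 0.12)


@dataclass(frozen=True)
class ArtifactConfig:
    """What to render on top of the clean spot lattice."""

    tissue: bool = False
    tissue_cover: tuple[float, float] = (0.2, 0.4)
    coloration: bool = False
    coloration_amplitude: float = 0.08
    n_smears: int = 0
    smear_radius_px: tuple[float, float] = (15.0, 30.0)
    n_bubbles: int = 0
    bubble_radius_px: tuple[float, float] = (8.0, 14.0)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ArtifactConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(cfg) - known
        if bad:
            raise ValueError(f"unknown artifact options: {sorted(bad)}")
        cfg = {
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()
        }
        return cls(**cfg)


@dataclass
class SyntheticGroundTruth:
    """Everything a benchmark needs to score a registration run."""

    true_spot_centers: pd.DataFrame  # columns col, row, x_px, y_px
    tissue_polygon: np.ndarray | None
    artifact_inventory: list[tuple[str, dict]]
    um_per_px: float
    seed: int
    rotation_deg: float = 0.0

    def under_tissue_nodes(self) -> np.ndarray:
        """Boolean flag per true spot: centroid inside the tissue polygon."""
        if self.tissue_polygon is None:
            return np.zeros(len(self.true_spot_centers), dtype=bool)
        path = MplPath(self.tissue_polygon)
        pts = self.true_spot_centers[["x_px", "y_px"]].to_numpy()
        return path.contains_points(pts)

    def to_json(self, path) -> None:
        payload = {
            "true_spot_centers": self.true_spot_centers.to_dict(orient="list"),
            "tissue_polygon": None
            if self.tissue_polygon is None
            else self.tissue_polygon.tolist(),
            "artifact_inventory": [
                [kind, {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                        for k, v in region.items()}]
                for kind, region in self.artifact_inventory
            ],
            "um_per_px": self.um_per_px,
            "seed": self.seed,
            "rotation_deg": self.rotation_deg,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        payload = json.loads(Path(path).read_text())
        poly = payload["tissue_polygon"]
        return cls(
            true_spot_centers=pd.DataFrame(payload["true_spot_centers"]),
            tissue_polygon=None if poly is None else np.asarray(poly, float),
            artifact_inventory=[
                (kind, region) for kind, region in payload["artifact_inventory"]
            ],
            um_per_px=payload["um_per_px"],
            seed=payload["seed"],
            rotation_deg=payload.get("rotation_deg", 0.0),
        )


def _disk_blend(canvas, cx, cy, radius, rgb, alpha=1.0):
    """Alpha-blend a filled disk with a 1-px anti-aliased edge."""
    h, w = canvas.shape[:2]
    x0, x1 = max(0, int(cx - radius - 2)), min(w, int(cx + radius + 3))
    y0, y1 = max(0, int(cy - radius - 2)), min(h, int(cy + radius + 3))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(xx - cx, yy - cy)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0) * alpha
    patch = canvas[y0:y1, x0:x1]
    patch += cov[:, :, None] * (np.asarray(rgb) - patch)


def _smooth_field(rng, shape, coarse=8):
    """Low-frequency unit-scale random field (coarse noise, upsampled)."""
    noise = rng.standard_normal((coarse, coarse))
    fld = resize(noise, shape, order=3, mode="reflect", anti_aliasing=False)
    fld -= fld.mean()
    m = np.abs(fld).max()
    return fld / m if m > 0 else fld


def _tissue_polygon(rng, center, mean_radius, aspect, n_vertices=256):
    """Fourier-perturbed ellipse: a smooth random tissue-like blob."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    radial = np.ones_like(theta)
    for k in range(2, 6):
        amp = rng.normal(0.0, 0.04)
        phase = rng.uniform(0, 2 * np.pi)
        radial += amp * np.cos(k * theta + phase)
    rx = mean_radius * aspect * radial
    ry = mean_radius / aspect * radial
    return np.column_stack(
        [center[0] + rx * np.cos(theta), center[1] + ry * np.sin(theta)]
    )


def render_array_image(
    design: ArrayDesign = DEFAULT_DESIGN,
    um_per_px: float = 200.0 / 14.0,
    artifacts: ArtifactConfig | dict | None = None,
    seed: int = 0,
    rotation_deg: float = 0.0,
    jitter_sd_px: float = 0.0,
    margin_px: float | None = None,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[RasterImage, SyntheticGroundTruth]:
    """Render a stained-array image and its ground truth.

    Spots are dark disks at exact lattice positions (optionally rotated
    by ``rotation_deg`` about the canvas center and jittered by
    ``jitter_sd_px``); artifacts are layered per ``artifacts``.  The
    canvas is sized to hold the grid plus ``margin_px`` (default 1.5
    pitches) unless ``canvas_shape`` is forced, in which case a grid that
    does not fit is rejected.  Identical arguments give bit-identical
    output.
    """
    if isinstance(artifacts, dict):
        artifacts = ArtifactConfig.from_dict(artifacts)
    art = artifacts or ArtifactConfig()
    rng = np.random.default_rng(seed)

    pitch = design.pitch_px(um_per_px)
    radius = design.spot_radius_px(um_per_px)
    if margin_px is None:
        margin_px = 1.5 * pitch

    cols, rows = np.meshgrid(
        np.arange(1, design.n_cols + 1), np.arange(1, design.n_rows + 1)
    )
    cols, rows = cols.ravel(), rows.ravel()
    gx = (cols - 1) * pitch
    gy = (rows - 1) * pitch
    t = np.radians(rotation_deg)
    cx0, cy0 = gx.mean(), gy.mean()
    xr = cx0 + np.cos(t) * (gx - cx0) - np.sin(t) * (gy - cy0)
    yr = cy0 + np.sin(t) * (gx - cx0) + np.cos(t) * (gy - cy0)
    xr = xr - xr.min() + margin_px
    yr = yr - yr.min() + margin_px
    if jitter_sd_px > 0:
        xr = xr + rng.normal(0.0, jitter_sd_px, xr.shape)
        yr = yr + rng.normal(0.0, jitter_sd_px, yr.shape)

    width = int(np.ceil(xr.max() + margin_px))
    height = int(np.ceil(yr.max() + margin_px))
    if canvas_shape is not None:
        ch, cw = canvas_shape
        if ch < height or cw < width:
            raise ValueError(
                f"canvas {cw}x{ch} too small for the grid: needs at least "
                f"{width}x{height} px at {um_per_px:.3f} um/px"
            )
        height, width = ch, cw

    canvas = np.empty((height, width, 3), dtype=float)
    base_noise = rng.normal(0.0, 0.008, (height, width))
    for ch3 in range(3):
        canvas[:, :, ch3] = BACKGROUND_RGB[ch3] + base_noise

    inventory: list[tuple[str, dict]] = []
    if art.coloration:
        fld = _smooth_field(rng, (height, width))
        canvas *= (1.0 + art.coloration_amplitude * fld)[:, :, None]
        inventory.append(
            ("coloration", {"amplitude": art.coloration_amplitude})
        )

    for x, y in zip(xr, yr):
        _disk_blend(canvas, x, y, radius, SPOT_RGB)

    tissue_poly = None
    if art.tissue:
        cover = rng.uniform(*art.tissue_cover)
        grid_w = xr.max() - xr.min()
        grid_h = yr.max() - yr.min()
        mean_radius = np.sqrt(cover * grid_w * grid_h / np.pi)
        center = (
            rng.uniform(xr.min() + 0.3 * grid_w, xr.min() + 0.7 * grid_w),
            rng.uniform(yr.min() + 0.3 * grid_h, yr.min() + 0.7 * grid_h),
        )
        aspect = rng.uniform(0.8, 1.25)
        tissue_poly = _tissue_polygon(rng, center, mean_radius, aspect)
        tmask = polygon2mask((height, width), tissue_poly[:, ::-1])
        mix = 0.5 * (1.0 + _smooth_field(rng, (height, width)))
        color = (
            mix[:, :, None] * np.asarray(EOSIN_RGB)
            + (1.0 - mix[:, :, None]) * np.asarray(HEMATOXYLIN_RGB)
        )
        texture = rng.normal(0.0, 0.04, (height, width))
        color += texture[:, :, None]
        alpha = 0.85
        canvas[tmask] += alpha * (color[tmask] - canvas[tmask])

    for _ in range(art.n_smears):
        r = rng.uniform(*art.smear_radius_px)
        sx = rng.uniform(margin_px, width - margin_px)
        sy = rng.uniform(margin_px, height - margin_px)
        yy, xx = np.mgrid[0:height, 0:width]
        fall = np.exp(-0.5 * ((xx - sx) ** 2 + (yy - sy) ** 2) / r**2)
        canvas -= fall[:, :, None] * np.asarray(SMEAR_DARKENING)
        inventory.append(("smear", {"center": (sx, sy), "radius": r}))

    for _ in range(art.n_bubbles):
        r = rng.uniform(*art.bubble_radius_px)
        # Keep bubbles clear of the 20-px background frame.
        bx = rng.uniform(margin_px + r, width - margin_px - r)
        by = rng.uniform(margin_px + r, height - margin_px - r)
        _disk_blend(canvas, bx, by, r, BUBBLE_RGB, alpha=0.97)
        inventory.append(("bubble", {"center": (bx, by), "radius": r}))

    truth = SyntheticGroundTruth(
        true_spot_centers=pd.DataFrame(
            {"col": cols, "row": rows, "x_px": xr, "y_px": yr}
        ),
        tissue_polygon=tissue_poly,
        artifact_inventory=inventory,
        um_per_px=um_per_px,
        seed=seed,
        rotation_deg=rotation_deg,
    )
    return RasterImage(np.clip(canvas, 0.0, 1.0)), truth


def artifact_region_mask(
    kind: str, region: dict, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize an inventory entry (disk-shaped kinds) to a boolean mask."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cx, cy = region["center"]
    return np.hypot(xx - cx, yy - cy) <= region["radius"]


@dataclass(frozen=True)
class RecoveryScore:
    """FP/FN percentages of reported spots vs ground truth."""

    fp_rate: float
    fn_rate: float
    match_radius_px: float
    n_reported: int
    n_truth: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp_rate <= 100.0 and 0.0 <= self.fn_rate <= 100.0):
            raise ValueError("rates must lie in [0, 100]")


def score_recovery(
    reported, truth, match_radius_px: float | None = None
) -> RecoveryScore:
    """Greedy one-to-one nearest matching of reported spots to truth.

    ``reported`` is a spot table (``pixel_x``/``pixel_y``) or an (N, 2)
    array; ``truth`` a :class:`SyntheticGroundTruth` or (M, 2) array.
    Candidate pairs within ``match_radius_px`` (default: half the modal
    nearest-neighbor spacing of the truth lattice) are matched in order
    of distance, ties broken toward the lower ground-truth index.
    ``fp_rate`` is the percentage of reported spots left unmatched,
    ``fn_rate`` the percentage of truth spots left unmatched.
    """
    if isinstance(reported, pd.DataFrame):
        rep = reported[["pixel_x", "pixel_y"]].to_numpy(dtype=float)
    else:
        rep = np.asarray(reported, dtype=float).reshape(-1, 2)
    if isinstance(truth, SyntheticGroundTruth):
        tru = truth.true_spot_centers[["x_px", "y_px"]].to_numpy(dtype=float)
    else:
        tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(tru) == 0:
        raise ValueError("ground truth is empty")
    if match_radius_px is None:
        tree = cKDTree(tru)
        d, _ = tree.query(tru, k=2)
        match_radius_px = float(np.median(d[:, 1])) / 2.0
    if match_radius_px <= 0:
        raise ValueError("match_radius_px must be positive")
    if len(rep) == 0:
        return RecoveryScore(0.0, 100.0, match_radius_px, 0, len(tru))

    tree = cKDTree(rep)
    pairs = []
    for ti, neighbors in enumerate(tree.query_ball_point(tru, match_radius_px)):
        for rj in neighbors:
            pairs.append((float(np.linalg.norm(tru[ti] - rep[rj])), ti, rj))
    pairs.sort()
    matched_t = np.zeros(len(tru), dtype=bool)
    matched_r = np.zeros(len(rep), dtype=bool)
    for _, ti, rj in pairs:
        if not matched_t[ti] and not matched_r[rj]:
            matched_t[ti] = True
            matched_r[rj] = True
    fp = 100.0 * float((~matched_r).sum()) / len(rep)
    fn = 100.0 * float((~matched_t).sum()) / len(tru)
    return RecoveryScore(fp, fn, match_radius_px, len(rep), len(tru))


def simulate_expression(
    design: ArrayDesign,
    truth: SyntheticGroundTruth,
    mean_counts: float = 100.0,
    seed: int = 0,
    n_genes: int = 50,
) -> pd.DataFrame:
    """Count-matrix fixture keyed by ``"{col}x{row}"``.

    Spots under the tissue polygon draw strictly positive totals from a
    zero-truncated Poisson with the stated mean, split multinomially over
    a fixed random gene profile; spots outside the tissue get zeros.
    """
    if mean_counts <= 0:
        raise ValueError("mean_counts must be positive")
    rng = np.random.default_rng(seed)
    under = truth.under_tissue_nodes()
    centers = truth.true_spot_centers
    gene_probs = rng.dirichlet(np.ones(n_genes) * 5.0)
    genes = [f"Gene{i + 1}" for i in range(n_genes)]
    counts = np.zeros((len(centers), n_genes), dtype=int)
    for i in np.nonzero(under)[0]:
        total = 0
        while total == 0:  # zero-truncated Poisson
            total = int(rng.poisson(mean_counts))
        counts[i] = rng.multinomial(total, gene_probs)
    index = [
        f"{int(c)}x{int(r)}"
        for c, r in zip(centers["col"], centers["row"])
    ]
    return pd.DataFrame(counts, index=pd.Index(index, name="spot"), columns=genes)


def simulate_line_profiles(
    offset_px: float,
    n_profiles: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    length: int = 81,
    nucleus_halfwidth_px: float = 12.0,
) -> list[tuple[ProfileTrace, ProfileTrace]]:
    """Paired (nuclear, footprint) traces with a known boundary offset.

    Each trace is a single nucleus-like peak with genuine local minima at
    its boundaries.  The footprint's boundaries sit exactly
    ``offset_px`` *outside* the nuclear boundaries on both sides (before
    noise); a negative offset places them inside.
    """
    rng = np.random.default_rng(seed)
    out = []
    pos = np.arange(length, dtype=float)
    for _ in range(n_profiles):
        center = length / 2.0 + rng.uniform(-2.0, 2.0)
        hw = nucleus_halfwidth_px * rng.uniform(0.9, 1.1)

        def trace(half):
            vals = w_profile(pos, center - half, center, center + half)
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, vals.shape)
            return ProfileTrace(pos.copy(), vals)

        nuclear = trace(hw)
        footprint = trace(hw + offset_px)
        out.append((nuclear, footprint))
    return out


def w_profile(
    positions: np.ndarray,
    left: float,
    center: float,
    right: float,
    floor: float = 0.2,
    peak: float = 1.0,
) -> np.ndarray:
    """W-shaped intensity curve with minima exactly at ``left``/``right``.

    Built as the quartic whose derivative has roots at the two
    boundaries and the central peak, rescaled so the peak reads ``peak``
    and the lower boundary ``floor`` — the shape a nucleus-spanning line
    profile takes, with surrounding signal rising again past the cell
    boundary.
    """
    if not left < center < right:
        raise ValueError("need left < center < right")
    from numpy.polynomial import polynomial as P

    deriv = P.polyfromroots([left, center, right])
    quartic = P.polyint(deriv)
    vals = P.polyval(positions, quartic)
    v_center = P.polyval(center, quartic)
    v_floor = min(P.polyval(left, quartic), P.polyval(right, quartic))
    return floor + (peak - floor) * (vals - v_floor) / (v_center - v_floor)


def simulate_saturation_data(
    v_max: float,
    k_m: float,
    read_depths,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(reads, unique molecules) samples from the saturation hyperbola.

    ``unique = v_max·R/(k_m + R)``, perturbed by multiplicative Gaussian
    noise of relative sd ``noise_sd``.
    """
    if v_max <= 0 or k_m <= 0:
        raise ValueError("v_max and k_m must be positive")
    reads = np.asarray(list(read_depths), dtype=float)
    if np.any(reads <= 0):
        raise ValueError("read depths must be positive")
    rng = np.random.default_rng(seed)
    s = v_max * reads / (k_m + reads)
    if noise_sd > 0:
        s = s * (1.0 + rng.normal(0.0, noise_sd, s.shape))
    return list(zip(reads.tolist(), s.tolist()))
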