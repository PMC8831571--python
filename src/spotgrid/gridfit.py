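"""Parametric regular-grid fitting with iterative outlier shedding.

The array's spots sit on a rectangular lattice, so the registration
problem reduces to estimating five parameters — origin, two pitches and
one rotation (axes constrained perpendicular) — from the lattice-
consistent blob centers.  The fit alternates nearest-node assignment
with least-squares parameter updates; a refinement loop then repeatedly
drops the worst-fitting 0.1% of points and refits until the occupied
layout matches the array design (33 columns × 35 rows by default), after
which every lattice node — including those hidden under tissue — has a
coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .detection import BlobSet


class GridFitError(ValueError):
    """Raised for degenerate inputs or unreachable grid targets."""

    def __init__(self, message: str, iteration_log: list | None = None):
        super().__init__(message)
        self.iteration_log = iteration_log or []


@dataclass
class GridModel:
    """Regular grid: ``node(c, r) = origin + R(rot)·((c−1)·px, (r−1)·py)``.

    ``origin`` is the pixel position of node (1, 1); ``pitch`` the (x, y)
    pixel step per index; ``rotation_deg`` the angle of the column axis,
    the row axis being perpendicular; ``n_cols``/``n_rows`` the occupied
    index extents.
    """

    origin: tuple[float, float]
    pitch: tuple[float, float]
    rotation_deg: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.pitch[0] <= 0 or self.pitch[1] <= 0:
            raise ValueError("pitches must be positive")
        if not (-45.0 < self.rotation_deg <= 45.0):
            raise ValueError("rotation must lie in (-45°, 45°]")

    def _axes(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.radians(self.rotation_deg)
        u = np.array([np.cos(t), np.sin(t)])
        return u, np.array([-u[1], u[0]])

    def node(self, col, row) -> np.ndarray:
        """Pixel coordinates of 1-based node indices (vectorized)."""
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        u, v = self._axes()
        o = np.asarray(self.origin)
        return (
            o
            + (col - 1)[..., None] * self.pitch[0] * u
            + (row - 1)[..., None] * self.pitch[1] * v
        )

    def all_nodes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(cols, rows, xy) for the full ``n_cols × n_rows`` node set."""
        cc, rr = np.meshgrid(
            np.arange(1, self.n_cols + 1), np.arange(1, self.n_rows + 1)
        )
        cols, rows = cc.ravel(), rr.ravel()
        return cols, rows, self.node(cols, rows)


@dataclass
class IterationRecord:
    n_points: int
    n_cols: int
    n_rows: int
    objective: float


@dataclass
class GridFitResult:
    """Fit diagnostics: model, per-point assignments, residuals, log.

    ``assignments`` holds 1-based (col, row) per surviving point;
    ``primary`` marks, for each node with several assigned points, the
    nearest one (injective node → point map).  ``objective`` is the sum
    of squared point-to-node distances over surviving points.
    """

    model: GridModel
    points: np.ndarray
    assignments: np.ndarray
    residuals: np.ndarray
    primary: np.ndarray
    objective: float
    iteration_log: list[IterationRecord] = field(default_factory=list)
    converged: bool = True

    def summary(self) -> str:
        m = self.model
        lines = [
            "Regular grid fit",
            "=" * 40,
            f"points (surviving)   {len(self.points):>10d}",
            f"layout (cols x rows) {m.n_cols:>6d} x {m.n_rows}",
            f"pitch x / y (px)     {m.pitch[0]:>10.4f} / {m.pitch[1]:.4f}",
            f"rotation (deg)       {m.rotation_deg:>10.4f}",
            f"origin (px)          ({m.origin[0]:.2f}, {m.origin[1]:.2f})",
            f"objective (SSR, px2) {self.objective:>10.4g}",
            f"rms residual (px)    {np.sqrt(np.mean(self.residuals**2)):>10.4f}",
            f"refine iterations    {len(self.iteration_log):>10d}",
        ]
        return "\n".join(lines)


def _solve_params(points, cols, rows, theta_init_deg, theta_halfwidth_deg=10.0):
    """Least squares for (origin, pitches) with a 1-D search over rotation.

    For fixed rotation the model is linear in (x0, y0, px, py), so the
    inner solve is an ordinary lstsq; the rotation is found by bounded
    scalar minimization around the initial estimate.
    """
    c = np.asarray(cols, dtype=float)
    r = np.asarray(rows, dtype=float)
    if np.unique(np.round(c)).size < 2 or np.unique(np.round(r)).size < 2:
        raise GridFitError("degenerate point cloud: grid indices collinear")
    x, y = points[:, 0], points[:, 1]
    n = len(points)
    rhs = np.concatenate([x, y])

    def solve(theta):
        ct, st = np.cos(theta), np.sin(theta)
        a = np.zeros((2 * n, 4))
        a[:n, 0] = 1.0
        a[n:, 1] = 1.0
        a[:n, 2] = c * ct
        a[n:, 2] = c * st
        a[:n, 3] = -r * st
        a[n:, 3] = r * ct
        beta, _, rank, _ = np.linalg.lstsq(a, rhs, rcond=None)
        if rank < 4:
            raise GridFitError("degenerate point cloud: rank-deficient fit")
        ssr = float(np.sum((a @ beta - rhs) ** 2))
        return beta, ssr

    t0 = np.radians(theta_init_deg)
    hw = np.radians(theta_halfwidth_deg)
    res = minimize_scalar(
        lambda t: solve(t)[1],
        bounds=(t0 - hw, t0 + hw),
        method="bounded",
        options={"xatol": 1e-9},
    )
    theta = float(res.x)
    beta, ssr = solve(theta)
    x0, y0, px, py = beta
    if px <= 0 or py <= 0:
        raise GridFitError("fit produced nonpositive pitch; check rotation init")
    return (x0, y0), (px, py), np.degrees(theta), ssr


def _assign(points, origin, pitch, rotation_deg, window):
    """Nearest-node indices (0-based), clipped to per-axis index windows."""
    t = np.radians(rotation_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    q = (points - np.asarray(origin)) @ rot  # derotate
    ci = np.round(q[:, 0] / pitch[0]).astype(int)
    ri = np.round(q[:, 1] / pitch[1]).astype(int)
    clipped = (ci < window[0][0]) | (ci > window[0][1]) | (
        ri < window[1][0]
    ) | (ri > window[1][1])
    ci = np.clip(ci, window[0][0], window[0][1])
    ri = np.clip(ri, window[1][0], window[1][1])
    return ci, ri, clipped


def _node_xy(origin, pitch, rotation_deg, ci, ri):
    t = np.radians(rotation_deg)
    u = np.array([np.cos(t), np.sin(t)])
    v = np.array([-u[1], u[0]])
    return (
        np.asarray(origin)
        + ci[:, None] * pitch[0] * u
        + ri[:, None] * pitch[1] * v
    )


def _primary_mask(ci, ri, residuals):
    """True for the nearest point of each occupied node."""
    order = np.lexsort((residuals, ri, ci))
    primary = np.zeros(len(ci), dtype=bool)
    seen: set[tuple[int, int]] = set()
    for i in order:
        key = (int(ci[i]), int(ri[i]))
        if key not in seen:
            seen.add(key)
            primary[i] = True
    return primary


def _alternate_fit(
    points,
    origin,
    pitch,
    rotation_deg,
    extent_window,
    tol: float = 1e-8,
    max_alternations: int = 200,
):
    """Alternate nearest-node assignment and parameter updates.

    ``extent_window`` gives the admissible 0-based index range per axis;
    points whose rounding falls outside are clipped onto the boundary and
    excluded from the parameter update (they keep their — large —
    residuals for outlier ranking).
    """
    prev_obj = np.inf
    ci = ri = clipped = None
    for _ in range(max_alternations):
        ci, ri, clipped = _assign(points, origin, pitch, rotation_deg, extent_window)
        use = ~clipped
        if use.sum() < 8:
            use = np.ones(len(points), dtype=bool)
        origin0, pitch0, rot0 = origin, pitch, rotation_deg
        origin, pitch, rotation_deg, _ = _solve_params(
            points[use], ci[use], ri[use], rotation_deg
        )
        nodes = _node_xy(origin, pitch, rotation_deg, ci, ri)
        resid = np.linalg.norm(points - nodes, axis=1)
        obj = float(np.sum(resid[~clipped] ** 2))
        if prev_obj - obj < tol * max(prev_obj, 1.0) and np.isfinite(prev_obj):
            break
        prev_obj = obj
    ci, ri, clipped = _assign(points, origin, pitch, rotation_deg, extent_window)
    nodes = _node_xy(origin, pitch, rotation_deg, ci, ri)
    resid = np.linalg.norm(points - nodes, axis=1)
    return origin, pitch, rotation_deg, ci, ri, clipped, resid


def _rebase(origin, pitch, rotation_deg, ci, ri):
    """Shift indices so each axis starts at 0, moving the origin along."""
    minc, minr = int(ci.min()), int(ri.min())
    if minc or minr:
        shift = _node_xy(
            origin, pitch, rotation_deg, np.array([float(minc)]), np.array([float(minr)])
        )[0]
        origin = (float(shift[0]), float(shift[1]))
        ci = ci - minc
        ri = ri - minr
    return origin, ci, ri


def fit_regular_grid(
    points: BlobSet | np.ndarray,
    init_extent: int = 42,
    pitch_hint: float | None = None,
    rotation_hint: float | None = None,
    tol: float = 1e-8,
    max_alternations: int = 200,
) -> GridFitResult:
    """Fit a regular grid to blob centers by alternating least squares.

    Each point is assigned to its nearest grid node (indices capped at
    ``init_extent`` per axis, the rough-fit assumption) and the summed
    squared point-to-node distance minimized over origin, pitches and
    rotation; assignment and parameter updates alternate until the
    objective change falls below ``tol``.
    """
    if isinstance(points, BlobSet):
        if pitch_hint is None:
            pitch_hint = points.pitch_px
        if rotation_hint is None:
            rotation_hint = points.rotation_deg
        pts = points.centers
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 8:
        raise GridFitError(f"grid fitting needs at least 8 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise GridFitError("degenerate point cloud: points are collinear")

    from .detection import estimate_pitch, estimate_rotation

    if pitch_hint is None:
        pitch_hint = estimate_pitch(pts)
    if rotation_hint is None:
        rotation_hint = estimate_rotation(pts, pitch_hint)

    # Initial origin: the minimum corner of the derotated cloud, snapped
    # to the lattice phase (circular mean of coordinates mod pitch, to
    # which outliers contribute only near-uniform noise).  Anchoring on
    # the raw minimum — possibly an outlier — would split lattice rows
    # and columns across index boundaries in the first assignment.
    t = np.radians(rotation_hint)
    derot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    q = pts @ derot.T
    origin_q = np.empty(2)
    for axis in range(2):
        z = np.exp(2j * np.pi * q[:, axis] / pitch_hint)
        phase = np.angle(z.mean()) / (2 * np.pi) * pitch_hint
        origin_q[axis] = phase + np.round(
            (q[:, axis].min() - phase) / pitch_hint
        ) * pitch_hint
    origin = tuple(derot.T @ origin_q)

    window = ((0, init_extent - 1), (0, init_extent - 1))
    origin, pitch, rotation_deg, ci, ri, clipped, resid = _alternate_fit(
        pts,
        origin,
        (pitch_hint, pitch_hint),
        rotation_hint,
        window,
        tol=tol,
        max_alternations=max_alternations,
    )
    origin, ci, ri = _rebase(origin, pitch, rotation_deg, ci, ri)
    model = GridModel(
        origin=tuple(map(float, origin)),
        pitch=tuple(map(float, pitch)),
        rotation_deg=float(rotation_deg),
        n_cols=int(ci.max()) + 1,
        n_rows=int(ri.max()) + 1,
    )
    objective = float(np.sum(resid**2))
    return GridFitResult(
        model=model,
        points=pts,
        assignments=np.column_stack([ci + 1, ri + 1]),
        residuals=resid,
        primary=_primary_mask(ci, ri, resid),
        objective=objective,
        iteration_log=[
            IterationRecord(len(pts), model.n_cols, model.n_rows, objective)
        ],
    )


def _best_window(indices: np.ndarray, extent: int, target: int) -> tuple[int, int]:
    """Contiguous index window of length ``target`` capturing most points."""
    if extent <= target:
        return 0, extent - 1
    counts = np.bincount(indices, minlength=extent)
    sums = np.convolve(counts, np.ones(target, dtype=int), mode="valid")
    w = int(np.argmax(sums))
    return w, w + target - 1


def iterative_refine(
    fit: GridFitResult,
    target_cols: int = 33,
    target_rows: int = 35,
    drop_fraction: float = 0.001,
    tol: float = 1e-8,
    max_iterations: int = 5000,
) -> GridFitResult:
    """Shed worst-fitting points until the grid reaches the target layout.

    Each iteration removes ``max(1, ceil(drop_fraction·N))`` points with
    the largest residuals (ties broken toward points farther from the
    grid centroid — peripheral artifacts first), refits, and recomputes
    the occupied extents; iteration stops once they equal the targets.
    Orientation is resolved by matching the larger target to the larger
    occupied extent (axes swapped and refit if needed).  Points outside
    the best target-sized index window are clipped onto its boundary, so
    stray detections beyond the array rank as worst and go first.
    """
    pts = fit.points.copy()
    model = fit.model
    origin, pitch, rotation_deg = model.origin, model.pitch, model.rotation_deg
    ci = fit.assignments[:, 0] - 1
    ri = fit.assignments[:, 1] - 1
    log = list(fit.iteration_log)

    # Orientation: larger target axis should match larger occupied extent.
    ncols, nrows = int(ci.max()) + 1, int(ri.max()) + 1
    if (target_cols - target_rows) * (ncols - nrows) < 0:
        ci, ri = ri, ci
        pitch = (pitch[1], pitch[0])
        new_rot = rotation_deg - 90.0
        while new_rot <= -45.0:
            new_rot += 90.0
        try:
            origin, pitch, rotation_deg, _ = _solve_params(pts, ci, ri, new_rot)
        except GridFitError:
            origin, pitch, rotation_deg, _ = _solve_params(pts, ci, ri, rotation_deg)

    unbounded = ((-(10**9), 10**9), (-(10**9), 10**9))
    for _ in range(max_iterations):
        ncols, nrows = int(ci.max()) + 1, int(ri.max()) + 1
        wc = _best_window(ci, ncols, target_cols)
        wr = _best_window(ri, nrows, target_rows)
        origin, pitch, rotation_deg, _, _, _, resid = _alternate_fit(
            pts, origin, pitch, rotation_deg, (wc, wr), tol=tol
        )
        # Occupied extents come from the UNCLIPPED nearest-node indices:
        # a stray point beyond the array keeps its true index (growing
        # the extent) while its window-clipped residual ranks it worst.
        ci, ri, _ = _assign(pts, origin, pitch, rotation_deg, unbounded)
        origin, ci, ri = _rebase(origin, pitch, rotation_deg, ci, ri)
        ncols, nrows = int(ci.max()) + 1, int(ri.max()) + 1
        obj = float(np.sum(resid**2))
        log.append(IterationRecord(len(pts), ncols, nrows, obj))
        if (ncols, nrows) == (target_cols, target_rows):
            model = GridModel(
                origin=tuple(map(float, origin)),
                pitch=tuple(map(float, pitch)),
                rotation_deg=float(rotation_deg),
                n_cols=target_cols,
                n_rows=target_rows,
            )
            return GridFitResult(
                model=model,
                points=pts,
                assignments=np.column_stack([ci + 1, ri + 1]),
                residuals=resid,
                primary=_primary_mask(ci, ri, resid),
                objective=obj,
                iteration_log=log,
            )
        n_drop = max(1, int(np.ceil(drop_fraction * len(pts))))
        if len(pts) - n_drop < max(8, target_cols + target_rows):
            raise GridFitError(
                "grid targets unreachable: points exhausted before reaching "
                f"{target_cols}x{target_rows}",
                iteration_log=log,
            )
        centroid = pts.mean(axis=0)
        d_centroid = np.linalg.norm(pts - centroid, axis=1)
        order = np.lexsort((-d_centroid, -resid))
        drop = order[:n_drop]
        keep = np.ones(len(pts), dtype=bool)
        keep[drop] = False
        pts, ci, ri = pts[keep], ci[keep], ri[keep]
        origin, ci, ri = _rebase(origin, pitch, rotation_deg, ci, ri)
    raise GridFitError(
        "grid targets unreachable: iteration limit hit", iteration_log=log
    )


def enumerate_nodes(model: GridModel) -> pd.DataFrame:
    """Full node table for a fitted grid (flags unset).

    One row per (col ∈ 1..n_cols, row ∈ 1..n_rows) with the model's
    pixel centroid — including nodes with no observed blob, i.e. spots
    hidden under tissue.
    """
    cols, rows, xy = model.all_nodes()
    return pd.DataFrame(
        {
            "x": cols.astype(int),
            "y": rows.astype(int),
            "pixel_x": xy[:, 0],
            "pixel_y": xy[:, 1],
            "under_tissue": False,
        }
    )
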