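"""Sequencing-library saturation: Michaelis–Menten model à la
Lineweaver–Burk.

Unique molecules S recovered at raw read depth R follow the saturating
hyperbola ``S = V_max · R / (K_M + R)``: ``V_max`` is the library's
maximum unique-molecule count and ``K_M`` the read depth at half of it.
The Lineweaver–Burk linearization, ``1/S = (K_M/V_max)·(1/R) + 1/V_max``,
turns three or more downsampled (R, S) summaries into a straight-line
fit, from which the reads required for a target saturation follow as
``R_s = S_s·K_M / (V_max − S_s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SaturationError(ValueError):
    """Raised for data inconsistent with a saturating model."""


@dataclass(frozen=True)
class SaturationPoint:
    """One downsampling summary: raw reads kept and unique molecules seen."""

    raw_reads: float
    unique_molecules: float
    fraction: float = 1.0
    unique_genes: int | None = None

    def __post_init__(self) -> None:
        if self.raw_reads < 0 or self.unique_molecules < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SaturationModel:
    """Fitted (V_max, K_M) of the saturation hyperbola."""

    v_max: float
    k_m: float

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k_m <= 0:
            raise ValueError("v_max and k_m must be positive")

    def molecules_at(self, raw_reads) -> np.ndarray:
        r = np.asarray(raw_reads, dtype=float)
        return self.v_max * r / (self.k_m + r)


@dataclass(frozen=True)
class SaturationFit:
    """Results of :func:`fit_saturation`: model, fit line, diagnostics."""

    model: SaturationModel
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    nonlinear_refined: bool = False

    def summary(self) -> str:
        m = self.model
        return "\n".join(
            [
                "Saturation model (Lineweaver-Burk)",
                "=" * 40,
                f"V_max (unique molecules) {m.v_max:>14.1f}",
                f"K_M (raw reads)          {m.k_m:>14.1f}",
                f"linearized slope         {self.slope:>14.6g}",
                f"linearized intercept     {self.intercept:>14.6g}",
                f"R^2 (1/S vs 1/R)         {self.r_squared:>14.6f}",
                f"points                   {self.n_points:>14d}",
                f"nonlinear refinement     {str(self.nonlinear_refined):>14s}",
            ]
        )


def _as_read_tallies(library) -> np.ndarray:
    """Molecule copy counts from a library fixture.

    Accepts an array of per-molecule read counts, or a spots × genes
    count matrix (approximation mode: each UMI becomes one molecule
    carrying a single read, since per-UMI read multiplicities are gone
    after collapsing).
    """
    if isinstance(library, pd.DataFrame):
        total = int(library.to_numpy().sum())
        return np.ones(total, dtype=int)
    arr = np.asarray(library)
    if arr.ndim != 1 or np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError(
            "library must be a 1-D array of per-molecule read counts or a "
            "count matrix"
        )
    return arr.astype(int)


def downsample_counts(library, fraction: float, seed: int = 0) -> SaturationPoint:
    """Binomially thin a library's reads to ``fraction`` and re-tally.

    Each read survives independently with probability ``fraction``; the
    unique-molecule count is the number of molecules retaining at least
    one read.  ``fraction = 1`` is the identity point.
    """
    if not 0.0 < fraction <= 1.0:
        raise SaturationError("fraction must lie in (0, 1]")
    tallies = _as_read_tallies(library)
    if fraction == 1.0:
        surviving = tallies
    else:
        rng = np.random.default_rng(seed)
        surviving = rng.binomial(tallies, fraction)
    return SaturationPoint(
        raw_reads=float(surviving.sum()),
        unique_molecules=float((surviving > 0).sum()),
        fraction=fraction,
    )


def fit_saturation(points, nonlinear_refine: bool = False) -> SaturationFit:
    """Fit (V_max, K_M) from ≥3 saturation points.

    Ordinary least squares on the linearized form (1/S against 1/R):
    ``v_max = 1/intercept``, ``k_m = slope/intercept``.  The
    linearization is noise-sensitive, so ``nonlinear_refine=True``
    polishes the estimate with a direct nonlinear fit of the hyperbola
    started from the linear solution.
    """
    pts = list(points)
    if len(pts) < 3:
        raise SaturationError("need at least 3 saturation points")
    r = np.array([p.raw_reads for p in pts], dtype=float)
    s = np.array([p.unique_molecules for p in pts], dtype=float)
    if np.any(r <= 0) or np.any(s <= 0):
        raise SaturationError("points must have positive reads and molecules")
    if np.unique(r).size < 3:
        raise SaturationError("need at least 3 distinct read depths")
    x, y = 1.0 / r, 1.0 / s
    slope, intercept = np.polyfit(x, y, 1)
    if intercept <= 0 or slope <= 0:
        raise SaturationError(
            "linearized fit has nonpositive slope or intercept: data are "
            "inconsistent with a saturating model"
        )
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    v_max = 1.0 / intercept
    k_m = slope / intercept
    refined = False
    if nonlinear_refine:
        from scipy.optimize import curve_fit

        try:
            (v_max, k_m), _ = curve_fit(
                lambda rr, v, k: v * rr / (k + rr), r, s, p0=(v_max, k_m)
            )
            refined = True
        except RuntimeError:
            pass
        if v_max <= 0 or k_m <= 0:
            raise SaturationError("nonlinear refinement left the model domain")
    return SaturationFit(
        model=SaturationModel(v_max=float(v_max), k_m=float(k_m)),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points=len(pts),
        nonlinear_refined=refined,
    )


def reads_for_saturation(model: SaturationModel, target_s: float) -> float:
    """Raw reads needed to reach ``target_s`` unique molecules.

    ``R_s = S_s · K_M / (V_max − S_s)``; the target must lie strictly
    below the library's maximum.
    """
    if target_s < 0:
        raise SaturationError("target saturation must be nonnegative")
    if target_s >= model.v_max:
        raise SaturationError(
            f"target {target_s} is at or above V_max={model.v_max:.1f}: "
            "unreachable saturation"
        )
    return float(target_s * model.k_m / (model.v_max - target_s))


def sample_curve(
    library,
    n_points: int = 9,
    fraction_range: tuple[float, float] = (1e-5, 1.0),
    seed: int = 0,
    gene_depth_threshold: float = 1e-6,
) -> list[SaturationPoint]:
    """Saturation curve: downsample at log-spaced fractions.

    For count-matrix libraries each point also tallies the number of
    genes whose surviving transcripts exceed ``gene_depth_threshold`` of
    the point's read depth (the "expressed gene" rule used in curve
    summaries).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    lo, hi = fraction_range
    if not 0.0 < lo < hi <= 1.0:
        raise ValueError("fraction_range must satisfy 0 < lo < hi <= 1")
    fractions = np.geomspace(lo, hi, n_points)
    rng = np.random.default_rng(seed)
    out = []
    is_matrix = isinstance(library, pd.DataFrame)
    for frac in fractions:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if is_matrix:
            counts = library.to_numpy()
            if frac == 1.0:
                surv = counts
            else:
                sub_rng = np.random.default_rng(sub_seed)
                surv = sub_rng.binomial(counts, frac)
            reads = float(surv.sum())
            genes = int(
                (surv.sum(axis=0) > gene_depth_threshold * max(reads, 1.0)).sum()
            )
            out.append(
                SaturationPoint(
                    raw_reads=reads,
                    unique_molecules=float((surv > 0).sum()),
                    fraction=float(frac),
                    unique_genes=genes,
                )
            )
        else:
            p = downsample_counts(library, float(frac), seed=sub_seed)
            out.append(p)
    return out


def curve_to_frame(points) -> pd.DataFrame:
    """Tabulate a saturation curve (``curve.tsv`` layout)."""
    return pd.DataFrame(
        {
            "fraction": [p.fraction for p in points],
            "raw_reads": [p.raw_reads for p in points],
            "unique_molecules": [p.unique_molecules for p in points],
            "unique_genes": [p.unique_genes for p in points],
        }
    )
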