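"""Rasterized map overlap: the Dice agreement between ONHC deficiency maps
and visual-field defect plots.

Both maps are rendered into a common right-eye visual-field raster
(default 0.1 deg/pixel over ±30°, i.e. 601×601 pixel centres) and compared
with the overlap statistic

    overlap = 100 × 2·|A ∩ B| / (|A| + |B|)   (per cent)

i.e. the Sørensen–Dice coefficient of the two binary masks.  ONHC
deficiency stages are rasterized from the hexagon polygons; each flagged
30-2 point contributes its natural 6°×6° lattice cell, clipped to the 30°
circular field.  Crossing the four deficiency stages with the four TD
stages yields the 4×4 overlap matrix; cohort summaries, the group t-test,
the one-way ANOVA with Bonferroni-adjusted post hoc pairs, and the
concave ("negative quadric") overlap-curve fit live here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import stats

from .geometry import HexArray, PerimetryGrid
from .perimetry import DefectPlot, TD_LEVELS
from .quantify import OnhcMap, STAGE_THRESHOLDS

DEFAULT_RESOLUTION = 0.1
DEFAULT_EXTENT = 30.0


@dataclass(frozen=True)
class RasterMask:
    """A binary mask over the central visual field.

    Pixel centres lie on a square lattice with the given resolution
    (deg/pixel), spanning [-extent, extent] in both axes inclusive.
    """

    grid: np.ndarray           # bool, (n, n); row 0 = superior edge
    resolution: float
    extent: float

    @property
    def area(self) -> float:
        """Mask area in deg² (pixel count × resolution²)."""
        return float(np.count_nonzero(self.grid)) * self.resolution ** 2

    def compatible(self, other: "RasterMask") -> bool:
        return (self.grid.shape == other.grid.shape
                and math.isclose(self.resolution, other.resolution)
                and math.isclose(self.extent, other.extent))

    def to_text(self, path) -> None:
        """Plain-text 0/1 grid, one row per line."""
        np.savetxt(path, self.grid.astype(np.uint8), fmt="%d", delimiter="")


def _axes(resolution: float, extent: float) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(2 * extent / resolution)) + 1
    xs = np.linspace(-extent, extent, n)
    ys = np.linspace(extent, -extent, n)  # row 0 superior
    return xs, ys


def empty_raster(resolution: float = DEFAULT_RESOLUTION,
                 extent: float = DEFAULT_EXTENT) -> RasterMask:
    xs, ys = _axes(resolution, extent)
    return RasterMask(grid=np.zeros((len(ys), len(xs)), dtype=bool),
                      resolution=resolution, extent=extent)


def rasterize_hex_mask(
    mask: np.ndarray,
    geometry: HexArray,
    resolution: float = DEFAULT_RESOLUTION,
    extent: float = DEFAULT_EXTENT,
) -> RasterMask:
    """Rasterize a per-hexagon boolean mask.

    A pixel is set when its centre falls inside any flagged hexagon.
    """
    if resolution > 0.25:
        raise ValueError("raster resolution coarser than 0.25 deg/px")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (61,):
        raise ValueError("hexagon mask must have 61 entries")
    xs, ys = _axes(resolution, extent)
    grid = np.zeros((len(ys), len(xs)), dtype=bool)
    for element, flagged in zip(geometry.elements, mask):
        if not flagged:
            continue
        vv = np.asarray(element.vertices)
        i0 = np.searchsorted(xs, vv[:, 0].min() - resolution)
        i1 = np.searchsorted(xs, vv[:, 0].max() + resolution)
        # ys is descending
        j0 = len(ys) - np.searchsorted(ys[::-1], vv[:, 1].max() + resolution)
        j1 = len(ys) - np.searchsorted(ys[::-1], vv[:, 1].min() - resolution)
        sub_x, sub_y = np.meshgrid(xs[i0:i1], ys[j0:j1])
        pts = np.column_stack([sub_x.ravel(), sub_y.ravel()])
        inside = MplPath(vv).contains_points(pts).reshape(sub_x.shape)
        grid[j0:j1, i0:i1] |= inside
    return RasterMask(grid=grid, resolution=resolution, extent=extent)


def rasterize_defect_mask(
    mask: np.ndarray,
    grid: PerimetryGrid,
    cell_size: float = 6.0,
    resolution: float = DEFAULT_RESOLUTION,
    extent: float = DEFAULT_EXTENT,
) -> RasterMask:
    """Rasterize a per-point 30-2 defect mask.

    Each flagged point contributes the axis-aligned cell_size × cell_size
    square centred on it (half-open on the upper edges so adjacent cells
    tile without double counting), clipped to the circular 30° field.
    """
    if resolution > 0.25:
        raise ValueError("raster resolution coarser than 0.25 deg/px")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (76,):
        raise ValueError("defect mask must have 76 entries")
    xs, ys = _axes(resolution, extent)
    gx, gy = np.meshgrid(xs, ys)
    out = np.zeros_like(gx, dtype=bool)
    h = cell_size / 2.0
    for (px, py), flagged in zip(grid.points, mask):
        if not flagged:
            continue
        out |= ((gx >= px - h) & (gx < px + h)
                & (gy >= py - h) & (gy < py + h))
    out &= gx ** 2 + gy ** 2 <= extent ** 2
    return RasterMask(grid=out, resolution=resolution, extent=extent)


def dice_overlap(a: RasterMask, b: RasterMask) -> float:
    """Overlap percentage 100·2|A∩B|/(|A|+|B|); nan when both masks are empty.

    Symmetric, bounded in [0, 100]; 100 exactly when the masks are
    identical and non-empty, 0 when they are disjoint and non-empty.
    """
    if not a.compatible(b):
        raise ValueError("raster frames differ (resolution/extent/shape)")
    na = int(np.count_nonzero(a.grid))
    nb = int(np.count_nonzero(b.grid))
    if na + nb == 0:
        return float("nan")
    inter = int(np.count_nonzero(a.grid & b.grid))
    return 100.0 * 2.0 * inter / (na + nb)


@dataclass(frozen=True)
class OverlapMatrix:
    """4×4 stage-overlap table: rows TD stages, columns ONHC ratio stages.

    ``overlap_pct[i, j]`` is the Dice overlap (%) between the TD stage
    ``td_levels[i]`` defect plot and the ratio < ``onhc_thresholds[j]``
    deficiency map; nan marks cells where both masks were empty.
    """

    overlap_pct: np.ndarray            # (4, 4), % or nan
    intersection_deg2: np.ndarray      # (4, 4)
    td_areas_deg2: np.ndarray          # (4,)
    onhc_areas_deg2: np.ndarray        # (4,)
    td_levels: tuple[float, ...] = TD_LEVELS
    onhc_thresholds: tuple[float, ...] = STAGE_THRESHOLDS

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.overlap_pct,
            index=[f"TD<{l:g}%" for l in self.td_levels],
            columns=[f"R<{t:g}" for t in self.onhc_thresholds],
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def overlap_matrix(
    onhc_map: OnhcMap,
    defect: DefectPlot,
    geometry: HexArray,
    grid: PerimetryGrid,
    resolution: float = DEFAULT_RESOLUTION,
    extent: float = DEFAULT_EXTENT,
) -> OverlapMatrix:
    """Dice overlaps over the 4×4 cross-product of stages for one eye."""
    onhc_rasters = [
        rasterize_hex_mask(onhc_map.stage_masks[t], geometry, resolution, extent)
        for t in STAGE_THRESHOLDS
    ]
    td_rasters = [
        rasterize_defect_mask(defect.stage_masks[l], grid, 6.0, resolution, extent)
        for l in TD_LEVELS
    ]
    pct = np.full((4, 4), np.nan)
    inter = np.zeros((4, 4))
    for i, tr in enumerate(td_rasters):
        for j, orr in enumerate(onhc_rasters):
            pct[i, j] = dice_overlap(tr, orr)
            inter[i, j] = float(np.count_nonzero(tr.grid & orr.grid)) * resolution ** 2
    return OverlapMatrix(
        overlap_pct=pct,
        intersection_deg2=inter,
        td_areas_deg2=np.array([r.area for r in td_rasters]),
        onhc_areas_deg2=np.array([r.area for r in onhc_rasters]),
    )


# ---------------------------------------------------------------------------
# cohort statistics
# ---------------------------------------------------------------------------

def cohort_overlap_stats(matrices: Sequence[OverlapMatrix]) -> pd.DataFrame:
    """Per-cell mean ± SD over eyes, skipping undefined (nan) cells.

    Returns a tidy frame with one row per (TD stage, ONHC stage) cell.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    stack = np.stack([m.overlap_pct for m in matrices])  # (n_eyes, 4, 4)
    rows = []
    for i, level in enumerate(TD_LEVELS):
        for j, thr in enumerate(STAGE_THRESHOLDS):
            cell = stack[:, i, j]
            defined = cell[np.isfinite(cell)]
            rows.append({
                "td_level": level,
                "onhc_threshold": thr,
                "n": defined.size,
                "mean_pct": float(np.mean(defined)) if defined.size else float("nan"),
                "sd_pct": float(np.std(defined, ddof=1)) if defined.size > 1
                          else float("nan"),
            })
    return pd.DataFrame(rows)


def independent_t(group_a: Sequence[float], group_b: Sequence[float],
                  equal_var: bool = True) -> tuple[float, float]:
    """Two-tailed independent-samples t-test (pooled or Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def anova_bonferroni(groups: Sequence[Sequence[float]]) -> dict:
    """One-way ANOVA with Bonferroni-adjusted pairwise post hoc t-tests.

    Pairwise adjusted p-values are min(1, m · p_raw) with m the number of
    pairwise comparisons.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 groups of at least 2 observations")
    f, p = stats.f_oneway(*arrays)
    m = len(arrays) * (len(arrays) - 1) // 2
    pairs = {}
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            t_ij, p_ij = stats.ttest_ind(arrays[i], arrays[j])
            pairs[(i, j)] = {"t": float(t_ij), "p_raw": float(p_ij),
                             "p_adj": float(min(1.0, m * p_ij))}
    return {"F": float(f), "p": float(p), "pairwise": pairs}


# ---------------------------------------------------------------------------
# quadric overlap-curve fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuadricFit:
    """Least-squares quadratic overlap ≈ a·s² + b·s + c over stage severity.

    When one map is fixed and the other grows through it, the overlap
    curve is concave with its maximum where the two areas match, so a
    negative leading coefficient ("negative quadric") is expected;
    ``concave`` flags that, and ``extrapolated`` flags a vertex outside
    the fitted severity range.
    """

    a: float
    b: float
    c: float
    vertex: float
    peak: float
    residual: float
    concave: bool
    extrapolated: bool

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


def fit_overlap_quadric(stage_severity: Sequence[float],
                        overlaps: Sequence[float]) -> QuadricFit:
    """Fit the concave overlap-vs-severity curve and locate its vertex."""
    s = np.asarray(stage_severity, dtype=float)
    y = np.asarray(overlaps, dtype=float)
    keep = np.isfinite(s) & np.isfinite(y)
    s, y = s[keep], y[keep]
    if np.unique(s).size < 3:
        raise ValueError("need at least 3 distinct severity points")
    a, b, c = np.polyfit(s, y, 2)
    if a == 0:
        raise ValueError("degenerate (collinear) overlap data")
    vertex = -b / (2 * a)
    resid = float(np.sqrt(np.mean((np.polyval([a, b, c], s) - y) ** 2)))
    return QuadricFit(
        a=float(a), b=float(b), c=float(c),
        vertex=float(vertex),
        peak=float(np.polyval([a, b, c], vertex)),
        residual=resid,
        concave=bool(a < 0),
        extrapolated=not (s.min() <= vertex <= s.max()),
    )
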