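"""Humphrey 30-2 total-deviation plots and staged defect extraction.

Total deviation (TD) is the pointwise difference, in dB, between measured
sensitivity and the age-matched normal value.  Points are staged by the
probability of their TD under the normal distribution: worse than 5%, 2%,
1% or 0.5% of normals.  The instrument's normative probability limits are
proprietary, so this package ships a synthetic per-point threshold table
(used consistently by the simulator and the analyser) derived from the
package's structure-function model, eccentricity-dependent like real
norms; see :func:`default_td_norms`.  The two blind-spot-adjacent points
are excluded from all masks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import Laterality, PerimetryGrid, build_30_2_grid
from .model import AMPLITUDE_EXPONENT, TD_SLOPE_DB, healthy_onhc_ratio

#: probability levels (%) of the four TD stages, loosest first
TD_LEVELS = (5.0, 2.0, 1.0, 0.5)

#: category labels used in CSV files, incl. "none"
CATEGORY_LABELS = ("none", "5", "2", "1", "0.5")

#: ratio stage boundaries mirrored by the four TD probability stages
_RATIO_STAGES = (0.5, 0.3, 0.2, 0.1)

#: how far each TD stage boundary is pushed into the next deeper ratio
#: stage's integrity band (fraction of the band width)
TD_STAGE_NESTING = 0.4


def default_td_norms(grid: PerimetryGrid) -> np.ndarray:
    """(76, 4) TD probability thresholds (dB) at p<5/2/1/0.5% per point.

    Instrument normative limits are proprietary, so the package derives a
    synthetic table from its own structure-function model: the TD stage at
    probability level k is placed at the dB loss that corresponds (via the
    linear dB-per-integrity slope) to the ganglion-cell integrity at which
    the ONHC ratio crosses its k-th stage boundary at the same
    eccentricity, offset by ``TD_STAGE_NESTING`` of the gap to the next
    deeper stage.  The offset nests each perimetric stage strictly inside
    the integrity band of its matched ratio stage, which stabilises the
    matched-stage agreement against sampling-geometry ties; absolute
    agreement with any perimeter's limits is not claimed.  Thresholds are
    strictly decreasing across levels at every point, and central points
    get tighter limits than peripheral ones, as in real perimetric norms.
    """
    ecc = np.hypot(grid.points[:, 0], grid.points[:, 1])
    rb = healthy_onhc_ratio(ecc)
    stages = np.asarray(_RATIO_STAGES)
    # integrity at which the ratio crosses each stage boundary, per point
    integrity = np.clip(stages[None, :] / rb[:, None], 0.0, 1.0) \
        ** (1.0 / AMPLITUDE_EXPONENT)
    gap = np.diff(integrity, axis=1)              # negative, (76, 3)
    nested = integrity.copy()
    nested[:, :3] += TD_STAGE_NESTING * gap
    nested[:, 3] += TD_STAGE_NESTING * gap[:, 2]
    return -TD_SLOPE_DB * (1.0 - np.clip(nested, 0.02, 1.0))


def assign_td_categories(
    td_db: np.ndarray,
    norms: np.ndarray,
    excluded_ids: Sequence[int] = (),
) -> np.ndarray:
    """Per-point probability category: the strictest level whose threshold
    lies above the measured TD.

    ``norms`` is (n_points, 4), columns ordered p<5/2/1/0.5%, rows
    non-increasing.  Excluded (blind-spot-adjacent) points are always
    "none".
    """
    td = np.asarray(td_db, dtype=float)
    norms = np.asarray(norms, dtype=float)
    if norms.shape != (td.size, 4):
        raise ValueError(f"norms must be ({td.size}, 4), got {norms.shape}")
    if np.any(np.diff(norms, axis=1) > 1e-12):
        raise ValueError("per-point thresholds must be non-increasing across levels")
    cats = np.full(td.size, "none", dtype=object)
    for j, label in enumerate(("5", "2", "1", "0.5")):
        cats[td < norms[:, j]] = label
    for pid in excluded_ids:
        cats[pid - 1] = "none"
    return cats.astype(str)


_CAT_RANK = {"none": 0, "5": 1, "2": 2, "1": 3, "0.5": 4}


@dataclass(frozen=True)
class TdPlot:
    """One eye's 30-2 total-deviation plot."""

    eye: Laterality
    td_db: np.ndarray                  # (76,)
    prob_category: np.ndarray          # (76,) of {"none","5","2","1","0.5"}
    excluded_ids: tuple[int, ...]
    md: float = float("nan")
    psd: float = float("nan")

    def __post_init__(self) -> None:
        td = np.asarray(self.td_db, dtype=float)
        object.__setattr__(self, "td_db", td)
        cats = np.asarray(self.prob_category, dtype=str)
        object.__setattr__(self, "prob_category", cats)
        if td.shape != (76,) or cats.shape != (76,):
            raise ValueError("TdPlot needs 76 TD values and categories")
        unknown = set(cats) - set(CATEGORY_LABELS)
        if unknown:
            raise ValueError(f"unknown probability categories {sorted(unknown)}")

    @classmethod
    def from_td(cls, td_db: np.ndarray, grid: PerimetryGrid,
                norms: np.ndarray | None = None) -> "TdPlot":
        """Build a plot from raw TD values, staging with the given norms."""
        norms = default_td_norms(grid) if norms is None else norms
        cats = assign_td_categories(td_db, norms, grid.blind_spot_ids)
        td = np.asarray(td_db, dtype=float)
        keep = np.ones(76, dtype=bool)
        for pid in grid.blind_spot_ids:
            keep[pid - 1] = False
        return cls(eye=grid.eye, td_db=td, prob_category=cats,
                   excluded_ids=tuple(grid.blind_spot_ids),
                   md=float(np.mean(td[keep])), psd=float(np.std(td[keep], ddof=1)))


@dataclass(frozen=True)
class DefectPlot:
    """Four nested per-point defect masks at p<5/2/1/0.5%."""

    stage_masks: dict[float, np.ndarray]

    def __post_init__(self) -> None:
        masks = [self.stage_masks[l] for l in TD_LEVELS]
        for tight, loose in zip(masks[1:], masks[:-1]):
            if np.any(tight & ~loose):
                raise ValueError("defect stage masks must be nested")


def extract_defect_plot(plot: TdPlot) -> DefectPlot:
    """Cumulative stage masks from a categorised TD plot.

    A point flagged at p<1% belongs to the p<5%, p<2% and p<1% masks;
    excluded points belong to none.
    """
    rank = np.array([_CAT_RANK[c] for c in plot.prob_category])
    for pid in plot.excluded_ids:
        rank[pid - 1] = 0
    masks = {level: rank >= j + 1 for j, level in enumerate(TD_LEVELS)}
    return DefectPlot(stage_masks=masks)


# ---------------------------------------------------------------------------
# CSV dialect: point_id,x_deg,y_deg,td_db,prob_category
# ---------------------------------------------------------------------------

def write_td_csv(plot: TdPlot, path, grid: PerimetryGrid | None = None) -> None:
    grid = grid or build_30_2_grid(plot.eye)
    pd.DataFrame({
        "point_id": np.arange(1, 77),
        "x_deg": grid.points[:, 0],
        "y_deg": grid.points[:, 1],
        "td_db": plot.td_db,
        "prob_category": plot.prob_category,
    }).to_csv(path, index=False, float_format="%.17g")


def read_td_csv(path, eye: Laterality = "right") -> TdPlot:
    """Read a 30-2 TD plot from the documented CSV dialect.

    Categories may be absent (empty column or all blank); they can then be
    assigned later with :func:`assign_td_categories` via
    :meth:`TdPlot.from_td`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"point_id", "td_db"}
    if not required.issubset(df.columns):
        raise ValueError(f"TD CSV needs at least columns {sorted(required)}")
    if len(df) != 76:
        raise ValueError(f"wrong point count: expected 76 rows, got {len(df)}")
    ids = df["point_id"].to_numpy()
    if len(np.unique(ids)) != 76:
        raise ValueError("duplicate points in TD CSV")
    df = df.sort_values("point_id")
    td = df["td_db"].to_numpy(dtype=float)
    if np.any(~np.isfinite(td)):
        raise ValueError("malformed td_db values")
    grid = build_30_2_grid(eye)
    if "prob_category" in df.columns and df["prob_category"].notna().all():
        # tolerate numeric parsing of the category column ("5.0" -> "5")
        norm = {"5.0": "5", "2.0": "2", "1.0": "1"}
        cats = np.array([norm.get(str(c), str(c))
                         for c in df["prob_category"]], dtype=str)
        keep = np.ones(76, dtype=bool)
        for pid in grid.blind_spot_ids:
            keep[pid - 1] = False
        return TdPlot(eye=eye, td_db=td, prob_category=cats,
                      excluded_ids=tuple(grid.blind_spot_ids),
                      md=float(np.mean(td[keep])),
                      psd=float(np.std(td[keep], ddof=1)))
    return TdPlot.from_td(td, grid)


def write_indices_json(plot: TdPlot, path) -> None:
    """MD/PSD sidecar for a TD plot."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"eye": plot.eye, "md_db": plot.md, "psd_db": plot.psd}, fh)
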