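"""Gray-scale map rendering for ONHC ratio and deficiency maps."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.collections import PolyCollection

from .geometry import HexArray
from .quantify import OnhcMap, STAGE_THRESHOLDS

#: gray levels of the four deficiency stages, loosest to deepest
STAGE_GRAYS = (0.75, 0.5, 0.25, 0.0)


def ratio_gray(ratio: np.ndarray) -> np.ndarray:
    """Gray level linear in the ONHC ratio, clipped to [0, 1]."""
    return np.clip(np.asarray(ratio, dtype=float), 0.0, 1.0)


def stage_gray(ratio: np.ndarray) -> np.ndarray:
    """Binned gray level: white when not deficient, four stage bins below."""
    r = np.asarray(ratio, dtype=float)
    g = np.ones_like(r)
    for thr, gray in zip(STAGE_THRESHOLDS, STAGE_GRAYS):
        g[r < thr] = gray
    return g


def render_ratio_map(onhc_map: OnhcMap, geometry: HexArray,
                     mode: str = "ratio", ax=None):
    """Draw the per-hexagon gray-scale map.

    ``mode`` is ``"ratio"`` (continuous gray, black = ratio 0, white = 1)
    or ``"deficiency"`` (four gray bins for the stages, white elsewhere).
    Returns the matplotlib Axes.
    """
    if mode == "ratio":
        grays = ratio_gray(onhc_map.ratio)
    elif mode == "deficiency":
        grays = stage_gray(onhc_map.ratio)
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    polys = [np.asarray(e.vertices) for e in geometry.elements]
    coll = PolyCollection(polys, facecolors=[str(g) for g in grays],
                          edgecolors="0.6", linewidths=0.4)
    ax.add_collection(coll)
    ax.set_xlim(-31, 31)
    ax.set_ylim(-31, 31)
    ax.set_aspect("equal")
    ax.set_xlabel("temporal field (deg)")
    ax.set_ylabel("superior field (deg)")
    return ax


def save_ratio_map(onhc_map: OnhcMap, geometry: HexArray, path,
                   mode: str = "ratio") -> None:
    ax = render_ratio_map(onhc_map, geometry, mode=mode)
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
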