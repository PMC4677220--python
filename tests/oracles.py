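"""Independent brute-force oracles used by the unit and acceptance tests."""

import numpy as np

from onhcmap.quantify import smooth_trace


def oracle_second_peak(w, epoch=(60.0, 90.0), baseline_time=20.0,
                       smooth_window=9, smooth_polyorder=2,
                       min_prominence=0.5):
    """Brute-force re-statement of the ONHC amplitude rule.

    Enumerates strict local maxima of the smoothed epoch slice, computes
    each peak's topographic prominence by explicit left/right scans,
    filters by prominence and baseline, and applies the
    second-else-sole-else-zero rule.
    """
    vs = smooth_trace(w.v, smooth_window, smooth_polyorder)
    b = float(np.interp(baseline_time, w.t, vs))
    sel = np.flatnonzero((w.t >= epoch[0]) & (w.t <= epoch[1]))
    seg = vs[sel]
    peaks = []
    for i in range(1, len(seg) - 1):
        if not (seg[i] > seg[i - 1] and seg[i] > seg[i + 1]):
            continue
        left_min = seg[i]
        j = i - 1
        while j >= 0 and seg[j] <= seg[i]:
            left_min = min(left_min, seg[j])
            j -= 1
        right_min = seg[i]
        j = i + 1
        while j < len(seg) and seg[j] <= seg[i]:
            right_min = min(right_min, seg[j])
            j += 1
        prominence = seg[i] - max(left_min, right_min)
        if prominence >= min_prominence and seg[i] > b:
            peaks.append(seg[i])
    if len(peaks) >= 2:
        return max(peaks[1] - b, 0.0)
    if len(peaks) == 1:
        return max(peaks[0] - b, 0.0)
    return 0.0


def oracle_dice_percent(grid_a, grid_b):
    """Overlap percentage by direct pixel counting on the boolean grids."""
    na = int(grid_a.sum())
    nb = int(grid_b.sum())
    if na + nb == 0:
        return float("nan")
    inter = int((grid_a & grid_b).sum())
    return 100.0 * 2.0 * inter / (na + nb)


def random_structured_mask(rng, shape, extent=30.0):
    """A random union of axis-aligned rectangles and discs (possibly empty)."""
    n = shape[0]
    xs = np.linspace(-extent, extent, n)
    gx, gy = np.meshgrid(xs, xs[::-1])
    out = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(0, 4)):
        if rng.random() < 0.5:
            cx, cy = rng.uniform(-20, 20, 2)
            r = rng.uniform(2, 12)
            out |= (gx - cx) ** 2 + (gy - cy) ** 2 <= r ** 2
        else:
            x0, y0 = rng.uniform(-25, 15, 2)
            w, h = rng.uniform(3, 15, 2)
            out |= (gx >= x0) & (gx < x0 + w) & (gy >= y0) & (gy < y0 + h)
    return out
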