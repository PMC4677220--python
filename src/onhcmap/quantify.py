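"""ONHC amplitude extraction, ratio normalisation and deficiency staging.

The optic nerve head component (ONHC) is read from each hexagon's
induced-component (IC) waveform as the baseline-to-peak amplitude of the
*second positive deflection* inside the 60-90 ms response epoch, the
baseline being the signal level of the initial direct-component response
at 20 ms.  Per-eye amplitudes are normalised to ONHC ratios by the mean of
the seven largest amplitudes (drawn from rings 1-3, the relatively spared
central elements), and ratios below 0.5 are staged into four nested
deficiency masks (<0.5, <0.3, <0.2, <0.1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .geometry import HexArray, Laterality

#: deficiency stage boundaries on the ONHC ratio (strict less-than)
STAGE_THRESHOLDS = (0.5, 0.3, 0.2, 0.1)

#: default IC response epoch (ms) containing the ONHC deflection
DEFAULT_EPOCH = (60.0, 90.0)

#: default baseline time (ms): the initial DC response level
DEFAULT_BASELINE_TIME = 20.0

#: stimulation frame interval (ms)
FRAME_INTERVAL_MS = 13.33

#: human-readable stage labels, loosest to deepest
STAGE_LABELS = ("0.3-0.5", "0.2-0.3", "0.1-0.2", "<0.1")


@dataclass(frozen=True)
class Waveform:
    """One hexagon's induced-component trace (nV/deg² vs ms)."""

    hex_id: int
    t: np.ndarray
    v: np.ndarray
    sample_interval: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and v must be matching 1-D arrays")
        dt = np.diff(t)
        if len(dt) == 0 or np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.allclose(dt, self.sample_interval, rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1])


@dataclass(frozen=True)
class MfergRecording:
    """Per-eye set of 61 induced-component waveforms."""

    eye: Laterality
    waveforms: Mapping[int, Waveform]
    frame_interval: float = FRAME_INTERVAL_MS

    def __post_init__(self) -> None:
        ids = sorted(self.waveforms)
        if ids != list(range(1, 62)):
            missing = sorted(set(range(1, 62)) - set(ids))
            raise ValueError(f"recording must hold hexagons 1..61; missing {missing}")
        intervals = {round(w.sample_interval, 9) for w in self.waveforms.values()}
        if len(intervals) != 1:
            raise ValueError("all waveforms must share one sample interval")

    # -- CSV dialect: long format, header hex_id,t_ms,v_nv_per_deg2 --------

    def to_csv(self, path) -> None:
        frames = []
        for hex_id in range(1, 62):
            w = self.waveforms[hex_id]
            frames.append(pd.DataFrame(
                {"hex_id": hex_id, "t_ms": w.t, "v_nv_per_deg2": w.v}))
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, eye: Laterality = "right",
                 frame_interval: float = FRAME_INTERVAL_MS) -> "MfergRecording":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"hex_id", "t_ms", "v_nv_per_deg2"}
        if not required.issubset(df.columns):
            raise ValueError(f"waveform CSV needs columns {sorted(required)}")
        waveforms = {}
        for hex_id, grp in df.groupby("hex_id"):
            grp = grp.sort_values("t_ms")
            t = grp["t_ms"].to_numpy(dtype=float)
            if t.size < 2:
                raise ValueError(
                    f"hexagon {hex_id}: waveform needs at least 2 samples")
            dt = float(np.median(np.diff(t)))
            waveforms[int(hex_id)] = Waveform(
                hex_id=int(hex_id), t=t,
                v=grp["v_nv_per_deg2"].to_numpy(dtype=float),
                sample_interval=dt)
        return cls(eye=eye, waveforms=waveforms, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------

def smooth_trace(v: np.ndarray, window: int, polyorder: int = 2) -> np.ndarray:
    """Pre-smoothing for peak detection (window in samples, must be odd).

    A Savitzky-Golay filter: ``polyorder`` 2 preserves peak heights while
    suppressing single-sample noise spikes; ``polyorder`` 0 degenerates to
    a plain centred moving average.  ``window`` 1 disables smoothing.
    """
    v = np.asarray(v, dtype=float)
    if window <= 1:
        return v
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    return savgol_filter(v, window, min(polyorder, window - 1))


def _epoch_local_maxima(t: np.ndarray, v: np.ndarray,
                        epoch: tuple[float, float],
                        min_prominence: float) -> list[tuple[float, float]]:
    """Local maxima (time, value) inside the epoch, in time order.

    Peaks are strict local maxima of the epoch slice with topographic
    prominence of at least ``min_prominence`` (prominence evaluated within
    the epoch window); epoch-edge samples are not peaks.
    """
    sel = np.flatnonzero((t >= epoch[0]) & (t <= epoch[1]))
    seg = v[sel]
    idx, _ = find_peaks(seg, prominence=min_prominence if min_prominence > 0
                        else None)
    return [(float(t[sel[i]]), float(seg[i])) for i in idx]


def extract_onhc_amplitude(
    w: Waveform,
    epoch: tuple[float, float] = DEFAULT_EPOCH,
    baseline_time: float = DEFAULT_BASELINE_TIME,
    smooth_window: int = 9,
    smooth_polyorder: int = 2,
    min_prominence: float = 0.5,
    baseline_window: float = 0.0,
    return_time: bool = False,
):
    """Baseline-to-peak amplitude of the second positive IC deflection.

    The trace is optionally smoothed with a Savitzky-Golay filter
    (``smooth_window`` samples, order ``smooth_polyorder``; window 1
    disables smoothing).  The baseline is the
    (interpolated) smoothed signal at ``baseline_time``, optionally
    averaged over ±``baseline_window`` ms.  Within the epoch all local
    maxima with topographic prominence of at least ``min_prominence``
    nV/deg² (suppressing residual noise wiggles; 0 disables the criterion)
    and values exceeding the baseline are enumerated in time order; the
    amplitude is the second one minus baseline, falling back to the sole
    maximum when only one exists, and to 0 when none does.  The result is
    clamped at 0.

    With ``return_time`` the implicit time of the measured peak (ms,
    refined to sub-sample precision by a three-point parabola) is returned
    as well; it is ``nan`` when no peak was found.
    """
    if epoch[0] >= epoch[1]:
        raise ValueError("epoch start must precede epoch end")
    lo, hi = w.span
    if baseline_time < lo or epoch[1] > hi or epoch[0] < lo:
        raise ValueError(
            f"waveform span {w.span} does not cover baseline {baseline_time} "
            f"ms and epoch {epoch} ms")

    vs = smooth_trace(w.v, smooth_window, smooth_polyorder)

    if baseline_window > 0:
        bsel = (w.t >= baseline_time - baseline_window) & \
               (w.t <= baseline_time + baseline_window)
        baseline = float(np.mean(vs[bsel]))
    else:
        baseline = float(np.interp(baseline_time, w.t, vs))

    peaks = [(pt, pv)
             for pt, pv in _epoch_local_maxima(w.t, vs, epoch, min_prominence)
             if pv > baseline]
    if len(peaks) >= 2:
        pt, pv = peaks[1]
    elif len(peaks) == 1:
        pt, pv = peaks[0]
    else:
        pt, pv = float("nan"), baseline
    amplitude = max(pv - baseline, 0.0)
    if not return_time:
        return amplitude
    if np.isfinite(pt):
        pt = _refine_peak_time(w.t, vs, pt)
    return amplitude, pt


def _refine_peak_time(t: np.ndarray, v: np.ndarray, peak_time: float) -> float:
    """Sub-sample peak position from a parabola through the top 3 samples."""
    i = int(np.argmin(np.abs(t - peak_time)))
    if i == 0 or i == len(t) - 1:
        return float(t[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the sample time
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = float(t[i + 1] - t[i])
    return float(t[i] + np.clip(delta, -0.5, 0.5) * dt)


def quantify_recording(rec: MfergRecording, **kwargs) -> np.ndarray:
    """ONHC amplitudes (nV/deg²) for all 61 hexagons, indexed hex_id-1."""
    return np.array([
        extract_onhc_amplitude(rec.waveforms[hex_id], **kwargs)
        for hex_id in range(1, 62)
    ])


# ---------------------------------------------------------------------------
# normalisation and staging
# ---------------------------------------------------------------------------

def select_reference(
    amplitudes: np.ndarray,
    geometry: HexArray,
    max_ring: int = 3,
) -> tuple[tuple[int, ...], float]:
    """The seven largest amplitudes among elements of ring <= ``max_ring``.

    Returns the selected hex ids (ties broken toward the lower id) and
    their arithmetic mean, the per-eye normalisation reference.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (61,):
        raise ValueError("need 61 amplitudes")
    if max_ring not in (3, 5):
        raise ValueError("max_ring must be 3 (central reference) or 5 (whole array)")
    eligible = geometry.ids_in_rings(max_ring)
    if len(eligible) < 7:
        raise ValueError("fewer than 7 eligible elements")
    order = sorted(eligible, key=lambda hid: (-amplitudes[hid - 1], hid))
    ids = tuple(order[:7])
    return ids, float(np.mean([amplitudes[i - 1] for i in ids]))


def compute_ratios(amplitudes: np.ndarray, reference_mean: float) -> np.ndarray:
    """ONHC ratios R_i = A_i / reference mean (dimensionless, may exceed 1).

    Ratios are reported at nine decimal places, which makes them invariant
    to the recording's overall gain (rescaling amplitudes and reference
    together cannot move a ratio by more than a few ulp, far below the
    reporting resolution).
    """
    if not reference_mean > 0:
        raise ValueError(
            f"reference mean {reference_mean} must be positive; "
            "the recording is unusable")
    return np.round(np.asarray(amplitudes, dtype=float) / reference_mean, 9)


def stage_deficiency(
    ratios: np.ndarray,
    thresholds: Sequence[float] = STAGE_THRESHOLDS,
) -> dict[float, np.ndarray]:
    """Cumulative deficiency masks {threshold: ratio < threshold}.

    Boundaries are strict, so the masks are nested by construction
    (R<0.1 ⊆ R<0.2 ⊆ R<0.3 ⊆ R<0.5).
    """
    ratios = np.asarray(ratios, dtype=float)
    return {thr: ratios < thr for thr in thresholds}


@dataclass(frozen=True)
class OnhcMap:
    """Per-eye ONHC amplitudes, ratios and staged deficiency masks."""

    amplitude: np.ndarray
    reference_ids: tuple[int, ...]
    reference_mean: float
    ratio: np.ndarray
    stage_masks: dict[float, np.ndarray]

    @classmethod
    def from_recording(cls, rec: MfergRecording, geometry: HexArray,
                       max_ring: int = 3, **extract_kwargs) -> "OnhcMap":
        amplitudes = quantify_recording(rec, **extract_kwargs)
        return cls.from_amplitudes(amplitudes, geometry, max_ring=max_ring)

    @classmethod
    def from_amplitudes(cls, amplitudes: np.ndarray, geometry: HexArray,
                        max_ring: int = 3) -> "OnhcMap":
        ids, ref_mean = select_reference(amplitudes, geometry, max_ring=max_ring)
        ratios = compute_ratios(amplitudes, ref_mean)
        return cls(amplitude=np.asarray(amplitudes, dtype=float),
                   reference_ids=ids, reference_mean=ref_mean, ratio=ratios,
                   stage_masks=stage_deficiency(ratios))

    def stage_label(self, hex_id: int) -> str:
        r = self.ratio[hex_id - 1]
        if r >= 0.5:
            return "none"
        for thr, lab in zip((0.1, 0.2, 0.3, 0.5),
                            ("<0.1", "0.1-0.2", "0.2-0.3", "0.3-0.5")):
            if r < thr:
                return lab
        return "none"  # pragma: no cover

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "hex_id": np.arange(1, 62),
            "amplitude": self.amplitude,
            "ratio": self.ratio,
            "stage": [self.stage_label(i) for i in range(1, 62)],
        }).to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "reference_ids": list(self.reference_ids),
            "reference_mean": self.reference_mean,
            "amplitude": self.amplitude.tolist(),
            "ratio": self.ratio.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# normative cut-offs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormativeCutoffs:
    """Lower-tail control-cohort cut-offs at the four probability levels."""

    levels: tuple[float, ...]
    cutoffs: tuple[float, ...]
    n: int
    quantile_method: str = "linear"

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.levels, self.cutoffs))


def normative_cutoffs(
    control_values: Sequence[float],
    levels: Sequence[float] = (5.0, 2.0, 1.0, 0.5),
) -> NormativeCutoffs:
    """Empirical lower-tail quantiles of a control distribution.

    ``levels`` are percentages (5 means the lower 5% tail).  Quantiles use
    the linear interpolation of order statistics (Hyndman-Fan type 7, the
    numpy default), recorded in the result's metadata.  Cut-offs are
    non-increasing as the level tightens.
    """
    values = np.asarray(control_values, dtype=float)
    if values.size < 20:
        raise ValueError(f"need at least 20 control values, got {values.size}")
    levels = tuple(float(l) for l in levels)
    if any(l <= 0 or l >= 100 for l in levels):
        raise ValueError("levels must be in (0, 100) percent")
    cuts = tuple(float(np.quantile(values, l / 100.0, method="linear"))
                 for l in levels)
    return NormativeCutoffs(levels=levels, cutoffs=cuts, n=values.size)
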