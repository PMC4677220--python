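"""Synthetic control and glaucomatous eyes with known ground truth.

A single scalar *integrity* field over the visual field (1 = fully
functional retinal ganglion cells, 0 = complete loss) drives both
modalities of a simulated eye:

* the mfERG induced-component waveform of each hexagon carries a direct
  component, a first positive IC deflection and an ONHC deflection whose
  height scales with local integrity and whose implicit time grows with
  the nerve-fibre path distance from the optic disc (the nasotemporal
  asymmetry), plus additive Gaussian recording noise;
* total deviation at each 30-2 point falls linearly with integrity loss,
  plus perimetric test-retest noise.

Because both maps derive from the same damage field, a correctly working
pipeline recovers colocalized, stage-matched deficiency and defect maps.
The integrity→amplitude mapping is a power law calibrated jointly with
the synthetic perimetric norm table so that the four ONHC ratio stage
boundaries and the four TD stage boundaries grade the same integrity
levels — the analogue of the clinical situation in which ratio staging
and TD probability staging grade the same underlying loss.

Damage fields are expressed in right-eye visual-field coordinates; a
superior-field defect is inferior retinal damage (the field↔retina
vertical inversion is implicit in this convention).  Arcuate defects stay
within one hemifield and therefore never bleed across the horizontal
raphe temporal to the disc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .geometry import (
    DiscLocation,
    HexArray,
    HexElement,
    PerimetryGrid,
    build_30_2_grid,
    build_hex_array,
    fiber_path_distance,
)
from .model import AMPLITUDE_EXPONENT, DEFAULT_RING_AMPLITUDE, TD_SLOPE_DB
from .perimetry import TdPlot
from .quantify import FRAME_INTERVAL_MS, MfergRecording, Waveform

DefectType = Literal["none", "arcuate", "nasal-step", "paracentral"]
Hemifield = Literal["superior", "inferior"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults are the package's study conditions."""

    # cohort
    n_control: int = 30
    n_glaucoma: int = 39
    defect_type: DefectType = "arcuate"
    defect_depth: float = 0.8
    defect_hemifield: Hemifield | Literal["random"] = "random"

    # healthy ONHC amplitude profile per ring (nV/deg²)
    ring_amplitude: tuple[float, ...] = DEFAULT_RING_AMPLITUDE
    #: integrity → amplitude power-law exponent (stage-boundary calibration)
    amplitude_exponent: float = AMPLITUDE_EXPONENT
    #: between-subject lognormal gain sigma
    subject_gain_sigma: float = 0.2

    # waveform shape (Gaussian deflections; latencies ms, heights nV/deg²)
    resting_offset: float = 1.0
    dc_latency: float = 30.0
    dc_sigma: float = 2.5
    dc_height: float = 20.0
    ic1_latency: float = 61.5
    ic1_sigma: float = 2.5
    ic1_height: float = 10.0
    onhc_sigma: float = 3.2

    # conduction model: implicit time = intercept + distance / velocity
    latency_intercept: float = 70.0
    velocity_m_s: float = 1.0
    mm_per_deg: float = 0.30
    path_model: Literal["euclidean", "bundle"] = "euclidean"

    # sampling
    sample_interval: float = FRAME_INTERVAL_MS / 16.0  # ≈0.833 ms (1200 Hz)
    n_samples: int = 128

    # noise
    noise_sd: float = 0.5       # waveform, nV/deg²
    td_noise_sd: float = 1.0    # perimetry test-retest, dB

    # integrity → TD mapping
    td_slope: float = TD_SLOPE_DB   # dB lost for a full-depth defect
    td_floor: float = -30.0

    # central sparing (preserved central 5-10°)
    central_sparing: bool = True
    sparing_radius: float = 8.0
    sparing_floor: float = 0.9

    # defect geometry jitter across eyes
    geometry_jitter: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.td_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.velocity_m_s <= 0:
            raise ValueError("conduction velocity must be positive")
        if any(a <= 0 for a in self.ring_amplitude):
            raise ValueError("ring amplitude profile must be positive")
        if not (0.0 <= self.defect_depth <= 1.0):
            raise ValueError("defect depth must lie in [0, 1]")


# ---------------------------------------------------------------------------
# damage fields
# ---------------------------------------------------------------------------

def _taper(u: np.ndarray, core: float, edge: float) -> np.ndarray:
    """1 inside |u|<=core, linear roll-off to 0 at |u|>=edge."""
    au = np.abs(u)
    w = np.clip((edge - au) / (edge - core), 0.0, 1.0)
    return np.where(au <= core, 1.0, w)


@dataclass(frozen=True)
class DamageField:
    """Integrity over the 30° field in [0, 1], with its defect descriptor."""

    defect_type: DefectType
    hemifield: Hemifield | None
    depth: float
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    core_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def integrity(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return np.clip(self.fn(x, y), 0.0, 1.0)

    def core_mask(self, x, y) -> np.ndarray:
        """True inside the full-depth core of the defect (empty for controls)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.core_fn is None:
            return np.zeros(np.broadcast(x, y).shape, dtype=bool)
        return self.core_fn(x, y)

    def grid(self, resolution: float = 0.5, extent: float = 30.0):
        n = int(round(2 * extent / resolution)) + 1
        xs = np.linspace(-extent, extent, n)
        ys = np.linspace(extent, -extent, n)
        gx, gy = np.meshgrid(xs, ys)
        return self.integrity(gx, gy)


def make_damage_field(
    params: SimParams,
    rng: np.random.Generator,
    defect_type: DefectType | None = None,
    hemifield: Hemifield | None = None,
    depth: float | None = None,
    disc: DiscLocation | None = None,
) -> DamageField:
    """Build a glaucomatous damage field (or a pristine control field).

    Deterministic given the generator state; with ``geometry_jitter`` the
    defect's band radius and angular extent vary mildly across eyes.
    """
    defect_type = params.defect_type if defect_type is None else defect_type
    depth = params.defect_depth if depth is None else depth
    disc = disc or DiscLocation()
    if defect_type == "none":
        return DamageField("none", None, 0.0, lambda x, y: np.ones_like(x))
    if hemifield is None:
        hf = params.defect_hemifield
        hemifield = (rng.choice(["superior", "inferior"]) if hf == "random" else hf)
    if hemifield not in ("superior", "inferior"):
        raise ValueError(f"invalid hemifield {hemifield!r}")
    sign = 1.0 if hemifield == "superior" else -1.0

    jitter = (lambda s: float(rng.normal(0.0, s))) if params.geometry_jitter \
        else (lambda s: 0.0)

    if defect_type == "arcuate":
        # Bjerrum-region band arcing over the blind spot: a full-depth core
        # with broad linear shoulders, so each deficiency stage occupies a
        # sizeable, geometrically shrinking portion of the hemifield
        band_r = 16.0 + jitter(1.5)
        half_w = 14.0 + jitter(1.0)
        th0 = math.radians(10.0 + jitter(5.0))
        th1 = math.radians(170.0 + jitter(5.0))
        ang_taper = math.radians(70.0)
        r_core = 0.45 * half_w

        def w_fn(x, y):
            rho = np.hypot(x, y)
            theta = np.arctan2(sign * y, x)  # fold into the defect hemifield
            wr = _taper(rho - band_r, r_core, half_w)
            mid, half_ang = (th0 + th1) / 2.0, (th1 - th0) / 2.0
            wa = _taper(theta - mid, half_ang - ang_taper, half_ang)
            w = wr * wa
            return np.where(sign * y > 0, w, 0.0)  # hard hemifield clip

        def core_fn(x, y):
            rho = np.hypot(x, y)
            theta = np.arctan2(sign * y, x)
            mid, half_ang = (th0 + th1) / 2.0, (th1 - th0) / 2.0
            return ((np.abs(rho - band_r) <= r_core)
                    & (np.abs(theta - mid) <= half_ang - ang_taper)
                    & (sign * y > 0))

    elif defect_type == "nasal-step":
        x_edge = -9.0 + jitter(1.0)
        y_out = 11.0 + jitter(1.0)

        def w_fn(x, y):
            wx = np.where(x <= x_edge, 1.0, _taper(x - x_edge, 0.0, 3.0))
            wy = np.where((sign * y > 0) & (sign * y <= y_out), 1.0,
                          np.where(sign * y > 0,
                                   _taper(sign * y - y_out, 0.0, 3.0), 0.0))
            return wx * wy

        def core_fn(x, y):
            return (x <= x_edge) & (sign * y > 0) & (sign * y <= y_out)

    elif defect_type == "paracentral":
        cx, cy = -6.0 + jitter(0.8), sign * (6.0 + abs(jitter(0.8)))
        radius = 4.0 + jitter(0.4)

        def w_fn(x, y):
            d = np.hypot(x - cx, y - cy)
            w = _taper(d, 0.6 * radius, radius)
            return np.where(sign * y > 0, w, 0.0)

        def core_fn(x, y):
            return (np.hypot(x - cx, y - cy) <= 0.6 * radius) & (sign * y > 0)

    else:
        raise ValueError(f"invalid defect descriptor {defect_type!r}")

    sparing = params.central_sparing
    s_rad, s_floor = params.sparing_radius, params.sparing_floor

    def integrity_fn(x, y):
        integ = 1.0 - depth * w_fn(x, y)
        if sparing:
            central = np.hypot(x, y) < s_rad
            integ = np.where(central, np.maximum(integ, s_floor), integ)
        return integ

    def core_masked(x, y):
        core = core_fn(x, y)
        if sparing:
            core = core & (np.hypot(x, y) >= s_rad)
        return core

    return DamageField(defect_type, hemifield, depth, integrity_fn, core_masked)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def onhc_latency(hex_center: tuple[float, float], disc: DiscLocation,
                 params: SimParams) -> float:
    """Implicit time (ms) of the ONHC deflection for a stimulus location."""
    d_mm = fiber_path_distance(hex_center, disc, model=params.path_model,
                               mm_per_deg=params.mm_per_deg)
    return params.latency_intercept + d_mm / params.velocity_m_s  # 1 m/s = 1 mm/ms


def simulate_waveform(
    hex_element: HexElement,
    integrity_local: float,
    disc: DiscLocation,
    params: SimParams,
    rng: np.random.Generator | None = None,
    subject_gain: float = 1.0,
) -> tuple[Waveform, float, float]:
    """One hexagon's IC waveform with a planted ONHC deflection.

    Returns (waveform, planted ONHC height, planted implicit time).  The
    direct component is unaffected by ganglion-cell loss; both IC
    deflections scale with local integrity (the induced component is
    inner-retina generated), the ONHC with the calibrated power law, so
    that under default geometry the ONHC is always the second positive
    peak of the epoch.
    """
    if not 0.0 <= integrity_local <= 1.0:
        raise ValueError("integrity must lie in [0, 1]")
    t = np.arange(params.n_samples) * params.sample_interval
    latency = onhc_latency(hex_element.center, disc, params)
    if not (61.0 <= latency <= 89.0):
        warnings.warn(
            f"ONHC latency {latency:.1f} ms for hexagon {hex_element.id} "
            "falls outside the 60-90 ms analysis epoch under these parameters")
    height = (params.ring_amplitude[hex_element.ring - 1]
              * integrity_local ** params.amplitude_exponent * subject_gain)
    ic1 = (params.ic1_height * integrity_local ** params.amplitude_exponent
           * subject_gain)
    v = (params.resting_offset
         + params.dc_height * _gauss(t, params.dc_latency, params.dc_sigma)
         + ic1 * _gauss(t, params.ic1_latency, params.ic1_sigma)
         + height * _gauss(t, latency, params.onhc_sigma))
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
    return (Waveform(hex_id=hex_element.id, t=t, v=v,
                     sample_interval=params.sample_interval),
            float(height), float(latency))


def hexagon_integrity(element: HexElement, damage: DamageField) -> float:
    """Representative integrity of a hexagon's retinal patch.

    Sampled at the element centre and a small surrounding shell (quarter
    of the way to each vertex): the local axon bundle serving the element,
    rather than an average over the full stimulus area, which would blur
    defect borders well beyond what the perimetric point samples resolve.
    """
    cx, cy = element.center
    pts = [(cx, cy)] + [(cx + 0.25 * (vx - cx), cy + 0.25 * (vy - cy))
                        for vx, vy in element.vertices]
    arr = np.array(pts)
    return float(np.mean(damage.integrity(arr[:, 0], arr[:, 1])))


# ---------------------------------------------------------------------------
# whole eyes and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    damage: DamageField
    hex_integrity: np.ndarray          # (61,)
    planted_amplitude: np.ndarray      # (61,) nV/deg²
    planted_latency: np.ndarray        # (61,) ms
    td_true: np.ndarray                # (76,) dB, noise-free
    subject_gain: float


@dataclass(frozen=True)
class SimulatedEye:
    label: Literal["control", "glaucoma"]
    recording: MfergRecording
    td_plot: TdPlot
    truth: GroundTruth


def simulate_eye(
    params: SimParams,
    rng: np.random.Generator,
    label: Literal["control", "glaucoma"] = "glaucoma",
    geometry: HexArray | None = None,
    grid: PerimetryGrid | None = None,
    disc: DiscLocation | None = None,
    damage: DamageField | None = None,
) -> SimulatedEye:
    """Simulate one eye end to end (recording + TD plot + ground truth)."""
    geometry = geometry or build_hex_array("right")
    grid = grid or build_30_2_grid("right")
    disc = disc or DiscLocation()
    gain = float(np.exp(rng.normal(0.0, params.subject_gain_sigma))) \
        if params.subject_gain_sigma > 0 else 1.0
    if damage is None:
        damage = make_damage_field(
            params, rng, defect_type="none" if label == "control" else None,
            disc=disc)

    waveforms, heights, latencies, integ = {}, [], [], []
    for element in geometry.elements:
        ih = hexagon_integrity(element, damage)
        w, h, lat = simulate_waveform(element, ih, disc, params, rng, gain)
        waveforms[element.id] = w
        heights.append(h)
        latencies.append(lat)
        integ.append(ih)
    recording = MfergRecording(eye=geometry.eye, waveforms=waveforms)

    pt_int = damage.integrity(grid.points[:, 0], grid.points[:, 1])
    td_true = np.maximum(-params.td_slope * (1.0 - pt_int), params.td_floor)
    td = td_true + (rng.normal(0.0, params.td_noise_sd, size=76)
                    if params.td_noise_sd > 0 else 0.0)
    td_plot = TdPlot.from_td(td, grid)

    truth = GroundTruth(
        damage=damage,
        hex_integrity=np.array(integ),
        planted_amplitude=np.array(heights),
        planted_latency=np.array(latencies),
        td_true=td_true,
        subject_gain=gain,
    )
    return SimulatedEye(label=label, recording=recording, td_plot=td_plot,
                        truth=truth)


def simulate_cohort(
    params: SimParams,
    seed: int | np.random.SeedSequence = 0,
    geometry: HexArray | None = None,
    grid: PerimetryGrid | None = None,
) -> list[SimulatedEye]:
    """Independent control and glaucomatous eyes, reproducible from one seed.

    Per-eye generators are spawned from the master seed, so the cohort is
    identical across runs and insensitive to per-eye consumption order.
    """
    if params.n_glaucoma < 0 or params.n_control < 0 or \
            params.n_glaucoma + params.n_control < 1:
        raise ValueError("cohort needs at least one eye")
    if params.n_control == 0:
        warnings.warn("cohort has no control eyes")
    geometry = geometry or build_hex_array("right")
    grid = grid or build_30_2_grid("right")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(params.n_control + params.n_glaucoma)
    eyes = []
    for i, child in enumerate(children):
        label = "control" if i < params.n_control else "glaucoma"
        rng = np.random.default_rng(child)
        eyes.append(simulate_eye(params, rng, label=label,
                                 geometry=geometry, grid=grid))
    return eyes
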