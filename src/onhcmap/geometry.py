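"""Stimulus and test geometry in visual-field coordinates.

Everything lives in a single right-eye visual-field frame: x positive
temporal, y positive superior, units are degrees of visual angle.  Left-eye
data are mirrored (x -> -x) into this frame before any comparison, so maps
from the two eyes can be pooled and overlaid.

Two geometries are defined here:

* the 61-element hexagonal mfERG stimulus array (rings of 1, 6, 12, 18 and
  24 elements, element size scaled with eccentricity so that all locations
  produce responses of comparable amplitude, outermost vertices at ~30°);
* the 76-point Humphrey 30-2 perimetry grid (6° lattice offset 3° from both
  meridians).

The scaled hexagon array is constructed by building a uniform hexagonal
tessellation and pushing its shared vertex set through a strictly monotone
piecewise-linear radial map.  Because adjacent elements keep sharing the
very same mapped vertices, the scaled array still tiles the field exactly
(no gaps, no overlaps), while element size grows with eccentricity
according to the per-ring scaling profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

Laterality = Literal["right", "left"]

#: ring sizes of the 61-element array, centre outwards
RING_SIZES = (1, 6, 12, 18, 24)

#: default per-ring linear scale factors (relative element size per ring)
DEFAULT_SCALING_PROFILE = (1.0, 1.25, 1.55, 1.90, 2.30)

#: radius (deg) of the outermost stimulus vertices
DEFAULT_MAX_RADIUS = 30.0

#: default optic-disc / blind-spot centre in right-eye field coordinates
DEFAULT_DISC_CENTER = (15.5, -1.5)

#: default retinal conversion factor, millimetres per degree of visual angle
DEFAULT_MM_PER_DEG = 0.30


def _validate_eye(eye: str) -> Laterality:
    if eye not in ("right", "left"):
        raise ValueError(f"laterality must be 'right' or 'left', got {eye!r}")
    return eye  # type: ignore[return-value]


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed-magnitude polygon area (deg²) by the shoelace formula."""
    x = np.asarray(vertices, dtype=float)[:, 0]
    y = np.asarray(vertices, dtype=float)[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass(frozen=True)
class HexElement:
    """One hexagonal stimulus element.

    ``vertices`` are ordered counter-clockwise; the polygon is convex and
    contains ``center``.
    """

    id: int
    ring: int
    center: tuple[float, float]
    vertices: tuple[tuple[float, float], ...]

    @property
    def area(self) -> float:
        return shoelace_area(np.asarray(self.vertices))

    @property
    def eccentricity(self) -> float:
        return math.hypot(*self.center)


@dataclass(frozen=True)
class HexArray:
    """The 61-element scaled hexagonal stimulus array for one eye."""

    eye: Laterality
    elements: tuple[HexElement, ...]
    max_radius: float
    scaling_profile: tuple[float, ...] = DEFAULT_SCALING_PROFILE

    def __post_init__(self) -> None:
        if len(self.elements) != 61:
            raise ValueError(f"HexArray needs 61 elements, got {len(self.elements)}")

    def element(self, hex_id: int) -> HexElement:
        return self.elements[hex_id - 1]

    @property
    def centers(self) -> np.ndarray:
        """(61, 2) array of element centres, indexed by hex_id - 1."""
        return np.array([e.center for e in self.elements])

    @property
    def rings(self) -> np.ndarray:
        """(61,) array of ring numbers (1..5), indexed by hex_id - 1."""
        return np.array([e.ring for e in self.elements])

    def ids_in_rings(self, max_ring: int) -> list[int]:
        return [e.id for e in self.elements if e.ring <= max_ring]

    @property
    def total_area(self) -> float:
        return float(sum(e.area for e in self.elements))

    def mirrored(self) -> "HexArray":
        """The same array for the fellow eye (x -> -x)."""
        eye: Laterality = "left" if self.eye == "right" else "right"
        elements = tuple(
            HexElement(
                id=e.id,
                ring=e.ring,
                center=(-e.center[0], e.center[1]),
                vertices=tuple((-vx, vy) for vx, vy in e.vertices),
            )
            for e in self.elements
        )
        return HexArray(eye=eye, elements=elements, max_radius=self.max_radius,
                        scaling_profile=self.scaling_profile)

    # -- serialisation -----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "eye": self.eye,
            "max_radius": round(self.max_radius, 2),
            "scaling_profile": list(self.scaling_profile),
            "elements": [
                {
                    "id": e.id,
                    "ring": e.ring,
                    "center": [round(c, 2) for c in e.center],
                    "vertices": [[round(v, 2) for v in vv] for vv in e.vertices],
                }
                for e in self.elements
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "HexArray":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        elements = tuple(
            HexElement(
                id=e["id"],
                ring=e["ring"],
                center=tuple(e["center"]),
                vertices=tuple(tuple(v) for v in e["vertices"]),
            )
            for e in payload["elements"]
        )
        return cls(eye=_validate_eye(payload["eye"]), elements=elements,
                   max_radius=float(payload["max_radius"]),
                   scaling_profile=tuple(payload["scaling_profile"]))


# ---------------------------------------------------------------------------
# hex array construction
# ---------------------------------------------------------------------------

_SQRT3 = math.sqrt(3.0)


def _axial_to_xy(q: int, r: int) -> tuple[float, float]:
    # flat-top axial coordinates with unit centre-to-centre spacing
    R = 1.0 / _SQRT3  # circumradius giving neighbour distance 1
    x = 1.5 * R * q
    y = _SQRT3 * R * (r + q / 2.0)
    return x, y


def _hex_ring_coords(ring: int) -> list[tuple[int, int]]:
    """Axial coordinates of the hexagonal ring at distance ``ring``."""
    coords = []
    for q in range(-ring, ring + 1):
        for r in range(-ring, ring + 1):
            if abs(q) + abs(r) + abs(q + r) == 2 * ring:
                coords.append((q, r))
    return coords


def _radial_map(radii: np.ndarray, profile: Sequence[float]) -> np.ndarray:
    """Monotone piecewise-linear radial stretch implementing the scaling profile.

    Segment k of the uniform-radius axis (one hex spacing per ring) is
    stretched by profile[k], so elements of ring k come out profile[k] times
    larger than a ring-1 element, while the map stays a bijection of the
    plane (hence the tessellation survives exactly).
    """
    prof = np.asarray(profile, dtype=float)
    knots = np.arange(len(prof) + 1, dtype=float)
    values = np.concatenate([[0.0], np.cumsum(prof)])
    # extend with the last slope beyond the final knot
    out = np.interp(radii, knots, values)
    beyond = radii > knots[-1]
    if np.any(beyond):
        out[beyond] = values[-1] + (radii[beyond] - knots[-1]) * prof[-1]
    return out


def build_hex_array(
    eye: Laterality = "right",
    scaling_profile: Sequence[float] = DEFAULT_SCALING_PROFILE,
    max_radius: float = DEFAULT_MAX_RADIUS,
) -> HexArray:
    """Construct the 61-element eccentricity-scaled stimulus array.

    Parameters
    ----------
    eye:
        ``"right"`` or ``"left"``; the left-eye array is the mirror image
        (x -> -x) of the right-eye array.
    scaling_profile:
        Five positive, non-decreasing per-ring linear scale factors.
    max_radius:
        Eccentricity (deg) of the outermost stimulus vertices; the mapped
        array is scaled uniformly so its farthest vertex lands here.
    """
    _validate_eye(eye)
    prof = tuple(float(s) for s in scaling_profile)
    if len(prof) != 5:
        raise ValueError("scaling_profile needs 5 per-ring entries")
    if any(s <= 0 for s in prof):
        raise ValueError("scaling_profile entries must be positive")
    if any(b < a for a, b in zip(prof, prof[1:])):
        raise ValueError("scaling_profile must be non-decreasing")

    # uniform array: ring-by-ring, within a ring ordered by polar angle
    R = 1.0 / _SQRT3
    vertex_angles = [math.radians(60 * k) for k in range(6)]

    axials: list[tuple[int, int, int]] = []  # (ring, q, r)
    for ring in range(5):
        coords = _hex_ring_coords(ring)
        coords.sort(key=lambda qr: math.atan2(*reversed(_axial_to_xy(*qr))) % (2 * math.pi))
        axials.extend((ring, q, r) for q, r in coords)

    # canonical shared-vertex table: identical float coordinates for vertices
    # shared by adjacent elements, so the radial map cannot open seams
    def _canon(p: tuple[float, float]) -> tuple[float, float]:
        return (round(p[0], 9), round(p[1], 9))

    raw_vertices: list[list[tuple[float, float]]] = []
    centers: list[tuple[float, float]] = []
    for _, q, r in axials:
        cx, cy = _axial_to_xy(q, r)
        centers.append((cx, cy))
        raw_vertices.append(
            [_canon((cx + R * math.cos(a), cy + R * math.sin(a))) for a in vertex_angles]
        )

    all_pts = np.array([p for hexv in raw_vertices for p in hexv] + centers)
    radii = np.hypot(all_pts[:, 0], all_pts[:, 1])
    mapped_r = _radial_map(radii, prof)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(radii > 0, mapped_r / np.where(radii > 0, radii, 1.0), 1.0)
    mapped = all_pts * scale[:, None]
    mapped *= max_radius / np.hypot(mapped[:, 0], mapped[:, 1]).max()

    elements = []
    n_vertex_pts = 6
    for i, (ring, _, _) in enumerate(axials):
        vv = mapped[i * n_vertex_pts:(i + 1) * n_vertex_pts]
        center = mapped[len(axials) * n_vertex_pts + i]
        elements.append(
            HexElement(
                id=i + 1,
                ring=ring + 1,
                center=(float(center[0]), float(center[1])),
                vertices=tuple((float(x), float(y)) for x, y in vv),
            )
        )
    array = HexArray(eye="right", elements=tuple(elements), max_radius=max_radius,
                     scaling_profile=prof)
    return array if eye == "right" else array.mirrored()


# ---------------------------------------------------------------------------
# 30-2 perimetry grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerimetryGrid:
    """The 76-point Humphrey 30-2 test pattern for one eye.

    Points sit on the 6° lattice offset 3° from both meridians, numbered
    row-major from the superior row, left to right.  ``blind_spot_ids``
    are the two points straddling the physiologic blind spot (temporal
    hemifield, ~15° eccentricity).
    """

    eye: Laterality
    points: np.ndarray  # (76, 2)
    blind_spot_ids: tuple[int, int]

    def __post_init__(self) -> None:
        if self.points.shape != (76, 2):
            raise ValueError("30-2 grid needs exactly 76 points")

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, 77)

    def mirrored(self) -> "PerimetryGrid":
        eye: Laterality = "left" if self.eye == "right" else "right"
        pts = self.points.copy()
        pts[:, 0] *= -1
        return PerimetryGrid(eye=eye, points=pts, blind_spot_ids=self.blind_spot_ids)


# x offsets (deg) per half-row, top row first; mirrored for inferior rows
_ROW_SPEC = {27: 9, 21: 15, 15: 21, 9: 27, 3: 27}


def build_30_2_grid(eye: Laterality = "right") -> PerimetryGrid:
    """Construct the 30-2 grid in the requested eye's field coordinates."""
    _validate_eye(eye)
    pts: list[tuple[float, float]] = []
    for y in (27, 21, 15, 9, 3, -3, -9, -15, -21, -27):
        xmax = _ROW_SPEC[abs(y)]
        for x in range(-xmax, xmax + 1, 6):
            pts.append((float(x), float(y)))
    points = np.array(pts)
    # blind-spot-adjacent points: temporal (x > 0) at (15, +/-3) for right eye
    bs = tuple(
        int(i + 1)
        for i, (x, y) in enumerate(points)
        if x == 15.0 and abs(y) == 3.0
    )
    grid = PerimetryGrid(eye="right", points=points, blind_spot_ids=(bs[0], bs[1]))
    return grid if eye == "right" else grid.mirrored()


# ---------------------------------------------------------------------------
# optic disc and nerve-fibre path distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscLocation:
    """Optic disc (blind spot) centre in right-eye field coordinates.

    ``raphe_y`` is the height of the horizontal raphe: the temporal seam,
    modelled as the ray y = raphe_y, x >= center.x, that nerve-fibre
    bundles do not cross.
    """

    center: tuple[float, float] = DEFAULT_DISC_CENTER
    raphe_y: float = 0.0

    def __post_init__(self) -> None:
        ecc = math.hypot(*self.center)
        if not (13.0 <= ecc <= 17.0):
            raise ValueError(
                f"disc eccentricity {ecc:.1f}° outside the anatomic 15±2° range"
            )


def _crosses_raphe(p: tuple[float, float], d: tuple[float, float],
                   disc: DiscLocation) -> bool:
    y0 = disc.raphe_y
    a, b = p[1] - y0, d[1] - y0
    if not (a > 0 > b or a < 0 < b):  # strictly opposite sides of the line
        return False
    t = a / (a - b)
    x_cross = p[0] + t * (d[0] - p[0])
    return x_cross > disc.center[0]


def fiber_path_distance(
    point: tuple[float, float],
    disc: DiscLocation | None = None,
    model: Literal["euclidean", "bundle"] = "euclidean",
    mm_per_deg: float = DEFAULT_MM_PER_DEG,
) -> float:
    """Retinal path length (mm) from a field location to the optic disc.

    The ``euclidean`` model is the straight-line retinal distance using the
    fixed deg->mm conversion.  The ``bundle`` model is the shortest path
    that does not cross the horizontal raphe temporal to the disc: if the
    straight segment would cross that seam, the path detours around the
    raphe origin at (disc_x, raphe_y), so it is always >= the euclidean
    distance.
    """
    disc = disc or DiscLocation()
    if math.hypot(*point) > 35.0:
        raise ValueError(f"point {point} outside the modelled 35° field")
    d = disc.center
    straight = math.hypot(point[0] - d[0], point[1] - d[1])
    if model == "euclidean":
        return straight * mm_per_deg
    if model != "bundle":
        raise ValueError(f"unknown fibre-path model {model!r}")
    if _crosses_raphe(point, d, disc):
        o = (disc.center[0], disc.raphe_y)
        deg = math.hypot(point[0] - o[0], point[1] - o[1]) + math.hypot(
            o[0] - d[0], o[1] - d[1]
        )
    else:
        deg = straight
    return deg * mm_per_deg
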