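"""Shared structure-function model constants.

The analyser's synthetic perimetric norm table and the simulator's signal
model are two views of one underlying model of glaucomatous loss, so the
constants that couple them live here:

* the healthy per-ring ONHC amplitude profile (nV/deg², amplitude
  density declining with eccentricity as in control recordings);
* the power law linking local retinal-ganglion-cell integrity to ONHC
  amplitude;
* the linear dB-per-integrity slope of total-deviation loss;
* the healthy ONHC ratio as a function of eccentricity implied by the
  profile (a step function over the radial footprints of the five
  stimulus rings).
"""

from __future__ import annotations

import numpy as np

#: healthy ONHC amplitude profile per stimulus ring, nV/deg²
DEFAULT_RING_AMPLITUDE: tuple[float, ...] = (17.0, 12.0, 11.0, 8.0, 8.0)

#: ONHC amplitude ∝ integrity ** AMPLITUDE_EXPONENT
AMPLITUDE_EXPONENT: float = 2.0

#: dB of total deviation lost per unit of integrity loss
TD_SLOPE_DB: float = 20.0

#: eccentricity cuts (deg) between the radial footprints of rings 1..5
#: (midpoints of the vertex-span overlaps of adjacent rings)
RING_ECC_CUTS: tuple[float, ...] = (2.5, 6.2, 11.9)


def healthy_reference_mean() -> float:
    """Mean of the seven largest healthy amplitudes (ring 1 + six of ring 2)."""
    p = DEFAULT_RING_AMPLITUDE
    return (p[0] + 6.0 * p[1]) / 7.0


def healthy_onhc_ratio(eccentricity) -> np.ndarray:
    """Expected ONHC ratio of a healthy eye at the given eccentricity (deg).

    Piecewise constant over the radial footprint of each stimulus ring;
    rings 4 and 5 share the plateau value, so a single outer step suffices.
    """
    e = np.asarray(eccentricity, dtype=float)
    ref = healthy_reference_mean()
    p = DEFAULT_RING_AMPLITUDE
    c1, c2, c3 = RING_ECC_CUTS
    return np.where(e < c1, p[0] / ref,
                    np.where(e < c2, p[1] / ref,
                             np.where(e < c3, p[2] / ref, p[3] / ref)))
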