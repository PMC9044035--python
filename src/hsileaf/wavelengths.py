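"""Canonical 147-entry VNIR wavelength table.

The snapshot VNIR sensor this package targets covers 468–898 nm in 147
spectrally subset bands on a slightly non-uniform grid.  The exact grid
lives in the camera's calibration file; here it is reconstructed by
monotone (PCHIP) interpolation through the band/wavelength pairs that are
publicly documented for the sensor's recommended band sets (true-colour
and false-colour presets, uniform selections, and neighborhood-grouping
selections).  Real data should always prefer the wavelength table in its
own header; this module exists so that synthetic cubes and index-based
band selections report physically sensible wavelengths.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

# (1-based band index, center wavelength in nm) anchor pairs.
# The documented pair (32, 557.84) is dropped: it would sit below the
# wavelength of band 30 (569.27 nm) and the grid must be strictly
# increasing; it is almost certainly a transcription slip.
_ANCHORS: tuple[tuple[int, float], ...] = (
    (1, 468.63),
    (2, 471.44),
    (14, 514.83),
    (15, 520.08),
    (19, 535.06),
    (25, 551.20),
    (30, 569.27),
    (33, 571.04),
    (36, 591.46),
    (37, 594.66),
    (39, 602.94),
    (55, 651.37),
    (59, 664.12),
    (68, 681.80),
    (69, 685.36),
    (74, 700.27),
    (80, 721.58),
    (88, 747.22),
    (89, 750.75),
    (92, 761.18),
    (103, 780.53),
    (104, 783.39),
    (109, 799.99),
    (110, 802.71),
    (117, 824.74),
    (118, 827.35),
    (126, 851.04),
    (128, 856.68),
    (137, 871.66),
    (147, 898.72),
)

N_BANDS = 147
RANGE_NM = (468.0, 898.0)


def default_wavelengths(bands: int = N_BANDS) -> np.ndarray:
    """Return a strictly increasing wavelength table in nm.

    For the canonical 147-band layout the table is interpolated through
    the documented anchors; for any other band count a uniform grid over
    the nominal 468–898 nm range is returned.
    """
    if bands == N_BANDS:
        idx = np.array([a[0] for a in _ANCHORS], dtype=float)
        nm = np.array([a[1] for a in _ANCHORS], dtype=float)
        wl = PchipInterpolator(idx, nm)(np.arange(1, N_BANDS + 1, dtype=float))
        # PCHIP through strictly increasing knots is monotone; guard anyway.
        if not np.all(np.diff(wl) > 0):  # pragma: no cover
            raise AssertionError("interpolated wavelength grid not increasing")
        return wl
    return np.linspace(RANGE_NM[0], RANGE_NM[1], bands)
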