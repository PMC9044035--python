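"""Representative reflectance curves of leaf regions.

Per tile, the mean spectrum over leaf pixels summarizes the image; per
species, the unweighted mean of its tiles' spectra gives the
generalized reflectance curve, with an across-image standard deviation
band.  A pixel predicate (e.g. "red leaf pixels") lets a colour
subgroup's curve be contrasted against the whole-leaf curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import EmptyROIError
from .hypercube import Hypercube
from .preprocess import LeafMask

logger = logging.getLogger(__name__)


@dataclass
class SpeciesSpectrum:
    """Mean reflectance curve with a dispersion band.

    ``sd`` is the population (ddof=0) standard deviation across the
    images that contributed to the mean.
    """

    wavelengths: np.ndarray | None
    mean: np.ndarray
    sd: np.ndarray
    n_images: int
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd must have identical shapes")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")

    def to_csv(self, path) -> None:
        import pandas as pd

        wl = (
            self.wavelengths
            if self.wavelengths is not None
            else np.arange(len(self.mean))
        )
        pd.DataFrame(
            {"wavelength_nm": wl, "mean": self.mean, "sd": self.sd}
        ).to_csv(path, index=False)


def image_mean_spectrum(tile: Hypercube, mask: LeafMask | np.ndarray) -> np.ndarray:
    """Mean reflectance per band over leaf pixels only."""
    m = mask.mask if isinstance(mask, LeafMask) else np.asarray(mask, dtype=bool)
    if m.shape != (tile.rows, tile.cols):
        raise ValueError("mask shape does not match tile")
    if not m.any():
        raise EmptyROIError("leaf mask selects no pixels")
    return tile.values[m].mean(axis=0, dtype=np.float64)


def species_curve(
    per_image_spectra: Sequence[np.ndarray],
    wavelengths: np.ndarray | None = None,
) -> SpeciesSpectrum:
    """Generalize per-image spectra into one species curve.

    The mean is the unweighted across-image mean per band; the sd band
    is the across-image population standard deviation.
    """
    if len(per_image_spectra) == 0:
        raise ValueError("need at least one spectrum")
    mat = np.asarray(per_image_spectra, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError("spectra must share one length")
    return SpeciesSpectrum(
        wavelengths=wavelengths,
        mean=mat.mean(axis=0),
        sd=mat.std(axis=0, ddof=0),
        n_images=mat.shape[0],
    )


def red_leaf_predicate(
    tile: Hypercube, red_nm: float = 660.0, green_nm: float = 550.0
) -> np.ndarray:
    """Default colour rule: red-band reflectance exceeds green-band.

    Selects pixels whose reflectance at the band nearest ``red_nm`` is
    larger than at the band nearest ``green_nm`` — a serviceable proxy
    for visibly red leaf tissue on vegetation, where green tissue has a
    green peak and a red absorption valley.
    """
    ir = int(np.argmin(np.abs(tile.wavelengths - red_nm)))
    ig = int(np.argmin(np.abs(tile.wavelengths - green_nm)))
    return tile.values[:, :, ir] > tile.values[:, :, ig]


def subgroup_curve_contrast(
    tiles: Sequence[Hypercube],
    masks: Sequence[LeafMask],
    pixel_predicate: Callable[[Hypercube], np.ndarray] = red_leaf_predicate,
) -> tuple[SpeciesSpectrum, SpeciesSpectrum]:
    """Contrast the whole-leaf curve with a colour-subgroup curve.

    Returns ``(global_curve, subgroup_curve)`` where the subgroup is the
    leaf pixels additionally satisfying ``pixel_predicate``.  Tiles
    whose subgroup is empty are skipped (logged); if every tile's
    subgroup is empty an :class:`EmptyROIError` is raised.
    """
    if len(tiles) != len(masks):
        raise ValueError("tiles and masks must align")
    global_specs, sub_specs = [], []
    for k, (tile, mask) in enumerate(zip(tiles, masks)):
        global_specs.append(image_mean_spectrum(tile, mask))
        sub = mask.mask & np.asarray(pixel_predicate(tile), dtype=bool)
        if not sub.any():
            logger.info("tile %d: predicate selects no leaf pixels; skipped", k)
            continue
        sub_specs.append(tile.values[sub].mean(axis=0, dtype=np.float64))
    if not sub_specs:
        raise EmptyROIError("predicate selects no pixels in any tile")
    wl = tiles[0].wavelengths
    return species_curve(global_specs, wl), species_curve(sub_specs, wl)
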