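"""Spectral dimensionality reduction: presets, UBS, FNGBS, and PCA.

Adjacent hyperspectral bands are strongly correlated, so a handful of
well-chosen bands usually carries nearly all the discriminative
information while avoiding the curse of dimensionality.  Four families
are implemented:

* fixed presets — the sensor-recommended true-colour RGB triplet, a
  false-colour NIR triplet, and their union;
* UBS — uniform band selection, equal-interval sampling over the whole
  spectrum;
* FNGBS — fast neighborhood-grouping band selection: partition the
  bands into M contiguous groups coarse-to-fine, then pick from each
  group the band maximizing local density x information entropy;
* PCA — a linear projection onto the leading principal components of
  the pixel-spectrum covariance.

Band indices are 1-based at the API surface (matching how band sets are
conventionally printed for this sensor) and 0-based internally;
:func:`to_zero_based` / :func:`to_one_based` are the only converters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import EmptySelectionError, MetadataError
from .hypercube import Hypercube

logger = logging.getLogger(__name__)

# Published band sets for the canonical 147-band layout (1-based).
PRESET_INDICES = {
    "preset_rgb": (2, 19, 39),
    "preset_nir": (89, 109, 126),
    "preset_rgb_nir": (2, 19, 39, 89, 109, 126),
}
# Nominal wavelengths (nm) of the preset bands, used to re-derive the
# presets by nearest wavelength on non-canonical band layouts.
PRESET_WAVELENGTHS = {
    "preset_rgb": (471.44, 535.06, 602.94),
    "preset_nir": (750.75, 799.99, 851.04),
    "preset_rgb_nir": (471.44, 535.06, 602.94, 750.75, 799.99, 851.04),
}
CANONICAL_BAND_COUNT = 147


def to_zero_based(indices) -> np.ndarray:
    return np.asarray(indices, dtype=int) - 1


def to_one_based(indices) -> np.ndarray:
    return np.asarray(indices, dtype=int) + 1


@dataclass
class BandSelection:
    """A resolved band subset or spectral projection.

    ``indices`` are strictly increasing 1-based band indices (empty for
    PCA).  For PCA, ``transform`` is the (bands, m) projection matrix of
    mean-centred principal axes and ``mean`` the training mean spectrum.
    """

    method: str
    m: int
    indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    transform: np.ndarray | None = None
    mean: np.ndarray | None = None
    energy: float | None = None  # cumulative eigenvalue energy (pca only)
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.method == "pca":
            if self.transform is None or self.transform.shape[1] != self.m:
                raise ValueError("pca selection requires a (bands, m) transform")
        else:
            if len(self.indices) != self.m:
                raise ValueError(
                    f"expected {self.m} indices, got {len(self.indices)}"
                )
            if len(self.indices) and (
                np.any(np.diff(self.indices) <= 0) or self.indices[0] < 1
            ):
                raise ValueError("indices must be strictly increasing and >= 1")

    def to_json_dict(self) -> dict:
        d = {"method": self.method, "m": self.m, "indices": self.indices.tolist()}
        if self.wavelengths is not None:
            d["wavelengths_nm"] = [round(float(w), 2) for w in self.wavelengths]
        if self.energy is not None:
            d["energy"] = float(self.energy)
        return d


def preset_bands(
    name: str, band_count: int, wavelengths: np.ndarray | None = None
) -> BandSelection:
    """Return a published preset band set.

    On the canonical 147-band layout the printed indices are returned
    verbatim; on any other layout the preset is re-derived by nearest
    wavelength, which requires a wavelength table.
    """
    key = name if name.startswith("preset_") else f"preset_{name}"
    if key not in PRESET_INDICES:
        raise ValueError(f"unknown preset '{name}'")
    if band_count == CANONICAL_BAND_COUNT:
        idx = np.array(PRESET_INDICES[key], dtype=int)
    else:
        if wavelengths is None:
            raise MetadataError(
                f"preset '{name}' on a {band_count}-band cube needs a "
                "wavelength table to re-derive band indices"
            )
        wl = np.asarray(wavelengths, dtype=float)
        idx = np.unique(
            [int(np.argmin(np.abs(wl - t))) + 1 for t in PRESET_WAVELENGTHS[key]]
        )
        if len(idx) != len(PRESET_WAVELENGTHS[key]):
            raise EmptySelectionError(
                f"preset '{name}' collapses to {len(idx)} distinct bands on "
                "this wavelength grid"
            )
    return BandSelection(method=key, m=len(idx), indices=idx)


def ubs_select(band_count: int, m: int) -> BandSelection:
    """Uniform band selection: equal-interval sampling of the spectrum.

    The k-th selected band (k = 0..M-1, 1-based output) is
    ``floor(1 + k * (B - 1) / (M - 1))``; the first and last band are
    always included for M >= 2.  M = 1 returns the middle band.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > band_count:
        raise ValueError(f"m={m} exceeds band count {band_count}")
    if m == 1:
        idx = np.array([(band_count + 1) // 2], dtype=int)
    else:
        k = np.arange(m, dtype=np.int64)
        idx = 1 + (k * (band_count - 1)) // (m - 1)
    return BandSelection(method="ubs", m=m, indices=idx.astype(int))


def band_entropy(sample: np.ndarray, band: int | None = None, bins: int = 256) -> float:
    """Shannon entropy (bits) of one band's histogram.

    The histogram uses ``bins`` equal-width bins spanning the band's
    observed range; a constant band has zero entropy by convention.
    ``sample`` is a (pixels, bands) matrix (or a 1-D vector with
    ``band=None``); ``band`` is 0-based.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.ndim == 2:
        if band is None:
            raise ValueError("band index required for a 2-D sample")
        x = x[:, band]
    if x.size == 0:
        raise ValueError("empty sample")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def _band_distance_matrix(sample: np.ndarray) -> np.ndarray:
    """Pairwise mean-squared distance between band vectors.

    D[i, j] = mean over pixels of (x_i - x_j)^2, i.e. the squared
    Euclidean distance normalized by the pixel count.
    """
    x = np.asarray(sample, dtype=np.float64)
    n = x.shape[0]
    sq = (x * x).mean(axis=0)
    g = x.T @ x / n
    d = sq[:, None] + sq[None, :] - 2.0 * g
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _coarse_partition(band_count: int, m: int) -> list[list[int]]:
    """Uniform contiguous partition of 0-based band indices into m groups."""
    bounds = [(g * band_count) // m for g in range(m + 1)]
    return [list(range(bounds[g], bounds[g + 1])) for g in range(m)]


def _refine_partition(
    groups: list[list[int]], dist: np.ndarray, max_iter: int
) -> list[list[int]]:
    """Fine step: reattach boundary bands to the spectrally closer group.

    For each boundary between adjacent groups, the boundary band moves
    to the neighbouring group if its mean distance to that group's
    members is smaller than to its own group's (other) members.  Groups
    stay contiguous (only boundary bands move) and non-empty (a group's
    last member never moves).  Iterated to a fixed point or ``max_iter``.
    """

    def mean_dist(band: int, members: list[int]) -> float:
        others = [b for b in members if b != band]
        if not others:
            return np.inf
        return float(dist[band, others].mean())

    for _ in range(max_iter):
        changed = False
        for g in range(len(groups) - 1):
            left, right = groups[g], groups[g + 1]
            moved_right = False
            if len(left) > 1:
                b = left[-1]
                if mean_dist(b, right) < mean_dist(b, left):
                    left.pop()
                    right.insert(0, b)
                    changed = moved_right = True
            if not moved_right and len(right) > 1:
                b = right[0]
                if mean_dist(b, left) < mean_dist(b, right):
                    right.pop(0)
                    left.append(b)
                    changed = True
        if not changed:
            break
    return groups


@dataclass
class BandScore:
    """Local density, entropy, and their product for one band."""

    band: int  # 1-based
    density: float
    entropy: float

    @property
    def score(self) -> float:
        return self.density * self.entropy


def fngbs_select(
    sample: np.ndarray,
    m: int,
    k_neighbors: int = 3,
    bins: int = 256,
    max_iter: int = 50,
    return_scores: bool = False,
):
    """Fast neighborhood-grouping band selection.

    Steps, on a (pixels, bands) sample matrix:

    1. coarse: partition the band indices into ``m`` uniform contiguous
       groups;
    2. fine: iteratively reattach boundary bands to whichever adjacent
       group they are spectrally closer to (mean pairwise band distance),
       keeping groups contiguous and non-empty;
    3. score every band by local density rho = exp(-mean distance to its
       ``k_neighbors`` nearest bands) times Shannon entropy H of its
       histogram (``bins`` bins over the observed range); band distances
       are squared Euclidean normalized by the pixel count;
    4. select per group the band with the maximum rho x H, ties to the
       smaller index.

    Returns a :class:`BandSelection` with 1-based indices (and the
    per-band :class:`BandScore` list when ``return_scores``).
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("sample must be (pixels, bands)")
    n_pix, n_bands = x.shape
    if not 1 <= m <= n_bands:
        raise ValueError(f"m={m} out of range for {n_bands} bands")
    if n_bands < k_neighbors + 1:
        raise ValueError("need at least k_neighbors + 1 bands")

    dist = _band_distance_matrix(x)
    groups = _coarse_partition(n_bands, m)
    groups = _refine_partition(groups, dist, max_iter)

    # local density: exp(-mean distance to the k nearest other bands)
    off = dist + np.diag(np.full(n_bands, np.inf))
    knn = np.sort(off, axis=1)[:, :k_neighbors]
    rho = np.exp(-knn.mean(axis=1))
    ent = np.array([band_entropy(x, b, bins=bins) for b in range(n_bands)])
    score = rho * ent

    chosen = []
    for members in groups:
        best = members[int(np.argmax(score[members]))]  # argmax ties -> first
        chosen.append(best)
    idx = to_one_based(np.sort(chosen))
    sel = BandSelection(method="fngbs", m=m, indices=idx)
    if return_scores:
        scores = [BandScore(b + 1, float(rho[b]), float(ent[b])) for b in range(n_bands)]
        return sel, scores
    return sel


def pool_leaf_pixels(
    manifest,
    max_pixels: int = 50_000,
    seed: int = 0,
    split: str = "train",
    threshold: float = 0.3,
) -> np.ndarray:
    """Pool a seeded random sample of leaf pixels across training tiles.

    Used to feed :func:`fngbs_select` and :func:`pca_reduce` with a
    manageable (pixels, bands) matrix.  Only the given split is used,
    so data-driven selections never see test tiles.
    """
    from .preprocess import extract_leaf_mask

    rng = np.random.default_rng(seed)
    records = manifest.subset(split)
    if records.empty:
        records = manifest.records
    per_tile = max(1, max_pixels // max(len(records), 1))
    chunks = []
    for path in records["path"]:
        cube = manifest.load(path)
        mask = extract_leaf_mask(cube, threshold).mask
        px = cube.values[mask]
        if len(px) == 0:
            continue
        take = min(per_tile, len(px))
        chunks.append(px[rng.choice(len(px), size=take, replace=False)])
    if not chunks:
        raise EmptySelectionError("no leaf pixels found in manifest")
    pooled = np.concatenate(chunks, axis=0)
    if len(pooled) > max_pixels:
        pooled = pooled[rng.choice(len(pooled), size=max_pixels, replace=False)]
    return pooled.astype(np.float64)


def pca_reduce(sample: np.ndarray, m: int) -> BandSelection:
    """Fit a PCA projection on a (pixels, bands) training sample.

    Components are mean-centred principal axes ordered by decreasing
    eigenvalue; ``energy`` reports the cumulative explained-variance
    fraction of the first ``m`` components.  Raises when ``m`` exceeds
    the rank of the centred sample.
    """
    x = np.asarray(sample, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("sample must be (pixels, bands)")
    n, b = x.shape
    if n < b:
        logger.warning("PCA sample has fewer pixels (%d) than bands (%d)", n, b)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    if m > rank:
        raise ValueError(f"m={m} exceeds sample rank {rank}")
    pca = PCA(n_components=m, svd_solver="full")
    pca.fit(x)
    return BandSelection(
        method="pca",
        m=m,
        transform=pca.components_.T.copy(),  # (bands, m)
        mean=pca.mean_.copy(),
        energy=float(pca.explained_variance_ratio_.sum()),
    )


def apply_selection(cube: Hypercube, sel: BandSelection) -> Hypercube:
    """Slice (index methods) or project (PCA) a cube to L = m bands."""
    if sel.method == "pca":
        if sel.transform.shape[0] != cube.bands:
            raise ValueError(
                f"selection fit on {sel.transform.shape[0]} bands, cube has "
                f"{cube.bands}"
            )
        flat = cube.values.reshape(-1, cube.bands).astype(np.float64)
        proj = (flat - sel.mean) @ sel.transform
        values = proj.reshape(cube.rows, cube.cols, sel.m)
        # component stacks are not reflectance: label axes by component no.
        return Hypercube(values, np.arange(1, sel.m + 1, dtype=float), "arbitrary")
    if len(sel.indices) and sel.indices[-1] > cube.bands:
        raise ValueError(
            f"selection indexes band {sel.indices[-1]} but cube has {cube.bands}"
        )
    zi = to_zero_based(sel.indices)
    return Hypercube(cube.values[:, :, zi], cube.wavelengths[zi], cube.scale)
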