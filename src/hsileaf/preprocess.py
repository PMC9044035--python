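"""Tiling, leaf masking, leaf-ratio filtering, and the dataset manifest.

Full-size calibrated cubes are cut into non-overlapping square tiles;
each tile gets a leaf/background mask from a two-band spectral
difference; tiles with too little leaf are dropped; and the survivors
are recorded in a manifest with a stratified train/test split.

The leaf mask follows the spectral-differencing recipe: find the bands
with the largest and smallest global mean reflectance (for vegetation
these land on the NIR plateau and a visible absorption valley), subtract
the two band images, and threshold the difference.  Leaf pixels are
bright in the NIR and dark in the visible, so their difference is large;
a dark background stays near zero.  The default threshold of 0.3 is on
the fraction reflectance scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyROIError, StratificationError
from .hypercube import Hypercube, band_global_means

logger = logging.getLogger(__name__)

DEFAULT_LEAF_THRESHOLD = 0.3
DEFAULT_MIN_LEAF_FRACTION = 0.6


@dataclass
class LeafMask:
    """Per-pixel leaf/background labelling of one tile.

    ``max_band``/``min_band`` are the 1-based indices of the bands with
    the largest/smallest global mean reflectance used to form the
    difference image.
    """

    mask: np.ndarray  # bool, (rows, cols)
    threshold: float
    max_band: int
    min_band: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def leaf_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class Tile:
    """A tile cut from a larger cube, with its 0-based grid position."""

    cube: Hypercube
    row: int
    col: int


def tile_image(cube: Hypercube, tile_size: int) -> list[Tile]:
    """Cut a cube into non-overlapping tile_size x tile_size tiles.

    Tiles are emitted in row-major order from the top-left corner;
    residual margins that do not fill a whole tile are dropped.
    """
    if tile_size <= 0:
        raise ValueError(f"tile_size must be positive, got {tile_size}")
    if tile_size > cube.rows or tile_size > cube.cols:
        raise ValueError(
            f"tile_size {tile_size} exceeds cube spatial dims "
            f"{cube.rows}x{cube.cols}"
        )
    tiles = []
    for i in range(cube.rows // tile_size):
        for j in range(cube.cols // tile_size):
            sub = cube.values[
                i * tile_size : (i + 1) * tile_size,
                j * tile_size : (j + 1) * tile_size,
            ]
            tiles.append(Tile(Hypercube(sub, cube.wavelengths, cube.scale), i, j))
    return tiles


def extract_leaf_mask(
    tile: Hypercube, threshold: float = DEFAULT_LEAF_THRESHOLD
) -> LeafMask:
    """Two-band difference leaf mask: (maxBand - minBand) > threshold.

    Ties in the arg-max/arg-min of the global band means resolve to the
    smallest band index.
    """
    if tile.scale != "fraction":
        raise ValueError("leaf masking expects a fraction-scale cube")
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    means = band_global_means(tile)
    bmax = int(np.argmax(means))  # first occurrence == smallest index on ties
    bmin = int(np.argmin(means))
    if means[bmax] == means[bmin]:
        logger.debug("degenerate tile: all band means equal")
    diff = tile.values[:, :, bmax].astype(np.float64) - tile.values[:, :, bmin]
    return LeafMask(diff > threshold, threshold, bmax + 1, bmin + 1)


def leaf_fraction_filter(
    tiles: Sequence[Tile],
    masks: Sequence[LeafMask],
    min_fraction: float = DEFAULT_MIN_LEAF_FRACTION,
) -> tuple[list[Tile], list[LeafMask]]:
    """Retain tiles whose leaf-pixel fraction is >= min_fraction."""
    if len(tiles) != len(masks):
        raise ValueError("tiles and masks must align")
    kept_t, kept_m = [], []
    for t, m in zip(tiles, masks):
        if m.leaf_fraction >= min_fraction:
            kept_t.append(t)
            kept_m.append(m)
    return kept_t, kept_m


class TileStore(Protocol):
    """Maps manifest paths/keys to hypercubes."""

    def load(self, key: str) -> Hypercube: ...


@dataclass
class DatasetManifest:
    """Tile records (path, class label, split tag) plus class names.

    ``records`` is a DataFrame with columns ``path`` (str key into the
    attached store or a file path), ``label`` (contiguous int from 0)
    and ``split`` ("train", "test", or "" before splitting).  ``store``
    resolves paths to cubes; when None, paths are read from disk.
    """

    records: pd.DataFrame
    class_names: list[str]
    store: TileStore | None = None

    def __post_init__(self) -> None:
        required = {"path", "label", "split"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        labels = np.sort(self.records["label"].unique())
        if len(labels) and not np.array_equal(labels, np.arange(len(labels))):
            raise ValueError("class ids must be contiguous from 0")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, split: str) -> pd.DataFrame:
        return self.records[self.records["split"] == split]

    def load(self, path: str) -> Hypercube:
        if self.store is not None:
            return self.store.load(path)
        from .hypercube import read_hypercube

        return read_hypercube(path)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, class_names: list[str] | None = None,
        store: TileStore | None = None,
    ) -> "DatasetManifest":
        df = pd.read_csv(path, keep_default_na=False)
        if class_names is None:
            class_names = [f"class{c}" for c in sorted(df["label"].unique())]
        return cls(df, class_names, store)


def split_dataset(
    manifest: DatasetManifest, train_fraction: float, seed: int
) -> DatasetManifest:
    """Stratified train/test split: round(train_fraction * n) per class.

    Counts are deterministic in n and train_fraction; which tiles land
    where depends only on the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    df = manifest.records.copy()
    split = pd.Series("", index=df.index, dtype=object)
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        if len(idx) < 2:
            raise StratificationError(
                f"class {label} has {len(idx)} tile(s); need at least 2"
            )
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both splits non-empty
        perm = rng.permutation(len(idx))
        split.loc[idx[perm[:n_train]]] = "train"
        split.loc[idx[perm[n_train:]]] = "test"
    df["split"] = split
    return DatasetManifest(df, list(manifest.class_names), manifest.store)
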