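"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit loops and naive arithmetic,
deliberately avoiding the vectorized code paths of the package, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def bruteforce_band_means(values: np.ndarray) -> list[float]:
    """Per-band mean via an explicit triple loop."""
    rows, cols, bands = values.shape
    means = []
    for b in range(bands):
        total = 0.0
        for i in range(rows):
            for j in range(cols):
                total += float(values[i, j, b])
        means.append(total / (rows * cols))
    return means


def bruteforce_entropy(x: np.ndarray, bins: int) -> float:
    """Shannon entropy of an equal-width histogram, by hand."""
    lo, hi = float(min(x)), float(max(x))
    if lo == hi:
        return 0.0
    counts = [0] * bins
    width = (hi - lo) / bins
    for v in x:
        k = int((float(v) - lo) / width)
        if k == bins:  # right edge belongs to the last bin
            k = bins - 1
        counts[k] += 1
    h = 0.0
    n = len(x)
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def bruteforce_fngbs(
    sample: np.ndarray,
    m: int,
    k_neighbors: int = 3,
    bins: int = 256,
    max_iter: int = 50,
) -> list[int]:
    """Naive-loop neighborhood-grouping band selection (1-based indices).

    Same contract as the package: uniform coarse partition; boundary
    bands iterate to the adjacent group with smaller mean member
    distance (groups stay contiguous and non-empty; within one boundary
    pass the right-move is considered before the left-move and excludes
    it); density rho = exp(-mean distance to the k nearest other
    bands); entropy over ``bins`` equal-width bins spanning each band's
    observed range; per group argmax rho * H, ties to the smaller index.
    Distances are squared Euclidean divided by the pixel count.
    """
    n_pix, n_bands = sample.shape

    def dist(i: int, j: int) -> float:
        total = 0.0
        for p in range(n_pix):
            d = float(sample[p, i]) - float(sample[p, j])
            total += d * d
        return total / n_pix

    def mean_dist(band: int, members: list[int]) -> float:
        others = [b for b in members if b != band]
        if not others:
            return math.inf
        return sum(dist(band, o) for o in others) / len(others)

    groups = []
    for g in range(m):
        start = (g * n_bands) // m
        stop = ((g + 1) * n_bands) // m
        groups.append(list(range(start, stop)))

    for _ in range(max_iter):
        changed = False
        for g in range(m - 1):
            left, right = groups[g], groups[g + 1]
            moved_right = False
            if len(left) > 1:
                b = left[-1]
                if mean_dist(b, right) < mean_dist(b, left):
                    left.remove(b)
                    right.insert(0, b)
                    changed = moved_right = True
            if not moved_right and len(right) > 1:
                b = right[0]
                if mean_dist(b, left) < mean_dist(b, right):
                    right.remove(b)
                    left.append(b)
                    changed = True
        if not changed:
            break

    scores = []
    for b in range(n_bands):
        ds = sorted(dist(b, o) for o in range(n_bands) if o != b)
        rho = math.exp(-sum(ds[:k_neighbors]) / k_neighbors)
        h = bruteforce_entropy(sample[:, b], bins)
        scores.append(rho * h)

    chosen = []
    for members in groups:
        best = members[0]
        for b in members:
            if scores[b] > scores[best]:
                best = b
        chosen.append(best + 1)
    return sorted(chosen)


def bruteforce_conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                           stride: int) -> np.ndarray:
    """Direct-loop same-padded convolution (cross-correlation) oracle."""
    h, wid, cin = x.shape
    k, _, _, cout = w.shape
    oh = math.ceil(h / stride)
    ow = math.ceil(wid / stride)
    pad_h = max((oh - 1) * stride + k - h, 0)
    pad_w = max((ow - 1) * stride + k - wid, 0)
    pt, pl = pad_h // 2, pad_w // 2
    y = np.zeros((oh, ow, cout))
    for oi in range(oh):
        for oj in range(ow):
            for co in range(cout):
                acc = float(b[co])
                for ki in range(k):
                    for kj in range(k):
                        ri = oi * stride + ki - pt
                        cj = oj * stride + kj - pl
                        if 0 <= ri < h and 0 <= cj < wid:
                            for ci in range(cin):
                                acc += float(x[ri, cj, ci]) * float(w[ki, kj, ci, co])
                y[oi, oj, co] = acc
    return y
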