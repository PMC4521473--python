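"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — exhaustive pairwise distances,
set-based boundary scans, textbook cluster-index formulas — and shares no
code with the package's implementations.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.morphology import skeletonize


def brute_max_pairwise(pixels: np.ndarray) -> float:
    best = 0.0
    pts = np.asarray(pixels, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
            if d > best:
                best = d
    return best


def brute_invasion_inhibition(pixels: np.ndarray) -> float:
    d = brute_max_pairwise(pixels)
    return 4.0 * len(pixels) / (math.pi * d * d)


def brute_boundary(pixels: np.ndarray) -> np.ndarray:
    pixset = {(int(x), int(y)) for x, y in pixels}
    out = []
    for x, y in sorted(pixset):
        if any((x + dx, y + dy) not in pixset
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) if dx or dy):
            out.append((x, y))
    return np.asarray(out, dtype=np.int64)


def brute_cell_polarity(centers: np.ndarray, pixels: np.ndarray
                        ) -> tuple[float, float]:
    boundary = brute_boundary(pixels)
    minima = []
    for cx, cy in np.atleast_2d(centers):
        minima.append(min(math.hypot(cx - bx, cy - by) for bx, by in boundary))
    arr = np.asarray(minima)
    return float(arr.mean()), float(arr.std(ddof=0))


def brute_branch_lengths(pixels: np.ndarray) -> list[int]:
    """Skeleton-graph branch lengths by explicit path walking (no networkx).

    Same stated definition as the package: skeleton pixels under
    8-adjacency; vertices are pixels of degree != 2; a branch is a path
    between vertices with exactly one degree-1 terminal; its length counts
    the path pixels excluding the non-tip terminal.
    """
    xs, ys = pixels[:, 0], pixels[:, 1]
    x0, y0 = int(xs.min()) - 1, int(ys.min()) - 1
    img = np.zeros((int(ys.max()) - y0 + 2, int(xs.max()) - x0 + 2), dtype=bool)
    img[ys - y0, xs - x0] = True
    skel = skeletonize(img)
    sy, sx = np.nonzero(skel)
    nodes = set(zip(sx.tolist(), sy.tolist()))
    if len(nodes) < 2:
        return []

    def neighbors(p):
        x, y = p
        return [(x + dx, y + dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                if (dx or dy) and (x + dx, y + dy) in nodes]

    degree = {p: len(neighbors(p)) for p in nodes}
    special = [p for p in nodes if degree[p] != 2]
    if not special:
        return []
    lengths = []
    seen = set()
    for start in special:
        for nb in neighbors(start):
            key = (start, nb)
            if key in seen or (nb, start) in seen:
                continue
            seen.add(key)
            path = [start, nb]
            prev, cur = start, nb
            while degree[cur] == 2:
                nxt = [p for p in neighbors(cur) if p != prev][0]
                seen.add((cur, nxt))
                prev, cur = cur, nxt
                path.append(cur)
            end = path[-1]
            if (degree[start] == 1) + (degree[end] == 1) == 1:
                lengths.append(len(path) - 1)
    return lengths


def brute_branching(pixels: np.ndarray) -> float:
    lengths = brute_branch_lengths(pixels)
    return float(np.mean(lengths)) if lengths else 0.0


def brute_davies_bouldin(x: np.ndarray, labels: np.ndarray) -> float:
    """Textbook Davies–Bouldin: mean over clusters of max_j (s_i+s_j)/d_ij,
    with s = mean distance to centroid and d = centroid distance."""
    ks = np.unique(labels)
    cents = np.array([x[labels == k].mean(axis=0) for k in ks])
    s = np.array([
        np.mean(np.linalg.norm(x[labels == k] - c, axis=1))
        for k, c in zip(ks, cents)
    ])
    total = 0.0
    for i in range(len(ks)):
        worst = 0.0
        for j in range(len(ks)):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            worst = max(worst, (s[i] + s[j]) / d)
        total += worst
    return total / len(ks)


def brute_calinski_harabasz(x: np.ndarray, labels: np.ndarray) -> float:
    """Textbook Calinski–Harabasz: (B/(k−1)) / (W/(n−k)) with between/within
    sums of squared distances."""
    n = len(x)
    ks = np.unique(labels)
    k = len(ks)
    grand = x.mean(axis=0)
    b = sum((labels == c).sum() * np.sum((x[labels == c].mean(axis=0) - grand) ** 2)
            for c in ks)
    w = sum(np.sum((x[labels == c] - x[labels == c].mean(axis=0)) ** 2) for c in ks)
    return (b / (k - 1)) / (w / (n - k))


def random_blob_mask(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A random connected mask (union of disks/bars, largest component)."""
    from scipy import ndimage

    canvas = np.zeros((size, size), dtype=bool)
    n_shapes = rng.integers(1, 5)
    yy, xx = np.mgrid[0:size, 0:size]
    cx0, cy0 = rng.uniform(size * 0.3, size * 0.7, size=2)
    for i in range(n_shapes):
        # chain shapes off the first so the union tends to connect
        cx = np.clip(cx0 + rng.normal(0, size * 0.12), 4, size - 5)
        cy = np.clip(cy0 + rng.normal(0, size * 0.12), 4, size - 5)
        if rng.uniform() < 0.6:
            r = rng.uniform(2, size * 0.18)
            canvas |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        else:
            w, h = rng.uniform(2, size * 0.25, size=2)
            canvas |= (np.abs(xx - cx) <= w) & (np.abs(yy - cy) <= h)
    labels, n = ndimage.label(canvas, structure=np.ones((3, 3)))
    if n == 0:
        return random_blob_mask(rng, size)
    sizes = ndimage.sum(canvas, labels, index=range(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    ys, xs = np.nonzero(labels == best)
    if len(xs) < 2:
        return random_blob_mask(rng, size)
    return np.column_stack([xs, ys]).astype(np.int64)
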