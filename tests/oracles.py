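"""Independent brute-force oracles used by the tests.

These are deliberately naive (explicit SE shifts, flood fills, direct
histograms) and share no code with the implementation they check.
"""

from __future__ import annotations

import numpy as np


def se_offsets(radius: int, ndim: int) -> np.ndarray:
    """Offsets of the Euclidean disk/ball SE: {o : |o| <= radius}."""
    rng = range(-radius, radius + 1)
    if ndim == 2:
        offs = [(a, b) for a in rng for b in rng if a * a + b * b <= radius**2]
    else:
        offs = [
            (a, b, c)
            for a in rng for b in rng for c in rng
            if a * a + b * b + c * c <= radius**2
        ]
    return np.array(offs, dtype=np.int64)


def brute_erode(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion by explicit set shifts; outside the array counts as
    background (so foreground touching the border erodes)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.ones_like(mask)
    shape = np.array(mask.shape)
    for off in se_offsets(radius, mask.ndim):
        shifted = np.zeros_like(mask)
        src = tuple(
            slice(max(0, o), s + min(0, o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, -o), s + min(0, -o)) for o, s in zip(off, shape)
        )
        shifted[dst] = mask[src]
        out &= shifted
    return out


def brute_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    shape = np.array(mask.shape)
    for off in se_offsets(radius, mask.ndim):
        src = tuple(
            slice(max(0, o), s + min(0, o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, -o), s + min(0, -o)) for o, s in zip(off, shape)
        )
        out[dst] |= mask[src]
    return out


def brute_open(mask: np.ndarray, radius: int) -> np.ndarray:
    return brute_dilate(brute_erode(mask, radius), radius)


def brute_cascade(mask: np.ndarray, radii) -> list:
    out = []
    current = np.asarray(mask, dtype=bool)
    for r in radii:
        current = brute_open(current, r)
        out.append(current)
    return out


def brute_local_mean(img: np.ndarray, window: int) -> np.ndarray:
    """Local mean with edge-including reflected borders (a b c | c b a),
    computed pixel by pixel."""
    half = window // 2
    padded = np.pad(img.astype(float), half, mode="symmetric")
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = padded[i : i + window, j : j + window].mean()
    return out


def disk_image(shape, center, radius) -> np.ndarray:
    """Boolean disk/ball: voxels whose centre is within radius of center."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius * radius


def flood_count_components(mask: np.ndarray, connectivity: int) -> int:
    """Connected-component count by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 26:
        neigh = [
            (a, b, c)
            for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
        ]
    else:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(mask)
    count = 0
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            p = stack.pop()
            for o in neigh:
                q = tuple(pi + oi for pi, oi in zip(p, o))
                if all(0 <= qi < s for qi, s in zip(q, mask.shape)) and mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
    return count
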