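"""Cell-size grading by cascaded morphological opening.

Nuclear-stain images are background-suppressed with a white top-hat,
binarized with a local adaptive threshold, and opened with disk (2D) or
ball (3D) structural elements of increasing radius. A foreground pixel's
grade is the band between the largest SE whose opening retains it and the
next one: with the default radii (6, 10, 14 px at 0.65 um/px)

* grade 0 — background, plus foreground removed by the smallest opening
  (sub-cellular noise),
* grade 1 — small somata (survive r=6, not r=10),
* grade 2 — medium somata (survive r=10, not r=14),
* grade 3 — large somata (survive r=14).

Openings here are exact Euclidean-disk openings computed via distance
transforms (a pixel survives erosion by the SE {o : |o| <= r} iff its
distance to background exceeds r), which is pixel-identical to explicit
SE-shift morphology and much faster for large radii. Outside the image is
treated as background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# structural elements
# --------------------------------------------------------------------------

def disk_se(radius: int, ndim: int = 2) -> np.ndarray:
    """Boolean disk (2D) / ball (3D) footprint: offsets with |o| <= radius."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    dist2 = sum(g.astype(np.int64) ** 2 for g in grids)
    return dist2 <= radius * radius


# --------------------------------------------------------------------------
# openings via Euclidean distance transforms
# --------------------------------------------------------------------------

def binary_erode_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Erosion by the Euclidean disk/ball SE; outside counts as background."""
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)
    return dist[tuple(slice(1, -1) for _ in mask.shape)] > radius


def binary_dilate_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Dilation by the Euclidean disk/ball SE."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius


def binary_open_disk(mask: np.ndarray, radius: int) -> np.ndarray:
    """Opening (erosion then dilation) by the Euclidean disk/ball SE."""
    return binary_dilate_disk(binary_erode_disk(mask, radius), radius)


# --------------------------------------------------------------------------
# standard 2D pipeline
# --------------------------------------------------------------------------

def tophat_filter(img: np.ndarray, radius_px: int = 20) -> np.ndarray:
    """White top-hat: image minus its grey opening with a disk SE.

    Suppresses structures wider than the SE (smooth background, vessels)
    while somata — narrower than the 20 px default — pass through intact.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"tophat_filter expects a 2D image, got ndim={img.ndim}")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    opened = ndimage.grey_opening(img, footprint=disk_se(radius_px, 2), mode="reflect")
    return img - opened


def binarize_adaptive(
    img: np.ndarray, window_px: int = 101, offset: float = 0.0
) -> np.ndarray:
    """Local-mean adaptive threshold: foreground where
    ``img > local_mean(window) + offset``; borders reflect-padded."""
    img = np.asarray(img, dtype=np.float64)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    local_mean = ndimage.uniform_filter(img, size=window_px, mode="reflect")
    return img > local_mean + offset


def cascade_open(
    binary: np.ndarray, radii_px: Sequence[int] = (6, 10, 14)
) -> List[np.ndarray]:
    """Three rounds of opening with increasing SE radii.

    Returns ``[O_r1, O_r2, O_r3]`` where each round opens the *previous
    round's output* (O_1 = opening of the input with r_1, O_2 = opening of
    O_1 with r_2, ...). For ideal Euclidean disks this equals opening the
    original mask per radius, but on the pixel grid a digital disk of
    radius 10 is not exactly a union of radius-6 disk translates, so only
    the sequential cascade guarantees the nesting O_r1 >= O_r2 >= O_r3 that
    grade banding requires. Anti-extensivity makes every output a subset of
    the input.
    """
    binary = np.asarray(binary, dtype=bool)
    radii = tuple(int(r) for r in radii_px)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii_px must be strictly increasing")
    out: List[np.ndarray] = []
    current = binary
    for r in radii:
        current = binary_open_disk(current, r)
        out.append(current)
    return out


def assign_grades(binary: np.ndarray, opened: Sequence[np.ndarray]) -> np.ndarray:
    """Band the openings into integer grades.

    grade n = survives the largest SE; grade g = survives radius r_g but not
    r_{g+1}; grade 0 = background plus foreground killed by the first
    opening (noise).
    """
    binary = np.asarray(binary, dtype=bool)
    prev = None
    for o in opened:
        o = np.asarray(o, dtype=bool)
        if o.shape != binary.shape:
            raise ValueError("opened masks must match the binary image shape")
        if not (o <= binary).all():
            raise ValueError("opened masks must be subsets of the binary image")
        if prev is not None and not (o <= prev).all():
            raise ValueError("opened masks must be nested (decreasing)")
        prev = o
    grades = np.zeros(binary.shape, dtype=np.uint8)
    for g, o in enumerate(opened, start=1):
        grades[o] = g
    return grades


def grade_image(
    img: np.ndarray,
    tophat_radius_px: int = 20,
    radii_px: Sequence[int] = (6, 10, 14),
    window_px: int = 101,
    offset_frac: float = 0.02,
) -> np.ndarray:
    """Full single-image grading: top-hat, adaptive binarization, cascaded
    opening, grade assignment. ``offset_frac`` scales the adaptive-threshold
    offset by the image dynamic range."""
    filtered = tophat_filter(img, tophat_radius_px)
    rng = float(filtered.max() - filtered.min())
    binary = binarize_adaptive(filtered, window_px, offset_frac * rng)
    return assign_grades(binary, cascade_open(binary, radii_px))


def grade_slices(
    data: np.ndarray,
    radii_px: Sequence[int] = (6, 10, 14),
    window_px: int = 101,
    offset_frac: float = 0.02,
    tophat_radius_px: int | None = None,
) -> np.ndarray:
    """Grade every z-slice of a 3D stack independently (the 2D method).

    ``tophat_radius_px=None`` skips background suppression — appropriate
    when the background is already flat (e.g. synthetic volumes); the
    threshold offset scales with the global dynamic range either way.
    """
    data = np.asarray(data)
    rng = float(data.max() - data.min())
    out = np.zeros(data.shape, dtype=np.uint8)
    for i, sl in enumerate(data):
        img = tophat_filter(sl, tophat_radius_px) if tophat_radius_px else sl
        binary = binarize_adaptive(img, window_px, offset_frac * rng)
        out[i] = assign_grades(binary, cascade_open(binary, radii_px))
    return out


# --------------------------------------------------------------------------
# enhancement (mean projection -> RGB)
# --------------------------------------------------------------------------

@dataclass
class EnhancedImage:
    """3-channel [0,1] image; channel c shows grade c+1 (R=small, G=medium,
    B=large), mean-projected over ``window_slices`` graded slices and
    per-channel brightness-rescaled."""

    data: np.ndarray  # (H, W, 3) float in [0, 1]
    window_slices: int


def enhance_projection(
    graded_stack: Sequence[np.ndarray],
    window_slices: int,
    n_grades: int = 3,
    percentile: float = 99.0,
) -> EnhancedImage:
    """Mean-project per-grade indicators over a slice window and rescale
    each channel so its ``percentile``-th positive value maps to 1."""
    stack = [np.asarray(g) for g in graded_stack]
    if len(stack) == 0:
        raise ValueError("empty graded stack")
    if not (1 <= window_slices <= len(stack)):
        raise ValueError("window_slices must be in [1, stack depth]")
    window = np.stack(stack[:window_slices], axis=0)
    channels = []
    for g in range(1, n_grades + 1):
        mean = (window == g).mean(axis=0)
        pos = mean[mean > 0]
        scale = np.percentile(pos, percentile) if pos.size else 1.0
        channels.append(np.clip(mean / max(scale, 1e-12), 0.0, 1.0))
    return EnhancedImage(data=np.stack(channels, axis=-1), window_slices=window_slices)


# --------------------------------------------------------------------------
# 3D variant (orthogonal-plane consensus + ball SEs)
# --------------------------------------------------------------------------

def binarize_3d_consensus(
    vol: np.ndarray,
    sigma: float = 1.0,
    window_px: int = 101,
    offset_frac: float = 0.02,
    spacing: Tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Slice-wise adaptive binarization in the three orthogonal plane
    families, averaged, Gaussian-smoothed, re-thresholded at 0.5.

    Intended for (approximately) isotropic volumes; warns otherwise.
    """
    vol = np.asarray(vol, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if spacing is not None and (max(spacing) / min(spacing)) > 1.5:
        import warnings

        warnings.warn(
            f"binarize_3d_consensus assumes near-isotropic voxels, got {spacing}",
            stacklevel=2,
        )
    rng = float(vol.max() - vol.min())
    offset = offset_frac * rng
    win = max(3, window_px if window_px % 2 == 1 else window_px - 1)
    consensus = np.zeros(vol.shape, dtype=np.float64)
    for axis in range(3):
        moved = np.moveaxis(vol, axis, 0)
        out = np.empty_like(moved, dtype=bool)
        for i in range(moved.shape[0]):
            out[i] = binarize_adaptive(moved[i], win, offset)
        consensus += np.moveaxis(out, 0, axis)
    consensus /= 3.0
    smoothed = ndimage.gaussian_filter(consensus, sigma=sigma)
    return smoothed > 0.5


def grade_voxels_3d(
    binary: np.ndarray, radii_px: Sequence[int] = (6, 10, 14)
) -> np.ndarray:
    """3D grading: cascaded openings with ball SEs, then grade banding."""
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 3:
        raise ValueError("expected a 3D binary volume")
    return assign_grades(binary, cascade_open(binary, radii_px))


# --------------------------------------------------------------------------
# radial signal curves (2D-vs-3D comparison protocol)
# --------------------------------------------------------------------------

@dataclass
class RadialGradeProfile:
    """Per-grade voxel counts over equal-width relative-depth bins."""

    counts: np.ndarray  # (n_bins, n_grades)
    bin_edges: np.ndarray  # (n_bins + 1,)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def radial_grade_profile(
    graded: np.ndarray,
    depth: Union[np.ndarray, int],
    n_bins: int = 20,
    n_grades: int = 3,
) -> RadialGradeProfile:
    """Count graded voxels per depth bin, per grade.

    ``depth`` is either a same-shaped relative-depth array in [0, 1] (NaN
    outside the cortex) or an integer axis, in which case depth is the
    normalized coordinate along that axis. Bins are half-open with the last
    bin closed at 1.
    """
    graded = np.asarray(graded)
    if isinstance(depth, (int, np.integer)):
        axis = int(depth)
        n = graded.shape[axis]
        coord = (np.arange(n) + 0.5) / n
        shape = [1] * graded.ndim
        shape[axis] = n
        depth_arr = np.broadcast_to(coord.reshape(shape), graded.shape)
    else:
        depth_arr = np.asarray(depth, dtype=np.float64)
        if depth_arr.shape != graded.shape:
            raise ValueError("graded and depth grids are misaligned")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = np.zeros((n_bins, n_grades), dtype=np.int64)
    valid = np.isfinite(depth_arr) & (graded > 0)
    idx = np.minimum((depth_arr[valid] * n_bins).astype(np.int64), n_bins - 1)
    grd = graded[valid].astype(np.int64) - 1
    keep = grd < n_grades
    np.add.at(counts, (idx[keep], grd[keep]), 1)
    return RadialGradeProfile(counts=counts, bin_edges=edges)
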