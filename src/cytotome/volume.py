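"""Volumetric image container and I/O.

The whole pipeline works on one container, :class:`ImageVolume`: a 3D scalar
array in fixed (z, y, x) axis order with anisotropic voxel spacing in
micrometres and a physical origin. Physical position of voxel (i, j, k) is
``origin + index * spacing`` (voxel-centred coordinates).

Supported on-disk formats: multi-page TIFF, a directory of per-slice TIFFs
(lexicographic z order), and NIfTI-1 (.nii / .nii.gz). Serial-sectioning
archives do not always carry the z pitch in metadata, so spacing can always
be overridden explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np


class VolumeFormatError(ValueError):
    """Unreadable or unsupported image file."""


class VolumeGeometryError(ValueError):
    """Inconsistent slice shapes or misaligned grids."""


class SpacingError(ValueError):
    """Missing or invalid voxel spacing."""


@dataclass
class ImageVolume:
    """A 3D intensity volume with physical geometry.

    Parameters
    ----------
    data:
        3D array, axis order (z, y, x).
    spacing:
        Voxel pitch (dz, dy, dx) in micrometres; all components > 0.
    origin:
        Physical position of voxel (0, 0, 0) in micrometres.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeGeometryError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise SpacingError(f"spacing must be 3 positive values, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy_with(self, **kw) -> "ImageVolume":
        return replace(self, **kw)


def _load_tiff_stack(path: Path) -> np.ndarray:
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 2D/3D TIFF, got ndim={arr.ndim}")
    return arr


def _load_tiff_dir(path: Path) -> np.ndarray:
    import tifffile

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"}
    )
    if not files:
        raise VolumeFormatError(f"{path}: no TIFF slices found")
    slices = [tifffile.imread(str(p)) for p in files]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise VolumeGeometryError(f"{path}: inconsistent slice shapes {sorted(shapes)}")
    return np.stack(slices, axis=0)


def _nifti_spacing(img) -> Optional[Tuple[float, float, float]]:
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        return None
    # NIfTI stores (x, y, z) zooms; our axis order is (z, y, x).
    return (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def load_volume(
    path: str | Path,
    spacing_override: Optional[Sequence[float]] = None,
) -> ImageVolume:
    """Load a TIFF stack, a per-slice TIFF directory, or a NIfTI volume.

    Spacing comes from file metadata (NIfTI zooms) when present; otherwise
    ``spacing_override`` (dz, dy, dx in um) is required. TIFFs carry no
    reliable 3D pitch, so for them the override is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"{path}: no such file or directory")

    spacing: Optional[Tuple[float, float, float]] = None
    if path.is_dir():
        data = _load_tiff_dir(path)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        data = _load_tiff_stack(path)
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error detail
            raise VolumeFormatError(f"{path}: {exc}") from exc
        # NIfTI data axes are (x, y, z); transpose to (z, y, x).
        data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
        spacing = _nifti_spacing(img)
    else:
        raise VolumeFormatError(f"{path}: unsupported format")

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)  # type: ignore[assignment]
    if spacing is None:
        raise SpacingError(
            f"{path}: no spacing metadata; pass spacing_override=(dz, dy, dx)"
        )
    return ImageVolume(data=data, spacing=spacing)


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF or NIfTI-1, by file extension."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), vol.data)
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        dz, dy, dx = vol.spacing
        affine = np.diag([dx, dy, dz, 1.0])
        img = nib.Nifti1Image(vol.data.transpose(2, 1, 0), affine)
        img.header.set_zooms((dx, dy, dz))
        nib.save(img, str(path))
    else:
        raise VolumeFormatError(f"{path}: unsupported output format")


def block_reduce_mean(
    data: np.ndarray, factors: Tuple[int, int, int]
) -> np.ndarray:
    """Block-mean reduction with partial edge blocks averaged over their
    actual member voxels (no zero-padding darkening)."""
    sums = data.astype(np.float64)
    counts = np.ones_like(sums)
    for ax, f in enumerate(factors):
        if f == 1:
            continue
        n = sums.shape[ax]
        nblocks = -(-n // f)
        pad = [(0, 0)] * sums.ndim
        pad[ax] = (0, nblocks * f - n)
        sums = np.pad(sums, pad).reshape(
            sums.shape[:ax] + (nblocks, f) + sums.shape[ax + 1 :]
        ).sum(axis=ax + 1)
        counts = np.pad(counts, pad).reshape(
            counts.shape[:ax] + (nblocks, f) + counts.shape[ax + 1 :]
        ).sum(axis=ax + 1)
    return sums / counts


def downsample_volume(vol: ImageVolume, target_spacing_um: float) -> ImageVolume:
    """Block-mean downsample onto an isotropic grid of the given pitch.

    The integer block shape per axis is ``round(target / spacing)``; the
    target pitch must therefore be an (approximate) integer multiple of each
    source pitch and at least as coarse as the coarsest source axis.
    """
    t = float(target_spacing_um)
    if t < max(vol.spacing) - 1e-9:
        raise SpacingError(
            f"target spacing {t} um finer than source spacing {vol.spacing}"
        )
    factors = []
    for s in vol.spacing:
        f = max(1, int(round(t / s)))
        if abs(f * s - t) > 0.01 * t:
            raise SpacingError(
                f"target {t} um is not an integer multiple of source pitch {s} um"
            )
        factors.append(f)
    out = block_reduce_mean(vol.data, tuple(factors))
    # voxel-centred convention: the first coarse voxel centre sits at the
    # centroid of its source block
    origin = tuple(
        o + (f - 1) / 2.0 * s for o, f, s in zip(vol.origin, factors, vol.spacing)
    )
    return ImageVolume(data=out, spacing=(t, t, t), origin=origin)
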