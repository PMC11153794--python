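"""Run configuration for the cytoarchitecture pipeline.

All tunable parameters of the pipeline live in :class:`RunConfig` so that a
whole run is reproducible from a single YAML file plus the input volumes.
Defaults correspond to the macaque whole-hemisphere analysis profile
(0.65 x 0.65 x 3 um native imaging, 12 um analysis grid, KNN radial units of
k = 1000); :func:`RunConfig.mouse_profile` switches to the mouse profile
(k = 50), everything else unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class RunConfig:
    """Parameters of the grading / coordinates / clustering pipeline.

    Attributes
    ----------
    tophat_radius_px:
        Radius (pixels) of the disk structural element of the white top-hat
        that suppresses background before binarization. Slightly larger than
        the largest soma cross-section.
    opening_radii_px:
        Strictly increasing disk/ball SE radii (pixels) of the cascaded
        morphological openings; one cell-size grade per radius.
    adaptive_window_px:
        Window (odd, pixels) of the local-mean adaptive threshold.
    adaptive_offset_frac:
        Threshold offset as a fraction of the image dynamic range.
    analysis_spacing_um:
        Pitch of the isotropic analysis grid (um); densities are counted in
        cubes of this size and the cortical coordinate system is solved on
        this grid.
    n_laminates:
        Number of equal-width relative-depth bins per radial unit.
    n_grades:
        Number of cell-size grades; must equal ``len(opening_radii_px)``.
    knn_k:
        Radial-unit size: number of nearest mid-thickness surface voxels
        grouped into one unit.
    pca_var_fraction:
        Fraction of total variance the retained principal components must
        explain.
    n_clusters:
        Number of parcels (K of K-means / Potts MRF).
    mrf_beta:
        Potts smoothness weight on z-normalized PCA scores.
    tomogram_intervals / tomogram_range:
        Number of depth intervals of the surface tomogram and the trimmed
        relative-depth range they equally divide.
    potential_outer / potential_inner:
        Dirichlet values of the Laplace potential at the layer-I/II and
        GM/WM interfaces.
    enhance_window_slices:
        Slices averaged in the mean-projection enhancement.
    enhance_percentile:
        Upper percentile mapped to 1.0 in per-channel brightness scaling.
    """

    tophat_radius_px: int = 20
    opening_radii_px: Tuple[int, ...] = (6, 10, 14)
    adaptive_window_px: int = 101
    adaptive_offset_frac: float = 0.02
    analysis_spacing_um: float = 12.0
    n_laminates: int = 20
    n_grades: int = 3
    knn_k: int = 1000
    pca_var_fraction: float = 0.95
    n_clusters: int = 10
    mrf_beta: float = 1.0
    mrf_max_sweeps: int = 100
    kmeans_n_init: int = 10
    tomogram_intervals: int = 9
    tomogram_range: Tuple[float, float] = (0.05, 0.95)
    potential_outer: float = 0.0
    potential_inner: float = 2000.0
    laplace_tol: float = 1e-3
    laplace_max_iter: int = 10_000
    streamline_step_frac: float = 0.5
    enhance_window_slices: int = 8
    enhance_percentile: float = 99.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.opening_radii_px = tuple(int(r) for r in self.opening_radii_px)
        if any(b <= a for a, b in zip(self.opening_radii_px, self.opening_radii_px[1:])):
            raise ValueError("opening_radii_px must be strictly increasing")
        if self.n_grades != len(self.opening_radii_px):
            raise ValueError("n_grades must equal len(opening_radii_px)")
        if not (0.0 < self.pca_var_fraction <= 1.0):
            raise ValueError("pca_var_fraction must be in (0, 1]")
        lo, hi = self.tomogram_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("tomogram_range must be an increasing pair within [0, 1]")
        if self.analysis_spacing_um <= 0:
            raise ValueError("analysis_spacing_um must be positive")
        if self.n_laminates < 1 or self.tomogram_intervals < 1:
            raise ValueError("bin counts must be >= 1")

    @classmethod
    def mouse_profile(cls, **overrides) -> "RunConfig":
        """Mouse analysis profile: smaller radial units (k = 50)."""
        overrides.setdefault("knn_k", 50)
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("opening_radii_px", "tomogram_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["opening_radii_px"] = list(self.opening_radii_px)
        data["tomogram_range"] = list(self.tomogram_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
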