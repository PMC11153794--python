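"""End-to-end orchestration: graded volume + cortex mask -> parcellation.

Chains the coordinate system (Laplace potential, streamline depth,
mid-surface, KNN radial units), density counting, laminar feature
extraction, PCA reduction, K-means initialization and MRF refinement. Each
stage's output is kept on the result object so tests and scripts can
inspect intermediates.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

logger = logging.getLogger("cytotome")

from .clustering import (
    ParcelLabels, ReducedScores, UnitAdjacency, build_adjacency, kmeans_init,
    mrf_refine, pca_reduce,
)
from .config import RunConfig
from .coords import (
    DepthField, GradientField, MidSurface, PotentialField, RadialUnitSet,
    build_radial_units, compute_depth, gradient_field, solve_laplace,
)
from .features import (
    DensityGrid, SignalMatrix, assemble_features, compute_signal_matrices,
    cube_density,
)
from .mask import CortexMask
from .volume import ImageVolume


@dataclass
class CoordinateSystem:
    potential: PotentialField
    gradient: GradientField
    depth: DepthField
    surface: MidSurface
    units: RadialUnitSet


@dataclass
class ParcellationResult:
    coords: CoordinateSystem
    density: DensityGrid
    signals: List[SignalMatrix]
    features: np.ndarray
    scores: ReducedScores
    adjacency: UnitAdjacency
    init_labels: ParcelLabels
    labels: ParcelLabels


def _log_stage(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall_s=%.2f %s", stage, time.perf_counter() - t0, extras)


def build_coordinates(mask: CortexMask, config: RunConfig) -> CoordinateSystem:
    t0 = time.perf_counter()
    potential = solve_laplace(
        mask,
        u_outer=config.potential_outer,
        u_inner=config.potential_inner,
        tol=config.laplace_tol,
        max_iter=config.laplace_max_iter,
    )
    _log_stage("laplace", t0, cortex_voxels=int(mask.cortex.sum()),
               residual=f"{potential.residual:.2e}")
    t0 = time.perf_counter()
    grad = gradient_field(potential, mask)
    step = config.streamline_step_frac * mask.spacing_um
    depth, surface = compute_depth(mask, grad, step_um=step)
    units = build_radial_units(surface, config.knn_k)
    _log_stage("coordinates", t0, surface_voxels=surface.n_ids, k=units.k)
    return CoordinateSystem(
        potential=potential, gradient=grad, depth=depth, surface=surface,
        units=units,
    )


def run_parcellation(
    graded: ImageVolume,
    mask: CortexMask,
    config: Optional[RunConfig] = None,
    coords: Optional[CoordinateSystem] = None,
    n_clusters: Optional[int] = None,
) -> ParcellationResult:
    """Run the full analysis on an already-graded volume.

    ``coords`` may be passed in to reuse a solved coordinate system (for
    example when sweeping the radial-unit size k).
    """
    config = config or RunConfig()
    if coords is None:
        coords = build_coordinates(mask, config)
    t0 = time.perf_counter()
    density = cube_density(
        graded, cube_um=config.analysis_spacing_um, n_grades=config.n_grades
    )
    if density.fractions.shape[1:] != mask.labels.shape:
        raise ValueError(
            f"density grid {density.fractions.shape[1:]} does not align with "
            f"mask grid {mask.labels.shape}"
        )
    signals = compute_signal_matrices(
        coords.units, coords.depth, density, n_laminates=config.n_laminates
    )
    features = assemble_features(coords.units, signals)
    scores = pca_reduce(features, var_fraction=config.pca_var_fraction)
    adjacency = build_adjacency(coords.units)
    K = n_clusters if n_clusters is not None else config.n_clusters
    init = kmeans_init(
        scores, K, seed=config.rng_seed, n_init=config.kmeans_n_init
    )
    labels = mrf_refine(
        init, scores, adjacency, beta=config.mrf_beta,
        max_sweeps=config.mrf_max_sweeps,
    )
    _log_stage(
        "parcellation", t0, units=coords.units.n_units,
        pcs=scores.n_components,
        parcels=int(len(np.unique(labels.labels))),
    )
    return ParcellationResult(
        coords=coords, density=density, signals=signals, features=features,
        scores=scores, adjacency=adjacency, init_labels=init, labels=labels,
    )
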