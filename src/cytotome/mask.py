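"""Cortex mask validation, repair and boundary labelling.

The cortical coordinate system needs a gray-matter mask that is a single
26-connected component with no internal cavities and no handles ("rings"),
bounded by two labelled interface shells: the layer-I/II interface (outer)
and the GM/WM interface (inner). This module checks that topology contract,
performs the safe repairs (largest component, cavity fill), and splits the
cortex-adjacent background into outer/inner boundary labels by geodesic
proximity to user-provided seed regions.

Digital topology conventions: foreground 26-connectivity, background
6-connectivity (the standard complementary pair). The reported Euler
characteristic is that of the mask's *boundary surface* (2 for a ball,
0 for a torus), computed as twice the Euler characteristic of the cubical
complex; the genus estimate assumes each component/cavity boundary is an
orientable closed surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

# label values of a CortexMask volume
BACKGROUND = 0
CORTEX = 1
OUTER_BOUNDARY = 2
INNER_BOUNDARY = 3

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class CortexMask:
    """Labelled analysis-grid volume: 0 background, 1 cortex, 2 outer
    (layer-I/II) boundary, 3 inner (GM/WM) boundary; isotropic spacing in
    micrometres."""

    labels: np.ndarray
    spacing_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def cortex(self) -> np.ndarray:
        return self.labels == CORTEX

    @property
    def outer(self) -> np.ndarray:
        return self.labels == OUTER_BOUNDARY

    @property
    def inner(self) -> np.ndarray:
        return self.labels == INNER_BOUNDARY


@dataclass
class TopologyReport:
    n_components: int
    n_cavities: int
    euler_characteristic: int  # of the boundary surface (2 = sphere)
    estimated_genus: int
    passed: bool


def _euler_characteristic_solid(mask: np.ndarray) -> int:
    """V - E + F - C of the cubical complex spanned by foreground voxels.

    A vertex/edge/face of the complex is present iff any incident voxel is
    foreground; counted by OR-ing shifted copies of the mask on staggered
    grids (vectorized, exact).
    """
    m = np.asarray(mask, dtype=bool)
    cubes = int(m.sum())

    def count_or(shifts: Tuple[Tuple[int, int, int], ...]) -> int:
        shape = tuple(
            s + max(sh[ax] for sh in shifts) for ax, s in enumerate(m.shape)
        )
        acc = np.zeros(shape, dtype=bool)
        for sh in shifts:
            sl = tuple(slice(sh[ax], sh[ax] + m.shape[ax]) for ax in range(3))
            acc[sl] |= m
        return int(acc.sum())

    # vertices: 8 incident voxels
    verts = count_or(tuple((a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)))
    # edges: 4 incident voxels each, 3 orientations
    edges = 0
    for ax in range(3):
        shifts = []
        for a in (0, 1):
            for b in (0, 1):
                sh = [0, 0, 0]
                others = [i for i in range(3) if i != ax]
                sh[others[0]] = a
                sh[others[1]] = b
                shifts.append(tuple(sh))
        edges += count_or(tuple(shifts))
    # faces: 2 incident voxels each, 3 orientations
    faces = 0
    for ax in range(3):
        sh = [0, 0, 0]
        sh[ax] = 1
        faces += count_or(((0, 0, 0), tuple(sh)))
    return verts - edges + faces - cubes


def _count_cavities(mask: np.ndarray) -> int:
    """Background 6-components not connected to the volume border."""
    bg = ~np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(bg, structure=_STRUCT_6)
    if n == 0:
        return 0
    border = np.zeros(mask.shape, dtype=bool)
    for ax in range(3):
        sl: list = [slice(None)] * 3
        sl[ax] = 0
        border[tuple(sl)] = True
        sl[ax] = -1
        border[tuple(sl)] = True
    touching = np.unique(labels[border & bg])
    return int(n - len(touching[touching > 0]))


def validate_mask(mask: CortexMask | np.ndarray) -> TopologyReport:
    """Check the contiguous / no-cavity / no-ring contract of the cortex."""
    cortex = mask.cortex if isinstance(mask, CortexMask) else np.asarray(mask, bool)
    if not cortex.any():
        raise ValueError("empty cortex mask")
    _, n_components = ndimage.label(cortex, structure=_STRUCT_26)
    n_cavities = _count_cavities(cortex)
    chi_solid = _euler_characteristic_solid(cortex)
    genus = n_components + n_cavities - chi_solid
    passed = n_components == 1 and n_cavities == 0 and genus == 0
    return TopologyReport(
        n_components=int(n_components),
        n_cavities=int(n_cavities),
        euler_characteristic=int(2 * chi_solid),
        estimated_genus=int(genus),
        passed=passed,
    )


def repair_mask(mask: CortexMask) -> Tuple[CortexMask, TopologyReport]:
    """Keep the largest cortex component and fill internal cavities.

    Handles (genus > 0) are reported, not repaired — cutting or filling a
    ring is an anatomical judgement, not a safe automatic fix.
    """
    cortex = mask.cortex
    labels, n = ndimage.label(cortex, structure=_STRUCT_26)
    if n == 0:
        raise ValueError("empty cortex mask")
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        cortex = labels == keep
    filled = ndimage.binary_fill_holes(cortex, structure=_STRUCT_6)
    out = np.where(filled, CORTEX, BACKGROUND).astype(mask.labels.dtype)
    # keep prior boundary labels where they do not collide with new cortex
    for val in (OUTER_BOUNDARY, INNER_BOUNDARY):
        out[(mask.labels == val) & ~filled] = val
    repaired = CortexMask(labels=out, spacing_um=mask.spacing_um)
    return repaired, validate_mask(repaired)


def derive_boundaries(
    cortex: np.ndarray,
    outer_seed: np.ndarray,
    inner_seed: np.ndarray,
    spacing_um: float = 1.0,
) -> CortexMask:
    """Label every cortex-adjacent background voxel outer or inner.

    Assignment is by geodesic distance *through the background* to the seed
    regions, so that closely spaced sulcal banks cannot leak a label across
    the gray matter: the path must go around, never through, the cortex.
    Ties go to the outer side (deterministic).
    """
    cortex = np.asarray(cortex, dtype=bool)
    outer_seed = np.asarray(outer_seed, dtype=bool)
    inner_seed = np.asarray(inner_seed, dtype=bool)
    if (outer_seed & cortex).any() or (inner_seed & cortex).any():
        raise ValueError("seeds must be disjoint from the cortex")
    if (outer_seed & inner_seed).any():
        raise ValueError("outer and inner seeds overlap")

    shell = ndimage.binary_dilation(cortex, structure=_STRUCT_26) & ~cortex

    from skimage.graph import MCP_Geometric

    costs = np.where(cortex, np.inf, 1.0)
    dists = []
    for seed in (outer_seed, inner_seed):
        if not seed.any():
            raise ValueError("empty boundary seed")
        mcp = MCP_Geometric(costs)
        d, _ = mcp.find_costs(np.argwhere(seed))
        dists.append(d)
    d_outer, d_inner = dists
    both_unreachable = shell & ~np.isfinite(d_outer) & ~np.isfinite(d_inner)
    if both_unreachable.any():
        raise ValueError(
            f"{int(both_unreachable.sum())} cortex-adjacent voxels reach no seed"
        )
    labels = np.zeros(cortex.shape, dtype=np.uint8)
    labels[cortex] = CORTEX
    labels[shell & (d_outer <= d_inner)] = OUTER_BOUNDARY
    labels[shell & (d_outer > d_inner)] = INNER_BOUNDARY
    return CortexMask(labels=labels, spacing_um=spacing_um)
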