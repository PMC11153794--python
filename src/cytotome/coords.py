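"""The cortical coordinate system.

Cortical laminae are locally parallel surfaces and cortical columns run
perpendicular to them, so the cortex between its two interfaces is modelled
with Laplace's equation: the layer-I/II interface is held at potential 0,
the GM/WM interface at 2000, and the harmonic interpolant in between yields
nested isopotential laminae. Integral curves of the potential gradient
(streamlines) run from the outer to the inner interface; arc length along a
voxel's streamline gives cortical thickness, the normalized position gives
relative depth (0 = outer, 1 = inner), and the arc-length midpoints form the
mid-thickness surface whose voxels — each with a unique lateral ID — are the
lateral coordinate. Radial units group each surface voxel with its k nearest
surface voxels (Euclidean, physical coordinates) and the full streamlines
hanging off them.

All tie-breaks are lexicographic in (z, y, x); the solver and tracer are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import cg, spsolve

from .mask import CortexMask, CORTEX, OUTER_BOUNDARY, INNER_BOUNDARY


class ConvergenceError(RuntimeError):
    pass


class ConnectivityError(ValueError):
    pass


# --------------------------------------------------------------------------
# Laplace potential
# --------------------------------------------------------------------------

@dataclass
class PotentialField:
    """Solved Laplace potential on the cortex (NaN elsewhere)."""

    u: np.ndarray
    u_outer: float
    u_inner: float
    residual: float
    spacing_um: float


_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def solve_laplace(
    mask: CortexMask,
    u_outer: float = 0.0,
    u_inner: float = 2000.0,
    tol: float = 1e-3,
    max_iter: int = 10_000,
) -> PotentialField:
    """Solve the discrete Dirichlet problem on the cortex voxels.

    6-neighbour Laplacian; cortex neighbours couple, boundary-labelled
    neighbours impose their fixed value *at the shared voxel face* through a
    ghost reflection (u_ghost = 2 g - u_P), so the physical interface sits
    half a voxel outside the outermost cortex voxels — consistent with the
    streamline depth convention and second-order accurate for flat
    interfaces. Unlabelled background neighbours are dropped from the
    stencil (homogeneous Neumann). The SPD system is solved by
    preconditioned conjugate gradients; ``tol`` bounds the final max-norm
    residual of the stencil equations (same meaning as a relaxation
    solver's max update at convergence).
    """
    labels = mask.labels
    cortex = labels == CORTEX
    n = int(cortex.sum())
    if n == 0:
        raise ValueError("mask has no cortex voxels")
    idx_of = -np.ones(labels.shape, dtype=np.int64)
    idx_of[cortex] = np.arange(n)
    coords = np.argwhere(cortex)

    fixed = np.full(labels.shape, np.nan)
    fixed[labels == OUTER_BOUNDARY] = u_outer
    fixed[labels == INNER_BOUNDARY] = u_inner

    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    diag = np.zeros(n)
    rhs = np.zeros(n)
    shape = labels.shape
    for off in _OFFSETS:
        nb = coords + off
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_clipped = np.clip(nb, 0, np.array(shape) - 1)
        nb_idx = idx_of[tuple(nb_clipped.T)]
        nb_fixed = fixed[tuple(nb_clipped.T)]
        is_cortex = inside & (nb_idx >= 0)
        is_fixed = inside & np.isfinite(nb_fixed)
        # ghost reflection for Dirichlet faces: neighbour term 2g - u_P
        diag += is_cortex.astype(float) + 2.0 * is_fixed.astype(float)
        rows.append(np.flatnonzero(is_cortex))
        cols.append(nb_idx[is_cortex])
        vals.append(-np.ones(int(is_cortex.sum())))
        rhs[is_fixed] += 2.0 * nb_fixed[is_fixed]

    if (diag == 0).any():
        raise ConnectivityError("isolated cortex voxels with no stencil neighbours")

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    x0 = np.full(n, 0.5 * (u_outer + u_inner))
    if n <= 4000:
        x = spsolve(A.tocsc(), rhs)
        info = 0
    else:
        from scipy.sparse import diags

        M = diags(1.0 / diag)
        # scale tolerance: cg's atol is on the 2-norm of the residual
        x, info = cg(A, rhs, x0=x0, M=M, rtol=0.0, atol=tol, maxiter=max_iter)
    residual = float(np.abs(A @ x - rhs).max())
    if info != 0 or residual > max(tol, 1e-6 * abs(u_inner - u_outer)):
        raise ConvergenceError(f"Laplace solve did not converge, residual={residual}")

    # a harmonic interpolant cannot leave the range of its boundary data
    lo, hi = min(u_outer, u_inner), max(u_outer, u_inner)
    x = np.clip(x, lo, hi)

    u = np.full(labels.shape, np.nan)
    u[cortex] = x
    u[labels == OUTER_BOUNDARY] = u_outer
    u[labels == INNER_BOUNDARY] = u_inner
    # unreachable check: any cortex voxel at exactly a boundary value with no
    # boundary contact would indicate a disconnected pocket; the maximum
    # principle makes interior values strictly inside (lo, hi) when connected.
    return PotentialField(
        u=u, u_outer=u_outer, u_inner=u_inner, residual=residual,
        spacing_um=mask.spacing_um,
    )


# --------------------------------------------------------------------------
# gradient field
# --------------------------------------------------------------------------

@dataclass
class GradientField:
    """Normalized potential gradient on the cortex, with magnitude and a
    flag volume marking singular (zero-gradient) cortex voxels."""

    direction: np.ndarray  # (3, Z, Y, X), unit vectors, NaN outside cortex
    magnitude: np.ndarray  # (Z, Y, X)
    singular: np.ndarray  # boolean
    spacing_um: float


def gradient_field(potential: PotentialField, mask: CortexMask) -> GradientField:
    """Central differences inside the cortex, one-sided at its edges.

    Missing neighbours (outside cortex and not boundary-labelled) reduce to
    one-sided differences; gradients are scaled by the voxel pitch.
    """
    u = potential.u
    h = potential.spacing_um
    valid = np.isfinite(u)
    grad = np.zeros((3,) + u.shape)
    for ax in range(3):
        fwd = np.full(u.shape, np.nan)
        bwd = np.full(u.shape, np.nan)
        sl_to = [slice(None)] * 3
        sl_from = [slice(None)] * 3
        sl_to[ax] = slice(0, -1)
        sl_from[ax] = slice(1, None)
        fwd[tuple(sl_to)] = u[tuple(sl_from)]
        bwd[tuple(sl_from)] = u[tuple(sl_to)]
        have_f = np.isfinite(fwd)
        have_b = np.isfinite(bwd)
        g = np.zeros(u.shape)
        both = have_f & have_b
        g[both] = (fwd[both] - bwd[both]) / (2 * h)
        only_f = have_f & ~have_b
        g[only_f] = (fwd[only_f] - u[only_f]) / h
        only_b = have_b & ~have_f
        g[only_b] = (u[only_b] - bwd[only_b]) / h
        grad[ax] = g
    mag = np.sqrt((grad**2).sum(axis=0))
    cortex = mask.cortex
    singular = cortex & (mag < 1e-12)
    direction = np.full_like(grad, np.nan)
    ok = valid & (mag > 1e-12)
    for ax in range(3):
        direction[ax][ok] = grad[ax][ok] / mag[ok]
    return GradientField(
        direction=direction, magnitude=mag, singular=singular,
        spacing_um=potential.spacing_um,
    )


# --------------------------------------------------------------------------
# streamline tracing
# --------------------------------------------------------------------------

@dataclass
class Streamline:
    """Ordered outer-to-inner path of one cortical streamline."""

    points_um: np.ndarray  # (n, 3) physical coordinates
    arc_length_um: float
    midpoint_um: np.ndarray  # (3,)
    seed_voxel: Tuple[int, int, int]
    truncated: bool


def _interp_direction(direction: np.ndarray, pts_vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of the (3, Z, Y, X) unit-vector field at
    fractional voxel coordinates (n, 3); NaNs outside cortex are treated as
    zero contribution and the result is renormalized."""
    out = np.zeros_like(pts_vox)
    comp = np.empty_like(pts_vox)
    filled = np.nan_to_num(direction, nan=0.0)
    weight_src = np.isfinite(direction[0]).astype(np.float64)
    coords = pts_vox.T
    for ax in range(3):
        comp[:, ax] = ndimage.map_coordinates(
            filled[ax], coords, order=1, mode="nearest"
        )
    w = ndimage.map_coordinates(weight_src, coords, order=1, mode="nearest")
    ok = w > 1e-6
    out[ok] = comp[ok] / w[ok, None]
    norm = np.linalg.norm(out, axis=1)
    nz = norm > 1e-9
    out[nz] /= norm[nz, None]
    return out


def _march(
    start_vox: np.ndarray,
    direction: np.ndarray,
    inside: np.ndarray,
    sign: float,
    step_vox: float,
    max_steps: int,
    record_paths: bool = False,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Optional[List[np.ndarray]]]:
    """Fixed-step Euler march of many points along +/- the direction field.

    Returns (final positions, arc lengths in voxels, truncated flags,
    optional per-step position history). Points stop when they leave the
    ``inside`` mask (nearest-voxel lookup) or the direction vanishes.
    """
    pos = start_vox.astype(np.float64).copy()
    n = pos.shape[0]
    lengths = np.zeros(n)
    active = np.ones(n, dtype=bool)
    truncated = np.zeros(n, dtype=bool)
    history: Optional[List[np.ndarray]] = [pos.copy()] if record_paths else None
    shape = np.array(inside.shape)
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        d = _interp_direction(direction, pos[idx])
        dead = np.linalg.norm(d, axis=1) < 1e-9
        active[idx[dead]] = False  # singular point: stop without moving
        move = idx[~dead]
        if move.size:
            newpos = pos[move] + sign * step_vox * d[~dead]
            pos[move] = newpos
            lengths[move] += step_vox
            nearest = np.clip(np.rint(newpos).astype(np.int64), 0, shape - 1)
            exited = ~inside[tuple(nearest.T)]
            outside_grid = np.any((newpos < -0.5) | (newpos > shape - 0.5), axis=1)
            active[move[exited | outside_grid]] = False
        if record_paths:
            history.append(pos.copy())  # type: ignore[union-attr]
    truncated[active] = True
    return pos, lengths, truncated, history


def _max_steps(shape: Tuple[int, ...], step_vox: float) -> int:
    return int(4 * sum(shape) / step_vox) + 10


def trace_streamline(
    seed_voxel: Tuple[int, int, int],
    grad: GradientField,
    mask: CortexMask,
    step_um: Optional[float] = None,
) -> Streamline:
    """Trace one streamline through a seed voxel, outer to inner.

    The normalized gradient is integrated with fixed-step Euler and
    trilinear interpolation: descending (against the gradient) to the outer
    interface and ascending to the inner one; the two half-paths are
    concatenated in outer-to-inner order.
    """
    h = grad.spacing_um
    step_um = 0.5 * h if step_um is None else step_um
    step_vox = step_um / h
    inside = mask.cortex
    if not inside[tuple(seed_voxel)]:
        raise ValueError(f"seed {seed_voxel} is not a cortex voxel")
    seed = np.array([seed_voxel], dtype=np.float64)
    max_steps = _max_steps(inside.shape, step_vox)
    down_pos, down_len, down_tr, down_hist = _march(
        seed, grad.direction, inside, -1.0, step_vox, max_steps, record_paths=True
    )
    up_pos, up_len, up_tr, up_hist = _march(
        seed, grad.direction, inside, +1.0, step_vox, max_steps, record_paths=True
    )
    down_path = [h * p[0] for p in down_hist]  # type: ignore[index]
    up_path = [h * p[0] for p in up_hist]  # type: ignore[index]
    # outer->inner: reversed descent then ascent (skip duplicated seed)
    pts = np.array(down_path[::-1] + up_path[1:])
    # drop repeated trailing points from inactive steps
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    arc = float((down_len[0] + up_len[0]) * h)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    mid = pts[np.searchsorted(cum, cum[-1] / 2.0)] if len(pts) > 1 else pts[0]
    return Streamline(
        points_um=pts,
        arc_length_um=arc,
        midpoint_um=mid,
        seed_voxel=tuple(int(v) for v in seed_voxel),
        truncated=bool(down_tr[0] or up_tr[0]),
    )


# --------------------------------------------------------------------------
# depth / thickness and mid-surface
# --------------------------------------------------------------------------

@dataclass
class DepthField:
    """Relative depth in [0, 1] on cortex voxels (0 = layer-I/II interface,
    1 = GM/WM interface) plus streamline thickness in micrometres."""

    depth: np.ndarray
    thickness_um: np.ndarray
    truncated: np.ndarray  # voxels whose streamline hit the step budget


@dataclass
class MidSurface:
    """Mid-thickness surface voxels with unique lateral IDs.

    ``voxels[i]`` is the (z, y, x) coordinate of surface voxel ID i (IDs
    contiguous from 0, lexicographic voxel order); ``id_of`` maps every
    cortex voxel to the ID of its streamline's midpoint voxel (-1 outside
    the cortex)."""

    voxels: np.ndarray  # (n_ids, 3) int
    id_of: np.ndarray  # (Z, Y, X) int, -1 outside cortex
    spacing_um: float

    @property
    def n_ids(self) -> int:
        return len(self.voxels)

    def centers_um(self) -> np.ndarray:
        return self.voxels * self.spacing_um


def compute_depth(
    mask: CortexMask,
    grad: GradientField,
    step_um: Optional[float] = None,
) -> Tuple[DepthField, MidSurface]:
    """Depth, thickness and mid-surface for every cortex voxel at once.

    Three vectorized marches: down to the outer interface (length L_out),
    up to the inner (L_in); depth = L_out / (L_out + L_in), thickness =
    L_out + L_in. A third, fixed-distance march from each seed locates the
    arc-length midpoint, whose nearest cortex voxel becomes the seed's
    mid-surface voxel. Truncated streamlines inherit depth from the nearest
    valid voxel and are flagged.
    """
    h = grad.spacing_um
    step_um = 0.5 * h if step_um is None else step_um
    step_vox = step_um / h
    inside = mask.cortex
    seeds = np.argwhere(inside)
    max_steps = _max_steps(inside.shape, step_vox)

    _, len_out, tr_out, _ = _march(
        seeds.astype(float), grad.direction, inside, -1.0, step_vox, max_steps
    )
    _, len_in, tr_in, _ = _march(
        seeds.astype(float), grad.direction, inside, +1.0, step_vox, max_steps
    )
    total = len_out + len_in
    bad = tr_out | tr_in | (total <= 0)
    depth_vals = np.full(len(seeds), np.nan)
    depth_vals[~bad] = len_out[~bad] / total[~bad]

    depth = np.full(inside.shape, np.nan)
    thickness = np.full(inside.shape, np.nan)
    truncated = np.zeros(inside.shape, dtype=bool)
    depth[tuple(seeds.T)] = depth_vals
    thickness[tuple(seeds.T)] = np.where(bad, np.nan, total * h)
    truncated[tuple(seeds.T)] = bad

    if bad.any() and (~bad).any():
        # impute from nearest valid cortex voxel
        good_idx = np.flatnonzero(~bad)
        from scipy.spatial import cKDTree

        tree = cKDTree(seeds[good_idx])
        _, nearest = tree.query(seeds[bad])
        src = good_idx[nearest]
        depth[tuple(seeds[bad].T)] = depth_vals[src]
        thickness[tuple(seeds[bad].T)] = total[src] * h

    # midpoint march: from the seed toward the farther interface for
    # (L_far - L_near) / 2, landing at the arc-length midpoint
    signed = np.where(len_out > len_in, -1.0, 1.0)  # toward the longer side
    travel = np.abs(len_out - len_in) / 2.0
    pos = seeds.astype(np.float64).copy()
    remaining = travel.copy()
    max_iters = int(np.ceil(remaining.max() / step_vox)) + 1 if len(remaining) else 0
    for _ in range(max_iters):
        act = remaining > 1e-9
        if not act.any():
            break
        d = _interp_direction(grad.direction, pos[act])
        s = np.minimum(step_vox, remaining[act])
        pos[act] += signed[act, None] * s[:, None] * d
        remaining[act] -= s

    mid_vox = np.clip(
        np.rint(pos).astype(np.int64), 0, np.array(inside.shape) - 1
    )
    # snap midpoints that rounded outside the cortex to the nearest cortex voxel
    off = ~inside[tuple(mid_vox.T)]
    if off.any():
        from scipy.spatial import cKDTree

        tree = cKDTree(seeds)
        _, nearest = tree.query(mid_vox[off])
        mid_vox[off] = seeds[nearest]

    surf_voxels, inv = np.unique(mid_vox, axis=0, return_inverse=True)
    # np.unique sorts rows lexicographically -> IDs are lexicographic
    id_of = -np.ones(inside.shape, dtype=np.int64)
    id_of[tuple(seeds.T)] = inv
    surface = MidSurface(voxels=surf_voxels, id_of=id_of, spacing_um=h)
    return (
        DepthField(depth=depth, thickness_um=thickness, truncated=truncated),
        surface,
    )


def extract_midsurface(depth_and_surface: Tuple[DepthField, MidSurface]) -> MidSurface:
    """The mid-surface is produced alongside the depth field; this accessor
    exists for pipeline readability."""
    return depth_and_surface[1]


# --------------------------------------------------------------------------
# radial units
# --------------------------------------------------------------------------

@dataclass
class RadialUnitSet:
    """Overlapping KNN groupings of streamlines.

    One unit per mid-surface voxel; ``members[i]`` holds the IDs of the k
    surface voxels nearest unit i's centre (self included). Units map to
    cortex voxels through ``MidSurface.id_of``.
    """

    surface: MidSurface
    members: np.ndarray  # (n_units, k) int
    k: int

    @property
    def n_units(self) -> int:
        return len(self.members)

    def unit_center_um(self, i: int) -> np.ndarray:
        return self.surface.voxels[i] * self.surface.spacing_um

    def unit_voxel_mask(self, i: int) -> np.ndarray:
        """Boolean cortex-voxel mask of unit i (union of member streamlines)."""
        return np.isin(self.surface.id_of, self.members[i])


def build_radial_units(surface: MidSurface, k: int) -> RadialUnitSet:
    """KNN grouping of mid-surface voxels in physical coordinates.

    k is clamped (with a warning) to the surface size; ties at the k-th
    distance are broken by lexicographic voxel order (via stable ordering of
    the sorted candidate list).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = surface.n_ids
    if k > n:
        import warnings

        warnings.warn(f"k={k} exceeds surface size {n}; clamped", stacklevel=2)
        k = n
    from sklearn.neighbors import NearestNeighbors

    pts = surface.centers_um().astype(np.float64)
    nn = NearestNeighbors(n_neighbors=k, algorithm="kd_tree").fit(pts)
    _, idx = nn.kneighbors(pts)
    return RadialUnitSet(surface=surface, members=idx.astype(np.int64), k=k)
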