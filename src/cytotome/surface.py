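"""Surface-based tomograms and parcel maps.

Cytoarchitectonic signals live on the mid-thickness surface: for each cell
size grade, mean cube densities are computed per radial unit within nine
equal depth intervals spanning relative depths 5%–95% and painted on the
unit-centre vertices (the tomogram array); parcellation labels are painted
the same way. Export formats are ASCII PLY and legacy-VTK polydata with
per-vertex scalars, plus a PNG montage of the grades x intervals panel
grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .coords import DepthField, MidSurface, RadialUnitSet
from .clustering import ParcelLabels
from .features import DensityGrid, _impute_empty


@dataclass
class SurfaceMap:
    """One value per mid-thickness surface vertex."""

    surface: MidSurface
    values: np.ndarray  # (n_vertices,)
    name: str = "scalar"


@dataclass
class TomogramArray:
    """Per-vertex maps over (grade, depth interval) pairs.

    ``maps[g, l]`` is the vertex map of grade g+1 in depth interval l; the
    ``interval_edges`` equally divide the configured depth range.
    """

    maps: np.ndarray  # (n_grades, n_intervals, n_vertices)
    interval_edges: np.ndarray  # (n_intervals + 1,)
    surface: MidSurface

    @property
    def n_grades(self) -> int:
        return self.maps.shape[0]

    @property
    def n_intervals(self) -> int:
        return self.maps.shape[1]


def depth_interval_maps(
    units: RadialUnitSet,
    depth: DepthField,
    grid: DensityGrid,
    n_intervals: int = 9,
    depth_range: Tuple[float, float] = (0.05, 0.95),
) -> TomogramArray:
    """Mean grade density per unit within each equal depth interval.

    Interval l covers ``[lo + w*l, lo + w*(l+1))`` with
    ``w = (hi - lo) / n_intervals`` (the last interval closed at ``hi``);
    depths outside [lo, hi] are excluded. Intervals empty within a unit are
    imputed from the nearest populated interval, as in the laminar signals.
    """
    lo, hi = depth_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("depth_range must be increasing within [0, 1]")
    edges = np.linspace(lo, hi, n_intervals + 1)
    width = (hi - lo) / n_intervals

    id_of = units.surface.id_of
    d = depth.depth
    valid = (id_of >= 0) & np.isfinite(d) & (d >= lo) & (d <= hi)
    ids = id_of[valid]
    iv = np.minimum(((d[valid] - lo) / width).astype(np.int64), n_intervals - 1)

    n_ids = units.surface.n_ids
    g = grid.n_grades
    sums = np.zeros((n_ids, n_intervals, g))
    counts = np.zeros((n_ids, n_intervals), dtype=np.int64)
    np.add.at(counts, (ids, iv), 1)
    for gi in range(g):
        np.add.at(sums[:, :, gi], (ids, iv), grid.fractions[gi][valid])

    n_units = units.n_units
    maps = np.zeros((g, n_intervals, n_units))
    for i, members in enumerate(units.members):
        s = sums[members].sum(axis=0)
        c = counts[members].sum(axis=0)
        vals = np.zeros_like(s)
        nz = c > 0
        vals[nz] = s[nz] / c[nz, None]
        _impute_empty(vals, c)
        maps[:, :, i] = vals.T
    return TomogramArray(maps=maps, interval_edges=edges, surface=units.surface)


def parcel_map(labels: ParcelLabels, surface: MidSurface) -> SurfaceMap:
    """Per-vertex cluster label (every vertex is a unit centre)."""
    if len(labels.labels) != surface.n_ids:
        raise ValueError(
            f"{len(labels.labels)} labels for {surface.n_ids} surface vertices"
        )
    return SurfaceMap(
        surface=surface, values=labels.labels.astype(np.float64), name="parcel"
    )


# --------------------------------------------------------------------------
# mesh / image export
# --------------------------------------------------------------------------

def _surface_faces(surface: MidSurface) -> np.ndarray:
    """Cosmetic triangulation from 26-adjacency of surface voxels: one
    triangle per voxel triple that is mutually 26-adjacent (deduplicated).
    The per-vertex scalars are the authoritative data."""
    from scipy.spatial import cKDTree

    vox = surface.voxels.astype(np.float64)
    tree = cKDTree(vox)
    pairs = tree.query_pairs(r=np.sqrt(3.0) + 1e-6, output_type="ndarray")
    nbrs: List[set] = [set() for _ in range(len(vox))]
    for a, b in pairs:
        nbrs[a].add(int(b))
        nbrs[b].add(int(a))
    faces = set()
    for a in range(len(vox)):
        na = sorted(x for x in nbrs[a] if x > a)
        for i, b in enumerate(na):
            for c in na[i + 1 :]:
                if c in nbrs[b]:
                    faces.add((a, b, c))
    return np.array(sorted(faces), dtype=np.int64).reshape(-1, 3)


def _write_ply(path: Path, verts: np.ndarray, scalars: np.ndarray,
               faces: Optional[np.ndarray], name: str) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"property float {name}\n")
        nfaces = 0 if faces is None else len(faces)
        fh.write(f"element face {nfaces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, s in zip(verts, scalars):
            fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g} {s:.6g}\n")
        if faces is not None:
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _write_vtk(path: Path, verts: np.ndarray, scalars: np.ndarray,
               faces: Optional[np.ndarray], name: str) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncytotome surface map\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(verts)} float\n")
        for v in verts:
            fh.write(f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}\n")
        if faces is not None and len(faces):
            fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for f in faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        fh.write(f"POINT_DATA {len(verts)}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for s in scalars:
            fh.write(f"{np.float32(s):.9g}\n")


def read_vtk_scalars(path: str | Path) -> Tuple[np.ndarray, np.ndarray]:
    """Read back points and per-vertex scalars from a legacy-VTK polydata
    file written by :func:`export_surface` (round-trip testing aid)."""
    lines = Path(path).read_text().splitlines()
    pts: List[List[float]] = []
    scal: List[float] = []
    i = 0
    while i < len(lines):
        t = lines[i].split()
        if t[:1] == ["POINTS"]:
            n = int(t[1])
            for j in range(n):
                pts.append([float(x) for x in lines[i + 1 + j].split()])
            i += n
        elif t[:1] == ["SCALARS"]:
            i += 1  # skip LOOKUP_TABLE
            n = len(pts)
            for j in range(n):
                scal.append(float(lines[i + 1 + j]))
            i += n
        i += 1
    return np.array(pts), np.array(scal)


def export_surface(
    obj: "SurfaceMap | TomogramArray",
    path: str | Path,
    fmt: str = "ply",
    with_faces: bool = True,
    normalize: str = "per_map",
) -> List[Path]:
    """Write a surface map (PLY/VTK) or a tomogram array (PNG montage, or
    one PLY/VTK per map).

    ``normalize`` for the montage: ``per_map`` rescales each (grade,
    interval) panel to its own maximum, ``per_grade`` shares the scale
    within a grade row.
    """
    path = Path(path)
    if fmt not in {"ply", "vtk", "png"}:
        raise ValueError(f"unsupported format: {fmt}")
    written: List[Path] = []

    if isinstance(obj, SurfaceMap):
        if fmt == "png":
            raise ValueError("png export applies to tomogram arrays")
        verts = obj.surface.centers_um().astype(np.float64)[:, ::-1]  # x,y,z
        faces = _surface_faces(obj.surface) if with_faces else None
        writer = _write_ply if fmt == "ply" else _write_vtk
        writer(path, verts, obj.values, faces, obj.name)
        written.append(path)
        return written

    if isinstance(obj, TomogramArray):
        if fmt == "png":
            written.append(_montage_png(obj, path, normalize))
            return written
        surface = obj.surface
        for g in range(obj.n_grades):
            for l in range(obj.n_intervals):
                # tomogram vertex values live at unit centres = surface voxels
                m = SurfaceMap(
                    surface=surface,
                    values=obj.maps[g, l],
                    name=f"grade{g + 1}_interval{l}",
                )
                p = path.with_name(f"{path.stem}_g{g + 1}_i{l}{path.suffix}")
                written += export_surface(m, p, fmt=fmt, with_faces=with_faces)
        return written
    raise TypeError(f"cannot export {type(obj)!r}")


def _montage_png(tomo: TomogramArray, path: Path, normalize: str) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # lay vertices out on their (y, x) lateral grid for display
    vox = tomo.surface.voxels
    y0, x0 = vox[:, 1].min(), vox[:, 2].min()
    H = vox[:, 1].max() - y0 + 1
    W = vox[:, 2].max() - x0 + 1
    g, n_iv = tomo.n_grades, tomo.n_intervals
    fig, axes = plt.subplots(g, n_iv, figsize=(1.2 * n_iv, 1.2 * g), squeeze=False)
    for gi in range(g):
        row_max = tomo.maps[gi].max() if normalize == "per_grade" else None
        for l in range(n_iv):
            img = np.full((H, W), np.nan)
            img[vox[:, 1] - y0, vox[:, 2] - x0] = tomo.maps[gi, l]
            vmax = row_max if row_max else max(tomo.maps[gi, l].max(), 1e-12)
            ax = axes[gi][l]
            ax.imshow(img, vmin=0, vmax=vmax, cmap="magma")
            ax.set_axis_off()
    fig.tight_layout(pad=0.1)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
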