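"""Voxelized deposition maps and planar projections.

To mimic gamma scintigraphy, the per-segment deposition solution is
mapped onto a 3-D grid of isotropic voxels (5 mm by default).  Each
voxel whose center lies inside a segment's cylinder shares that
segment's capture probability uniformly (voxels straddling a junction
belong to the deeper-generation segment); a segment too thin to contain
any voxel center deposits its whole mass in the voxel holding its
midpoint, so probability is conserved exactly.  Mass escaping through a
terminal segment is spread uniformly over a 3x3x3 cube of voxels at the
segment's distal end; overlapping cubes accumulate.

The coronal projection integrates the grid along the ventral–dorsal
(y) axis and reports probability per unit projected area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .markov import DepositionResult
from .tree import AirwayTree

__all__ = ["VoxelGrid", "CoronalProjection", "voxelize", "coronal_projection",
           "write_projection_csv", "write_projection_png"]


@dataclass(frozen=True)
class VoxelGrid:
    origin: np.ndarray  # (3,) m, corner of voxel [0,0,0]
    edge: float  # m
    values: np.ndarray  # (nx, ny, nz) probability per voxel

    def total(self) -> float:
        return float(self.values.sum())

    def voxel_index(self, point: np.ndarray) -> tuple[int, int, int]:
        i = np.floor((np.asarray(point) - self.origin) / self.edge).astype(int)
        i = np.clip(i, 0, np.array(self.values.shape) - 1)
        return tuple(int(v) for v in i)


@dataclass(frozen=True)
class CoronalProjection:
    values: np.ndarray  # (nx, nz) probability per unit area
    pixel_edge: float  # m

    def total_probability(self) -> float:
        return float(self.values.sum() * self.pixel_edge ** 2)


def voxelize(tree: AirwayTree, deposition: DepositionResult,
             voxel_edge: float = 0.005) -> VoxelGrid:
    """Distribute a deposition solution over an isotropic voxel grid."""
    if voxel_edge <= 0:
        raise ValueError("voxel edge must be positive")
    pts = np.array([p for seg in tree.segments.values()
                    for p in (seg.start, seg.end)])
    max_r = max(seg.diameter / 2 for seg in tree.segments.values())
    margin = 2.5 * voxel_edge + max_r
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.ceil((hi - lo) / voxel_edge).astype(int) + 1
    values = np.zeros(tuple(shape))
    owner = np.full(tuple(shape), -1, dtype=np.int64)

    # claim voxel centers segment by segment; deeper generations win junctions
    axes = [lo[k] + (np.arange(shape[k]) + 0.5) * voxel_edge for k in range(3)]
    for s in sorted(tree.segments,
                    key=lambda s: tree.segments[s].generation):
        seg = tree.segments[s]
        r = seg.diameter / 2.0
        bb_lo = np.minimum(seg.start, seg.end) - r
        bb_hi = np.maximum(seg.start, seg.end) + r
        sl = []
        for k in range(3):
            i0 = int(np.searchsorted(axes[k], bb_lo[k], side="left"))
            i1 = int(np.searchsorted(axes[k], bb_hi[k], side="right"))
            if i0 >= i1:
                sl = None
                break
            sl.append((i0, i1))
        if sl is None:
            continue
        X, Y, Z = np.meshgrid(axes[0][sl[0][0]:sl[0][1]],
                              axes[1][sl[1][0]:sl[1][1]],
                              axes[2][sl[2][0]:sl[2][1]], indexing="ij")
        P = np.stack([X, Y, Z], axis=-1) - seg.start
        u = seg.direction
        t = P @ u
        radial = np.linalg.norm(P - t[..., None] * u, axis=-1)
        inside = (t >= 0) & (t <= seg.length) & (radial <= r)
        block = owner[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
        block[inside] = s

    # per-segment uniform fill, renormalized so each segment's voxels sum
    # exactly to its capture probability
    for s, cap in deposition.capture.items():
        if cap == 0.0:
            continue
        mask = owner == s
        n = int(mask.sum())
        if n > 0:
            values[mask] += cap / n
        else:
            seg = tree.segments[s]
            mid = (seg.start + seg.end) / 2.0
            idx = np.clip(np.floor((mid - lo) / voxel_edge).astype(int), 0,
                          shape - 1)
            values[tuple(idx)] += cap

    # escape mass: 3x3x3 cube at each terminal's distal end
    for t_state, esc in deposition.escape_by_terminal.items():
        if esc == 0.0:
            continue
        seg = tree.segments[t_state]
        c = np.clip(np.floor((seg.end - lo) / voxel_edge).astype(int), 1,
                    shape - 2)
        cube = values[c[0] - 1:c[0] + 2, c[1] - 1:c[1] + 2, c[2] - 1:c[2] + 2]
        cube += esc / 27.0

    return VoxelGrid(origin=lo, edge=voxel_edge, values=values)


def coronal_projection(grid: VoxelGrid) -> CoronalProjection:
    """Integrate along the ventral–dorsal (y) axis; per-unit-area pixels."""
    pix = grid.values.sum(axis=1) / grid.edge ** 2
    return CoronalProjection(values=pix, pixel_edge=grid.edge)


def write_projection_csv(proj: CoronalProjection, path) -> None:
    np.savetxt(path, proj.values, delimiter=",")


def write_projection_png(proj: CoronalProjection, path) -> None:
    """16-bit grayscale PNG plus a JSON sidecar with the intensity scale."""
    from PIL import Image

    vmax = float(proj.values.max())
    scale = (65535.0 / vmax) if vmax > 0 else 1.0
    img = (proj.values * scale).astype(np.uint16)
    # image rows are the z axis (head-foot), columns the x axis
    Image.fromarray(img.T[::-1]).save(path)  # uint16 -> 16-bit grayscale
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"pixel_edge_m": proj.pixel_edge,
                   "probability_per_m2_per_count": 1.0 / scale}, fh)
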