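"""Isotropic resampling, boundary-surface graphs and compartment morphometry.

The membrane surface of a compartment is represented as a weighted graph
over its boundary voxels: a voxel belongs to the surface when at least one
of its six face neighbors carries a different label (or lies outside the
volume), and two surface voxels are connected when they are
26-neighbors, with the Euclidean distance between their centers as edge
weight. Geodesic (along-the-membrane) distances are shortest paths in
this graph. On a raster the graph metric overestimates the true surface
distance by a bounded chamfer factor (<~8% in-plane); observed and
randomized particle patterns share the metric, so comparative statistics
are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from skmap.volume_io import LabelVolume, VoxelSpacing

__all__ = [
    "SurfaceGraph",
    "CompartmentMetrics",
    "resample_isotropic",
    "extract_surface",
    "measure_compartment",
    "binarize",
]

# half of the 26-neighborhood: each unordered voxel pair visited once
_HALF_OFFSETS = np.array(
    [
        (dk, dj, di)
        for dk in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for di in (-1, 0, 1)
        if (dk, dj, di) > (0, 0, 0)
    ],
    dtype=int,
)

_FACE_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=int
)


@dataclass
class SurfaceGraph:
    """Boundary-voxel graph of one compartment's membrane surface.

    Nodes are boundary-voxel centers with nm positions (x, y, z) and an
    area weight equal to (number of exposed faces) x (face area); edges
    connect 26-adjacent boundary voxels with positive symmetric Euclidean
    weights.
    """

    compartment_id: int
    voxels: np.ndarray  # (n, 3) int voxel indices (k, j, i)
    positions: np.ndarray  # (n, 3) float nm, columns (x, y, z)
    areas: np.ndarray  # (n,) nm^2, exposed-face area per node
    edges: np.ndarray  # (m, 2) int node index pairs
    weights: np.ndarray  # (m,) nm
    spacing: VoxelSpacing
    _csgraph: sparse.csr_matrix | None = field(default=None, repr=False)
    _kdtree: cKDTree | None = field(default=None, repr=False)
    _dense_dist: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def total_area_nm2(self) -> float:
        return float(self.areas.sum())

    def csgraph(self) -> sparse.csr_matrix:
        """Symmetric sparse adjacency matrix with nm edge weights."""
        if self._csgraph is None:
            n = self.n_nodes
            if len(self.edges):
                i, j = self.edges[:, 0], self.edges[:, 1]
                w = self.weights
                g = sparse.coo_matrix(
                    (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
                    shape=(n, n),
                )
            else:
                g = sparse.coo_matrix((n, n))
            self._csgraph = g.tocsr()
        return self._csgraph

    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.positions)
        return self._kdtree

    def nearest_node(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest surface node for each (x, y, z) point; (distances, indices)."""
        d, idx = self.kdtree().query(np.atleast_2d(points))
        return d, idx

    def geodesic_from(self, sources: np.ndarray) -> np.ndarray:
        """Single/multi-source geodesic distance field, shape (n_sources, n_nodes)."""
        sources = np.atleast_1d(np.asarray(sources, dtype=int))
        return dijkstra(self.csgraph(), directed=False, indices=sources)

    def distance_matrix(self, max_nodes: int = 6000) -> np.ndarray:
        """Full node-to-node geodesic matrix, cached; guarded by ``max_nodes``."""
        if self._dense_dist is None:
            if self.n_nodes > max_nodes:
                raise MemoryError(
                    f"surface has {self.n_nodes} nodes, refusing dense matrix > {max_nodes}"
                )
            self._dense_dist = dijkstra(self.csgraph(), directed=False)
        return self._dense_dist

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.csgraph(), directed=False)
        return ncomp == 1


@dataclass(frozen=True)
class CompartmentMetrics:
    """Volume, surface extent and section span of one compartment."""

    compartment_id: int
    volume_um3: float
    surface_area_um2: float
    n_sections_spanned: int
    n_voxels: int


def resample_isotropic(vol: LabelVolume, target: float = 20.0) -> LabelVolume:
    """Block-reduce the x-y plane so voxels become ``target`` nm cubes.

    The acquisition grid is typically 5x5 nm in-plane with 20 nm
    sections; reduction to 20 nm cubes uses a majority vote over each
    block (ties resolved to the lowest label), which preserves thin
    necks better than strided sampling and is deterministic. ``dz`` must
    already equal ``target``; z is never resampled. Labels wholly
    swallowed by the vote disappear (tiny compartments) — callers can
    compare label sets before and after.
    """
    s = vol.spacing
    if s.dz != target:
        raise ValueError(f"dz = {s.dz} must equal target {target} (z is not resampled)")
    fx = target / s.dx
    fy = target / s.dy
    if fx != int(fx) or fy != int(fy):
        raise ValueError(f"target {target} must be an integer multiple of dx={s.dx}, dy={s.dy}")
    fx, fy = int(fx), int(fy)
    if fx == 1 and fy == 1:
        return vol

    nz, ny, nx = vol.shape
    ny2, nx2 = ny // fy, nx // fx
    if ny2 == 0 or nx2 == 0:
        raise ValueError("volume smaller than one output voxel in-plane")
    trimmed = vol.labels[:, : ny2 * fy, : nx2 * fx]
    blocks = trimmed.reshape(nz, ny2, fy, nx2, fx).transpose(0, 1, 3, 2, 4)
    blocks = blocks.reshape(nz, ny2, nx2, fy * fx)
    # scipy.stats.mode returns the smallest modal value on ties
    voted = stats.mode(blocks, axis=-1, keepdims=False).mode
    return LabelVolume(
        labels=voted.astype(vol.labels.dtype),
        spacing=VoxelSpacing(target, target, target),
    )


def binarize(vol: LabelVolume, labels: set[int] | None = None, merged_id: int = 1) -> LabelVolume:
    """Merge the given labels (default: all nonzero) into one compartment.

    Used to analyze a whole dendrite (shaft + spines) as a single
    membrane surface.
    """
    if labels is None:
        mask = vol.labels > 0
    else:
        mask = np.isin(vol.labels, list(labels))
    return LabelVolume(
        labels=np.where(mask, merged_id, 0).astype(np.int32), spacing=vol.spacing
    )


def _boundary_mask(labels: np.ndarray, compartment_id: int) -> tuple[np.ndarray, np.ndarray]:
    """(boundary mask, exposed-face count grid) for one compartment.

    A face is exposed when the 6-neighbor across it has a different label
    or lies outside the volume.
    """
    mask = labels == compartment_id
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    exposed = np.zeros(labels.shape, dtype=np.int8)
    for dk, dj, di in _FACE_OFFSETS:
        neigh = padded[
            1 + dk : padded.shape[0] - 1 + dk,
            1 + dj : padded.shape[1] - 1 + dj,
            1 + di : padded.shape[2] - 1 + di,
        ]
        exposed += (~neigh) & mask
    return (exposed > 0), exposed


def extract_surface(vol: LabelVolume, compartment_id: int) -> SurfaceGraph:
    """Extract the boundary-voxel surface graph of one compartment.

    Requires an isotropic volume (resample first). Node area is the
    exposed-face count times the face area; this overestimates smooth
    surface area by a known raster bias (x1.5 for a sphere), which
    cancels in the area-weighted randomization because all placements
    share the weighting.
    """
    if not vol.spacing.is_isotropic:
        raise ValueError("surface extraction requires an isotropic volume; resample first")
    labels = vol.labels
    if compartment_id not in vol.label_set():
        raise KeyError(f"label {compartment_id} not present in volume")

    boundary, exposed = _boundary_mask(labels, compartment_id)
    voxels = np.argwhere(boundary)  # (n, 3) as (k, j, i)
    n = len(voxels)
    s = vol.spacing.dx
    positions = np.empty((n, 3), dtype=float)
    positions[:, 0] = (voxels[:, 2] + 0.5) * s  # x
    positions[:, 1] = (voxels[:, 1] + 0.5) * s  # y
    positions[:, 2] = (voxels[:, 0] + 0.5) * s  # z
    areas = exposed[boundary].astype(float) * s * s

    node_id = np.full(labels.shape, -1, dtype=np.int64)
    node_id[tuple(voxels.T)] = np.arange(n)

    edge_list = []
    weight_list = []
    shape = np.array(labels.shape)
    for off in _HALF_OFFSETS:
        neigh = voxels + off
        ok = np.all((neigh >= 0) & (neigh < shape), axis=1)
        src = np.arange(n)[ok]
        dst = node_id[tuple(neigh[ok].T)]
        valid = dst >= 0
        if valid.any():
            edge_list.append(np.column_stack([src[valid], dst[valid]]))
            w = s * float(np.sqrt((off**2).sum()))
            weight_list.append(np.full(valid.sum(), w))
    if edge_list:
        edges = np.concatenate(edge_list)
        weights = np.concatenate(weight_list)
    else:
        edges = np.empty((0, 2), dtype=int)
        weights = np.empty((0,), dtype=float)

    return SurfaceGraph(
        compartment_id=compartment_id,
        voxels=voxels,
        positions=positions,
        areas=areas,
        edges=edges,
        weights=weights,
        spacing=vol.spacing,
    )


def measure_compartment(vol: LabelVolume, compartment_id: int) -> CompartmentMetrics:
    """Volume (μm³), raster surface area (μm²) and z-section span of a label."""
    mask = vol.labels == compartment_id
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise KeyError(f"label {compartment_id} not present in volume")
    volume_um3 = n_vox * vol.spacing.voxel_volume_nm3 * 1e-9
    _, exposed = _boundary_mask(vol.labels, compartment_id)
    if vol.spacing.is_isotropic:
        face = vol.spacing.dx**2
        area_um2 = float(exposed.sum()) * face * 1e-6
    else:
        # anisotropic faces: count per orientation
        area_nm2 = 0.0
        s = vol.spacing
        face_areas = {0: s.dx * s.dy, 1: s.dx * s.dz, 2: s.dy * s.dz}
        padded = np.pad(mask, 1, mode="constant", constant_values=False)
        for dk, dj, di in _FACE_OFFSETS:
            neigh = padded[
                1 + dk : padded.shape[0] - 1 + dk,
                1 + dj : padded.shape[1] - 1 + dj,
                1 + di : padded.shape[2] - 1 + di,
            ]
            axis = 0 if dk else (1 if dj else 2)
            area_nm2 += ((~neigh) & mask).sum() * face_areas[axis]
        area_um2 = area_nm2 * 1e-6
    z_span = int((mask.any(axis=(1, 2))).sum())
    return CompartmentMetrics(
        compartment_id=compartment_id,
        volume_um3=volume_um3,
        surface_area_um2=area_um2,
        n_sections_spanned=z_span,
        n_voxels=n_vox,
    )
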