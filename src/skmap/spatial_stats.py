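"""Geodesic nearest-neighbor statistics, randomness testing, cluster calling
and distance-to-synapse profiling on membrane surface graphs.

The central quantity is the nearest-neighbor distance (NND) between
membrane-bound particles, measured *along the membrane* as a shortest
path in the boundary-voxel surface graph rather than through space.
Whether an observed pattern is clustered is decided against a
Monte-Carlo null: the same number of particles is placed uniformly at
random on the very same membrane (area-weighted over surface nodes), the
mean NND recomputed for each of ``reps`` control placements (100 by
default), and the observed mean compared to that null distribution via a
z-score and an empirical one-sided p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from skmap.surface_model import SurfaceGraph
from skmap.volume_io import LabelVolume, ParticleRecord, SynapseMeta

__all__ = [
    "NNDResult",
    "RandomizationResult",
    "ClusterSet",
    "DistanceProfile",
    "geodesic_distance",
    "nnd_analysis",
    "randomization_test",
    "call_clusters",
    "synapse_profile",
    "project_particles",
    "map_patches_to_surface",
]

#: above this node count the full geodesic matrix is not materialized
DENSE_NODE_LIMIT = 6000


@dataclass
class NNDResult:
    """Per-particle geodesic nearest-neighbor distances with summary stats."""

    nnds: np.ndarray  # nm, one per particle
    mean_nnd: float
    sd_nnd: float  # sample SD (ddof=1)
    n_particles: int
    particle_ids: np.ndarray | None = None
    node_ids: np.ndarray | None = None


@dataclass
class RandomizationResult:
    """Observed mean NND against a Monte-Carlo uniform-placement null.

    ``p_empirical`` is the one-sided add-one estimate
    ``(1 + #{null <= observed}) / (reps + 1)``: small when particles sit
    closer together than random placement explains (clustering).
    ``z_score`` is ``(observed - null_mean) / null_sd``; None for a
    degenerate single-replicate run.
    """

    observed_mean_nnd: float
    null_means: np.ndarray
    null_mean: float
    null_sd: float | None
    z_score: float | None
    p_empirical: float
    reps: int
    seed: int | None


@dataclass
class ClusterSet:
    """Single-linkage grouping of membrane particles at a distance threshold.

    Groups of >= 3 particles are clusters; groups of 1-2 are scattered
    or isolated particles. ``scattered_count`` counts *particles* in
    such small groups.
    """

    clusters: list[list[int]]  # particle ids, groups of size >= 3
    scattered: list[list[int]]  # groups of size 1-2
    threshold_nm: float
    rule: str

    @property
    def sizes(self) -> dict[int, int]:
        """Histogram of cluster sizes (clusters only, size >= 3)."""
        h: dict[int, int] = {}
        for c in self.clusters:
            h[len(c)] = h.get(len(c), 0) + 1
        return h

    @property
    def scattered_count(self) -> int:
        return sum(len(g) for g in self.scattered)

    @property
    def n_clustered_particles(self) -> int:
        return sum(len(c) for c in self.clusters)


@dataclass
class DistanceProfile:
    """Binned distances from membrane particles to the nearest synapse edge.

    Eleven 60-nm bins exactly cover [0, 660) nm by default; proportions
    are over particles within the limit (the within-limit and beyond
    totals are both reported, since either denominator can be of
    interest).
    """

    synapse_type: str
    bin_width: float
    limit: float
    bin_edges: np.ndarray  # len n_bins + 1
    counts: np.ndarray  # per-bin particle counts
    proportions: np.ndarray  # counts / n_within (zeros if empty)
    n_within_limit: int
    n_beyond_limit: int
    distances: np.ndarray = field(repr=False, default=None)

    @property
    def n_total(self) -> int:
        return self.n_within_limit + self.n_beyond_limit


# ---------------------------------------------------------------------------


def geodesic_distance(surface: SurfaceGraph, node_a: int, node_b: int) -> float:
    """Shortest-path (geodesic) distance in nm between two surface nodes.

    Returns ``inf`` when the nodes lie on disconnected surface pieces.
    """
    n = surface.n_nodes
    for node in (node_a, node_b):
        if not (0 <= node < n):
            raise ValueError(f"node {node} not in surface graph of {n} nodes")
    if node_a == node_b:
        return 0.0
    d = surface.geodesic_from(np.array([node_a]))[0]
    return float(d[node_b])


def project_particles(
    particles: list[ParticleRecord], surface: SurfaceGraph
) -> tuple[np.ndarray, np.ndarray]:
    """(node_ids, particle_ids) of PM-classified particles on this surface."""
    nodes, pids = [], []
    for p in particles:
        if p.localization == "PM" and p.nearest_surface_node is not None:
            if surface.compartment_id is None or p.compartment_id in (
                None,
                surface.compartment_id,
            ):
                nodes.append(p.nearest_surface_node)
                pids.append(p.particle_id)
    return np.asarray(nodes, dtype=int), np.asarray(pids, dtype=int)


def _as_nodes(pm_particles, surface) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pm_particles, (list, tuple)) and pm_particles and isinstance(
        pm_particles[0], ParticleRecord
    ):
        return project_particles(list(pm_particles), surface)
    nodes = np.asarray(pm_particles, dtype=int)
    return nodes, np.arange(len(nodes))


def _pairwise_geodesic(surface: SurfaceGraph, nodes: np.ndarray) -> np.ndarray:
    """(n, n) geodesic distance matrix between particle nodes."""
    if surface.n_nodes <= DENSE_NODE_LIMIT:
        full = surface.distance_matrix()
        return full[np.ix_(nodes, nodes)]
    rows = surface.geodesic_from(nodes)  # (n, N)
    return rows[:, nodes]


def _nnd_from_pairwise(pd_mat: np.ndarray) -> np.ndarray:
    m = pd_mat.copy()
    np.fill_diagonal(m, np.inf)
    return m.min(axis=1)


def nnd_analysis(pm_particles, surface: SurfaceGraph) -> NNDResult:
    """Geodesic nearest-neighbor distance of each membrane particle.

    ``pm_particles`` is either a list of PM-classified
    :class:`ParticleRecord` (projected via ``nearest_surface_node``) or
    an array of surface node indices. Needs at least two particles.
    """
    nodes, pids = _as_nodes(pm_particles, surface)
    n = len(nodes)
    if n < 2:
        raise ValueError(f"NND needs >= 2 membrane particles, got {n}")
    nnds = _nnd_from_pairwise(_pairwise_geodesic(surface, nodes))
    if np.isinf(nnds).any():
        warnings.warn("some particles lie on disconnected surface pieces; their NND is inf")
    return NNDResult(
        nnds=nnds,
        mean_nnd=float(np.mean(nnds)),
        sd_nnd=float(np.std(nnds, ddof=1)),
        n_particles=n,
        particle_ids=pids,
        node_ids=nodes,
    )


def randomization_test(
    pm_particles,
    surface: SurfaceGraph,
    reps: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RandomizationResult:
    """Monte-Carlo test of complete spatial randomness on the membrane.

    Each control replicate draws the same number of *distinct* surface
    nodes with probability proportional to node area (approximating a
    uniform draw over the continuous membrane, since boundary voxels
    expose 1-5 faces) and recomputes the mean NND. The observed mean is
    then located within that null distribution.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    nodes, _ = _as_nodes(pm_particles, surface)
    n = len(nodes)
    if n < 2:
        raise ValueError("randomization test needs >= 2 membrane particles")
    if n > surface.n_nodes:
        raise ValueError(
            f"{n} particles exceed {surface.n_nodes} surface nodes; cannot draw distinct nodes"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    weights = surface.areas / surface.areas.sum()
    use_dense = surface.n_nodes <= DENSE_NODE_LIMIT
    if use_dense:
        full = surface.distance_matrix()
        observed = float(np.mean(_nnd_from_pairwise(full[np.ix_(nodes, nodes)])))
    else:
        observed = float(np.mean(_nnd_from_pairwise(_pairwise_geodesic(surface, nodes))))

    null_means = np.empty(reps)
    all_nodes = np.arange(surface.n_nodes)
    for r in range(reps):
        draw = rng.choice(all_nodes, size=n, replace=False, p=weights)
        if use_dense:
            sub = full[np.ix_(draw, draw)]
        else:
            sub = surface.geodesic_from(draw)[:, draw]
        null_means[r] = np.mean(_nnd_from_pairwise(sub))

    null_mean = float(null_means.mean())
    if reps >= 2:
        null_sd = float(null_means.std(ddof=1))
        z = (observed - null_mean) / null_sd if null_sd > 0 else None
    else:
        null_sd = None
        z = None
    p_emp = (1 + int(np.sum(null_means <= observed))) / (reps + 1)
    return RandomizationResult(
        observed_mean_nnd=observed,
        null_means=null_means,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        p_empirical=p_emp,
        reps=reps,
        seed=seed,
    )


def call_clusters(
    pm_particles,
    surface: SurfaceGraph,
    nnd: NNDResult,
    rule: str = "plus2sd",
) -> ClusterSet:
    """Group membrane particles by single linkage at an NND-derived threshold.

    Particles closer (geodesically) than the threshold belong to the
    same group; groups of 3 or more particles are clusters, groups of
    1-2 are scattered/isolated. The default threshold is
    ``mean_nnd + 2 sd_nnd`` (rule ``"plus2sd"``); rule ``"minus2sd"``
    uses ``mean - 2 sd``, which for clustered data (SD > mean/2) is
    typically negative and rejected.
    """
    nodes, pids = _as_nodes(pm_particles, surface)
    if len(nodes) != nnd.n_particles:
        raise ValueError("NND result was computed on a different particle set")
    if rule == "plus2sd":
        threshold = nnd.mean_nnd + 2 * nnd.sd_nnd
    elif rule == "minus2sd":
        threshold = nnd.mean_nnd - 2 * nnd.sd_nnd
    else:
        raise ValueError(f"unknown cluster rule {rule!r}")
    if threshold <= 0:
        raise ValueError(
            f"cluster threshold {threshold:.1f} nm (rule {rule}) is not positive"
        )

    pd_mat = _pairwise_geodesic(surface, nodes)
    adj = sparse.csr_matrix(pd_mat <= threshold)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[int]] = {}
    for pid, lab in zip(pids, labels):
        groups.setdefault(int(lab), []).append(int(pid))
    clusters = sorted((g for g in groups.values() if len(g) >= 3), key=len, reverse=True)
    scattered = sorted((g for g in groups.values() if len(g) < 3), key=len, reverse=True)
    return ClusterSet(
        clusters=clusters, scattered=scattered, threshold_nm=float(threshold), rule=rule
    )


# ---------------------------------------------------------------------------
# synapse distance profiles


def map_patches_to_surface(
    synapse_vol: LabelVolume,
    synapse_meta: list[SynapseMeta],
    surface: SurfaceGraph,
) -> dict[int, np.ndarray]:
    """Surface node indices covered by each painted synapse patch.

    A surface node belongs to a patch when its voxel, or any of its six
    face neighbors, carries the patch id in the synapse volume (patches
    are painted on or immediately against the membrane).
    """
    labels = synapse_vol.labels
    nz, ny, nx = labels.shape
    out: dict[int, np.ndarray] = {}
    vox = surface.voxels
    neigh_offsets = np.array(
        [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    )
    covering = np.zeros((len(vox),), dtype=np.int64)
    for off in neigh_offsets:
        pos = vox + off
        ok = (
            (pos[:, 0] >= 0) & (pos[:, 0] < nz)
            & (pos[:, 1] >= 0) & (pos[:, 1] < ny)
            & (pos[:, 2] >= 0) & (pos[:, 2] < nx)
        )
        vals = np.zeros(len(vox), dtype=labels.dtype)
        vals[ok] = labels[tuple(pos[ok].T)]
        covering = np.where((covering == 0) & (vals > 0), vals, covering)
    for meta in synapse_meta:
        out[meta.patch_id] = np.flatnonzero(covering == meta.patch_id)
    return out


def _patch_edge_nodes(surface: SurfaceGraph, patch_nodes: np.ndarray) -> np.ndarray:
    """Patch nodes adjacent (in the surface graph) to >= 1 non-patch node."""
    in_patch = np.zeros(surface.n_nodes, dtype=bool)
    in_patch[patch_nodes] = True
    if len(surface.edges) == 0:
        return patch_nodes
    i, j = surface.edges[:, 0], surface.edges[:, 1]
    edge_mask = np.zeros(surface.n_nodes, dtype=bool)
    cross = in_patch[i] & ~in_patch[j]
    edge_mask[i[cross]] = True
    cross = in_patch[j] & ~in_patch[i]
    edge_mask[j[cross]] = True
    edge = np.flatnonzero(edge_mask)
    return edge if len(edge) else patch_nodes


def synapse_profile(
    pm_particles,
    patch_nodes_by_id: dict[int, np.ndarray],
    surface: SurfaceGraph,
    synapse_type: str,
    bin_width: float = 60.0,
    limit: float = 660.0,
) -> DistanceProfile:
    """Distances from membrane particles to the nearest synapse *edge*.

    For every particle the geodesic distance to the closest edge node of
    any patch of the given type is recorded (particles lying inside a
    patch get distance 0) and binned in ``bin_width``-nm bins up to
    ``limit`` (60 and 660 nm by default: 11 bins). Proportions are over
    within-limit particles.
    """
    if limit <= 0 or bin_width <= 0 or limit % bin_width:
        raise ValueError("limit must be a positive multiple of bin_width")
    nodes, pids = _as_nodes(pm_particles, surface)
    n_bins = int(round(limit / bin_width))
    edges = np.arange(n_bins + 1) * bin_width

    if not patch_nodes_by_id or all(len(v) == 0 for v in patch_nodes_by_id.values()):
        warnings.warn(f"no {synapse_type} synapse patch on this surface; empty profile")
        return DistanceProfile(
            synapse_type=synapse_type,
            bin_width=bin_width,
            limit=limit,
            bin_edges=edges,
            counts=np.zeros(n_bins, dtype=int),
            proportions=np.zeros(n_bins),
            n_within_limit=0,
            n_beyond_limit=0,
            distances=np.empty(0),
        )

    all_patch = np.unique(np.concatenate([v for v in patch_nodes_by_id.values() if len(v)]))
    edge_nodes = np.unique(
        np.concatenate(
            [_patch_edge_nodes(surface, v) for v in patch_nodes_by_id.values() if len(v)]
        )
    )
    dist_field = surface.geodesic_from(edge_nodes).min(axis=0)  # (N,)
    distances = dist_field[nodes]
    inside = np.isin(nodes, all_patch)
    distances = np.where(inside, 0.0, distances)

    within = distances < limit
    counts, _ = np.histogram(distances[within], bins=edges)
    n_within = int(within.sum())
    proportions = counts / n_within if n_within else np.zeros(n_bins)
    return DistanceProfile(
        synapse_type=synapse_type,
        bin_width=bin_width,
        limit=limit,
        bin_edges=edges,
        counts=counts,
        proportions=proportions,
        n_within_limit=n_within,
        n_beyond_limit=int(len(distances) - n_within),
        distances=distances,
    )
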