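"""Geodesic NND, randomization null, cluster calling and synapse profiles.

The independent oracles here go through networkx shortest paths, a
different code path from the scipy.sparse.csgraph implementation used by
the package.
"""

import networkx as nx
import numpy as np
import pytest

from skmap.spatial_stats import (
    call_clusters,
    geodesic_distance,
    map_patches_to_surface,
    nnd_analysis,
    randomization_test,
    synapse_profile,
    NNDResult,
)
from skmap.surface_model import extract_surface
from skmap.volume_io import LabelVolume, SynapseMeta

from conftest import ISO, make_box_volume


def nx_graph(surface):
    g = nx.Graph()
    g.add_nodes_from(range(surface.n_nodes))
    for (a, b), w in zip(surface.edges, surface.weights):
        g.add_edge(int(a), int(b), weight=float(w))
    return g


class TestGeodesicDistance:
    def test_node_to_itself_zero(self, sphere_surface):
        assert geodesic_distance(sphere_surface, 7, 7) == 0.0

    def test_face_neighbors_one_voxel_apart(self):
        labels = np.zeros((3, 3, 4), dtype=np.int32)
        labels[1, 1, 1:3] = 1
        surf = extract_surface(LabelVolume(labels, ISO), 1)
        assert geodesic_distance(surf, 0, 1) == pytest.approx(20.0)

    def test_unknown_node_rejected(self, sphere_surface):
        with pytest.raises(ValueError):
            geodesic_distance(sphere_surface, 0, sphere_surface.n_nodes + 5)

    def test_matches_bruteforce_oracle_on_small_surface(self, sphere_surface):
        assert sphere_surface.n_nodes <= 500
        g = nx_graph(sphere_surface)
        rng = np.random.default_rng(1)
        for _ in range(12):
            a, b = rng.integers(0, sphere_surface.n_nodes, 2)
            oracle = nx.bellman_ford_path_length(g, int(a), int(b), weight="weight")
            assert geodesic_distance(sphere_surface, int(a), int(b)) == pytest.approx(
                oracle
            )

    def test_metric_properties_on_random_triples(self, sphere_surface):
        rng = np.random.default_rng(3)
        nodes = rng.integers(0, sphere_surface.n_nodes, (20, 3))
        for a, b, c in nodes:
            dab = geodesic_distance(sphere_surface, int(a), int(b))
            dba = geodesic_distance(sphere_surface, int(b), int(a))
            dbc = geodesic_distance(sphere_surface, int(b), int(c))
            dac = geodesic_distance(sphere_surface, int(a), int(c))
            assert dab == pytest.approx(dba)  # symmetry
            assert dac <= dab + dbc + 1e-9  # triangle inequality
            eu = np.linalg.norm(
                sphere_surface.positions[a] - sphere_surface.positions[c]
            )
            assert dac >= eu - 1e-9  # never shorter than through space


class TestNND:
    def test_two_particles_share_their_pairwise_distance(self, sphere_surface):
        nodes = np.array([0, sphere_surface.n_nodes // 2])
        res = nnd_analysis(nodes, sphere_surface)
        d = geodesic_distance(sphere_surface, int(nodes[0]), int(nodes[1]))
        assert res.nnds == pytest.approx([d, d])
        assert res.sd_nnd == pytest.approx(0.0)

    def test_single_particle_rejected(self, sphere_surface):
        with pytest.raises(ValueError):
            nnd_analysis(np.array([0]), sphere_surface)

    def test_matches_pairwise_dijkstra_oracle(self, sphere_surface):
        rng = np.random.default_rng(7)
        nodes = rng.choice(sphere_surface.n_nodes, size=25, replace=False)
        res = nnd_analysis(nodes, sphere_surface)
        g = nx_graph(sphere_surface)
        for i, a in enumerate(nodes):
            oracle = min(
                nx.dijkstra_path_length(g, int(a), int(b), weight="weight")
                for j, b in enumerate(nodes)
                if j != i
            )
            assert res.nnds[i] == pytest.approx(oracle)
        assert res.mean_nnd == pytest.approx(res.nnds.mean())
        assert res.sd_nnd == pytest.approx(np.std(res.nnds, ddof=1))

    def test_near_axis_nnd_close_to_euclidean_on_flat_sheet(self, sheet_surface):
        # chamfer bound: on a flat face, graph distances between nodes in a
        # near-axis direction stay within ~8% of Euclidean
        top = np.flatnonzero(sheet_surface.voxels[:, 0] == 0)
        pos = sheet_surface.positions[top]
        # a row of nodes along x at fixed y
        row = top[np.lexsort((pos[:, 0], pos[:, 1]))][5:25]
        res = nnd_analysis(row, sheet_surface)
        eu = 20.0  # consecutive nodes along the axis
        assert np.all(res.nnds <= eu * 1.08 + 1e-9)
        assert np.all(res.nnds >= eu - 1e-9)


class TestRandomization:
    def test_reproducible_under_seed(self, sheet_surface):
        nodes = np.arange(0, 200, 10)
        r1 = randomization_test(nodes, sheet_surface, reps=20, seed=5)
        r2 = randomization_test(nodes, sheet_surface, reps=20, seed=5)
        assert np.array_equal(r1.null_means, r2.null_means)
        assert r1.p_empirical == r2.p_empirical

    def test_single_replicate_degenerate(self, sheet_surface):
        r = randomization_test(np.arange(0, 100, 5), sheet_surface, reps=1, seed=0)
        assert r.null_sd is None and r.z_score is None
        assert r.p_empirical in (0.5, 1.0)

    def test_bad_parameters_rejected(self, sheet_surface):
        with pytest.raises(ValueError):
            randomization_test(np.array([1, 2]), sheet_surface, reps=0, seed=0)
        too_many = np.arange(sheet_surface.n_nodes + 1)
        with pytest.raises(ValueError):
            randomization_test(too_many, sheet_surface, reps=5, seed=0)

    def test_p_uses_add_one_estimator(self, sheet_surface):
        r = randomization_test(np.arange(0, 120, 6), sheet_surface, reps=19, seed=2)
        k = int(np.sum(r.null_means <= r.observed_mean_nnd))
        assert r.p_empirical == (1 + k) / 20
        assert 0 < r.p_empirical <= 1

    def test_clustered_pattern_detected(self, sheet_surface):
        # a tight clump plus the randomization null: observed far below null
        rng = np.random.default_rng(4)
        center = sheet_surface.n_nodes // 2
        d = sheet_surface.geodesic_from(np.array([center]))[0]
        clump = np.argsort(d)[:15]
        r = randomization_test(clump, sheet_surface, reps=99, seed=1)
        assert r.observed_mean_nnd < r.null_means.min()
        assert r.p_empirical == pytest.approx(1 / 100)
        assert r.z_score < -2


class TestClusters:
    def test_three_close_one_far(self, sheet_surface):
        d = sheet_surface.geodesic_from(np.array([0]))[0]
        order = np.argsort(d)
        nodes = np.array([order[0], order[1], order[2], order[-1]])
        nnd = nnd_analysis(nodes, sheet_surface)
        # mean 20 + 2*5 nm: keeps the adjacent trio linked, leaves the far one out
        summary = NNDResult(nnds=nnd.nnds, mean_nnd=20.0, sd_nnd=5.0, n_particles=4)
        cs = call_clusters(nodes, sheet_surface, summary)
        assert len(cs.clusters) == 1 and len(cs.clusters[0]) == 3
        assert cs.scattered_count == 1

    def test_all_far_apart_all_scattered(self, sheet_surface):
        d0 = sheet_surface.geodesic_from(np.array([0]))[0]
        far = np.argsort(d0)
        nodes = np.array([0, far[-1], far[len(far) // 2]])
        nnd = nnd_analysis(nodes, sheet_surface)
        # force a tiny threshold via a shrunken NND result
        tiny = NNDResult(nnds=nnd.nnds, mean_nnd=10.0, sd_nnd=1.0, n_particles=3)
        cs = call_clusters(nodes, sheet_surface, tiny)
        assert len(cs.clusters) == 0
        assert cs.scattered_count == 3

    def test_partition_property(self, tube_surface):
        rng = np.random.default_rng(9)
        nodes = rng.choice(tube_surface.n_nodes, 60, replace=False)
        nnd = nnd_analysis(nodes, tube_surface)
        cs = call_clusters(nodes, tube_surface, nnd)
        members = sorted(p for g in cs.clusters + cs.scattered for p in g)
        assert members == list(range(60))

    def test_merging_monotone_in_threshold(self, tube_surface):
        rng = np.random.default_rng(10)
        nodes = rng.choice(tube_surface.n_nodes, 40, replace=False)
        nnd = nnd_analysis(nodes, tube_surface)
        n_groups = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            fake = NNDResult(
                nnds=nnd.nnds,
                mean_nnd=nnd.mean_nnd * scale,
                sd_nnd=nnd.sd_nnd * scale,
                n_particles=nnd.n_particles,
            )
            cs = call_clusters(nodes, tube_surface, fake)
            n_groups.append(len(cs.clusters) + len(cs.scattered))
        assert n_groups == sorted(n_groups, reverse=True)

    def test_negative_threshold_rejected(self, sheet_surface):
        nnd = NNDResult(nnds=np.array([50.0, 50.0]), mean_nnd=50.0, sd_nnd=40.0,
                        n_particles=2)
        with pytest.raises(ValueError):
            call_clusters(np.array([0, 1]), sheet_surface, nnd, rule="minus2sd")


@pytest.fixture(scope="module")
def sheet_with_patch():
    """Large flat sheet with one round synapse patch at the center."""
    vol = make_box_volume(3, 90, 90)
    surf = extract_surface(vol, 1)
    syn = np.zeros(vol.shape, dtype=np.int32)
    cy = cx = 45
    j, i = np.indices((90, 90))
    patch = (j - cy) ** 2 + (i - cx) ** 2 <= 5**2  # 100 nm radius
    syn[0][patch] = 1
    syn_vol = LabelVolume(syn, ISO)
    meta = [SynapseMeta(patch_id=1, type="asymmetric", compartment_id=1)]
    patches = map_patches_to_surface(syn_vol, meta, surf)
    return vol, surf, patches


class TestSynapseProfile:
    def test_eleven_bins_cover_limit(self, sheet_with_patch):
        _, surf, patches = sheet_with_patch
        prof = synapse_profile(np.array([0, 1]), patches, surf, "asymmetric")
        assert len(prof.counts) == 11
        assert prof.bin_edges[0] == 0 and prof.bin_edges[-1] == 660

    def test_particle_on_patch_gets_zero(self, sheet_with_patch):
        _, surf, patches = sheet_with_patch
        inside = patches[1][:1]
        prof = synapse_profile(inside, patches, surf, "asymmetric")
        assert prof.distances[0] == 0.0
        assert prof.counts[0] == 1

    def test_particle_adjacent_to_edge_in_first_bin(self, sheet_with_patch):
        _, surf, patches = sheet_with_patch
        # neighbor of an edge node that is not itself in the patch
        in_patch = np.zeros(surf.n_nodes, dtype=bool)
        in_patch[patches[1]] = True
        a, b = surf.edges[:, 0], surf.edges[:, 1]
        outside = np.concatenate([b[in_patch[a] & ~in_patch[b]],
                                  a[in_patch[b] & ~in_patch[a]]])
        prof = synapse_profile(outside[:1], patches, surf, "asymmetric")
        assert 0 < prof.distances[0] < 60
        assert prof.counts[0] == 1

    def test_missing_patch_type_warns_empty(self, sheet_with_patch):
        _, surf, patches = sheet_with_patch
        with pytest.warns(UserWarning):
            prof = synapse_profile(np.array([0, 1]), {}, surf, "symmetric")
        assert prof.n_total == 0

    def test_uniform_particles_match_annulus_area_oracle(self, sheet_with_patch):
        vol, surf, patches = sheet_with_patch
        rng = np.random.default_rng(12)
        # uniform draw over the top face (constant node area there)
        top = np.flatnonzero(surf.voxels[:, 0] == 0)
        particles = rng.choice(top, size=4000, replace=True)
        prof = synapse_profile(particles, patches, surf, "asymmetric")
        assert prof.proportions.sum() == pytest.approx(1.0)
        assert prof.n_within_limit + prof.n_beyond_limit == 4000
        # CSR on a plane: expected proportion per ring ~ annulus area around
        # the patch edge (radius a = 100 nm); the raster geodesic inflates
        # distances by <= ~8%, hence the generous per-bin tolerance
        a = 100.0
        edges = prof.bin_edges
        ring = np.pi * ((a + edges[1:]) ** 2 - (a + edges[:-1]) ** 2)
        expected = ring / ring.sum()
        assert np.all(np.abs(prof.proportions - expected) < 0.05)
        # and the profile grows with distance as ring area does
        assert prof.proportions[-1] > prof.proportions[0]
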