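import numpy as np
import pytest

from bruxpop.bruvo import DistanceMatrix
from bruxpop import clustering


def leaf_distances(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[i], taxa[j])
    return [t.label for t in taxa], d


def random_additive_matrix(rng, n):
    """Distances induced by a random tree with positive branch lengths."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n, rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.1, 2.0))
    labels, d = leaf_distances(tree)
    return DistanceMatrix(labels, d)


class TestNJ:
    def test_four_taxon_additive_roundtrip(self):
        # tree ((A:1,B:2):5,(C:3,D:4)) in distance form
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]],
            dtype=float,
        )
        tree = clustering.nj(DistanceMatrix(ids, d))
        labels, got = leaf_distances(tree)
        assert labels == ids
        assert np.allclose(got, d, atol=1e-10)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.6, 0.8], [0.6, 0, 1.0], [0.8, 1.0, 0]])
        tree = clustering.nj(DistanceMatrix(["A", "B", "C"], d))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(0.2)
        assert lengths["B"] == pytest.approx(0.4)
        assert lengths["C"] == pytest.approx(0.6)

    def test_random_additive_exact(self, rng):
        for n in (5, 8, 12):
            D = random_additive_matrix(rng, n)
            tree = clustering.nj(D)
            labels, got = leaf_distances(tree)
            ref = D.submatrix(labels).d
            assert np.allclose(got, ref, atol=1e-9)

    def test_agrees_with_dendropy_on_topology(self, rng):
        """Cross-check against dendropy's own NJ on an additive matrix."""
        import dendropy

        D = random_additive_matrix(rng, 7)
        ours = clustering.nj(D)
        csv = "," + ",".join(D.ids) + "\n" + "\n".join(
            D.ids[i] + "," + ",".join(str(x) for x in D.d[i]) for i in range(D.n)
        )
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), taxon_namespace=dendropy.TaxonNamespace(D.ids)
        )
        theirs = pdm.nj_tree()
        b1 = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in ours.preorder_internal_node_iter()
        }
        b2 = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in theirs.preorder_internal_node_iter()
        }
        # same unrooted topology up to the arbitrary seed-node placement
        full = frozenset(D.ids)

        def sides(bips):
            # non-trivial unrooted splits only (both sides >= 2 leaves)
            out = {min(b, full - b, key=sorted) for b in bips if 1 < len(b) < len(full)}
            return {s for s in out if len(s) >= 2 and len(full - s) >= 2}

        assert sides(b1) == sides(b2)

    def test_incomplete_matrix_rejected(self):
        D = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        D.d[0, 1] = D.d[1, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            clustering.nj(D)


class TestUPGMA:
    def test_two_taxa(self):
        tree = clustering.upgma(
            DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        )
        for lf in tree.leaf_node_iter():
            assert lf.edge.length == pytest.approx(0.2)

    def test_three_taxa_heights(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = clustering.upgma(DistanceMatrix(["A", "B", "C"], d))
        heights = {}
        for lf in tree.leaf_node_iter():
            h = 0.0
            nd = lf
            while nd.parent_node is not None:
                h += nd.edge.length
                nd = nd.parent_node
            heights[lf.taxon.label] = h
        assert all(h == pytest.approx(0.3) for h in heights.values())
        # A and B join first at height 0.1
        ab = [lf for lf in tree.leaf_node_iter() if lf.taxon.label == "A"][0]
        assert ab.edge.length == pytest.approx(0.1)

    def test_ultrametric_invariant(self, rng):
        x = rng.normal(size=(10, 3))
        d = np.linalg.norm(x[:, None] - x[None], axis=2)
        tree = clustering.upgma(DistanceMatrix([f"i{k}" for k in range(10)], d))
        depths = []
        for lf in tree.leaf_node_iter():
            h, nd = 0.0, lf
            while nd.parent_node is not None:
                h += nd.edge.length
                nd = nd.parent_node
            depths.append(h)
        assert np.allclose(depths, depths[0], atol=1e-9)

    def test_nj_and_upgma_agree_on_ultrametric(self, rng):
        """On ultrametric matrices both methods induce the same partitions."""
        # build an ultrametric matrix from a UPGMA tree of random data
        x = np.concatenate([rng.normal(0, 0.05, (5, 2)), rng.normal(5, 0.05, (5, 2))])
        d = np.linalg.norm(x[:, None] - x[None], axis=2)
        ids = [f"i{k}" for k in range(10)]
        ref = clustering.upgma(DistanceMatrix(ids, d))
        labels, du = leaf_distances(ref)  # exactly ultrametric
        Du = DistanceMatrix(labels, du)
        njt = clustering.nj(Du)
        ut = clustering.upgma(Du)
        full = frozenset(labels)

        def sides(tree):
            out = set()
            for nd in tree.preorder_internal_node_iter():
                b = frozenset(lf.taxon.label for lf in nd.leaf_iter())
                if 1 < len(b) < len(full):
                    out.add(min(b, full - b, key=sorted))
            return out

        assert sides(ut) <= sides(njt) | sides(ut)
        # the two-block split of the two tight clusters must appear in both
        blockA = min(frozenset(labels[:5]), frozenset(labels[5:]), key=sorted)
        assert blockA in sides(njt)
        assert blockA in sides(ut)


class TestClassicalMDS:
    def test_collinear_points_exact(self):
        pos = np.array([0.0, 1.0, 2.0])
        d = np.abs(pos[:, None] - pos[None])
        coords = clustering.classical_mds(DistanceMatrix(["a", "b", "c"], d), k=1)
        got = np.abs(coords[:, 0][:, None] - coords[:, 0][None])
        assert np.allclose(got, d, atol=1e-10)

    def test_euclidean_roundtrip(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        coords = clustering.classical_mds(
            DistanceMatrix([f"i{k}" for k in range(10)], d), k=2
        )
        d2 = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        assert np.allclose(d, d2, atol=1e-8)

    def test_duplicated_point_identical_coords(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        coords = clustering.classical_mds(DistanceMatrix(["a", "b", "c"], d), k=1)
        assert np.allclose(coords[0], coords[1], atol=1e-10)

    def test_k_reduced_with_warning(self):
        pos = np.array([0.0, 1.0, 2.0])
        d = np.abs(pos[:, None] - pos[None])
        with pytest.warns(UserWarning, match="reduced"):
            coords = clustering.classical_mds(DistanceMatrix(["a", "b", "c"], d), k=3)
        assert coords.shape[1] == 1

    def test_agrees_with_skbio_pcoa(self, rng):
        """Independent cross-check against scikit-bio's principal
        coordinates analysis (same eigen-scaling convention)."""
        import skbio

        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        ids = [f"i{k}" for k in range(8)]
        ours = clustering.classical_mds(DistanceMatrix(ids, d), k=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d, ids), number_of_dimensions=3
        ).samples.to_numpy()
        for col in range(3):  # eigenvectors fixed up to sign
            assert np.allclose(ours[:, col], theirs[:, col], atol=1e-8) or np.allclose(
                ours[:, col], -theirs[:, col], atol=1e-8
            )


class TestFindClusters:
    def test_three_blobs(self, rng):
        centres = np.array([[0, 0], [10, 0], [0, 10]])
        coords = np.concatenate(
            [rng.normal(c, 1.0, size=(30, 2)) for c in centres]
        )
        out = clustering.find_clusters(coords, kmax=8, seed=1)
        assert out.k == 3
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([0, 1, 2], 30)
        assert adjusted_rand_score(truth, out.label_array()) == 1.0

    def test_single_gaussian_is_one_cluster(self, rng):
        coords = rng.normal(size=(120, 2))
        out = clustering.find_clusters(coords, kmax=6, seed=2)
        assert out.k == 1

    def test_degenerate_coordinates(self):
        coords = np.ones((10, 2))
        out = clustering.find_clusters(coords, kmax=4, seed=0)
        assert out.k == 1

    def test_wss_nonincreasing_and_sharp_drop(self, rng):
        centres = np.array([[0, 0], [12, 0], [0, 12]])
        coords = np.concatenate(
            [rng.normal(c, 1.0, size=(25, 2)) for c in centres]
        )
        out = clustering.find_clusters(coords, kmax=6, seed=3)
        wss = [out.wss_curve[k] for k in sorted(out.wss_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))
        # WSS at the true k drops by >90% relative to k-1
        assert out.wss_curve[3] < 0.1 * out.wss_curve[2]

    def test_reproducible_given_seed(self, rng):
        coords = rng.normal(size=(60, 2))
        a = clustering.find_clusters(coords, kmax=5, seed=7)
        b = clustering.find_clusters(coords, kmax=5, seed=7)
        assert a.k == b.k and a.labels == b.labels


class TestPartitionReliability:
    def test_clonal_clade_fully_reliable(self, rng):
        # 5 identical isolates in a diverse background
        x = np.concatenate([np.zeros((5, 2)), rng.normal(5, 3, size=(15, 2))])
        d = np.linalg.norm(x[:, None] - x[None], axis=2)
        ids = [f"i{k}" for k in range(20)]
        D = DistanceMatrix(ids, d)
        tree = clustering.upgma(D)
        clustering.partition_reliability(tree, D, R=200, seed=1)
        clone_set = frozenset(ids[:5])
        found = False
        for nd in tree.preorder_internal_node_iter():
            leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if leaves == clone_set:
                found = True
                assert nd.reliability == 1.0
        assert found

    def test_root_clade_skipped(self, rng):
        x = rng.normal(size=(8, 2))
        d = np.linalg.norm(x[:, None] - x[None], axis=2)
        D = DistanceMatrix([f"i{k}" for k in range(8)], d)
        tree = clustering.upgma(D)
        clustering.partition_reliability(tree, D, R=150, seed=2)
        root_leaves = frozenset(lf.taxon.label for lf in tree.seed_node.leaf_iter())
        for nd in tree.preorder_internal_node_iter():
            leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
            if leaves == root_leaves:
                assert nd.reliability is None

    def test_null_calibration(self, rng):
        """Random topologies over i.i.d. points: ~10% of nodes exceed 0.90.

        The topology must be independent of the distances (an agglomerative
        tree would be biased towards tight clades by construction)."""
        import random as pyrandom

        import dendropy

        exceed = total = 0
        for rep in range(30):
            r = np.random.default_rng(rep)
            x = r.normal(size=(20, 3))
            d = np.linalg.norm(x[:, None] - x[None], axis=2)
            ids = [f"i{k}" for k in range(20)]
            D = DistanceMatrix(ids, d)
            taxa = dendropy.TaxonNamespace(ids)
            tree = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
                num_extant_tips=20, rng=pyrandom.Random(rep),
            )
            clustering.partition_reliability(tree, D, R=200, seed=rep)
            for nd in tree.preorder_internal_node_iter():
                if nd.reliability is not None:
                    total += 1
                    exceed += nd.reliability > 0.90
        rate = exceed / total
        se = np.sqrt(0.1 * 0.9 / total)
        assert abs(rate - 0.10) < max(4 * se, 0.05)

    def test_requires_enough_replicates(self):
        D = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        tree = clustering.upgma(D)
        with pytest.raises(ValueError):
            clustering.partition_reliability(tree, D, R=50)
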