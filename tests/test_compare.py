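import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from skbio import TreeNode

from nifhamp.cluster import complete_linkage_cluster
from nifhamp.compare import (
    nj_tree,
    overlap_matrix,
    p_distance_matrix,
    patristic_matrix,
    pcoa,
    sorensen,
    sorensen_matrix,
    unifrac_matrix,
    weighted_unifrac,
)
from nifhamp.qc import ProteinSeq
from nifhamp.simulate import CONSENSUS

from .helpers import mutate, random_additive_tree


def _cs(column_a, column_b, rng=None):
    """ClusterSet over distinct sequences with two sample columns."""
    rng = rng or np.random.default_rng(0)
    n = len(column_a)
    pseqs = [
        ProteinSeq(f"P{i:05d}", mutate(CONSENSUS, 12 + i % 5, rng),
                   {k: v for k, v in (("a", column_a[i]), ("b", column_b[i])) if v})
        for i in range(n)
    ]
    # sequences are far apart, so 100% clustering keeps them distinct
    return complete_linkage_cluster(pseqs, 100.0)


class TestSorensen:
    def test_identical_supports_give_100(self):
        cs = _cs([3, 2, 1], [1, 5, 2])
        assert sorensen(cs, "a", "b") == pytest.approx(100.0)

    def test_formula_on_2_3_5(self):
        # a has 3 clusters, b has 5, sharing 2 -> Cs = 2*2/8*100 = 50
        cs = _cs([1, 1, 1, 0, 0, 0], [1, 1, 0, 1, 1, 1])
        assert sorensen(cs, "a", "b") == pytest.approx(50.0)

    def test_disjoint_supports_give_0(self):
        cs = _cs([1, 1, 0, 0], [0, 0, 1, 1])
        assert sorensen(cs, "a", "b") == 0.0

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        cs = _cs([1, 1, 0], [0, 1, 1])
        mat = sorensen_matrix(cs)
        assert mat.loc["a", "a"] == 100.0
        assert mat.loc["a", "b"] == mat.loc["b", "a"]

    def test_overlap_matrix_diagonal_counts_clusters(self):
        cs = _cs([1, 1, 0], [0, 1, 1])
        mat = overlap_matrix(cs)
        assert mat.loc["a", "a"] == 2 and mat.loc["b", "b"] == 2
        assert mat.loc["a", "b"] == 1


class TestNeighborJoining:
    def test_fewer_than_three_taxa_raises(self):
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.zeros((2, 2)))

    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(["a", "b", "c"], D)
        lengths = {t.name: t.length for t in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree: (A:0.2, B:0.3) -- 0.4 -- (C:0.5, D:0.1)
        D = np.array(
            [
                [0.0, 0.5, 1.1, 0.7],
                [0.5, 0.0, 1.2, 0.8],
                [1.1, 1.2, 0.0, 0.6],
                [0.7, 0.8, 0.6, 0.0],
            ]
        )
        labels = ["A", "B", "C", "D"]
        tree = nj_tree(labels, D)
        np.testing.assert_allclose(patristic_matrix(tree, labels), D, atol=1e-9)

    def test_random_additive_matrices_round_trip(self, rng):
        for _ in range(20):
            labels, D = random_additive_tree(int(rng.integers(4, 9)), rng)
            tree = nj_tree(labels, D)
            np.testing.assert_allclose(patristic_matrix(tree, labels), D,
                                       atol=1e-9)

    def test_identical_sequences_get_zero_length_branches(self):
        seqs = [CONSENSUS, CONSENSUS, mutate(CONSENSUS, 20, np.random.default_rng(1))]
        D = p_distance_matrix(seqs)
        tree = nj_tree(["x", "y", "z"], D)
        lengths = {t.name: t.length for t in tree.children}
        assert lengths["x"] == pytest.approx(0.0, abs=1e-12)
        assert lengths["y"] == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_reference_nj_on_additive_matrix(self, rng):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix

        labels, D = random_additive_tree(6, rng)
        ours = patristic_matrix(nj_tree(labels, D), labels)
        theirs_tree = skbio_nj(DistanceMatrix(D, ids=labels))
        theirs = theirs_tree.tip_tip_distances(endpoints=labels).data
        np.testing.assert_allclose(ours, np.asarray(theirs), atol=1e-9)


def _two_leaf_tree():
    return TreeNode.read(["(x:1.0,y:1.0):0.0;"])


class TestWeightedUnifrac:
    def test_identical_relative_abundances_give_zero(self):
        tree = _two_leaf_tree()
        ab = pd.DataFrame({"a": [10, 30], "b": [1, 3]}, index=["x", "y"])
        assert weighted_unifrac(tree, ab, "a", "b") == pytest.approx(0.0)

    def test_two_leaf_hand_value(self):
        tree = _two_leaf_tree()
        ab = pd.DataFrame({"a": [5, 0], "b": [0, 7]}, index=["x", "y"])
        assert weighted_unifrac(tree, ab, "a", "b") == pytest.approx(2.0)

    def test_scaling_invariance(self, rng):
        labels, D = random_additive_tree(5, rng)
        tree = nj_tree(labels, D)
        counts = rng.integers(1, 50, size=(5, 2))
        ab = pd.DataFrame(counts, index=labels, columns=["a", "b"])
        d1 = weighted_unifrac(tree, ab, "a", "b")
        ab10 = ab.copy()
        ab10["a"] *= 10
        assert weighted_unifrac(tree, ab10, "a", "b") == pytest.approx(d1)

    def test_unmapped_cluster_raises_with_names(self):
        tree = _two_leaf_tree()
        ab = pd.DataFrame({"a": [1, 1], "b": [1, 1]}, index=["x", "zz"])
        with pytest.raises(KeyError, match="zz"):
            weighted_unifrac(tree, ab, "a", "b")

    def test_reference_leaves_carry_zero_weight(self):
        tree = TreeNode.read(["((x:1.0,y:1.0):0.5,ref:2.0):0.0;"])
        ab = pd.DataFrame({"a": [5, 0], "b": [0, 7]}, index=["x", "y"])
        assert weighted_unifrac(tree, ab, "a", "b") == pytest.approx(2.0)

    def test_metric_properties_on_random_instances(self, rng):
        for _ in range(10):
            labels, D = random_additive_tree(5, rng)
            tree = nj_tree(labels, D)
            counts = rng.integers(0, 30, size=(5, 3)) + np.eye(5, 3, dtype=int)
            ab = pd.DataFrame(counts, index=labels, columns=["a", "b", "c"])
            dm = unifrac_matrix(tree, ab).to_data_frame()
            assert np.allclose(dm, dm.T) and np.allclose(np.diag(dm), 0)
            for x, y, z in (("a", "b", "c"), ("b", "c", "a"), ("c", "a", "b")):
                assert dm.loc[x, z] <= dm.loc[x, y] + dm.loc[y, z] + 1e-12

    def test_agrees_with_reference_implementation(self, rng):
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        labels, D = random_additive_tree(6, rng)
        tree = nj_tree(labels, D)
        rooted = tree.root_at_midpoint()
        counts = rng.integers(0, 40, size=(6, 2)) + 1
        ab = pd.DataFrame(counts, index=labels, columns=["a", "b"])
        mine = weighted_unifrac(rooted, ab, "a", "b")
        theirs = skbio_wu(
            ab["a"].to_numpy(), ab["b"].to_numpy(), taxa=labels, tree=rooted,
        )
        assert mine == pytest.approx(float(theirs), rel=1e-9)


class TestPcoa:
    def test_two_samples_at_distance_d(self):
        D = np.array([[0.0, 0.8], [0.8, 0.0]])
        res = pcoa(D, n_axes=2, ids=["a", "b"])
        coords = np.sort(res.coordinates["PC1"].to_numpy())
        np.testing.assert_allclose(coords, [-0.4, 0.4], atol=1e-12)

    def test_three_collinear_points(self):
        pts = np.array([0.0, 1.0, 3.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(D, n_axes=2)
        axis1 = res.coordinates["PC1"].to_numpy()
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0], atol=1e-9)

    def test_zero_matrix_degenerates_to_origin(self):
        res = pcoa(np.zeros((4, 4)), n_axes=2)
        assert res.coordinates.shape[1] == 0

    def test_euclidean_distances_are_reproduced(self, rng):
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(D, n_axes=6)
        C = res.coordinates.to_numpy()
        D2 = np.linalg.norm(C[:, None] - C[None, :], axis=2)
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_coordinates_are_centered(self, rng):
        pts = rng.normal(size=(5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(D)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-10)


def test_sorensen_and_unifrac_rank_concordantly():
    """Graded community overlap: taxonomic and phylogenetic similarity agree."""
    rhos = []
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        pool = []
        while len(pool) < 24:
            cand = mutate(CONSENSUS, 16, rng)
            if all(sum(a != b for a, b in zip(cand, p)) > 6 for p in pool):
                pool.append(cand)
        labels = [f"V{i:02d}" for i in range(24)]
        tree = nj_tree(labels, p_distance_matrix(pool))
        samples = {f"s{k}": set(range(3 * k, 3 * k + 12)) for k in range(5)}
        ab = pd.DataFrame(
            {s: [10 if i in idx else 0 for i in range(24)]
             for s, idx in samples.items()},
            index=labels,
        )
        sor, uni = [], []
        names = sorted(samples)
        for i, s1 in enumerate(names):
            for s2 in names[i + 1:]:
                x = samples[s1] & samples[s2]
                u = samples[s1] | samples[s2]
                sor.append(2 * len(x) / (len(samples[s1]) + len(samples[s2])))
                uni.append(1 - weighted_unifrac(tree, ab, s1, s2, normalized=True))
        rhos.append(spearmanr(sor, uni).statistic)
    assert np.mean(rhos) >= 0.8
    assert min(rhos) > 0.5
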