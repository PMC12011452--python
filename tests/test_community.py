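"""Bray-Curtis, NMDS, intergroup distances, UPGMA, Venn counts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from oracles import brute_bray_curtis, naive_upgma_cophenetic

from dietniche.community import (
    DistanceMatrix,
    bray_curtis,
    bray_curtis_matrix,
    intergroup_distances,
    kruskal_stress,
    nmds,
    pcoa_coordinates,
    shared_otu_counts,
    upgma,
)
from dietniche.io import OtuTable, SampleRecord, Season, Species, ValidationError


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0], [0, 2]) == 1.0

    def test_hand_arithmetic(self):
        assert bray_curtis([1, 0], [0.5, 0.5]) == pytest.approx(0.5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.floats(0, 5), min_size=2, max_size=10),
        st.lists(st.floats(0, 5), min_size=2, max_size=10),
    )
    def test_l1_identity_on_normalized_vectors(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if x.sum() == 0 or y.sum() == 0:
            return
        x, y = x / x.sum(), y / y.sum()
        assert bray_curtis(x, y) == pytest.approx(0.5 * np.abs(x - y).sum(), abs=1e-9)
        assert bray_curtis(x, y) == pytest.approx(brute_bray_curtis(x, y), abs=1e-9)

    def test_matrix_validation(self):
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.3, 0.0]]))


class TestNmds:
    def _planar(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.2, 1.5]])
        return pts, DistanceMatrix(list("abcd"), squareform(pdist(pts)))

    def test_recovers_perfectly_embeddable_configuration(self):
        pts, dm = self._planar()
        result = nmds(dm, n_restarts=3, seed=0)
        assert result.stress < 1e-6
        _, _, disparity = procrustes(pts, result.coordinates)
        assert disparity < 1e-4

    def test_two_points_zero_stress(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.7], [0.7, 0.0]]))
        assert nmds(dm, n_restarts=1, seed=0).stress == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(10, 4))
        dm = DistanceMatrix([f"s{i}" for i in range(10)], squareform(pdist(pts)))
        a = nmds(dm, n_restarts=4, seed=11)
        b = nmds(dm, n_restarts=4, seed=11)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_stress_not_worse_than_initialization(self, rng):
        pts = rng.normal(size=(12, 5))
        dm = DistanceMatrix([f"s{i}" for i in range(12)], squareform(pdist(pts)))
        init_stress = kruskal_stress(dm, pcoa_coordinates(dm, 2))
        result = nmds(dm, n_restarts=1, seed=3)
        assert kruskal_stress(dm, result.coordinates) <= init_stress + 1e-9

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestIntergroup:
    def test_far_clusters_between_exceeds_within(self, rng):
        a = rng.normal(0, 0.05, size=(5, 3))
        b = rng.normal(5, 0.05, size=(5, 3))
        pts = np.vstack([a, b])
        ids = [f"s{i}" for i in range(10)]
        dm = DistanceMatrix(ids, squareform(pdist(pts)))
        labels = {s: ("A" if i < 5 else "B") for i, s in enumerate(ids)}
        res = intergroup_distances(dm, labels)
        assert np.median(res.between[("A", "B")]) > np.median(res.within["A"])
        assert np.median(res.between[("A", "B")]) > np.median(res.within["B"])
        assert res.kruskal[("A", "B")][1] < 0.01

    def test_identical_samples_all_distances_zero(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        labels = {"a": "G1", "b": "G1", "c": "G2", "d": "G2"}
        res = intergroup_distances(dm, labels)
        assert all((v == 0).all() for v in res.within.values())
        assert res.kruskal[("G1", "G2")] == (0.0, 1.0)

    def test_invariant_to_relabeling_within_group(self, rng):
        pts = rng.normal(size=(6, 2))
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(ids, squareform(pdist(pts)))
        labels = {s: ("A" if i % 2 else "B") for i, s in enumerate(ids)}
        res1 = intergroup_distances(dm, labels)
        # permute the sample order inside the matrix, same labels
        perm = [1, 0, 3, 2, 5, 4]
        dm2 = DistanceMatrix([ids[i] for i in perm], dm.D[np.ix_(perm, perm)])
        res2 = intergroup_distances(dm2, labels)
        for g in res1.within:
            assert sorted(res1.within[g]) == pytest.approx(sorted(res2.within[g]))

    def test_singleton_group_flagged(self):
        dm = DistanceMatrix(list("abc"), squareform([0.3, 0.4, 0.5]))
        labels = {"a": "A", "b": "A", "c": "B"}
        res = intergroup_distances(dm, labels)
        assert res.singleton_groups == ["B"]
        assert res.within["B"].size == 0


def _tree_cophenetic(node, acc=None):
    if acc is None:
        acc = {}
    if node.is_leaf:
        return acc
    for i, a in enumerate(node.children):
        for b in node.children[i + 1 :]:
            for x in a.leaf_names():
                for y in b.leaf_names():
                    acc[frozenset([x, y])] = 2 * node.height
    for c in node.children:
        _tree_cophenetic(c, acc)
    return acc


class TestUpgma:
    def test_two_leaves_split_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.8], [0.8, 0.0]]))
        tree = upgma(dm)
        assert tree.height == pytest.approx(0.4)
        assert tree.to_newick() in ("(a:0.4,b:0.4):0;", "(b:0.4,a:0.4):0;")

    def test_closest_pair_joins_first(self):
        D = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
        tree = upgma(DistanceMatrix(list("abc"), D))
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(inner.leaf_names()) == ["a", "b"]

    def test_matches_naive_agglomeration(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(6, 3))
            dm = DistanceMatrix([f"s{i}" for i in range(6)], squareform(pdist(pts)))
            tree = upgma(dm)
            got = _tree_cophenetic(tree)
            want = naive_upgma_cophenetic(dm.ids, dm.D)
            assert set(got) == set(want)
            for pair in want:
                assert got[pair] == pytest.approx(want[pair], abs=1e-10)

    def test_ultrametric_root_to_leaf_paths(self, rng):
        pts = rng.normal(size=(8, 3))
        dm = DistanceMatrix([f"s{i}" for i in range(8)], squareform(pdist(pts)))
        tree = upgma(dm)

        def depths(node, acc):
            if node.is_leaf:
                return [acc + node.height]
            return [d for c in node.children for d in depths(c, acc + node.height - c.height)]

        path_lengths = depths(tree, 0.0)
        assert np.ptp(path_lengths) < 1e-12


class TestSharedOtus:
    meta = [
        SampleRecord("d1", Species.SIKA_DEER, Season.FALL),
        SampleRecord("m1", Species.REEVES_MUNTJAC, Season.FALL),
        SampleRecord("h1", Species.CHINESE_HARE, Season.FALL),
    ]

    def test_identical_presence_all_shared(self):
        counts = np.array([[3, 1], [2, 2], [1, 4]])
        table = OtuTable(["d1", "m1", "h1"], ["A", "B"], counts)
        s = shared_otu_counts(table, self.meta, Season.FALL)
        assert s.shared_all == 2
        assert all(v == 0 for v in s.specific.values())

    def test_disjoint_sets_all_specific(self):
        counts = np.eye(3, dtype=int) * 5
        table = OtuTable(["d1", "m1", "h1"], ["A", "B", "C"], counts)
        s = shared_otu_counts(table, self.meta, Season.FALL)
        assert s.shared_all == 0
        assert sorted(s.specific.values()) == [1, 1, 1]

    def test_set_arithmetic_example(self):
        # deer {A,B}, muntjac {B,C}, hare {B}
        counts = np.array([[1, 1, 0], [0, 1, 1], [0, 1, 0]])
        table = OtuTable(["d1", "m1", "h1"], ["A", "B", "C"], counts)
        s = shared_otu_counts(table, self.meta, Season.FALL)
        assert s.shared_all == 1
        assert s.specific[Species.SIKA_DEER] == 1
        assert s.specific[Species.REEVES_MUNTJAC] == 1
        assert s.specific[Species.CHINESE_HARE] == 0
        assert s.total_present == 3  # region counts partition the present OTUs

    def test_region_counts_sum_to_present_otus(self, tiny_dataset):
        s = shared_otu_counts(tiny_dataset.table, tiny_dataset.metadata, Season.SPRING)
        # every OTU present in >= 1 species is in exactly one region
        meta = [r for r in tiny_dataset.metadata if r.season == Season.SPRING]
        rows = [tiny_dataset.table.sample_ids.index(r.sample_id) for r in meta]
        present = (tiny_dataset.table.counts[rows].sum(axis=0) > 0).sum()
        assert s.total_present == present
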