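"""KO matrix loading, filtering, distances, linkage and tree cutting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from airway_profiler.ko_profiles import (
    ClusterAssignment,
    Dendrogram,
    DistanceMatrix,
    KOProfileMatrix,
    collapse_duplicate_kos,
    complete_linkage,
    dynamic_tree_cut,
    expand_duplicate_kos,
    filter_zero_variance,
    load_ko_matrix,
    manhattan_distance,
    split_cluster,
    to_newick,
)
from airway_profiler.synthetic_data import simulate_ko_matrix
from helpers_oracles import adjusted_rand_index, distinct_columns, naive_complete_linkage


# ---------------------------------------------------------------------------
# loading & validation

class TestLoading:
    def test_round_trip_small_matrix(self, tmp_path):
        df = pd.DataFrame([[1, 0, 1, 1], [0, 0, 1, 0], [1, 1, 1, 0]],
                          index=["a", "b", "c"],
                          columns=["K00001", "K00002", "K00003", "K00004"])
        p = tmp_path / "m.tsv"
        df.to_csv(p, sep="\t")
        m = load_ko_matrix(p)
        assert (m.n_isolates, m.n_kos) == (3, 4)
        assert (m.to_frame() == df).all().all()

    def test_transposed_orientation_auto_detected(self, tmp_path):
        df = pd.DataFrame([[1, 0], [0, 1], [1, 1]],
                          index=["K00001", "K00002", "K00003"],
                          columns=["isoA", "isoB"])
        p = tmp_path / "m.tsv"
        df.to_csv(p, sep="\t")
        m = load_ko_matrix(p)
        assert m.isolate_ids == ["isoA", "isoB"]
        assert m.ko_ids == ["K00001", "K00002", "K00003"]

    def test_duplicate_isolate_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tK00001\tK00002\na\t1\t0\na\t0\t1\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_ko_matrix(p)

    def test_non_binary_cell_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tK00001\tK00002\na\t1\t2\nb\t0\t1\n")
        with pytest.raises(ValueError, match="0/1"):
            load_ko_matrix(p)

    def test_truthy_mapping_accepts_symbols(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tK00001\tK00002\na\tyes\tno\nb\tno\tyes\n")
        m = load_ko_matrix(p, truthy={"yes": 1, "no": 0})
        assert m.values.tolist() == [[1, 0], [0, 1]]


class TestZeroVarianceFilter:
    def test_constant_columns_removed(self):
        m = KOProfileMatrix(["a", "b"], ["K00001", "K00002", "K00003"],
                            np.array([[1, 1, 0], [1, 0, 0]]))
        out, removed = filter_zero_variance(m)
        assert removed == ["K00001", "K00003"]
        assert out.ko_ids == ["K00002"]

    def test_no_constant_columns_is_identity(self, toy_ko_matrix):
        out, removed = filter_zero_variance(toy_ko_matrix)
        assert removed == []
        assert out.ko_ids == toy_ko_matrix.ko_ids
        assert (out.values == toy_ko_matrix.values).all()


class TestDuplicateCollapse:
    def test_identical_columns_collapse_to_representative(self):
        m = KOProfileMatrix(["a", "b", "c"], ["K00001", "K00002", "K00003"],
                            np.array([[1, 1, 0], [0, 0, 1], [1, 1, 1]]))
        out, maps = collapse_duplicate_kos(m)
        assert out.ko_ids == ["K00001", "K00003"]
        assert len(maps) == 1
        assert maps[0].representative_ko == "K00001"
        assert maps[0].members == ["K00002"]

    def test_all_distinct_is_identity(self):
        m = KOProfileMatrix(["a", "b", "c"], ["K00001", "K00002", "K00003"],
                            np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0]]))
        out, maps = collapse_duplicate_kos(m)
        assert maps == []
        assert out.ko_ids == m.ko_ids

    def test_reduced_width_matches_distinct_column_count(self):
        rng = np.random.default_rng(11)
        vals = rng.integers(0, 2, size=(20, 50))
        m = KOProfileMatrix([f"i{r}" for r in range(20)],
                            [f"K{j:05d}" for j in range(1, 51)], vals)
        out, maps = collapse_duplicate_kos(m)
        assert out.n_kos == distinct_columns(vals)
        collapsed = [mem for g in maps for mem in g.members]
        assert len(collapsed) == 50 - out.n_kos
        assert len(set(collapsed)) == len(collapsed)

    def test_expansion_restores_column_multiset(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 2, size=(8, 30))
        m = KOProfileMatrix([f"i{r}" for r in range(8)],
                            [f"K{j:05d}" for j in range(1, 31)], vals)
        reduced, maps = collapse_duplicate_kos(m)
        back = expand_duplicate_kos(reduced, maps)
        orig_cols = sorted(tuple(vals[:, j]) for j in range(30))
        new_cols = sorted(tuple(back.values[:, j]) for j in range(back.n_kos))
        assert new_cols == orig_cols


# ---------------------------------------------------------------------------
# distances

class TestManhattanDistance:
    def test_hand_counted_pair(self):
        m = KOProfileMatrix(["a", "b"], [f"K0000{j}" for j in range(1, 6)],
                            np.array([[1, 0, 1, 1, 0], [1, 1, 1, 0, 0]]))
        assert manhattan_distance(m).d[0, 1] == 2

    def test_identical_and_complementary_rows(self):
        m = KOProfileMatrix(["a", "b", "c"], [f"K0000{j}" for j in range(1, 5)],
                            np.array([[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]]))
        d = manhattan_distance(m).d
        assert d[0, 1] == 0
        assert d[0, 2] == 4

    def test_single_isolate_rejected(self):
        m = KOProfileMatrix(["a"], ["K00001"], np.array([[1]]))
        with pytest.raises(ValueError):
            manhattan_distance(m)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.uint8, st.tuples(st.integers(2, 12), st.integers(1, 40)),
                  elements=st.integers(0, 1)))
    def test_equals_xor_count(self, vals):
        m = KOProfileMatrix([f"i{r}" for r in range(vals.shape[0])],
                            [f"K{j:05d}" for j in range(1, vals.shape[1] + 1)], vals)
        d = manhattan_distance(m).d
        for i in range(vals.shape[0]):
            for j in range(vals.shape[0]):
                assert d[i, j] == int(np.bitwise_xor(vals[i], vals[j]).sum())


# ---------------------------------------------------------------------------
# linkage

class TestCompleteLinkage:
    def test_two_points_merge_at_their_distance(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 3.5], [3.5, 0.0]]))
        t = complete_linkage(d)
        assert t.merges == [(0, 1, 3.5, 2)]

    def test_forced_merge_order_three_points(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float))
        t = complete_linkage(d)
        assert t.merges[0] == (0, 1, 1.0, 2)
        assert t.merges[1] == (2, 3, 10.0, 3)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_naive_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            # mix of float and small-integer (tie-rich) distance matrices
            raw = rng.integers(1, 6, size=(n, n)).astype(float) if rng.random() < 0.5 \
                else rng.random((n, n)) * 10
            d = np.triu(raw, 1)
            d = d + d.T
            dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
            assert complete_linkage(dm).merges == naive_complete_linkage(d)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNewick:
    def test_tree_preserves_leaves_and_root_depth(self):
        d = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float))
        nwk = to_newick(complete_linkage(d))
        import skbio

        tree = skbio.TreeNode.read([nwk])
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        # leaf depth equals the root merge height
        assert tree.find("C").accumulate_to_ancestor(tree) == pytest.approx(8.0)
        assert tree.find("A").accumulate_to_ancestor(tree) == pytest.approx(8.0)


# ---------------------------------------------------------------------------
# tree cutting

def _cut_labels(m, truth=None, mcs=3, ds=2):
    d = manhattan_distance(m)
    t = complete_linkage(d)
    a = dynamic_tree_cut(t, d, mcs, ds)
    lab = [a.labels[i] for i in m.isolate_ids]
    if truth is None:
        return a, lab
    return a, lab, [truth.cluster_labels[i] for i in m.isolate_ids]


class TestDynamicTreeCut:
    def test_noiseless_planted_blocks_recovered_exactly(self):
        m, truth = simulate_ko_matrix(3, 10, 100, 30, 0.0, seed=2)
        a, lab, tl = _cut_labels(m, truth)
        assert a.n_clusters == 3
        assert adjusted_rand_index(lab, tl) == 1.0

    def test_noisy_blocks_recovered_with_high_ari(self):
        m, truth = simulate_ko_matrix(2, 10, 100, 30, 0.05, seed=3)
        a, lab, tl = _cut_labels(m, truth, mcs=4)
        assert adjusted_rand_index(lab, tl) >= 0.9

    def test_homogeneous_block_is_one_cluster(self):
        m, _ = simulate_ko_matrix(1, 12, 100, 10, 0.0, seed=4)
        a, _ = _cut_labels(m)
        assert a.n_clusters == 1
        assert all(v == 1 for v in a.labels.values())

    def test_min_cluster_size_larger_than_n_rejected(self):
        m, _ = simulate_ko_matrix(2, 3, 20, 5, 0.0, seed=1)
        d = manhattan_distance(m)
        t = complete_linkage(d)
        with pytest.raises(ValueError):
            dynamic_tree_cut(t, d, min_cluster_size=7)

    def test_pipeline_invariant_under_ko_column_permutation(self):
        m, _ = simulate_ko_matrix(3, 8, 80, 20, 0.02, seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_kos)
        m2 = KOProfileMatrix(m.isolate_ids, [m.ko_ids[j] for j in perm],
                             m.values[:, perm])

        def full_pipeline(mat):
            f, _ = filter_zero_variance(mat)
            r, _ = collapse_duplicate_kos(f)
            d = manhattan_distance(r)
            return dynamic_tree_cut(complete_linkage(d), d)

        a1 = full_pipeline(m)
        a2 = full_pipeline(m2)
        l1 = [a1.labels[i] for i in m.isolate_ids]
        l2 = [a2.labels[i] for i in m.isolate_ids]
        assert adjusted_rand_index(l1, l2) == 1.0


class TestSplitCluster:
    def test_split_increases_cluster_count_by_one(self, toy_labels):
        members = toy_labels.members(1)
        part = {iso: (1 if i < 2 else 2) for i, iso in enumerate(members)}
        out = split_cluster(toy_labels, 1, part)
        assert out.n_clusters == toy_labels.n_clusters + 1
        # other cluster untouched
        assert out.members(2) == toy_labels.members(2)

    def test_one_sided_partition_rejected(self, toy_labels):
        part = {iso: 1 for iso in toy_labels.members(1)}
        with pytest.raises(ValueError):
            split_cluster(toy_labels, 1, part)

    def test_partition_must_cover_members(self, toy_labels):
        part = {iso: 1 for iso in toy_labels.members(1)[:-1]}
        part[toy_labels.members(1)[0]] = 2
        with pytest.raises(ValueError):
            split_cluster(toy_labels, 1, part)

    def test_split_then_merge_restores_co_assignment(self, toy_labels):
        members = toy_labels.members(1)
        part = {iso: (1 if i % 2 else 2) for i, iso in enumerate(members)}
        out = split_cluster(toy_labels, 1, part)
        remerged = {iso: (1 if out.labels[iso] > toy_labels.n_clusters else out.labels[iso])
                    for iso in out.labels}
        co = lambda lab: {frozenset((a, b)) for a in lab for b in lab
                          if a < b and lab[a] == lab[b]}
        assert co(remerged) == co(toy_labels.labels)
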