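"""Jaccard matching, annotation rules, cluster similarity, dendrograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ornstage import (
    cluster_profiles,
    AnnotationRule,
    annotate_by_receptor,
    annotate_by_rules,
    jaccard,
    jaccard_matrix,
    match_clusters,
    default_one_way_policy,
    pearson_cluster_similarity,
    dendrogram,
    call_receptors,
)
from ornstage.match import ClusterProfiles

from conftest import make_norm_adata


class TestJaccard:
    def test_identity_and_disjoint(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_shared_one_of_three(self):
        assert jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_two_empty_sets_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 0.0

    def test_matrix_matches_bruteforce_on_random_sets(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(30)]
        sets_a = {
            f"a{i}": frozenset(rng.choice(universe, size=rng.integers(0, 12), replace=False))
            for i in range(10)
        }
        sets_b = {
            f"b{i}": frozenset(rng.choice(universe, size=rng.integers(0, 12), replace=False))
            for i in range(10)
        }
        J = jaccard_matrix(sets_a, sets_b)
        for ka, va in sets_a.items():
            for kb, vb in sets_b.items():
                inter = len(set(va) & set(vb))
                union = len(set(va) | set(vb))
                expected = inter / union if union else 0.0
                assert J.loc[ka, kb] == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(
        st.frozensets(st.integers(0, 20), max_size=15),
        st.frozensets(st.integers(0, 20), max_size=15),
    )
    def test_symmetry_and_bounds(self, x, y):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            j_xy, j_yx = jaccard(x, y), jaccard(y, x)
        assert j_xy == j_yx
        assert 0.0 <= j_xy <= 1.0
        if x or y:
            assert (j_xy == 1.0) == (x == y)


class TestMatchClusters:
    def test_diagonal_dominant_all_two_way(self):
        sim = pd.DataFrame(
            np.eye(4) * 0.9 + 0.01,
            index=[f"a{i}" for i in range(4)],
            columns=[f"b{i}" for i in range(4)],
        )
        res = match_clusters(sim)
        assert res.two_way == {f"a{i}": f"b{i}" for i in range(4)}
        assert not res.one_way

    def test_three_by_three_hand_enumeration(self):
        sim = pd.DataFrame(
            [[0.9, 0.1, 0.0], [0.8, 0.2, 0.1], [0.0, 0.1, 0.7]],
            index=["A0", "A1", "A2"],
            columns=["B0", "B1", "B2"],
        )
        allowed = match_clusters(sim, allow_one_way=True)
        assert allowed.two_way == {"A0": "B0", "A2": "B2"}
        assert allowed.one_way == {"A1": "B0"}
        forbidden = match_clusters(sim, allow_one_way=False)
        assert forbidden.two_way == {"A0": "B0", "A2": "B2"}
        assert not forbidden.one_way

    def test_ties_reported_never_broken(self):
        sim = pd.DataFrame(
            [[0.5, 0.5], [0.1, 0.2]], index=["A0", "A1"], columns=["B0", "B1"]
        )
        res = match_clusters(sim)
        assert "A0" in res.ties
        assert all(m.cluster_a != "A0" for m in res.matches)

    def test_all_zero_row_unmatched(self):
        sim = pd.DataFrame(
            [[0.0, 0.0], [0.3, 0.1]], index=["A0", "A1"], columns=["B0", "B1"]
        )
        res = match_clusters(sim)
        assert "A0" in res.unmatched
        assert res.two_way == {"A1": "B0"}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        sim = pd.DataFrame(
            rng.uniform(0.01, 1, size=(6, 6)),
            index=[f"a{i}" for i in range(6)],
            columns=[f"b{i}" for i in range(6)],
        )
        base = match_clusters(sim)
        perm = rng.permutation(6)
        shuffled = sim.iloc[perm, rng.permutation(6)]
        again = match_clusters(shuffled)
        as_pairs = lambda r: {(m.cluster_a, m.cluster_b, m.kind) for m in r.matches}
        assert as_pairs(base) == as_pairs(again)

    def test_two_way_is_partial_injection(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            sim = pd.DataFrame(
                rng.uniform(size=(5, 7)),
                index=[f"a{i}" for i in range(5)],
                columns=[f"b{i}" for i in range(7)],
            )
            res = match_clusters(sim)
            targets = list(res.two_way.values())
            assert len(targets) == len(set(targets))

    def test_one_way_policy_by_stage_pair(self):
        assert default_one_way_policy("24hAPF", "42hAPF")
        assert not default_one_way_policy("42hAPF", "adult")
        assert not default_one_way_policy("24hAPF", "adult")


class TestAnnotateByReceptor:
    def _calls(self, values, genes):
        return call_receptors(
            make_norm_adata(values, genes, categories="receptor")
        )

    def test_cluster_specific_receptor_labels_cluster(self):
        values = np.zeros((20, 1))
        values[:10, 0] = 6.0  # receptor on in 10 cells, all in cluster 3
        calls = self._calls(values, ["r1"])
        labels = np.r_[np.full(10, 3), np.full(10, 0)]
        out = annotate_by_receptor(labels, calls, {"r1": "DM1"})
        assert out == {"3": "DM1"}

    def test_four_positive_cells_fail_expressed_rule(self):
        values = np.zeros((20, 1))
        values[:4, 0] = 6.0
        calls = self._calls(values, ["r1"])
        labels = np.r_[np.full(10, 3), np.full(10, 0)]
        assert annotate_by_receptor(labels, calls, {"r1": "DM1"}) == {}

    def test_split_receptor_fails_majority_rule(self):
        values = np.zeros((40, 1))
        values[:10, 0] = 6.0
        values[20:30, 0] = 6.0  # 50/50 split between clusters 0 and 1
        calls = self._calls(values, ["r1"])
        labels = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        assert annotate_by_receptor(labels, calls, {"r1": "DM1"}) == {}

    def test_compound_label_for_multi_type_cluster(self):
        values = np.zeros((30, 2))
        values[:10, 0] = 6.0
        values[10:20, 1] = 6.0
        calls = self._calls(values, ["r1", "r2"])
        labels = np.r_[np.zeros(20, dtype=int), np.ones(10, dtype=int)]
        out = annotate_by_receptor(labels, calls, {"r1": "VM3", "r2": "VA5"})
        assert out == {"0": "VA5_VM3"}

    def test_empty_map_raises(self):
        calls = self._calls(np.zeros((5, 1)), ["r1"])
        with pytest.raises(ValueError):
            annotate_by_receptor(np.zeros(5, dtype=int), calls, {})


class TestAnnotateByRules:
    def _profiles(self):
        means = pd.DataFrame(
            {"c0": [5.0, 0.0, 1.0], "c1": [0.0, 5.0, 1.0], "c2": [0.0, 5.0, 1.0]},
            index=["fkh", "shared", "flat"],
        )
        return ClusterProfiles(means=means, n_cells=pd.Series({"c0": 10, "c1": 8, "c2": 9}))

    def test_unique_fire_assigns_label(self):
        rules = [AnnotationRule(label="V", required=(("fkh", 2.0),))]
        labels, ambiguous = annotate_by_rules(self._profiles(), rules)
        assert labels == {"c0": "V"}
        assert not ambiguous

    def test_multi_cluster_fire_is_ambiguous(self):
        rules = [AnnotationRule(label="X", required=(("shared", 2.0),))]
        labels, ambiguous = annotate_by_rules(self._profiles(), rules)
        assert labels == {}
        assert ambiguous == {"X": ["c1", "c2"]}

    def test_forbidden_gene_blocks_fire(self):
        rules = [
            AnnotationRule(
                label="X", required=(("shared", 2.0),), forbidden=(("flat", 0.5),)
            )
        ]
        labels, _ = annotate_by_rules(self._profiles(), rules)
        assert labels == {}

    def test_absent_gene_skips_rule_with_warning(self):
        rules = [AnnotationRule(label="V", required=(("nope", 2.0),))]
        with pytest.warns(UserWarning, match="nope"):
            labels, _ = annotate_by_rules(self._profiles(), rules)
        assert labels == {}


class TestClusterProfilesAndPearson:
    def test_profile_means_match_manual_average(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 5, size=(9, 4))
        adata = make_norm_adata(values, list("abcd"))
        labels = np.array([0, 0, 0, 1, 1, 1, -1, 2, 2])
        prof = cluster_profiles(adata, labels)
        np.testing.assert_allclose(prof.means["0"], values[:3].mean(axis=0))
        np.testing.assert_allclose(prof.means["2"], values[7:].mean(axis=0))
        assert "-1" not in prof.clusters
        assert prof.n_cells["1"] == 3

    def test_self_and_affine_correlation(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 5, size=10)
        means = pd.DataFrame(
            {"p": base, "affine": 3.0 * base + 1.0, "noise": rng.uniform(size=10)},
            index=[f"g{i}" for i in range(10)],
        )
        prof = ClusterProfiles(means=means, n_cells=pd.Series({"p": 5, "affine": 5, "noise": 5}))
        r = pearson_cluster_similarity(prof, prof, means.index)
        assert r.loc["p", "p"] == pytest.approx(1.0)
        assert r.loc["p", "affine"] == pytest.approx(1.0)

    def test_zero_variance_profile_flagged_nan(self):
        means = pd.DataFrame(
            {"flat": np.ones(5), "var": np.arange(5, dtype=float)},
            index=[f"g{i}" for i in range(5)],
        )
        prof = ClusterProfiles(means=means, n_cells=pd.Series({"flat": 3, "var": 3}))
        with pytest.warns(UserWarning):
            r = pearson_cluster_similarity(prof, prof, means.index)
        assert np.isnan(r.loc["flat", "var"])

    def test_matches_independent_pearson(self):
        rng = np.random.default_rng(12)
        means = pd.DataFrame(
            rng.uniform(0, 5, size=(20, 3)), columns=["a", "b", "c"],
            index=[f"g{i}" for i in range(20)],
        )
        prof = ClusterProfiles(means=means, n_cells=pd.Series({"a": 4, "b": 4, "c": 4}))
        r = pearson_cluster_similarity(prof, prof, means.index)
        expected = np.corrcoef(means.to_numpy().T)
        np.testing.assert_allclose(r.to_numpy().astype(float), expected, rtol=1e-10)


class TestDendrogram:
    def test_identical_profiles_merge_first_at_zero(self):
        means = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [9.0, 9.0]},
            index=["g1", "g2"],
        )
        prof = ClusterProfiles(means=means, n_cells=pd.Series({"a": 2, "b": 2, "c": 2}))
        newick, Z = dendrogram(prof)
        assert Z[0, 2] == 0.0  # first merge at height 0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # the identical pair
        assert newick.endswith(";")

    def test_collinear_profiles_merge_in_distance_order(self):
        means = pd.DataFrame(
            {"x0": [0.0], "x1": [1.0], "x10": [10.0]}, index=["g"]
        )
        prof = ClusterProfiles(means=means, n_cells=pd.Series({"x0": 1, "x1": 1, "x10": 1}))
        _, Z = dendrogram(prof)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}  # (x0, x1) first

    def test_topology_matches_naive_agglomerative_oracle(self):
        rng = np.random.default_rng(3)
        names = ["p0", "p1", "p2", "p3", "p4"]
        means = pd.DataFrame(
            rng.uniform(0, 10, size=(6, 5)), columns=names,
            index=[f"g{i}" for i in range(6)],
        )
        prof = ClusterProfiles(means=means, n_cells=pd.Series(1, index=names))
        newick, _ = dendrogram(prof)

        # independent oracle: naive average-linkage agglomeration tracking
        # the clades it creates
        pts = {n: means[n].to_numpy() for n in names}
        clusters = {i: frozenset([n]) for i, n in enumerate(names)}
        clades = []
        while len(clusters) > 1:
            best = None
            for i in clusters:
                for j in clusters:
                    if i >= j:
                        continue
                    d = np.mean(
                        [
                            np.linalg.norm(pts[a] - pts[b])
                            for a in clusters[i]
                            for b in clusters[j]
                        ]
                    )
                    if best is None or d < best[0]:
                        best = (d, i, j)
            _, i, j = best
            merged = clusters.pop(i) | clusters.pop(j)
            key = max(list(clusters) + [i, j]) + 1
            clusters[key] = merged
            clades.append(merged)

        from skbio.tree import TreeNode
        import io

        tree = TreeNode.read(io.StringIO(newick))
        got_clades = {
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips(include_self=True)
        }
        assert set(clades[:-1]) <= got_clades

    def test_single_profile_raises(self):
        means = pd.DataFrame({"only": [1.0]}, index=["g"])
        prof = ClusterProfiles(means=means, n_cells=pd.Series({"only": 1}))
        with pytest.raises(ValueError):
            dendrogram(prof)
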