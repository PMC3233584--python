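"""Cluster detection, barcode sharing, identifiability rules and categories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodesurvey.delimit import (
    assess_species,
    barcode_sharing,
    deep_divergence_table,
    detect_clusters,
)
from barcodesurvey.distance import pairwise_matrix
from barcodesurvey.errors import DatasetError, MissingDistanceError

from conftest import BASE_SEQ, make_dataset, make_matrix, mutate, tree_from_newick


class TestDetectClusters:
    def test_all_zero_one_cluster(self):
        m = make_matrix(["x1", "x2", "x3"], {
            ("x1", "x2"): 0, ("x1", "x3"): 0, ("x2", "x3"): 0})
        part = detect_clusters(m, ["x1", "x2", "x3"])
        assert part.n_clusters == 1
        assert sorted(part.clusters[0].members) == ["x1", "x2", "x3"]

    def test_two_clusters_between_min(self):
        m = make_matrix(["x1", "x2", "x3"], {
            ("x1", "x2"): 0.005, ("x1", "x3"): 0.05, ("x2", "x3"): 0.05})
        part = detect_clusters(m, ["x1", "x2", "x3"])
        assert part.n_clusters == 2
        assert sorted(len(c.members) for c in part.clusters) == [1, 2]
        ((lo, hi),) = part.between.values()
        assert lo == pytest.approx(0.05) and hi == pytest.approx(0.05)

    def test_single_linkage_chaining(self):
        m = make_matrix(["x1", "x2", "x3"], {
            ("x1", "x2"): 0.01, ("x2", "x3"): 0.01, ("x1", "x3"): 0.02})
        part = detect_clusters(m, ["x1", "x2", "x3"])
        assert part.n_clusters == 1  # chained through x2

    def test_missing_distance_errors(self):
        m = make_matrix(["x1", "x2", "x3"], {("x1", "x2"): 0.01})
        with pytest.raises(MissingDistanceError):
            detect_clusters(m, ["x1", "x2", "x3"])

    def test_singleton_member(self):
        m = make_matrix(["x1"], {})
        part = detect_clusters(m, ["x1"])
        assert part.n_clusters == 1
        assert part.clusters[0].within_min is None

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_validity_random(self, seed):
        """Clusters partition members; both threshold guarantees hold."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        labels = [f"x{i}" for i in range(n)]
        base = rng.uniform(0, 0.08, size=(n, n))
        d = np.triu(base, 1) + np.triu(base, 1).T
        m = make_matrix(labels, {
            (labels[i], labels[j]): d[i, j]
            for i in range(n) for j in range(i + 1, n)})
        thr = 0.015
        part = detect_clusters(m, labels, thr)
        all_members = sorted(x for c in part.clusters for x in c.members)
        assert all_members == sorted(labels)
        # between-cluster minimum strictly above threshold
        for (lo, hi) in part.between.values():
            assert lo > thr and hi >= lo
        # within-cluster connectivity: each member joins via a path <= thr
        for c in part.clusters:
            if len(c.members) == 1:
                continue
            idx = [labels.index(x) for x in c.members]
            sub = d[np.ix_(idx, idx)]
            reach = sub <= thr
            paths = np.linalg.matrix_power(
                reach.astype(int) + np.eye(len(idx), dtype=int), len(idx))
            assert (paths > 0).all()

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, seed):
        """Raising the threshold never increases the cluster count."""
        rng = np.random.default_rng(seed)
        n = 8
        labels = [f"x{i}" for i in range(n)]
        base = rng.uniform(0, 0.05, size=(n, n))
        d = np.triu(base, 1) + np.triu(base, 1).T
        m = make_matrix(labels, {
            (labels[i], labels[j]): d[i, j]
            for i in range(n) for j in range(i + 1, n)})
        counts = [detect_clusters(m, labels, t).n_clusters
                  for t in (0.005, 0.01, 0.02, 0.04)]
        assert counts == sorted(counts, reverse=True)


class TestBarcodeSharing:
    def _dataset(self):
        return make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "Ch"),
            ("a2", "Genus alpha", BASE_SEQ, "Pu"),
            ("b1", "Genus beta", BASE_SEQ, "Ch"),       # identical to alpha
            ("c1", "Genus gamma", mutate(BASE_SEQ, range(20, 38)), "N"),
        ])

    def test_identical_sequences_shared(self):
        ds = self._dataset()
        m = pairwise_matrix(ds)
        v = barcode_sharing(m, ds, "Genus alpha", "Genus beta")
        assert v.shared and v.zero_distance
        assert v.geography == "sympatric"  # Ch in common

    def test_distant_pair_not_shared(self):
        ds = self._dataset()
        m = pairwise_matrix(ds)
        v = barcode_sharing(m, ds, "Genus alpha", "Genus gamma")
        assert not v.shared
        assert v.geography == "allopatric"

    def test_different_genera_error(self):
        ds = make_dataset([
            ("a1", "Alpha one", BASE_SEQ),
            ("b1", "Beta one", BASE_SEQ),
        ])
        m = pairwise_matrix(ds)
        with pytest.raises(DatasetError, match="congeners"):
            barcode_sharing(m, ds, "Alpha one", "Beta one")

    def test_interdigitation_trigger(self):
        # mutually non-monophyletic with interleaved tips, no zero distance
        labels = ["a1", "a2", "b1", "b2"]
        m = make_matrix(labels, {(x, y): 0.02 for i, x in enumerate(labels)
                                 for y in labels[i + 1:]})
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "Ch"),
            ("a2", "Genus alpha", mutate(BASE_SEQ, [0]), "Ch"),
            ("b1", "Genus beta", mutate(BASE_SEQ, [1]), "Pu"),
            ("b2", "Genus beta", mutate(BASE_SEQ, [2]), "Pu"),
        ])
        tree = tree_from_newick("((a1,b1),(a2,b2));")
        v = barcode_sharing(m, ds, "Genus alpha", "Genus beta", tree=tree)
        assert v.shared and v.interdigitated and not v.zero_distance
        assert v.geography == "allopatric"

    def test_missing_areas_undetermined(self):
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ),
            ("b1", "Genus beta", BASE_SEQ),
        ])
        m = pairwise_matrix(ds)
        v = barcode_sharing(m, ds, "Genus alpha", "Genus beta")
        assert v.geography == "undetermined"


class TestAssessSpecies:
    def test_clear_species_identifiable(self):
        """Monophyletic, distant from congeners, low intraspecific spread."""
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "N"),
            ("a2", "Genus alpha", mutate(BASE_SEQ, [0]), "N"),
            ("b1", "Genus beta", mutate(BASE_SEQ, range(30, 46)), "Ron"),
            ("b2", "Genus beta", mutate(BASE_SEQ, list(range(30, 46)) + [1]), "Ron"),
        ])
        m = pairwise_matrix(ds)
        tree = tree_from_newick("((a1,a2),(b1,b2));")
        q5 = 0.05
        a = assess_species("Genus alpha", tree, m, ds, q5)
        assert a.identifiable and not a.categories
        assert a.monophyly_status == "monophyletic"
        assert a.sister_species == "Genus beta"

    def test_close_sisters_category_iii(self):
        """(4,1) sisters at 0.5% K2P: the test cannot reject chance (p=0.1)."""
        ds = make_dataset(
            [(f"a{i}", "Genus alpha", BASE_SEQ, "N") for i in range(1, 5)]
            + [("b1", "Genus beta", mutate(BASE_SEQ, [0]), "Ron")])
        m = pairwise_matrix(ds)
        tree = tree_from_newick("(((a1,a2),(a3,a4)),b1);")
        a = assess_species("Genus alpha", tree, m, ds, q5=0.05)
        assert a.rule_c and not a.identifiable
        assert a.categories == {"III"}
        assert a.monophyly_test_p == pytest.approx(0.1)
        assert a.rule_c_close_sister_trigger

    def test_interdigitated_deep_clusters_categories_i_iv(self):
        """Divergent clusters straddling a sympatric congener: I and IV."""
        labels = ["x1", "x2", "x3", "x4", "y1", "y2"]
        pairs = {}
        near = 0.004
        far = 0.06
        groups = {"x1": 0, "x2": 0, "x3": 1, "x4": 1, "y1": 1, "y2": 1}
        for i, p in enumerate(labels):
            for q in labels[i + 1:]:
                pairs[(p, q)] = near if groups[p] == groups[q] else far
        m = make_matrix(labels, pairs)
        ds = make_dataset(
            [("x1", "Genus ex", BASE_SEQ, "Ch"),
             ("x2", "Genus ex", mutate(BASE_SEQ, [0]), "Ch"),
             ("x3", "Genus ex", mutate(BASE_SEQ, [1]), "Ch"),
             ("x4", "Genus ex", mutate(BASE_SEQ, [2]), "Ch"),
             ("y1", "Genus why", mutate(BASE_SEQ, [3]), "Ch"),
             ("y2", "Genus why", mutate(BASE_SEQ, [4]), "Ch")])
        tree = tree_from_newick("((x1,x2),(y1,(x3,(x4,y2))));")
        a = assess_species("Genus ex", tree, m, ds, q5=0.02)
        assert not a.identifiable
        assert a.rule_a  # non-monophyletic
        assert "IV" in a.categories
        assert "I" in a.categories  # interdigitated + sympatric
        assert a.n_clusters == 2

    def test_singleton_cannot_fail_rule_a(self):
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "N"),
            ("b1", "Genus beta", mutate(BASE_SEQ, range(30, 46)), "Ron"),
        ])
        m = pairwise_matrix(ds)
        tree = tree_from_newick("(a1,b1);")
        a = assess_species("Genus alpha", tree, m, ds, q5=0.05)
        assert a.monophyly_status == "trivial"
        assert not a.rule_a


class TestDeepDivergenceTable:
    def _assessments(self, m, ds, tree, q5=0.05):
        return {s: assess_species(s, tree, m, ds, q5) for s in ds.species_list}

    def test_no_deep_species_empty(self):
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "N"),
            ("a2", "Genus alpha", mutate(BASE_SEQ, [0]), "N"),
            ("b1", "Genus beta", mutate(BASE_SEQ, range(30, 46)), "Ron"),
            ("b2", "Genus beta", mutate(BASE_SEQ, list(range(30, 46)) + [1]), "Ron"),
        ])
        m = pairwise_matrix(ds)
        tree = tree_from_newick("((a1,a2),(b1,b2));")
        assessments = self._assessments(m, ds, tree)
        parts = {s: detect_clusters(m, ds.species_members(s), species=s,
                                    dataset=ds) for s in ds.species_list}
        assert deep_divergence_table(assessments, parts) == []

    def test_monophyletic_deep_species_included(self):
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "N"),
            ("a2", "Genus alpha", mutate(BASE_SEQ, range(0, 21)), "Ron"),  # ~11%
            ("b1", "Genus beta", mutate(BASE_SEQ, range(100, 140)), "Be"),
            ("b2", "Genus beta", mutate(BASE_SEQ, list(range(100, 140)) + [1]), "Be"),
        ])
        m = pairwise_matrix(ds)
        tree = tree_from_newick("((a1,a2),(b1,b2));")
        assessments = self._assessments(m, ds, tree, q5=0.03)
        parts = {s: detect_clusters(m, ds.species_members(s), species=s,
                                    dataset=ds) for s in ds.species_list}
        rows = deep_divergence_table(assessments, parts)
        assert [r["species"] for r in rows] == ["Genus alpha"]
        assert rows[0]["n_clusters"] == 2
        assert rows[0]["max_within"] == pytest.approx(
            m.get("a1", "a2"))

    def test_non_monophyletic_deep_species_routed_out(self):
        """Paraphyletic deep species belong to the category-IV table, not here."""
        labels = ["x1", "x2", "x3", "x4", "y1", "y2"]
        near, far = 0.004, 0.06
        groups = {"x1": 0, "x2": 0, "x3": 1, "x4": 1, "y1": 1, "y2": 1}
        pairs = {(p, q): (near if groups[p] == groups[q] else far)
                 for i, p in enumerate(labels) for q in labels[i + 1:]}
        m = make_matrix(labels, pairs)
        ds = make_dataset(
            [("x1", "Genus ex", BASE_SEQ, "Ch"),
             ("x2", "Genus ex", mutate(BASE_SEQ, [0]), "Ch"),
             ("x3", "Genus ex", mutate(BASE_SEQ, [1]), "Ch"),
             ("x4", "Genus ex", mutate(BASE_SEQ, [2]), "Ch"),
             ("y1", "Genus why", mutate(BASE_SEQ, [3]), "Ch"),
             ("y2", "Genus why", mutate(BASE_SEQ, [4]), "Ch")])
        tree = tree_from_newick("((x1,x2),(y1,(x3,(x4,y2))));")
        assessments = {s: assess_species(s, tree, m, ds, q5=0.02)
                       for s in ds.species_list}
        parts = {s: detect_clusters(m, ds.species_members(s), species=s,
                                    dataset=ds) for s in ds.species_list}
        rows = deep_divergence_table(assessments, parts)
        assert "Genus ex" not in [r["species"] for r in rows]

    def test_decision_soundness_recheck(self):
        """identifiable=True implies every individual rule is quiet."""
        ds = make_dataset([
            ("a1", "Genus alpha", BASE_SEQ, "N"),
            ("a2", "Genus alpha", mutate(BASE_SEQ, [0]), "N"),
            ("b1", "Genus beta", mutate(BASE_SEQ, range(30, 46)), "Ron"),
            ("b2", "Genus beta", mutate(BASE_SEQ, list(range(30, 46)) + [1]), "Ron"),
        ])
        m = pairwise_matrix(ds)
        tree = tree_from_newick("((a1,a2),(b1,b2));")
        for s in ds.species_list:
            a = assess_species(s, tree, m, ds, q5=0.05)
            if a.identifiable:
                assert not (a.rule_a or a.rule_b or a.rule_c)
                assert a.monophyly_status in ("monophyletic", "trivial")
                assert not a.shares_with
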