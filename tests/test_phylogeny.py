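"""Poisson distances, NJ construction, bootstrap and clade labeling."""

import dendropy
import numpy as np
import pytest

from conftest import (
    dendropy_splits,
    graph_leaf_distances,
    graph_splits,
    random_additive_tree,
)
from optfam.phylogeny import (
    Alignment,
    DistanceMatrix,
    UndefinedDistanceError,
    assign_clades,
    bootstrap_support,
    nj_tree,
    poisson_distance,
    tree_path_distances,
)


class TestPoissonDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(["a", "b"], ["MKVL", "MKVL"])
        assert poisson_distance(aln).d[0, 1] == 0.0

    def test_closed_form_ten_percent(self):
        row_a = "A" * 100
        row_b = "C" * 10 + "A" * 90
        d = poisson_distance(Alignment(["a", "b"], [row_a, row_b])).d[0, 1]
        assert d == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_matches_column_count_oracle(self, rng):
        aas = "ACDEFGHIKL"
        rows = [
            "".join(aas[i] for i in rng.integers(0, 10, 200)) for _ in range(4)
        ]
        dm = poisson_distance(Alignment(list("abcd"), rows))
        for i in range(4):
            for j in range(i + 1, 4):
                p = sum(x != y for x, y in zip(rows[i], rows[j])) / 200
                assert dm.d[i, j] == pytest.approx(-np.log(1 - p))
                assert dm.d[i, j] >= p  # correction only stretches

    def test_saturated_pair_raises(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(UndefinedDistanceError, match="a.*b"):
            poisson_distance(aln)

    def test_gap_policies(self):
        # column 2 (where a and b differ) is gapped in c: complete deletion
        # removes it for everyone, pairwise deletion keeps it for a vs b
        aln = Alignment(["a", "b", "c"], ["AKV", "ADV", "A-V"])
        complete = poisson_distance(aln, "complete")
        assert complete.d[0, 1] == 0.0
        pairwise = poisson_distance(aln, "pairwise")
        assert pairwise.d[0, 1] == pytest.approx(-np.log(1 - 1 / 3))
        with pytest.raises(UndefinedDistanceError):
            poisson_distance(Alignment(["a", "b"], ["A-", "-A"]), "pairwise")


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = nj_tree(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_recovers_known_five_leaf_tree(self, rng):
        labels = list("ABCDE")
        g = random_additive_tree(labels, rng)
        d = graph_leaf_distances(g, labels)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert dendropy_splits(tree, labels) == graph_splits(g, labels)
        paths = tree_path_distances(tree)
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                key = tuple(sorted((a, labels[j])))
                assert paths[key] == pytest.approx(d[i, j], abs=1e-9)

    def test_equal_distances_zero_internal_branches(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(n)], d))
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is None or edge.head_node.is_leaf():
                continue
            assert edge.length == pytest.approx(0.0, abs=1e-12)

    def test_total_length_invariant_under_taxon_order(self, rng):
        labels = list("ABCDEF")
        g = random_additive_tree(labels, rng)
        d = graph_leaf_distances(g, labels)
        t1 = nj_tree(DistanceMatrix(labels, d))
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        t2 = nj_tree(DistanceMatrix(labels2, d[np.ix_(perm, perm)]))
        assert t1.length() == pytest.approx(t2.length(), abs=1e-9)
        assert dendropy_splits(t1, labels) == dendropy_splits(t2, labels)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            nj_tree(dm)


def _clustered_alignment(rng, n_cols=120):
    """Six taxa, two clean 3-taxon groups separated at most columns."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    base = [aas[i] for i in rng.integers(0, 20, n_cols)]
    other = [aas[(i + 1) % 20] for i in rng.integers(0, 20, n_cols)]
    rows = []
    for k in range(6):
        template = base if k < 3 else other
        row = list(template)
        for pos in rng.choice(n_cols, size=8, replace=False):
            row[pos] = aas[rng.integers(0, 20)]
        rows.append("".join(row))
    return Alignment([f"t{k}" for k in range(6)], rows)


class TestBootstrap:
    def test_deterministic_under_seed(self, rng):
        aln = _clustered_alignment(rng)
        t1 = bootstrap_support(aln, replicates=100, seed=7)
        t2 = bootstrap_support(aln, replicates=100, seed=7)
        s1 = t1.as_string(schema="newick", suppress_rooting=True)
        assert s1 == t2.as_string(schema="newick", suppress_rooting=True)

    def test_supports_in_range(self, rng):
        aln = _clustered_alignment(rng)
        tree = bootstrap_support(aln, replicates=100, seed=1)
        supports = [
            int(n.label) for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        ]
        assert supports and all(0 <= s <= 100 for s in supports)

    def test_unanimous_split_gets_full_support(self, rng):
        """Every column separates the same two groups → that edge reads 100."""
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(aas[i] for i in rng.integers(0, 20, 80))
        other = "".join(aas[(i + 3) % 20] for i in rng.integers(0, 20, 80))
        aln = Alignment(
            [f"t{k}" for k in range(6)], [base] * 3 + [other] * 3
        )
        tree = bootstrap_support(aln, replicates=50, seed=5)
        group = {"t0", "t1", "t2"}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if leaves in (group, {"t3", "t4", "t5"}):
                assert node.label == "100"
                break
        else:
            pytest.fail("planted bipartition missing from the tree")

    def test_single_replicate_granularity(self, rng):
        aln = _clustered_alignment(rng)
        tree = bootstrap_support(aln, replicates=1, seed=3)
        supports = {
            int(n.label) for n in tree.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None and n.label
        }
        assert supports <= {0, 100}

    def test_matches_reference_nj_topology(self, rng):
        """Cross-check: our NJ topology equals scikit-bio's on the same matrix."""
        skbio = pytest.importorskip("skbio")
        labels = list("ABCDEF")
        g = random_additive_tree(labels, rng)
        d = graph_leaf_distances(g, labels)
        d = (d + d.T) / 2  # dijkstra round-off breaks skbio's symmetry check
        ours = nj_tree(DistanceMatrix(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref_tree = dendropy.Tree.get(
            data=str(ref), schema="newick",
            taxon_namespace=dendropy.TaxonNamespace(),
        )
        assert dendropy_splits(ours, labels) == dendropy_splits(ref_tree, labels)


class TestAssignClades:
    newick = "(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(q1:1,out:1):1);"

    def _tree(self):
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def test_clean_groups_labeled(self):
        tree = dendropy.Tree.get(
            data="(((a1:1,x1:1):1,a2:1):1,((b1:1,x2:1):1,b2:1):1,out:1);",
            schema="newick",
        )
        labels = assign_clades(
            tree, {"a1": "PT", "a2": "PT", "b1": "YSL", "b2": "YSL"}, "out"
        )
        assert labels["x1"] == "PT"
        assert labels["x2"] == "YSL"

    def test_taxon_sister_to_outgroup_ambiguous(self):
        labels = assign_clades(
            self._tree(), {"a1": "PT", "a2": "PT", "b1": "YSL", "b2": "YSL"},
            "out",
        )
        assert labels["q1"] == "ambiguous"

    def test_single_reference_group_labels_everything(self):
        labels = assign_clades(self._tree(), {"a1": "PT"}, "out")
        assert set(labels.values()) == {"PT"}

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError):
            assign_clades(self._tree(), {"a1": "PT"}, "nope")
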