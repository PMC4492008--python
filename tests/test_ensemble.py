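"""Centroid-edge decomposition and ensemble construction."""

import pytest

from conftest import balanced_newick
from hmmstitch import (
    DNA,
    Alignment,
    PhyloTree,
    RunConfig,
    build_ensemble,
    decompose,
    find_centroid_edge,
)


class TestCentroidEdge:
    def test_quartet_splits_two_and_two(self):
        smaller, larger = find_centroid_edge(PhyloTree.from_newick("((A,B),(C,D));"))
        assert {smaller, larger} == {frozenset("AB"), frozenset("CD")}

    def test_caterpillar_finds_three_three_split(self):
        tree = PhyloTree.from_newick("(((A,B),C),(D,(E,F)));")
        smaller, larger = find_centroid_edge(tree)
        assert len(smaller) == 3 and len(larger) == 3
        assert {smaller, larger} == {frozenset("ABC"), frozenset("DEF")}

    def test_three_leaf_star_uses_tie_rule(self):
        # all pendant edges give a 1|2 split; the tie rule picks the smaller
        # side with the lexicographically least label
        smaller, larger = find_centroid_edge(PhyloTree.from_newick("(A,B,C);"))
        assert smaller == frozenset("A")
        assert larger == frozenset("BC")

    def test_deterministic_under_repetition(self):
        tree = PhyloTree.from_newick(balanced_newick(16))
        assert find_centroid_edge(tree) == find_centroid_edge(tree)


class TestDecompose:
    def cfg(self, subset_max=10):
        return RunConfig(backbone_size=1000, subset_max=subset_max)

    def test_small_tree_single_node(self):
        tree = PhyloTree.from_newick("(" + ",".join(f"t{i}" for i in range(10)) + ");")
        node = decompose(tree, self.cfg())
        assert node.children == () and len(node.leaf_ids) == 10

    @pytest.mark.parametrize("n,expected_nodes", [(16, 3), (32, 7), (64, 15)])
    def test_balanced_tree_closed_form(self, n, expected_nodes):
        tree = PhyloTree.from_newick(balanced_newick(n))
        node = decompose(tree, self.cfg())
        assert len(list(node.nodes())) == expected_nodes

    def test_children_partition_parent(self):
        tree = PhyloTree.from_newick(balanced_newick(32))
        for node in decompose(tree, self.cfg()).nodes():
            if node.children:
                a, b = node.children
                assert a.leaf_ids | b.leaf_ids == node.leaf_ids
                assert not (a.leaf_ids & b.leaf_ids)

    def test_leaf_subsets_cover_all_and_respect_cap(self):
        tree = PhyloTree.from_newick(balanced_newick(64))
        decomp = decompose(tree, self.cfg())
        leaves = list(decomp.leaves())
        assert all(len(n.leaf_ids) <= 10 for n in leaves)
        union = frozenset().union(*(n.leaf_ids for n in leaves))
        assert union == frozenset(tree.leaf_labels)


class TestBuildEnsemble:
    def make_backbone(self, n=16, width=12):
        import numpy as np

        rng = np.random.default_rng(3)
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT-"), width).tolist())
            for i in range(n)
        }
        for sid in rows:  # no empty rows
            if set(rows[sid]) == {"-"}:
                rows[sid] = "A" * width
        return Alignment(rows, DNA)

    def test_mode_none_yields_single_hmm(self):
        aln = self.make_backbone()
        tree = PhyloTree.from_newick(balanced_newick(16))
        cfg = RunConfig(backbone_size=100, subset_max=10, decomposition_mode="none")
        ens = build_ensemble(aln, decompose(tree, cfg), cfg)
        assert len(ens) == 1
        assert ens.members[0].leaf_ids == frozenset(tree.leaf_labels)

    def test_hierarchical_and_disjoint_counts(self):
        aln = self.make_backbone()
        tree = PhyloTree.from_newick(balanced_newick(16))
        cfg = RunConfig(backbone_size=100, subset_max=10)
        decomp = decompose(tree, cfg)
        assert len(build_ensemble(aln, decomp, cfg)) == 3
        dis = build_ensemble(
            aln, decomp, cfg.with_overrides(decomposition_mode="disjoint")
        )
        assert len(dis) == 2
        # disjoint subsets partition the backbone
        seen = set()
        for m in dis:
            assert not (m.leaf_ids & seen)
            seen |= m.leaf_ids
        assert seen == frozenset(tree.leaf_labels)

    def test_full_set_hmm_is_subset_id_zero(self):
        aln = self.make_backbone()
        tree = PhyloTree.from_newick(balanced_newick(16))
        cfg = RunConfig(backbone_size=100, subset_max=10)
        ens = build_ensemble(aln, decompose(tree, cfg), cfg)
        assert ens.members[0].subset_id == 0
        assert ens.members[0].leaf_ids == frozenset(tree.leaf_labels)

    def test_column_maps_index_shared_backbone_columns(self):
        aln = Alignment({"t0": "A-C", "t1": "AGC", "t2": "--C"}, DNA)
        tree = PhyloTree.from_newick("(t0,t1,t2);")
        cfg = RunConfig(backbone_size=100, subset_max=2)
        ens = build_ensemble(aln, decompose(tree, cfg), cfg)
        for m in ens:
            sub = aln.restrict(m.leaf_ids)
            for k, col in enumerate(m.hmm.column_map):
                # the mapped backbone column holds >=1 residue of the subset
                assert any(sub.rows[sid][col] != "-" for sid in sub.rows)

    def test_restriction_to_sparse_row_shrinks_model(self):
        aln = Alignment({"t0": "A-C", "t1": "AGC", "t2": "--C"}, DNA)
        from hmmstitch import build_profile

        h12 = build_profile(aln.restrict(["t0", "t1"]))
        assert h12.K == 3
        h3 = build_profile(aln.restrict(["t2"]))
        assert h3.K == 1 and h3.column_map.tolist() == [2]
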