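"""Phylogenetic validation: homolog-count rule, placement test, toy NJ."""

import dendropy
import numpy as np
import pytest

from nanohgt.phylo import (
    homolog_count_rule,
    neighbor_joining,
    tree_placement_test,
    validate_candidates,
)
from nanohgt.seqio import GeneTree, HGTCall, parse_newick
from tree_enum import clade_masks, newick, oracle_placement, unrooted_topologies


class TestHomologCountRule:
    @pytest.mark.parametrize(
        "prok,euk,expected",
        [
            (6, 0, "HGT_NO_TREE"),     # "more than five" prokaryotic homologs
            (5, 0, "UNSUPPORTED"),     # five is not more than five
            (0, 0, "UNSUPPORTED"),
            (10, 3, "NEEDS_TREE"),     # homologs in both domains -> build a tree
            (0, 1, "NEEDS_TREE"),
            (100, 0, "HGT_NO_TREE"),
        ],
    )
    def test_boundaries(self, prok, euk, expected):
        assert homolog_count_rule(prok, euk) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            homolog_count_rule(-1, 0)


class TestPlacement:
    def test_query_nested_in_prokaryotes(self):
        gt = parse_newick("(((QUERY_g,PROK_p1),PROK_p2),(EUK_e1,EUK_e2));")
        res = tree_placement_test(gt)
        assert res.verdict == "HGT_TREE_SUPPORTED"
        a, b = res.witness_bipartition
        assert "QUERY_g" in a and not {t for t in a if t.startswith("EUK_")}
        assert {t for t in b if t.startswith("EUK_")}

    def test_query_with_eukaryote_sister_rejected(self):
        gt = parse_newick("(((QUERY_g,EUK_e1),PROK_p1),(PROK_p2,EUK_e2));")
        res = tree_placement_test(gt)
        assert res.verdict == "REJECTED" and res.witness_bipartition is None

    def test_prokaryotes_behind_eukaryotes_rejected(self):
        # no bipartition groups the query with prokaryotes only
        gt = parse_newick("(((QUERY_g,EUK_e1),EUK_e2),(PROK_p1,PROK_p2));")
        assert tree_placement_test(gt).verdict == "REJECTED"

    def test_witness_via_terminal_eukaryote_edge(self):
        # only the eukaryote's terminal edge separates prok+query from it
        gt = parse_newick("((QUERY_g,PROK_p1),PROK_p2,EUK_e1);")
        assert tree_placement_test(gt).verdict == "HGT_TREE_SUPPORTED"

    def test_multiple_query_tips_must_share_the_clade(self):
        good = parse_newick(
            "(((QUERY_a,QUERY_b),(PROK_p1,PROK_p2)),(EUK_e1,EUK_e2));"
        )
        assert tree_placement_test(good).verdict == "HGT_TREE_SUPPORTED"
        split = parse_newick(
            "(((QUERY_a,EUK_e1),(PROK_p1,QUERY_b)),(PROK_p2,EUK_e2));"
        )
        assert tree_placement_test(split).verdict == "REJECTED"

    def test_missing_class_is_error(self):
        gt = parse_newick("((QUERY_g,PROK_p1),PROK_p2);")
        with pytest.raises(ValueError, match="EUKARYOTE"):
            tree_placement_test(gt)

    def test_rerooting_invariance(self, sim_dataset):
        for gid, gt in list(sim_dataset.trees.items())[:4]:
            base = tree_placement_test(gt).verdict
            for edge in list(gt.tree.preorder_edge_iter())[1:]:
                clone = gt.tree.clone(depth=1)
                # find the corresponding edge in the clone by leaf set
                target_leaves = frozenset(
                    l.taxon.label for l in edge.head_node.leaf_iter()
                )
                for e2 in clone.preorder_edge_iter():
                    if e2.head_node.parent_node is None:
                        continue
                    leaves = frozenset(
                        l.taxon.label for l in e2.head_node.leaf_iter()
                    )
                    if leaves == target_leaves:
                        clone.reroot_at_edge(e2)
                        break
                assert (
                    tree_placement_test(GeneTree(clone, gt.tip_class)).verdict
                    == base
                )

    def test_extra_prok_tip_in_witness_clade_keeps_support(self):
        gt = parse_newick("(((QUERY_g,PROK_p1),PROK_p2),(EUK_e1,EUK_e2));")
        assert tree_placement_test(gt).verdict == "HGT_TREE_SUPPORTED"
        grown = parse_newick(
            "(((QUERY_g,(PROK_p1,PROK_new)),PROK_p2),(EUK_e1,EUK_e2));"
        )
        assert tree_placement_test(grown).verdict == "HGT_TREE_SUPPORTED"

    def test_matches_oracle_small_trees(self):
        """Edge scan == rooted-clade enumeration on all 5/6-tip topologies."""
        for n in (5, 6):
            names = [f"t{i}" for i in range(n)]
            for topo in unrooted_topologies(n):
                tree = dendropy.Tree.get(
                    data=newick(topo, names), schema="newick",
                    preserve_underscores=True,
                )
                for assign in range(1 << (n - 1)):
                    prok_mask = assign << 1
                    euk_mask = ((1 << n) - 2) & ~prok_mask
                    if not prok_mask or not euk_mask:
                        continue
                    classes = {"t0": "QUERY"}
                    for i in range(1, n):
                        classes[f"t{i}"] = (
                            "PROKARYOTE" if prok_mask >> i & 1 else "EUKARYOTE"
                        )
                    got = tree_placement_test(GeneTree(tree, classes)).verdict
                    want = oracle_placement(topo, n, prok_mask, euk_mask)
                    assert (got == "HGT_TREE_SUPPORTED") == want


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> pairwise path lengths
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        gt = neighbor_joining(d, labels)
        pdm = gt.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in gt.tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d[i, j])

    def test_topology_matches_scikit_bio(self):
        """Independent cross-check of the recovered split against skbio's NJ."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = ["a", "b", "c", "d"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        sk = skbio_nj(DistanceMatrix(d, labels))
        # both must recover the ab|cd split
        sk_split = {frozenset(t.name for t in c.tips()) for c in sk.children}
        assert frozenset({"a", "b"}) in sk_split or frozenset({"c", "d"}) in sk_split
        gt = neighbor_joining(d, labels)
        splits = set()
        for node in gt.tree.postorder_node_iter():
            if node.parent_node is not None and not node.is_leaf():
                splits.add(frozenset(l.taxon.label for l in node.leaf_iter()))
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits

    def test_three_taxa_star(self):
        gt = neighbor_joining(np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float),
                              ["a", "b", "c"])
        assert len(gt.tree.seed_node.child_nodes()) == 3

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float),
                             list("abc"))
        with pytest.raises(ValueError, match="non-negative"):
            neighbor_joining(np.array([[0, -1, 2], [-1, 0, 1], [2, 1, 0]], float),
                             list("abc"))
        with pytest.raises(ValueError, match="3 taxa"):
            neighbor_joining(np.zeros((2, 2)), list("ab"))


class TestValidateCandidates:
    def _candidate(self, gid):
        return HGTCall(gid, True, True, 0.9, True, True, False, True)

    def test_shortcut_candidate_becomes_hgt(self):
        calls = validate_candidates([self._candidate("g")], {"g": (8, 0)}, {})
        assert calls[0].phylo_verdict == "HGT_NO_TREE"
        assert calls[0].final_status == "HGT"

    def test_rejected_tree_means_not_hgt(self):
        tree = parse_newick("(((QUERY_g,EUK_e1),PROK_p1),(PROK_p2,EUK_e2));")
        calls = validate_candidates([self._candidate("g")], {"g": (9, 2)}, {"g": tree})
        assert calls[0].phylo_verdict == "REJECTED"
        assert calls[0].final_status == "NOT_HGT"

    def test_few_prokaryote_homologs_unsupported(self):
        calls = validate_candidates([self._candidate("g")], {"g": (4, 0)}, {})
        assert calls[0].phylo_verdict == "UNSUPPORTED"
        assert calls[0].final_status == "NOT_HGT"

    def test_missing_tree_names_gene(self):
        with pytest.raises(ValueError, match="g1"):
            validate_candidates([self._candidate("g1")], {"g1": (9, 2)}, {})

    def test_full_recovery_on_simulated_data(self, sim_dataset, sim_truth):
        from nanohgt.screen import ScreenConfig, screen_genome

        calls = screen_genome(
            sim_dataset.contigs, sim_dataset.genes, sim_dataset.hits, ScreenConfig()
        )
        calls = validate_candidates(
            calls, sim_dataset.homolog_counts, sim_dataset.trees
        )
        final = {c.gene_id for c in calls if c.final_status == "HGT"}
        assert final == sim_truth.genes_of_class("HGT")
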