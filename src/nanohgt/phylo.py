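"""Phylogenetic validation of HGT candidates.

Two routes, mirroring how candidates are confirmed in practice:

* the homolog-count shortcut — a candidate with more than five prokaryotic
  homologs and none in eukaryotes is accepted without a tree;
* the tree-placement test — when homologs exist in both domains, the gene
  tree must place the query inside a purely prokaryotic clade that has a
  eukaryotic outgroup.

The placement test is defined on the *unrooted* topology: gene trees from
fast ML programs carry no meaningful root.  An edge of the unrooted tree
splits the tips into two sides (A, B); the query is "nested within
prokaryotes with a eukaryotic outgroup" iff for some edge

    A ⊇ all QUERY tips,  A \\ QUERY is non-empty and all PROKARYOTE,
    and B contains at least one EUKARYOTE tip.

Every edge (terminal edges included) is scanned: rooting the tree on a
eukaryote's terminal edge is exactly what makes the remaining tips a clade,
and that rooting must count.  A query-only clade sister to eukaryotes does
not qualify — the query must sit *inside* prokaryotic diversity.

A toy neighbor-joining builder is included solely to make test fixtures
from distance matrices; it is not part of the detection method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .seqio import GeneTree, HGTCall

__all__ = [
    "PlacementResult",
    "homolog_count_rule",
    "tree_placement_test",
    "neighbor_joining",
    "validate_candidates",
]


@dataclass
class PlacementResult:
    """Outcome of the tree test; the witness bipartition (prokaryote+query
    side, outgroup side) is present iff the verdict is HGT_TREE_SUPPORTED."""

    verdict: str
    witness_bipartition: tuple[frozenset[str], frozenset[str]] | None = None

    def __post_init__(self) -> None:
        assert (self.verdict == "HGT_TREE_SUPPORTED") == (
            self.witness_bipartition is not None
        )


def homolog_count_rule(prok_homologs: int, euk_homologs: int) -> str:
    """Decide from domain-level homolog counts alone.

    more than five prokaryotic homologs and none eukaryotic -> HGT_NO_TREE;
    any eukaryotic homolog -> NEEDS_TREE (a gene tree must arbitrate);
    at most five prokaryotic and none eukaryotic -> UNSUPPORTED.
    """
    if prok_homologs < 0 or euk_homologs < 0:
        raise ValueError("homolog counts must be non-negative")
    if euk_homologs >= 1:
        return "NEEDS_TREE"
    if prok_homologs > 5:
        return "HGT_NO_TREE"
    return "UNSUPPORTED"


def tree_placement_test(gene_tree: GeneTree) -> PlacementResult:
    """Test whether the query nests inside a prokaryotic clade with a
    eukaryotic outgroup (see module docstring for the bipartition form).

    Invariant under rerooting and tip order: only the unrooted bipartition
    set matters.  The witness is the first qualifying bipartition met in a
    postorder edge scan.
    """
    gene_tree.validate_classes()
    assert gene_tree.tip_class is not None
    tips = gene_tree.tip_labels()
    classes = gene_tree.tip_class
    query = frozenset(t for t in tips if classes[t] == "QUERY")
    prok = frozenset(t for t in tips if classes[t] == "PROKARYOTE")
    euk = frozenset(t for t in tips if classes[t] == "EUKARYOTE")
    missing = [
        name
        for name, group in (("QUERY", query), ("PROKARYOTE", prok), ("EUKARYOTE", euk))
        if not group
    ]
    if missing:
        raise ValueError(f"tree lacks required tip classes: {', '.join(missing)}")

    all_tips = frozenset(tips)
    for side_a in _edge_bipartitions(gene_tree.tree):
        for a in (side_a, all_tips - side_a):
            b = all_tips - a
            if (
                query <= a
                and (a - query)
                and (a - query) <= prok
                and (b & euk)
            ):
                return PlacementResult("HGT_TREE_SUPPORTED", (a, b))
    return PlacementResult("REJECTED")


def _edge_bipartitions(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf set below each edge (child side), in postorder; cheap and
    allocation-light for the small per-gene trees this stage sees."""
    below: dict[dendropy.Node, frozenset[str]] = {}
    out: list[frozenset[str]] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            s: frozenset[str] = frozenset()
            for child in node.child_nodes():
                s |= below[child]
            below[node] = s
        if node.parent_node is not None:
            out.append(below[node])
    return out


# ---------------------------------------------------------------------------
# toy neighbor joining (fixture construction only)
# ---------------------------------------------------------------------------


def neighbor_joining(
    distance_matrix: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[str],
) -> GeneTree:
    """Classic neighbor joining on a symmetric distance matrix.

    Additive matrices are recovered exactly (tree path lengths reproduce the
    input).  Tip classes are resolved from QUERY_/PROK_/EUK_ label prefixes
    when all labels carry one, else left unset.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if len(labels) != n:
        raise ValueError("labels length must match matrix size")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("distance matrix must be non-negative")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix diagonal must be zero")

    taxon_ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in labels:
        taxon = dendropy.Taxon(label=label)
        taxon_ns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    d = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, i, j)  # deterministic tie-break by index
                if best is None or key < best:
                    best = key
        assert best is not None
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reuse slot i for the new node; retire slot j
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    root = dendropy.Node()
    nodes[a].edge.length = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    nodes[b].edge.length = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    nodes[c].edge.length = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for x in (a, b, c):
        root.add_child(nodes[x])
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tree.is_rooted = False

    from .seqio import classify_tip

    classes = {label: classify_tip(label) for label in labels}
    tip_class = None
    if all(v is not None for v in classes.values()):
        tip_class = {k: v for k, v in classes.items() if v is not None}
    return GeneTree(tree=tree, tip_class=tip_class)


# ---------------------------------------------------------------------------
# candidate validation
# ---------------------------------------------------------------------------


def validate_candidates(
    calls: Iterable[HGTCall],
    homolog_counts: Mapping[str, tuple[int, int]],
    trees: Mapping[str, GeneTree],
) -> list[HGTCall]:
    """Fill phylo_verdict and final_status for every call.

    ``homolog_counts`` maps gene_id -> (prokaryotic, eukaryotic) homolog
    counts from a domain-partitioned homolog search; ``trees`` supplies a
    gene tree for every candidate whose counts demand one.  Non-candidates
    are finalized as NOT_HGT without consulting either.
    """
    out: list[HGTCall] = []
    for call in calls:
        if call.is_candidate:
            if call.gene_id not in homolog_counts:
                raise ValueError(f"candidate {call.gene_id!r} has no homolog counts")
            prok, euk = homolog_counts[call.gene_id]
            decision = homolog_count_rule(prok, euk)
            if decision == "NEEDS_TREE":
                tree = trees.get(call.gene_id)
                if tree is None:
                    raise ValueError(
                        f"candidate {call.gene_id!r} needs a gene tree but none "
                        "was provided"
                    )
                call.phylo_verdict = tree_placement_test(tree).verdict
            else:
                call.phylo_verdict = decision
        call.finalize()
        out.append(call)
    return out
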