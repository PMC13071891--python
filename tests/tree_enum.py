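"""Exhaustive enumeration of unrooted binary tree topologies, plus an
independent rooted-clade oracle for the query-placement rule.

An unrooted binary topology on tips 0..n-1 is represented as a nested tuple
over tips 1..n-1 (the tree "hung" from tip 0).  Tip i is the integer i.
"""

from __future__ import annotations

from typing import Iterator


def unrooted_topologies(n: int) -> Iterator[object]:
    """All (2n-5)!! unrooted binary topologies on tips 0..n-1."""

    def insertions(tree: object, leaf: int) -> Iterator[object]:
        yield (tree, leaf)
        if isinstance(tree, tuple):
            left, right = tree
            for t in insertions(left, leaf):
                yield (t, right)
            for t in insertions(right, leaf):
                yield (left, t)

    def grow(k: int) -> Iterator[object]:
        if k == 1:
            yield 1
            return
        for t in grow(k - 1):
            yield from insertions(t, k)

    yield from grow(n - 1)


def newick(tree: object, names: list[str]) -> str:
    """Newick string of the full unrooted tree (tip 0 re-attached)."""

    def fmt(t: object) -> str:
        if isinstance(t, int):
            return names[t]
        return f"({fmt(t[0])},{fmt(t[1])})"

    assert isinstance(tree, tuple)
    return f"({names[0]},{fmt(tree[0])},{fmt(tree[1])});"


def clade_masks(tree: object) -> set[int]:
    """Bitmasks of every subtree of the hung representation (tip-0 side
    excluded; callers complement as needed)."""
    masks: set[int] = set()

    def walk(t: object) -> int:
        if isinstance(t, int):
            m = 1 << t
        else:
            m = walk(t[0]) | walk(t[1])
        masks.add(m)
        return m

    walk(tree)
    return masks


def oracle_placement(tree: object, n: int, prok_mask: int, euk_mask: int) -> bool:
    """Brute-force oracle: enumerate every clade of every possible rooting
    (equivalently both sides of every edge) and ask whether some clade
    contains the query (tip 0) plus at least one other tip, all of them
    prokaryotic, while a eukaryote lies outside."""
    full = (1 << n) - 1
    query = 1
    clades: set[int] = set()
    for m in clade_masks(tree):
        clades.add(m)
        clades.add(full & ~m)
    for c in clades:
        if c & query:
            rest = c & ~query
            if rest and not rest & ~prok_mask and (full & ~c) & euk_mask:
                return True
    return False
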