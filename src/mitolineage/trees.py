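"""Unrooted-tree utilities: bipartitions, monophyly, Robinson-Foulds.

Trees are dendropy objects.  All comparisons here use the unrooted
convention: a set of tips is monophyletic iff some edge bipartition
isolates exactly that set, and the RF distance is the symmetric
difference of the two trees' non-trivial bipartition sets.
"""

from __future__ import annotations

import dendropy

__all__ = ["tip_labels", "bipartitions", "is_monophyletic", "rf_distance"]


def tip_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of the smaller-or-canonical side.

    Each internal edge splits the tips in two; the split is recorded as the
    side not containing the alphabetically first tip, which canonicalises
    orientation without reference to rooting.
    """
    all_tips = tip_labels(tree)
    anchor = min(all_tips)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if anchor not in below else frozenset(all_tips - below)
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(side)
    return splits


def is_monophyletic(tree: dendropy.Tree, tips: set[str]) -> bool:
    """True iff some edge isolates exactly ``tips`` (unrooted convention)."""
    all_tips = tip_labels(tree)
    tips = set(tips)
    if not tips <= all_tips:
        raise ValueError(f"tips not in tree: {sorted(tips - all_tips)}")
    if not tips or tips == all_tips:
        raise ValueError("monophyly of the empty or full tip set is undefined")
    if len(tips) == 1 or len(tips) == len(all_tips) - 1:
        return True  # trivial splits always exist
    anchor = min(all_tips)
    query = frozenset(tips) if anchor not in tips else frozenset(all_tips - tips)
    return query in bipartitions(tree)


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric-difference count of non-trivial bipartitions."""
    if tip_labels(t1) != tip_labels(t2):
        raise ValueError("trees have different tip sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)
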