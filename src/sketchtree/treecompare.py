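"""Robinson-Foulds topology comparison.

The Robinson-Foulds (RF) distance counts the non-trivial bipartitions
(splits) present in one tree but not the other; the normalized form divides
by the total number of splits in both trees, giving a value in [0, 1] where
0 means identical unrooted topologies and 1 means no shared splits. Branch
lengths and rootings are ignored: a rooted binary tree and its unrooted
re-representation induce the same split set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .treebuild import TreeNode


@dataclass(frozen=True)
class BipartitionSet:
    """Non-trivial splits of a tree, canonically oriented.

    Each split is stored as the frozenset of leaf names on the side NOT
    containing the reference leaf (the lexicographically smallest name), so
    the same bipartition is represented identically in any rooting.
    """

    universe: frozenset[str]
    splits: frozenset[frozenset[str]]

    def __len__(self) -> int:
        return len(self.splits)


def bipartitions(tree: TreeNode) -> BipartitionSet:
    """One split per internal edge of the unrooted interpretation of ``tree``.

    Trivial splits (leaf edges and the whole set) are excluded; a binary
    root's duplicate edge is collapsed. A fully resolved unrooted binary
    tree on n leaves yields exactly n - 3 splits.
    """
    names = tree.leaf_names()
    dupes = sorted({x for x in names if names.count(x) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf names: {dupes}")
    universe = frozenset(names)
    n = len(universe)
    ref = min(universe) if universe else None
    splits = set()

    def clade(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        members = frozenset().union(*(clade(c) for c in node.children))
        if node is not tree:
            side = universe - members if ref in members else members
            if 2 <= len(side) <= n - 2:
                splits.add(side)
        return members

    clade(tree)
    return BipartitionSet(universe=universe, splits=frozenset(splits))


def rf(t1: TreeNode, t2: TreeNode) -> int:
    """Unnormalized RF distance: size of the symmetric split-set difference."""
    b1, b2 = bipartitions(t1), bipartitions(t2)
    if b1.universe != b2.universe:
        only1 = sorted(b1.universe - b2.universe)
        only2 = sorted(b2.universe - b1.universe)
        raise ValueError(
            f"leaf sets differ: only in first tree {only1}, only in second {only2}"
        )
    return len(b1.splits ^ b2.splits)


def nrf(t1: TreeNode, t2: TreeNode) -> float:
    """Normalized RF in [0, 1]: RF / (|splits(t1)| + |splits(t2)|).

    0 iff the unrooted topologies are identical; 1 iff no split is shared.
    For two fully resolved trees the denominator is 2(n - 3). Two trees with
    no internal structure at all (stars) are topologically identical: 0.
    """
    b1, b2 = bipartitions(t1), bipartitions(t2)
    if b1.universe != b2.universe:
        only1 = sorted(b1.universe - b2.universe)
        only2 = sorted(b2.universe - b1.universe)
        raise ValueError(
            f"leaf sets differ: only in first tree {only1}, only in second {only2}"
        )
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1.splits ^ b2.splits) / denom
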