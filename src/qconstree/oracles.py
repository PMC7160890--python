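"""Exhaustive small-instance oracles.

Brute-force enumerations used to validate the completion algorithm and the
dynamic program on instances small enough to check every possibility:

* enumeration of all binary unrooted topologies on a leaf set
  ((2n-5)!! of them), and of all topologies including multifurcations
  (every pairwise-compatible subset of some binary tree's splits);
* the minimum RF distance achievable by any tree compatible with a backbone
  (the quantity the multifurcating completion claims to attain);
* the maximum quartet score over all binary topologies, optionally filtered
  to trees compatible with a constraint (the quantity the DP claims to
  attain).

Everything here is deliberately simple and independent of the algorithms it
checks; cost grows super-exponentially, so keep ``n`` at 8 or below.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Iterable, Iterator, Optional, Sequence

from .quartets import topology_counter
from .tree import Node, PhyloTree, bipartitions, restrict

__all__ = [
    "all_binary_trees",
    "all_tree_splitsets",
    "min_rf_completion",
    "max_quartet_tree",
    "brute_quartet_score",
]


def all_binary_trees(labels: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every binary unrooted topology on ``labels`` exactly once."""
    labels = sorted(labels)
    if len(labels) < 3:
        root = Node()
        for lb in labels:
            root.add_child(Node(lb))
        yield PhyloTree(root)
        return

    def build(k: int) -> Iterator[Node]:
        # trees over labels[:k], root with 3+ children (unrooted shape)
        if k == 3:
            root = Node()
            for lb in labels[:3]:
                root.add_child(Node(lb))
            yield root
            return
        for smaller in build(k - 1):
            # every edge = every non-root node
            nodes = [nd for nd in smaller.iter_preorder() if nd.parent is not None]
            for i in range(len(nodes)):
                clone = smaller.copy()
                cnodes = [nd for nd in clone.iter_preorder() if nd.parent is not None]
                target = cnodes[i]
                parent = target.parent
                mid = Node()
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add_child(target)
                mid.add_child(Node(labels[k - 1]))
                yield clone

    for root in build(len(labels)):
        yield PhyloTree(root)


@lru_cache(maxsize=32)
def all_tree_splitsets(labels: frozenset) -> list[frozenset]:
    """Every unrooted topology (any resolution) on ``labels``, as split sets.

    A tree is identified with its set of non-trivial splits; every subset of
    a binary tree's (pairwise compatible) split set is again a tree, and every
    multifurcating tree arises this way.
    """
    seen: set[frozenset] = set()
    for t in all_binary_trees(sorted(labels)):
        splits = tuple(bipartitions(t))
        for r in range(len(splits) + 1):
            for subset in combinations(splits, r):
                seen.add(frozenset(subset))
    def canon(s: frozenset) -> str:
        return str(sorted(sorted(map(sorted, pair)) for pair in s))

    return sorted(seen, key=lambda s: (len(s), canon(s)))


def _restrict_splits(splits: Iterable[frozenset], keep: frozenset) -> frozenset:
    out = set()
    for s in splits:
        a, b = tuple(s)
        a, b = a & keep, b & keep
        if len(a) >= 2 and len(b) >= 2:
            out.add(frozenset({a, b}))
    return frozenset(out)


def min_rf_completion(backbone: PhyloTree, reference: PhyloTree) -> int:
    """Minimum RF distance to the reference over *all* trees on the union
    leaf set (any resolution) whose restriction resolves the backbone."""
    union = frozenset(backbone.leaf_labels | reference.leaf_labels)
    bb = bipartitions(backbone)
    br = bipartitions(reference)
    bl = frozenset(backbone.leaf_labels)
    rl = frozenset(reference.leaf_labels)
    best = None
    for splits in all_tree_splitsets(union):
        if not bb <= _restrict_splits(splits, bl):
            continue
        rs = _restrict_splits(splits, rl)
        rf = len(br ^ rs)
        if best is None or rf < best:
            best = rf
    return best


def brute_quartet_score(tree: PhyloTree, genetrees: Sequence[PhyloTree]) -> int:
    """Quartet score by restricting the trees to every shared 4-subset.

    Independent of the LCA-depth machinery used elsewhere.
    """
    score = 0
    for gt in genetrees:
        shared = sorted(tree.leaf_labels & gt.leaf_labels)
        for quad in combinations(shared, 4):
            s1 = bipartitions(restrict(tree, quad))
            s2 = bipartitions(restrict(gt, quad))
            if s1 and s1 == s2:
                score += 1
    return score


@lru_cache(maxsize=8)
def _binary_trees_with_masks(labels: tuple) -> list:
    """All binary trees on ``labels`` with their splits as bit masks
    (one arbitrary side per split, bit i = labels[i])."""
    pos = {lb: i for i, lb in enumerate(labels)}
    out = []
    for t in all_binary_trees(list(labels)):
        masks = []
        for s in bipartitions(t):
            a, _ = tuple(s)
            masks.append(sum(1 << pos[x] for x in a))
        out.append((t, tuple(masks)))
    return out


def max_quartet_tree(genetrees: Sequence[PhyloTree],
                     labels: Optional[Iterable[str]] = None,
                     constraint: Optional[PhyloTree] = None
                     ) -> tuple[int, PhyloTree]:
    """Maximum quartet score over all binary topologies on ``labels``
    (optionally only those compatible with ``constraint``), by enumeration.

    Returns ``(best score, first best tree in enumeration order)``.
    """
    if labels is None:
        labels = frozenset().union(*(gt.leaf_labels for gt in genetrees))
    labels = tuple(sorted(labels))
    pos = {lb: i for i, lb in enumerate(labels)}
    full = (1 << len(labels)) - 1
    topo_masks = []
    for topo, cnt in topology_counter(genetrees).items():
        p, q = tuple(topo)
        if not (set(p) | set(q)) <= set(labels):
            continue
        pm = sum(1 << pos[x] for x in p)
        qm = sum(1 << pos[x] for x in q)
        topo_masks.append((pm, qm, cnt))
    cons_masks = None
    if constraint is not None:
        cons_masks = []
        for s in bipartitions(constraint):
            a, b = tuple(s)
            cons_masks.append((sum(1 << pos[x] for x in a),
                               sum(1 << pos[x] for x in b)))

    def shown(pm: int, qm: int, smask: int, cmask: int) -> bool:
        return (pm & smask == pm and qm & smask == 0) or \
               (qm & smask == qm and pm & smask == 0)

    best, best_tree = None, None
    for t, masks in _binary_trees_with_masks(labels):
        if cons_masks is not None:
            ok = all(any(shown(am, bm, s, full ^ s) for s in masks)
                     for am, bm in cons_masks)
            if not ok:
                continue
        score = 0
        for pm, qm, cnt in topo_masks:
            for s in masks:
                if shown(pm, qm, s, full ^ s):
                    score += cnt
                    break
        if best is None or score > best:
            best, best_tree = score, t
    if best is None:
        raise ValueError("no binary tree satisfies the constraint")
    return best, best_tree
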