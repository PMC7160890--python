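"""Induced quartet topologies and aggregated quartet-frequency tables.

A quartet ``{a,b,c,d}`` induced by a tree is either unresolved or takes one of
three topologies ``ab|cd``, ``ac|bd``, ``ad|bc``.  The topology is read off
from six leaf-pair LCA depths after rooting the tree anywhere: the pairing
whose two LCA depths sum strictly highest is the induced split; a tie means
the quartet is unresolved (a polytomy separates it).

Aggregated tables (topology -> count over gene trees) back both the quartet
score and the tripartition weights of the dynamic program.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np

from .tree import LcaIndex, PhyloTree

__all__ = [
    "quartet_topologies",
    "topology_counter",
    "pair_support_counts",
]


def _pair_lca_depths(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Depths of LCAs for every leaf pair (and each leaf's own depth on the
    diagonal)."""
    labels = sorted(tree.leaf_labels)
    index = LcaIndex(tree)
    depth: dict[int, int] = {}
    for nd in tree.iter_nodes("pre"):
        depth[id(nd)] = 0 if nd.parent is None else depth[id(nd.parent)] + 1
    n = len(labels)
    mat = np.zeros((n, n), dtype=np.int64)
    leaf_nodes = [index._resolve(lb) for lb in labels]
    for i in range(n):
        mat[i, i] = depth[id(leaf_nodes[i])]
        for j in range(i + 1, n):
            d = depth[id(index.lca(leaf_nodes[i], leaf_nodes[j]))]
            mat[i, j] = mat[j, i] = d
    return labels, mat


def quartet_topologies(tree: PhyloTree,
                       quartets: Optional[Iterable[frozenset]] = None) -> dict:
    """Map each resolved 4-subset of leaves to its induced topology.

    Keys are ``frozenset({a,b,c,d})``; values are
    ``frozenset({frozenset({a,b}), frozenset({c,d})})``.  Unresolved quartets
    are omitted.
    """
    labels, mat = _pair_lca_depths(tree)
    pos = {lb: i for i, lb in enumerate(labels)}
    out: dict[frozenset, frozenset] = {}
    if quartets is None:
        quartet_iter = combinations(labels, 4)
    else:
        quartet_iter = (tuple(sorted(q)) for q in quartets
                        if len(q) == 4 and all(x in pos for x in q))
    for a, b, c, d in quartet_iter:
        ia, ib, ic, id_ = pos[a], pos[b], pos[c], pos[d]
        s1 = mat[ia, ib] + mat[ic, id_]
        s2 = mat[ia, ic] + mat[ib, id_]
        s3 = mat[ia, id_] + mat[ib, ic]
        if s1 > s2 and s1 > s3:
            topo = frozenset({frozenset({a, b}), frozenset({c, d})})
        elif s2 > s1 and s2 > s3:
            topo = frozenset({frozenset({a, c}), frozenset({b, d})})
        elif s3 > s1 and s3 > s2:
            topo = frozenset({frozenset({a, d}), frozenset({b, c})})
        else:
            continue
        out[frozenset((a, b, c, d))] = topo
    return out


def topology_counter(genetrees: Sequence[PhyloTree]) -> Counter:
    """Aggregate resolved quartet topologies over a set of gene trees.

    Keys are topology frozensets as in :func:`quartet_topologies` (the key
    alone identifies the four leaves); values are counts.
    """
    counter: Counter = Counter()
    for gt in genetrees:
        counter.update(quartet_topologies(gt).values())
    return counter


def pair_support_counts(genetrees: Sequence[PhyloTree],
                        taxa: Sequence[str],
                        max_quartets_per_tree: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sibling and co-occurrence counts over resolved gene-tree quartets.

    ``sib[i, j]`` counts resolved quartets in which taxa ``i`` and ``j`` are
    paired on the same side; ``cooc[i, j]`` counts resolved quartets containing
    both.  When a gene tree has more than ``max_quartets_per_tree`` quartets a
    seeded random sample of 4-subsets is scored instead of the full
    enumeration.
    """
    n = len(taxa)
    pos = {lb: i for i, lb in enumerate(taxa)}
    sib = np.zeros((n, n), dtype=np.float64)
    cooc = np.zeros((n, n), dtype=np.float64)
    for gt in genetrees:
        leaves = sorted(gt.leaf_labels)
        m = len(leaves)
        if m < 4:
            continue
        total = m * (m - 1) * (m - 2) * (m - 3) // 24
        sample = None
        if max_quartets_per_tree is not None and total > max_quartets_per_tree:
            if rng is None:
                rng = np.random.default_rng(0)
            sample = set()
            while len(sample) < max_quartets_per_tree:
                pick = rng.choice(m, size=4, replace=False)
                sample.add(frozenset(leaves[i] for i in pick))
        topos = quartet_topologies(gt, quartets=sample)
        for quartet, topo in topos.items():
            idx = [pos[x] for x in quartet]
            for i, j in combinations(idx, 2):
                cooc[i, j] += 1
                cooc[j, i] += 1
            for side in topo:
                i, j = (pos[x] for x in side)
                sib[i, j] += 1
                sib[j, i] += 1
    return sib, cooc
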