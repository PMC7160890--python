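"""Constructing the restricted DP search space of clusters.

The dynamic program explores only clusters in a set ``X``.  For the program
to be well-defined, every cluster of ``X`` must sit inside at least one
complete binary tree all of whose clusters are in ``X`` (property P1); for
the inferred tree to honor a user constraint, every cluster must additionally
be compatible with the constraint tree (property P2).

Both properties are obtained *by construction*: ``X`` is the union of the
cluster sets of a collection of complete binary *witness* trees, and every
witness is built by completing/resolving trees that are themselves compatible
with the constraint.  The pipeline:

1. force each gene tree to be compatible with the constraint by completing
   the constraint with the gene tree (:func:`qconstree.completion.comp` with
   the constraint as backbone);
2. complete the resulting trees to the full taxon set in a reference-free
   fashion (guide tree from a greedy consensus, or from the quartet
   similarity matrix when no complete tree exists);
3. build greedy consensus trees of the completed trees at several thresholds;
4. force the consensus trees to be compatible with the constraint (again
   backbone-first completion);
5. resolve every remaining polytomy agglomeratively with the quartet
   similarity matrix (one deterministic resolution plus seeded randomized
   variants) and pool all witness clusters, singletons, and the full cluster.

``verify_p1`` / ``verify_p2`` re-check the two properties independently of
the construction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .completion import comp
from .quartets import pair_support_counts
from .tree import (
    Node,
    PhyloTree,
    bipartitions,
    clusters_of,
    is_binary,
    is_compatible,
    split_compatible,
    tree_from_clusters,
)

logger = logging.getLogger("qconstree")

__all__ = [
    "QuartetSimilarityMatrix",
    "SearchSpace",
    "quartet_similarity_matrix",
    "greedy_consensus",
    "reference_free_complete",
    "resolve_polytomies",
    "build_search_space",
    "verify_p1",
    "verify_p2",
]


@dataclass
class QuartetSimilarityMatrix:
    """Pairwise taxon similarity from quartet frequencies.

    ``matrix[i, j]`` is the fraction of resolved gene-tree quartets containing
    taxa ``i`` and ``j`` in which the two are paired on the same side.  Pairs
    never co-occurring in a resolved quartet are imputed with the row mean
    (and flagged); the diagonal is set to the maximum.
    """

    taxa: tuple
    matrix: np.ndarray
    imputed_pairs: list = field(default_factory=list)

    def pair(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.matrix[i, j])


def quartet_similarity_matrix(genetrees: Sequence[PhyloTree],
                              taxa: Optional[Sequence[str]] = None,
                              max_quartets_per_tree: Optional[int] = 100_000,
                              seed: int = 0) -> QuartetSimilarityMatrix:
    if not genetrees:
        raise ValueError("need at least one gene tree")
    if taxa is None:
        taxa = sorted(frozenset().union(*(t.leaf_labels for t in genetrees)))
    taxa = tuple(sorted(taxa))
    rng = np.random.default_rng(seed)
    sib, cooc = pair_support_counts(genetrees, taxa,
                                    max_quartets_per_tree=max_quartets_per_tree,
                                    rng=rng)
    n = len(taxa)
    mat = np.full((n, n), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(cooc > 0, sib / np.maximum(cooc, 1), np.nan)
    mat[:, :] = ratio
    off_diag = ~np.eye(n, dtype=bool)
    imputed = []
    for i in range(n):
        row = mat[i]
        defined = ~np.isnan(row) & (np.arange(n) != i)
        fill = row[defined].mean() if defined.any() else np.nan
        for j in range(n):
            if i != j and np.isnan(mat[i, j]):
                imputed.append((taxa[i], taxa[j]))
                mat[i, j] = fill
    still = np.isnan(mat) & off_diag
    if still.any():
        rest = mat[off_diag & ~np.isnan(mat)]
        # rows with no resolved quartets at all: uninformative similarity
        mat[still] = rest.mean() if rest.size else 0.5
    # symmetrize after row-mean imputation, then maximal diagonal
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, max(1.0, float(mat[off_diag].max())))
    if imputed:
        logger.info("similarity matrix: %d pair(s) imputed with row means",
                    len(imputed) // 2)
    return QuartetSimilarityMatrix(taxa, mat, imputed)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def greedy_consensus(trees: Sequence[PhyloTree],
                     thresholds: Sequence[float]) -> list[PhyloTree]:
    """Greedy (frequency-ordered) consensus at each threshold.

    All trees must share one complete leaf set.  Splits are added in order of
    decreasing frequency (deterministic tie-break) whenever compatible with
    the splits already accepted; a split is kept only if its frequency is at
    least the threshold, so 1.0 yields the strict consensus and 0.0 the full
    greedy consensus.
    """
    if not trees:
        raise ValueError("no trees given")
    leafset = trees[0].leaf_labels
    if any(t.leaf_labels != leafset for t in trees):
        raise ValueError("consensus requires a common leaf set")
    counts: Counter = Counter()
    for t in trees:
        counts.update(bipartitions(t))
    k = len(trees)

    def canon(split: frozenset) -> list:
        return sorted(sorted(side) for side in split)

    ordered = sorted(counts, key=lambda s: (-counts[s], canon(s)))
    outgroup = min(leafset)
    out = []
    for thr in thresholds:
        accepted: list[frozenset] = []
        for s in ordered:
            if counts[s] / k < thr:
                continue
            if all(split_compatible(s, a) for a in accepted):
                accepted.append(s)
        clusters = set()
        for s in accepted:
            a, b = tuple(s)
            clusters.add(b if outgroup in a else a)
        out.append(tree_from_clusters(clusters, leafset, outgroup))
    return out


# ---------------------------------------------------------------------------
# guide trees and reference-free completion
# ---------------------------------------------------------------------------

def _linkage_tree(matrix: QuartetSimilarityMatrix,
                  noise: Optional[np.ndarray] = None) -> PhyloTree:
    """Average-linkage agglomeration on the similarity matrix: a complete
    binary guide tree."""
    taxa = matrix.taxa
    sim = matrix.matrix if noise is None else matrix.matrix + noise
    items: list[tuple[tuple, Node]] = [((i,), Node(taxa[i]))
                                       for i in range(len(taxa))]
    while len(items) > 2:
        best = None
        for a, b in combinations(range(len(items)), 2):
            ia, ib = items[a][0], items[b][0]
            score = sim[np.ix_(ia, ib)].mean()
            key = (-score, items[a][0], items[b][0])
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        na, nb = items[a][1], items[b][1]
        merged = Node()
        merged.add_child(na)
        merged.add_child(nb)
        idx = tuple(sorted(items[a][0] + items[b][0]))
        items = [it for i, it in enumerate(items) if i not in (a, b)]
        items.append((idx, merged))
    root = Node()
    for _, nd in items:
        root.add_child(nd)
    t = PhyloTree(root)
    t.suppress_unifurcations()
    t.canonicalize()
    return t


def reference_free_complete(trees: Sequence[PhyloTree],
                            matrix: QuartetSimilarityMatrix
                            ) -> list[PhyloTree]:
    """Complete every tree onto the full taxon set without a constraint.

    The guide is the greedy consensus of the already-complete input trees,
    resolved with the similarity matrix; if no input tree is complete, the
    guide is built from the similarity matrix alone.  Each incomplete tree is
    completed against the guide, so its own topology is preserved (the output
    restricted to the input's leaves resolves the input).
    """
    full = frozenset(matrix.taxa)
    complete = [t for t in trees if t.leaf_labels == full]
    if complete:
        guide = greedy_consensus(complete, [0.0])[0]
        guide = resolve_polytomies(guide, matrix, 1, 0)[0]
    else:
        guide = _linkage_tree(matrix)
    out = []
    for t in trees:
        if t.leaf_labels == full:
            out.append(t.copy())
        else:
            out.append(comp(t, guide))
    return out


# ---------------------------------------------------------------------------
# polytomy resolution
# ---------------------------------------------------------------------------

def _resolve_once(tree: PhyloTree, matrix: QuartetSimilarityMatrix,
                  sim: np.ndarray) -> PhyloTree:
    taxa_pos = {lb: i for i, lb in enumerate(matrix.taxa)}
    o = min(tree.leaf_labels)
    rooted = tree.root_at_leaf(o)
    rooted.canonicalize()
    for nd in list(rooted.root.iter_postorder()):
        while len(nd.children) > 2:
            groups = [(tuple(sorted(taxa_pos[lb] for lb in c.leaf_set())), c)
                      for c in nd.children]
            best = None
            for a, b in combinations(range(len(groups)), 2):
                ia, ib = groups[a][0], groups[b][0]
                score = sim[np.ix_(ia, ib)].mean()
                key = (-score, groups[a][0], groups[b][0])
                if best is None or key < best[0]:
                    best = (key, a, b)
            _, a, b = best
            na, nb = groups[a][1], groups[b][1]
            merged = Node()
            nd.children.remove(na)
            nd.children.remove(nb)
            merged.add_child(na)
            merged.add_child(nb)
            nd.add_child(merged)
    out = rooted.unroot_from_leaf()
    out.suppress_unifurcations()
    out.canonicalize()
    return out


def resolve_polytomies(tree: PhyloTree, matrix: QuartetSimilarityMatrix,
                       rounds: int, seed: int) -> list[PhyloTree]:
    """Binary resolutions of a complete tree.

    The first resolution agglomerates each polytomy's children by average
    similarity (deterministic); each further round perturbs the similarity
    matrix with seeded Gaussian noise, producing alternative resolutions.
    Every output is a resolution of the input (contracting the new edges
    recovers it), so constraint compatibility is inherited.
    """
    if is_binary(tree):
        return [tree.copy()]
    out = [_resolve_once(tree, matrix, matrix.matrix)]
    scale = 0.05 * max(1e-6, float(np.std(matrix.matrix)))
    for r in range(1, max(1, rounds)):
        rng = np.random.default_rng((seed, r))
        noise = rng.normal(0.0, scale or 0.05, size=matrix.matrix.shape)
        noise = (noise + noise.T) / 2.0
        out.append(_resolve_once(tree, matrix, matrix.matrix + noise))
    return out


# ---------------------------------------------------------------------------
# the search space
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """The cluster set ``X`` with its P1 witnesses and P2 constraint."""

    taxa: tuple
    outgroup: str
    clusters: frozenset
    witnesses: list
    constraint: Optional[PhyloTree] = None
    matrix: Optional[QuartetSimilarityMatrix] = None

    @property
    def leafset(self) -> frozenset:
        return frozenset(self.taxa)

    def __len__(self) -> int:
        return len(self.clusters)


def _witness_clusters(tree: PhyloTree, outgroup: str) -> set:
    lprime = tree.leaf_labels - {outgroup}
    cl = clusters_of(tree, outgroup)
    cl.add(frozenset(lprime))
    cl.update(frozenset([x]) for x in lprime)
    return cl


def build_search_space(genetrees: Sequence[PhyloTree],
                       constraint: Optional[PhyloTree] = None,
                       seed: int = 0,
                       thresholds: Sequence[float] = (0.0, 0.2, 0.5),
                       rounds: int = 2,
                       outgroup: Optional[str] = None,
                       size_warning: int = 20_000,
                       matrix: Optional[QuartetSimilarityMatrix] = None
                       ) -> SearchSpace:
    """Build ``X`` from gene trees and an optional constraint tree."""
    if not genetrees:
        raise ValueError("need at least one gene tree")
    leafset = frozenset().union(*(t.leaf_labels for t in genetrees))
    if constraint is not None:
        leafset = leafset | constraint.leaf_labels
    taxa = tuple(sorted(leafset))
    if outgroup is None:
        shared_all = frozenset(taxa)
        for t in genetrees:
            shared_all &= t.leaf_labels
        if constraint is not None:
            shared_all &= constraint.leaf_labels
        outgroup = min(shared_all) if shared_all else taxa[0]
    elif outgroup not in leafset:
        raise ValueError(f"outgroup {outgroup!r} not among the taxa")

    if matrix is None:
        matrix = quartet_similarity_matrix(genetrees, taxa=taxa, seed=seed)

    # step 1: force gene trees to be compatible with the constraint
    step1 = []
    for t in genetrees:
        if constraint is not None:
            if constraint.leaf_labels & t.leaf_labels:
                step1.append(comp(constraint, t))
            else:
                logger.warning("gene tree shares no leaf with the constraint; "
                               "used without constraint forcing")
                step1.append(t)
        else:
            step1.append(t)

    # step 2: reference-free completion to the full taxon set
    completed = reference_free_complete(step1, matrix)

    # step 3: greedy consensus trees
    consensus = greedy_consensus(completed, thresholds)

    # step 4: force consensus trees to be compatible with the constraint
    if constraint is not None:
        consensus = [comp(constraint, c) for c in consensus]

    # step 5: resolve polytomies; pool witness clusters
    witnesses: list[PhyloTree] = []
    for i, t in enumerate(completed + consensus):
        sub_seed = (seed * 1_000_003 + i) % (2 ** 31)
        witnesses.extend(resolve_polytomies(t, matrix, rounds, sub_seed))

    clusters: set = set()
    for w in witnesses:
        clusters |= _witness_clusters(w, outgroup)
    if len(clusters) > size_warning:
        logger.warning("search space size |X|=%d above the soft budget %d",
                       len(clusters), size_warning)
    return SearchSpace(taxa=taxa, outgroup=outgroup,
                       clusters=frozenset(clusters), witnesses=witnesses,
                       constraint=constraint, matrix=matrix)


def verify_p1(space: SearchSpace) -> bool:
    """Every cluster belongs to a complete binary witness tree whose clusters
    are all in ``X``."""
    full = space.leafset
    covered: set = set()
    for w in space.witnesses:
        if w.leaf_labels != full or not is_binary(w):
            continue
        wc = _witness_clusters(w, space.outgroup)
        if wc <= space.clusters:
            covered |= wc
    return space.clusters <= covered


def verify_p2(space: SearchSpace) -> bool:
    """Every cluster is compatible with the constraint tree."""
    if space.constraint is None:
        return True
    return all(is_compatible(c, space.constraint) for c in space.clusters)
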