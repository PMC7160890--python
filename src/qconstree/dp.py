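"""The cluster dynamic program maximizing the quartet score.

States are clusters ``A`` (subsets of ``L' = L \\ {o}``, held as bit masks);
the recursion

    S(A) = max over splits (A', A \\ A') with both halves in X of
           S(A') + S(A \\ A') + w(A' | A \\ A' | L \\ A)

with ``S({x}) = 0`` finds the tree on ``L`` whose clusters all lie in the
search space ``X`` and whose quartet score against the gene trees is
maximal.  The tripartition weight ``w`` counts, over gene trees, resolved
quartets with two leaves paired inside one part and the other two leaves in
the two remaining parts; summed over the internal nodes of any binary tree
rooted at ``o`` these weights equal exactly twice the tree's quartet score,
so the DP value is kept in that *doubled* integer convention and halved only
at the reporting boundary.

``exact_solve`` runs the same recursion over the full powerset of ``L'``
(feasible to ~10 taxa) and is therefore provably optimal; ``dp_solve`` runs
over a restricted ``X``; ``constrained_infer`` glues search-space
construction and the DP together.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .quartets import quartet_topologies
from .search_space import SearchSpace, build_search_space
from .tree import PhyloTree, tree_from_clusters

__all__ = [
    "WeightFunction",
    "DPSolution",
    "tripartition_weight",
    "dp_solve",
    "exact_solve",
    "constrained_infer",
]


class SearchSpaceError(ValueError):
    """A cluster reachable by the DP has no decomposition within X."""


class WeightFunction:
    """Tripartition weights backed by aggregated gene-tree quartet tables."""

    def __init__(self, genetrees: Sequence[PhyloTree],
                 taxa: Optional[Sequence[str]] = None):
        if taxa is None:
            taxa = sorted(frozenset().union(*(t.leaf_labels for t in genetrees)))
        self.taxa = tuple(sorted(taxa))
        pos = {lb: i for i, lb in enumerate(self.taxa)}
        counts: dict[tuple, int] = {}
        for gt in genetrees:
            for topo in quartet_topologies(gt).values():
                (a, b), (c, d) = (sorted(pos[x] for x in side) for side in topo)
                key = ((a, b), (c, d)) if (a, b) <= (c, d) else ((c, d), (a, b))
                counts[key] = counts.get(key, 0) + 1
        self._counts = counts
        self._cache: dict[tuple, int] = {}

    def weight(self, parts: tuple[tuple, tuple, tuple]) -> int:
        """Weight of a tripartition given as three sorted index tuples."""
        key = tuple(sorted(parts))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts = self._counts
        get = counts.get
        total = 0
        for i in range(3):
            p = parts[i]
            q = parts[(i + 1) % 3]
            r = parts[(i + 2) % 3]
            if len(p) < 2 or not q or not r:
                continue
            for pair in combinations(p, 2):
                for c in q:
                    for d in r:
                        other = (c, d) if c < d else (d, c)
                        k = (pair, other) if pair <= other else (other, pair)
                        cnt = get(k)
                        if cnt:
                            total += cnt
        self._cache[key] = total
        return total


def tripartition_weight(parts: Sequence[Sequence[str]],
                        genetrees: Sequence[PhyloTree],
                        weightfn: Optional[WeightFunction] = None) -> int:
    """Weight of a tripartition of the full taxon set, by label."""
    sets = [frozenset(p) for p in parts]
    if len(sets) != 3:
        raise ValueError("a tripartition has exactly three parts")
    union = sets[0] | sets[1] | sets[2]
    if sum(len(s) for s in sets) != len(union):
        raise ValueError("parts must be pairwise disjoint")
    wf = weightfn or WeightFunction(genetrees, sorted(union))
    if union != frozenset(wf.taxa):
        raise ValueError("parts must partition the full taxon set")
    pos = {lb: i for i, lb in enumerate(wf.taxa)}
    idx = tuple(tuple(sorted(pos[x] for x in s)) for s in sets)
    return wf.weight(idx)


@dataclass
class DPSolution:
    """Optimal doubled quartet score, the backtracked tree, and the table."""

    doubled_score: int
    tree: PhyloTree
    table: dict = field(repr=False, default_factory=dict)
    search_space: Optional[SearchSpace] = None

    @property
    def score(self) -> float:
        """The (undoubled) quartet score."""
        return self.doubled_score / 2 if self.doubled_score % 2 else self.doubled_score // 2


def _run_dp(taxa: tuple, outgroup: str, masks: Optional[list],
            weightfn: WeightFunction, powerset: bool) -> tuple[int, dict, dict]:
    """Shared DP core.  Returns (optimum, value table, chosen-split table)."""
    lprime = [t for t in taxa if t != outgroup]
    nl = len(lprime)
    full = (1 << nl) - 1
    pos_global = {lb: i for i, lb in enumerate(taxa)}
    o_index = pos_global[outgroup]
    lp_to_global = [pos_global[lb] for lb in lprime]

    idx_cache: dict[int, tuple] = {}

    def indices(mask: int) -> tuple:
        hit = idx_cache.get(mask)
        if hit is None:
            hit = tuple(lp_to_global[i] for i in range(nl) if mask >> i & 1)
            idx_cache[mask] = hit
        return hit

    def side_labels(mask: int) -> tuple:
        return tuple(lprime[i] for i in range(nl) if mask >> i & 1)

    if powerset:
        order = sorted(range(1, full + 1), key=lambda m: (m.bit_count(), m))
        in_space = None
    else:
        mask_set = set(masks)
        order = sorted(mask_set, key=lambda m: (m.bit_count(), m))
        in_space = mask_set

    value: dict[int, int] = {}
    choice: dict[int, tuple] = {}
    rest_cache: dict[int, tuple] = {}
    weight = weightfn.weight

    for a in order:
        size = a.bit_count()
        if size == 1:
            value[a] = 0
            continue
        # the complement part L \ A includes the outgroup
        rest = tuple(sorted(indices(full ^ a) + (o_index,)))
        low = a & -a
        best = None
        best_key = None
        if powerset:
            sub = (a - 1) & a
            candidates = []
            while sub:
                if sub & low and (a ^ sub):
                    candidates.append(sub)
                sub = (sub - 1) & a
        else:
            candidates = [b for b in order
                          if b & low and b != a and b & a == b
                          and (a ^ b) in in_space]
        for b in candidates:
            c = a ^ b
            vb = value.get(b)
            vc = value.get(c)
            if vb is None or vc is None:
                continue
            w = weight((indices(b), indices(c), rest))
            v = vb + vc + w
            if best is None or v > best[0]:
                best = (v, b, c)
                best_key = None
            elif v == best[0]:
                if best_key is None:
                    best_key = _split_key(side_labels(best[1]), side_labels(best[2]))
                cand_key = _split_key(side_labels(b), side_labels(c))
                if cand_key < best_key:
                    best = (v, b, c)
                    best_key = cand_key
        if best is None:
            raise SearchSpaceError(
                f"cluster {side_labels(a)} has no decomposition within X "
                "(P1 violation)")
        value[a] = best[0]
        choice[a] = (best[1], best[2])

    if full not in value:
        raise SearchSpaceError("the full cluster L' is missing from X")
    return value[full], value, choice


def _split_key(labels_b: tuple, labels_c: tuple) -> tuple:
    sb, sc = tuple(sorted(labels_b)), tuple(sorted(labels_c))
    if (len(sb), sb) <= (len(sc), sc):
        return (len(sb), sb)
    return (len(sc), sc)


def _backtrack(full: int, choice: dict, lprime: list) -> set:
    clusters = set()
    stack = [full]
    while stack:
        a = stack.pop()
        clusters.add(frozenset(lprime[i] for i in range(len(lprime)) if a >> i & 1))
        if a in choice:
            stack.extend(choice[a])
    return clusters


def dp_solve(space: SearchSpace, genetrees: Sequence[PhyloTree],
             weightfn: Optional[WeightFunction] = None) -> DPSolution:
    """Maximize the doubled quartet score over trees assembled from ``X``."""
    taxa = space.taxa
    outgroup = space.outgroup
    lprime = [t for t in taxa if t != outgroup]
    lp_pos = {lb: i for i, lb in enumerate(lprime)}
    masks = []
    for cl in space.clusters:
        m = 0
        for lb in cl:
            m |= 1 << lp_pos[lb]
        masks.append(m)
    full = (1 << len(lprime)) - 1
    if full not in masks:
        masks.append(full)
    wf = weightfn or WeightFunction(genetrees, taxa)
    opt, value, choice = _run_dp(taxa, outgroup, masks, wf, powerset=False)
    clusters = _backtrack(full, choice, lprime)
    tree = tree_from_clusters(clusters, taxa, outgroup)
    table = {frozenset(lprime[i] for i in range(len(lprime)) if m >> i & 1): v
             for m, v in value.items()}
    return DPSolution(opt, tree, table, search_space=space)


def exact_solve(genetrees: Sequence[PhyloTree],
                outgroup: Optional[str] = None,
                cap: int = 10) -> DPSolution:
    """Provably optimal tree by DP over the full powerset of clusters."""
    taxa = tuple(sorted(frozenset().union(*(t.leaf_labels for t in genetrees))))
    if len(taxa) > cap:
        raise ValueError(
            f"{len(taxa)} taxa exceeds the exact-mode cap {cap}; "
            "use the restricted search space instead")
    if outgroup is None:
        outgroup = taxa[0]
    elif outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not among the taxa")
    lprime = [t for t in taxa if t != outgroup]
    wf = WeightFunction(genetrees, taxa)
    opt, value, choice = _run_dp(taxa, outgroup, None, wf, powerset=True)
    full = (1 << len(lprime)) - 1
    clusters = _backtrack(full, choice, lprime)
    tree = tree_from_clusters(clusters, taxa, outgroup)
    table = {frozenset(lprime[i] for i in range(len(lprime)) if m >> i & 1): v
             for m, v in value.items()}
    return DPSolution(opt, tree, table)


def constrained_infer(genetrees: Sequence[PhyloTree],
                      constraint: Optional[PhyloTree] = None,
                      seed: int = 0,
                      thresholds: Sequence[float] = (0.0, 0.2, 0.5),
                      rounds: int = 2,
                      outgroup: Optional[str] = None) -> DPSolution:
    """Constrained species-tree inference: build ``X`` honoring the
    constraint, then run the DP with weights from the *original* gene trees."""
    space = build_search_space(genetrees, constraint=constraint, seed=seed,
                               thresholds=thresholds, rounds=rounds,
                               outgroup=outgroup)
    wf = WeightFunction(genetrees, space.taxa)
    return dp_solve(space, genetrees, weightfn=wf)
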