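"""Tripartition weights and the cluster dynamic program."""

from itertools import combinations
from math import comb

import pytest

from conftest import labels, random_tree
from qconstree.dp import (
    SearchSpaceError,
    WeightFunction,
    constrained_infer,
    dp_solve,
    exact_solve,
    tripartition_weight,
)
from qconstree.oracles import brute_quartet_score, max_quartet_tree
from qconstree.search_space import SearchSpace
from qconstree.tree import (
    bipartitions,
    clusters_of,
    is_compatible,
    parse_newick,
    restrict,
    trees_isomorphic,
)


def summed_node_weights(tree, wf):
    """Sum of tripartition weights over internal nodes, tree rooted at the
    smallest leaf — the quantity contracted to equal twice the quartet score."""
    o = min(tree.leaf_labels)
    rooted = tree.root_at_leaf(o)
    pos = {lb: i for i, lb in enumerate(wf.taxa)}
    total = 0
    for nd in rooted.root.iter_preorder():
        if nd is rooted.root or nd.is_leaf or len(nd.children) != 2:
            continue
        p1 = tuple(sorted(pos[x] for x in nd.children[0].leaf_set()))
        p2 = tuple(sorted(pos[x] for x in nd.children[1].leaf_set()))
        rest = tuple(sorted(pos[x]
                            for x in tree.leaf_labels - nd.leaf_set()))
        total += wf.weight((p1, p2, rest))
    return total


def powerset_space(taxa, outgroup, constraint=None):
    """All clusters of L' (optionally filtered to constraint-compatible)."""
    lp = [t for t in taxa if t != outgroup]
    clusters = set()
    for r in range(1, len(lp) + 1):
        for c in combinations(lp, r):
            cl = frozenset(c)
            if constraint is None or is_compatible(cl, constraint):
                clusters.add(cl)
    return SearchSpace(taxa=tuple(sorted(taxa)), outgroup=outgroup,
                       clusters=frozenset(clusters), witnesses=[],
                       constraint=constraint)


class TestTripartitionWeight:
    def test_single_quartet(self):
        t = parse_newick("((a,b),(c,d));")
        assert tripartition_weight([["a"], ["b"], ["c", "d"]], [t]) == 1

    def test_doubling_identity_four_taxa(self):
        t = parse_newick("((a,b),(c,d));")
        total = (tripartition_weight([["a"], ["b"], ["c", "d"]], [t])
                 + tripartition_weight([["c"], ["a", "b"], ["d"]], [t]))
        assert total == 2  # = 2 * quartet score of the tree against itself

    def test_star_genes_zero(self):
        star = parse_newick("(a,b,c,d);")
        assert tripartition_weight([["a"], ["b"], ["c", "d"]], [star]) == 0

    def test_non_partition_rejected(self):
        t = parse_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            tripartition_weight([["a"], ["a", "b"], ["c", "d"]], [t])

    def test_weight_sum_identity_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 8))
            genes = [random_tree(labels(n), rng, multifurcating=True)
                     for _ in range(3)]
            tree = random_tree(labels(n), rng)
            wf = WeightFunction(genes, labels(n))
            assert summed_node_weights(tree, wf) == \
                2 * brute_quartet_score(tree, genes)


class TestExactSolve:
    def test_unanimous_genes(self, rng):
        t = random_tree(labels(6), rng)
        sol = exact_solve([t] * 3)
        assert trees_isomorphic(sol.tree, t)
        assert sol.doubled_score == 2 * 3 * comb(6, 4)
        assert sol.score == 3 * comb(6, 4)

    def test_four_taxa_majority(self):
        a = parse_newick("((a,b),(c,d));")
        b = parse_newick("((a,c),(b,d));")
        sol = exact_solve([a, a, b])
        assert trees_isomorphic(sol.tree, a)

    def test_matches_enumeration(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 8))
            genes = [random_tree(labels(n), rng, multifurcating=True)
                     for _ in range(4)]
            sol = exact_solve(genes)
            best, _ = max_quartet_tree(genes, labels(n))
            assert sol.doubled_score == 2 * best
            # the reported tree attains the reported score
            assert brute_quartet_score(sol.tree, genes) == best

    def test_cap(self, rng):
        genes = [random_tree(labels(12), rng)]
        with pytest.raises(ValueError):
            exact_solve(genes, cap=10)


class TestDpSolve:
    def test_three_copies_recover_quartet(self):
        t = parse_newick("((a,b),(c,d));")
        space = SearchSpace(
            taxa=("a", "b", "c", "d"), outgroup="a",
            clusters=frozenset({frozenset("b"), frozenset("c"),
                                frozenset("d"), frozenset("cd"),
                                frozenset("bcd")}),
            witnesses=[t])
        sol = dp_solve(space, [t] * 3)
        assert sol.doubled_score == 6
        assert trees_isomorphic(sol.tree, t)

    def test_self_space_scores_all_quartets(self, rng):
        for n in (6, 7, 8):
            t = random_tree(labels(n), rng)
            o = "a"
            clusters = set(clusters_of(t, o))
            clusters |= {frozenset([x]) for x in labels(n) if x != o}
            clusters.add(frozenset(labels(n)) - {o})
            space = SearchSpace(taxa=tuple(labels(n)), outgroup=o,
                                clusters=frozenset(clusters), witnesses=[t])
            sol = dp_solve(space, [t])
            assert sol.doubled_score == 2 * comb(n, 4)
            assert trees_isomorphic(sol.tree, t)

    def test_missing_decomposition_raises(self):
        t = parse_newick("((a,b),(c,d),e);")
        # bcd cannot split: bc/bd/cd absent and singleton complements absent
        space = SearchSpace(
            taxa=("a", "b", "c", "d", "e"), outgroup="a",
            clusters=frozenset({frozenset("b"), frozenset("c"),
                                frozenset("bcde")}),
            witnesses=[])
        with pytest.raises(SearchSpaceError):
            dp_solve(space, [t])

    def test_star_genes_zero_score(self, rng):
        star = parse_newick("(a,b,c,d,e,f);")
        t = random_tree(labels(6), rng)
        o = "a"
        clusters = set(clusters_of(t, o))
        clusters |= {frozenset([x]) for x in labels(6) if x != o}
        clusters.add(frozenset(labels(6)) - {o})
        space = SearchSpace(taxa=tuple(labels(6)), outgroup=o,
                            clusters=frozenset(clusters), witnesses=[t])
        sol = dp_solve(space, [star] * 3)
        assert sol.doubled_score == 0


class TestConstrainedOptimality:
    def test_filtered_powerset_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 8))
            genes = [random_tree(labels(n), rng) for _ in range(3)]
            true = random_tree(labels(n), rng)
            constraint = restrict(true, labels(n - 1))
            space = powerset_space(labels(n), "a", constraint)
            sol = dp_solve(space, genes)
            best, _ = max_quartet_tree(genes, labels(n), constraint=constraint)
            assert sol.doubled_score == 2 * best
            # output honors the constraint
            r = restrict(sol.tree, constraint.leaf_labels)
            assert bipartitions(constraint) <= bipartitions(r)

    def test_constraint_cannot_raise_the_optimum(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 8))
            genes = [random_tree(labels(n), rng) for _ in range(3)]
            constraint = random_tree(labels(n), rng, multifurcating=True)
            unconstrained = dp_solve(powerset_space(labels(n), "a"), genes)
            constrained = dp_solve(
                powerset_space(labels(n), "a", constraint), genes)
            assert constrained.doubled_score <= unconstrained.doubled_score


class TestConstrainedInfer:
    def test_output_compatible_and_scored(self, rng):
        for rep in range(5):
            n = int(rng.integers(7, 10))
            true = random_tree(labels(n), rng)
            genes = [random_tree(labels(n), rng) for _ in range(5)]
            constraint = restrict(true, labels(n - 2))
            sol = constrained_infer(genes, constraint=constraint, seed=rep)
            r = restrict(sol.tree, constraint.leaf_labels)
            assert bipartitions(constraint) <= bipartitions(r)
            # doubled value is consistent with the tree it reports
            assert sol.doubled_score == \
                2 * brute_quartet_score(sol.tree, genes)

    def test_self_constraint_is_idempotent(self, rng):
        genes = [random_tree(labels(8), rng, multifurcating=True)
                 for _ in range(5)]
        free = constrained_infer(genes, seed=0)
        pinned = constrained_infer(genes, constraint=free.tree, seed=0)
        assert trees_isomorphic(pinned.tree, free.tree)
        assert pinned.doubled_score == free.doubled_score

    def test_restricted_at_least_best_witness(self, rng):
        genes = [random_tree(labels(8), rng) for _ in range(4)]
        sol = constrained_infer(genes, seed=1)
        best_witness = max(
            brute_quartet_score(w, genes)
            for w in sol.search_space.witnesses)
        assert sol.score >= best_witness
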