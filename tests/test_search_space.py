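"""Search-space construction: similarity matrix, consensus, P1/P2."""

import numpy as np
import pytest

from conftest import labels, random_tree
from qconstree.dp import dp_solve
from qconstree.search_space import (
    SearchSpace,
    build_search_space,
    greedy_consensus,
    quartet_similarity_matrix,
    reference_free_complete,
    resolve_polytomies,
    verify_p1,
    verify_p2,
)
from qconstree.tree import (
    bipartitions,
    clusters_of,
    contract_edges,
    is_binary,
    parse_newick,
    restrict,
    trees_isomorphic,
)


class TestSimilarityMatrix:
    def test_siblings_score_higher(self):
        m = quartet_similarity_matrix([parse_newick("((a,b),(c,d));")])
        assert m.pair("a", "b") > m.pair("a", "c")

    def test_frequency_invariance(self):
        t = parse_newick("((a,b),(c,e),d);")
        m1 = quartet_similarity_matrix([t])
        mk = quartet_similarity_matrix([t] * 4)
        assert np.allclose(m1.matrix, mk.matrix)

    def test_star_trees_uniform(self):
        m = quartet_similarity_matrix([parse_newick("(a,b,c,d,e);")] * 2)
        off = m.matrix[~np.eye(5, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_never_cooccurring_pair_imputed(self):
        genes = [parse_newick("((a,b),(c,d));"),
                 parse_newick("((a,b),(c,e));")]
        m = quartet_similarity_matrix(genes)
        assert ("d", "e") in m.imputed_pairs or ("e", "d") in m.imputed_pairs
        assert not np.isnan(m.matrix).any()


class TestGreedyConsensus:
    def test_identical_trees_any_threshold(self, rng):
        t = random_tree(labels(7), rng)
        for c in greedy_consensus([t] * 3, [0.0, 0.5, 1.0]):
            assert trees_isomorphic(c, t)

    def test_strict_consensus_keeps_only_unanimous(self):
        a = parse_newick("((a,b),(c,d),e);")
        b = parse_newick("((a,b),(c,e),d);")
        (strict,) = greedy_consensus([a, b], [1.0])
        assert bipartitions(strict) == frozenset(
            {frozenset({frozenset("ab"), frozenset("cde")})})

    def test_majority_threshold_cutoff(self):
        a = parse_newick("((a,b),(c,d),e);")
        b = parse_newick("((a,b),(c,d),e);")
        c = parse_newick("((a,e),(c,d),b);")
        maj, tight = greedy_consensus([a, b, c], [0.5, 0.9])
        two_thirds = frozenset({frozenset("ab"), frozenset("cde")})
        assert two_thirds in bipartitions(maj)
        assert two_thirds not in bipartitions(tight)
        assert frozenset({frozenset("cd"), frozenset("abe")}) \
            in bipartitions(tight)

    def test_unequal_leafsets_rejected(self):
        with pytest.raises(ValueError):
            greedy_consensus([parse_newick("((a,b),(c,d));"),
                              parse_newick("((a,b),(c,e));")], [0.5])


class TestReferenceFreeComplete:
    def test_complete_inputs_unchanged(self, rng):
        trees = [random_tree(labels(7), rng) for _ in range(3)]
        m = quartet_similarity_matrix(trees)
        for before, after in zip(trees, reference_free_complete(trees, m)):
            assert trees_isomorphic(before, after)

    def test_missing_leaf_restored_and_topology_kept(self, rng):
        full = [random_tree(labels(7), rng) for _ in range(3)]
        partial = restrict(full[0], labels(6))
        m = quartet_similarity_matrix(full)
        out = reference_free_complete(full[1:] + [partial], m)[-1]
        assert out.leaf_labels == frozenset(labels(7))
        r = restrict(out, partial.leaf_labels)
        assert bipartitions(partial) <= bipartitions(r)

    def test_completeness_audit_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 10))
            trees = []
            for _ in range(4):
                t = random_tree(labels(n), rng, multifurcating=True)
                if rng.random() < 0.6:
                    keep = sorted(t.leaf_labels)[:int(rng.integers(4, n))]
                    t = restrict(t, keep)
                trees.append(t)
            m = quartet_similarity_matrix(trees, taxa=labels(n))
            for before, after in zip(trees, reference_free_complete(trees, m)):
                assert after.leaf_labels == frozenset(labels(n))
                r = restrict(after, before.leaf_labels)
                assert bipartitions(before) <= bipartitions(r)


class TestResolvePolytomies:
    def test_binary_input_unchanged(self, rng):
        t = random_tree(labels(7), rng)
        m = quartet_similarity_matrix([t])
        outs = resolve_polytomies(t, m, rounds=3, seed=1)
        assert len(outs) == 1 and trees_isomorphic(outs[0], t)

    def test_dominant_pair_resolves_first(self):
        genes = [parse_newick("((a,b),(c,d));")] * 3
        m = quartet_similarity_matrix(genes)
        star = parse_newick("(a,b,c,d);")
        out = resolve_polytomies(star, m, rounds=1, seed=0)[0]
        assert frozenset({frozenset("ab"), frozenset("cd")}) \
            in bipartitions(out)

    def test_every_output_is_a_resolution(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 10))
            t = random_tree(labels(n), rng, multifurcating=True, p_contract=0.6)
            genes = [random_tree(labels(n), rng) for _ in range(2)]
            m = quartet_similarity_matrix(genes)
            for out in resolve_polytomies(t, m, rounds=3, seed=7):
                assert is_binary(out)
                assert bipartitions(t) <= bipartitions(out)


class TestBuildSearchSpace:
    def test_identical_genes_recoverable(self, rng):
        t = random_tree(labels(8), rng)
        genes = [t.copy() for _ in range(4)]
        space = build_search_space(genes, seed=0)
        assert clusters_of(t, space.outgroup) <= space.clusters
        sol = dp_solve(space, genes)
        assert trees_isomorphic(sol.tree, t)

    def test_p1_p2_random_instances(self, rng):
        for rep in range(20):
            n = int(rng.integers(6, 12))
            true = random_tree(labels(n), rng)
            genes = []
            for _ in range(int(rng.integers(3, 7))):
                g = random_tree(labels(n), rng, multifurcating=True)
                if rng.random() < 0.5:
                    keep = sorted(g.leaf_labels)[:int(rng.integers(5, n + 1))]
                    g = restrict(g, keep)
                genes.append(g)
            mode = rep % 3
            if mode == 0:
                constraint = None
            elif mode == 1:
                keep = [labels(n)[i] for i in
                        rng.choice(n, size=n - 2, replace=False)]
                constraint = restrict(true, keep)
            else:
                sp = sorted(bipartitions(true),
                            key=lambda s: sorted(map(sorted, s)))
                drop = [sp[i] for i in
                        rng.choice(len(sp), size=min(2, len(sp)),
                                   replace=False)]
                constraint = contract_edges(true, drop)
            space = build_search_space(genes, constraint=constraint, seed=rep)
            assert verify_p1(space)
            assert verify_p2(space)

    def test_negative_controls(self, rng):
        from itertools import combinations

        from qconstree.tree import is_compatible

        t = random_tree(labels(7), rng)
        constraint = restrict(t, labels(6))
        space = build_search_space([t.copy() for _ in range(3)],
                                   constraint=constraint, seed=1)
        assert verify_p1(space) and verify_p2(space)
        base = sorted(space.leafset - {space.outgroup})
        # inject a cluster crossing the constraint -> P2 fails
        crossing = next(
            frozenset(c) for r in (2, 3)
            for c in combinations(base, r)
            if not is_compatible(frozenset(c), constraint))
        bad2 = SearchSpace(space.taxa, space.outgroup,
                           space.clusters | {crossing}, space.witnesses,
                           constraint=constraint)
        assert not verify_p2(bad2)
        # inject an orphan cluster with no witness -> P1 fails
        orphan = next(
            frozenset(c) for r in (2, 3)
            for c in combinations(base, r)
            if frozenset(c) not in space.clusters)
        bad1 = SearchSpace(space.taxa, space.outgroup,
                           space.clusters | {orphan}, space.witnesses,
                           constraint=None)
        assert not verify_p1(bad1)

    def test_rounds_monotonic(self, rng):
        genes = [random_tree(labels(8), rng, multifurcating=True)
                 for _ in range(4)]
        s1 = build_search_space(genes, seed=3, rounds=1)
        s2 = build_search_space(genes, seed=3, rounds=3)
        assert s1.clusters <= s2.clusters

    def test_constraint_shrinks_x_tendency(self, rng):
        # statistical direction over replicates: a large true-tree constraint
        # rarely enlarges X
        from qconstree.simulate import SimulationConfig, derive_constraint, simulate
        wins = 0
        reps = 8
        for s in range(reps):
            cfg = SimulationConfig(n_taxa=12, n_genes=8, discordance=0.5,
                                   error=2.0, seed=100 + s)
            species, genes = simulate(cfg)
            cons = derive_constraint(species, "prune", 3, seed=s)
            xu = len(build_search_space(genes, seed=s))
            xc = len(build_search_space(genes, constraint=cons, seed=s))
            wins += xc <= xu
        assert wins >= int(0.8 * reps)
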