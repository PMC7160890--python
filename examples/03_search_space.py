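"""Build the restricted DP search space X and check its two guarantees.

P1: every cluster sits in a complete binary witness tree inside X, so the
dynamic program can always assemble full trees.  P2: every cluster is
compatible with the constraint, so any DP output honors it.
"""

from qconstree import (
    SimulationConfig,
    build_search_space,
    derive_constraint,
    simulate,
    verify_p1,
    verify_p2,
)

cfg = SimulationConfig(n_taxa=12, n_genes=10, discordance=0.5, error=2.0, seed=3)
species, genes = simulate(cfg)
constraint = derive_constraint(species, "collapse", 4, seed=2)

space = build_search_space(genes, constraint=constraint, seed=3)
print(f"|X| = {len(space)} clusters over {len(space.taxa)} taxa "
      f"(outgroup {space.outgroup}), {len(space.witnesses)} witness trees")
print("P1 (witnessed completeness):", verify_p1(space))
print("P2 (constraint compatibility):", verify_p2(space))
print("smallest non-singleton clusters:")
for cl in sorted((c for c in space.clusters if 1 < len(c) < 5),
                 key=lambda c: (len(c), sorted(c)))[:5]:
    print("  ", ",".join(sorted(cl)))
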