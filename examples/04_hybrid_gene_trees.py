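"""Hybrid gene trees: complete a support-collapsed species tree with each
gene tree.

Branches of the species tree with low support are contracted; the remaining
well-supported core is the backbone, and each gene tree fills in its own
resolution and missing leaves.  The hybrids are, by construction, at least
as close to the collapsed core as the original gene trees.
"""

from qconstree import hybridize, parse_newick, rf_distance, write_newick
from qconstree.tree import contract_by_support

species = parse_newick("(((a,b)0.6,(c,d)1.0)1.0,((e,f)0.7,(g,h)1.0)1.0);")
genes = [
    parse_newick("(((a,c),(b,d)),((e,g),(f,h)));"),
    parse_newick("(((a,b),(c,e)),((d,f),(g,h)));"),
]

core = contract_by_support(species, 0.99)
print("species tree:", write_newick(species))
print("well-supported core:", write_newick(core))
for g, h in zip(genes, hybridize(genes, species, support_threshold=0.99)):
    print(f"gene   {write_newick(g)}  RF to core = {rf_distance(g, core)}")
    print(f"hybrid {write_newick(h)}  RF to core = {rf_distance(h, core)}")
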