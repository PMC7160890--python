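"""RF-minimizing tree completion: graft a reference tree's missing leaves
onto a backbone without disturbing it.

Shows the binary completion and the polytomy-aware variant on an instance
where forcing a binary output creates a spurious branch: the polytomy
output has strictly smaller RF distance to the reference.
"""

from qconstree import CompletionTask, brf_plus, brf_star, comp, parse_newick, rf_distance, write_newick

reference = parse_newick("((a,b),(x,(c,d)));")   # knows where x belongs
backbone = parse_newick("((a,c),(b,d));")        # disagrees about a,b,c,d

task = CompletionTask(backbone, reference)
binary = brf_plus(task)
multi = brf_star(task)

print("reference:", write_newick(reference))
print("backbone: ", write_newick(backbone))
print("binary completion:   ", write_newick(binary),
      " RF to reference =", rf_distance(binary, reference))
print("polytomy completion: ", write_newick(multi),
      " RF to reference =", rf_distance(multi, reference))
print("(the polytomy avoids inventing a branch the reference never had)")

# the general comp() handles multifurcating, mutually incomplete inputs
cons = parse_newick("((a,b),c,d,(p,q));")        # polytomy + extra leaves p,q
gene = parse_newick("(((a,b),(c,d)),(e,f));")    # resolves it + adds e,f
merged = comp(cons, gene)
print("comp(constraint, gene):", write_newick(merged),
      "  (complete on both leaf sets, still a resolution of the constraint)")
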