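"""Per-domain NJ trees and the mirror-tree co-evolution test.

Translates each annotated region of a simulated family, builds
Poisson-distance NJ trees with bootstrap support, compares the two
domain topologies, and runs the Mantel test between their distance
matrices.  High r with small permutation p indicates the domains share
evolutionary history beyond what independent evolution would give.
"""

import famevol as fv

aln, truth = fv.simulate_alignment(fv.SimulationConfig(seed=2, rho=0.9))

trees = {}
for name in ("DUF3594", "PHD"):
    prot = fv.translate_alignment(fv.slice_domain(aln, name))
    trees[name] = fv.bootstrap_support(prot, B=100, seed=2)
    print(f"{name} NJ tree: {trees[name].to_newick()[:80]} ...")

cmp = fv.compare_topologies(trees["DUF3594"], trees["PHD"])
print(f"\nshared splits: {cmp['shared_splits']}, RF distance: {cmp['rf_distance']}")

for res in fv.coevolution_scan(aln, n_perm=5000, seed=2):
    print(f"{res.domain_a} vs {res.domain_b}: r = {res.r_linear:.4f}, "
          f"Mantel p = {res.p_mantel:.4g} ({res.n_perm} permutations)")
print("\nr near 1 with p << 0.05 for DUF-vs-PHD reflects the shared "
      "branch rates (rho = 0.9) the family was simulated with.")
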