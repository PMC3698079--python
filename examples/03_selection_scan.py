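"""Site-model and branch-site positive-selection scan.

Simulates clade-restricted positive selection (10% of sites at
omega2 = 5 on the AL1 clade), fits the M0/M1a/M2a site models, then runs
branch-site model A with each labeled clade foreground in turn.  Only
the truly selected clade should give a significant df = 1 LRT, with
empirical-Bayes sites concentrated in the simulated positive classes.
"""

import famevol as fv
from famevol.codon_models import branch_site_scan

cfg = fv.SimulationConfig(seed=3, rho=0.0, sigma_b=0.0,
                          region_lengths=(200, 100, 100))
aln, truth = fv.simulate_alignment(cfg)
tree = truth.gene_family_tree

m0 = fv.fit_m0(aln, tree)
print(f"M0: lnL = {m0.lnL:.3f}, omega = {m0.params['omega']:.3f}, "
      f"kappa = {m0.kappa:.2f}  -> {fv.classify_selection(m0.params['omega'])}")
for name in ("M1a", "M2a"):
    f = fv.fit_model(aln, tree, name, m0_fit=m0)
    print(f"{name}: lnL = {f.lnL:.3f}")

print("\nbranch-site scan (each clade foreground in turn):")
for row in branch_site_scan(aln, tree, ["AL1", "AL2", "AL3", "AL4"], m0_fit=m0):
    sites = ", ".join(f"{s}({p:.2f})" for s, p in row["selected_sites"][:4])
    print(f"  {row['clade']}: 2dl = {row['stat']:6.2f}, p = {row['p']:.4g}"
          + (f", sites: {sites}" if sites else ""))
print("\nAL1 carries the simulated foreground selection; the other clades "
      "are the scan's built-in negative controls.")
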