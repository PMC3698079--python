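# famevol

Molecular-evolution analyses for small multi-domain gene families — the
kind of study done on a transcription-factor family such as the
Alfin-like (AL) proteins of *Arabidopsis thaliana*, *A. lyrata* and the
salt-tolerant crucifer *Thellungiella*: ~20 genes in 4–7 ortholog
groups, each protein built from a DUF3594-like domain and a PHD finger.

For such a family the package answers, from one in-frame codon
alignment plus a tree:

- **Do the domains co-evolve?**  Mirror-tree test: Pearson correlation
  between per-domain pairwise distance matrices, with a Mantel
  permutation p-value (exact by enumeration at small n).
- **Where did positive selection act?**  GY94 codon models: site models
  M0/M1a/M2a/M3/M7/M8 and branch-site model A with each labeled clade
  foreground in turn, likelihood-ratio tests
  (2Δℓ ~ χ²), and NEB/grid-BEB identification of selected sites
  (ω = dN/dS: < 1 purifying, = 1 neutral, > 1 positive).
- **Does codon usage differ between species?**  Wright's effective
  number of codons (ENC), GC3, CAI, the mutation-only null curve
  ENC\* = 2 + s + 29/(s² + (1−s)²), and exact Mann–Whitney group tests.
- **Did segmental duplication or gene conversion shape the family?**
  Reciprocal-best Needleman–Wunsch matching of flanking-gene sets, and a
  permutation scan for unexpectedly long identical runs over polymorphic
  sites between paralogs.
- **Does the phenotype differ?**  Root-growth tolerance index
  TI = (L_stress − mean L_control)/mean L_control with one-way ANOVA and
  Bonferroni pairwise comparisons.

A forward simulator generates gene families with known ground truth —
duplication/loss history, per-site ω classes, a tunable shared-rate
fraction ρ that creates the domain co-evolution signal, and a
species-specific GC3 shift — so every stage is validated against truth.

## Worked example

Simulate clade-restricted positive selection (10% of sites at ω₂ = 5 on
the AL1 ortholog group, purifying background ω₀ = 0.07) and scan every
clade:

```python
import famevol as fv
from famevol.codon_models import branch_site_scan

cfg = fv.SimulationConfig(seed=3, rho=0.0, sigma_b=0.0,
                          region_lengths=(200, 100, 100))
aln, truth = fv.simulate_alignment(cfg)
tree = truth.gene_family_tree

m0 = fv.fit_m0(aln, tree)
for row in branch_site_scan(aln, tree, ["AL1", "AL2", "AL3", "AL4"], m0_fit=m0):
    print(row["clade"], round(row["stat"], 2), f"{row['p']:.4g}",
          row["selected_sites"][:2])
```

prints

```
AL1 27.76 1.375e-07 [(65, 0.96...), (72, 0.98...)]
AL2 0.35 0.5561 []
AL3 0.0 0.9969 []
AL4 0.0 0.9969 []
```

Only the truly selected clade gives a significant df = 1 LRT
(2Δℓ = 27.8), and its empirical-Bayes sites (posterior > 0.95) fall in
the simulated positive classes; the other clades behave as negative
controls.  The co-evolution stage on the same machinery
(`fv.coevolution_scan`) reports, for a family simulated with ρ = 0.9,
domain–domain correlations r ≈ 0.85–0.92 with Mantel p = 0.0002 at 5000
permutations.

The `examples/` directory holds one short script per capability
(simulation, domain trees + co-evolution, selection scan, codon usage,
duplication/conversion, phenotype); each prints its numbers with a line
on what they mean.  A thin CLI wraps the same stages:

```bash
famevol simulate --preset al-family --seed 1 --out fam/
famevol coevolve --alignment fam/simulated_cds.fasta \
                 --domains fam/simulated_domains.tsv --out co/
famevol all --config pipeline.toml     # any subset of stages, TOML-configured
```

## Layout

```
src/famevol/      alignment, trees, gy94, simulate, phylo, coevolution,
                  codon_models, codon_usage, genome_scan, phenotype,
                  pipeline, cli
docs/methods.md   models, conventions, generator scope, limitations
examples/         one narrative script per capability
tests/            unit + property tests and the acceptance suite
```
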