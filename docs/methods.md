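# Methods

`famevol` analyses the molecular evolution of a small multi-domain gene
family — the motivating case is an Alfin-like (AL) transcription-factor
family of ~20 genes in three crucifer species, each protein carrying a
DUF3594-like N-terminal domain and a PHD-finger-like C-terminal domain.
This note records the models, the conventions chosen where the design
was genuinely open, and what the synthetic data generator does and does
not emulate.

## Codon substitution model

All sequence-level inference uses the GY94 codon model on the 61 sense
codons.  The instantaneous rate of change from codon *i* to *j* is 0 if
they differ at more than one position and otherwise proportional to
π_j · κ^[transition] · ω^[nonsynonymous], where π is the codon frequency
vector (F3×4 by default: per-position nucleotide frequencies with stop
codons excluded and renormalized), κ > 0 the transition/transversion
rate ratio and ω = dN/dS.  The chain is time-reversible, so transition
probabilities are computed from a symmetric eigendecomposition
(D^½ Q D^-½), which is both fast and numerically stable.

**Rate scaling.**  A single-class matrix is scaled so the expected
number of substitutions per codon site per unit time at stationarity is
one; branch lengths are therefore expected substitutions per codon.
For site mixtures there is a genuine convention choice.  Here the class
matrices keep their natural relative rates (a class with ω = 5 evolves
faster than one with ω = 0.07, as in CODEML), and one global rate-scale
parameter multiplies all branch lengths.  The simulator ties that scale
to the reciprocal of the proportion-weighted mean background-class rate
(the CODEML convention, so simulated branch lengths are on the expected
substitutions-per-codon scale); the likelihood fits leave the scale
free in the outer optimization, where at the MLE it plays the same role.
Freeing it keeps per-class site likelihoods independent of the class
proportions, which is what makes the inner EM below exact.  Earlier
per-class scaling (every class normalized to rate 1) was rejected: it
removes the rate contrast between classes and measurably destroys
branch-site test power.

## Likelihood computation and fitting

Site likelihoods use Felsenstein pruning over pattern-compressed
alignment columns with per-site rescaling at internal nodes (log scale
factors accumulated, so no underflow on valid input).  Codons containing
gaps or N are treated as missing data (partial likelihood 1 over all
codons), consistent with pairwise deletion elsewhere in the package.

Supported models: M0 (one ratio), M1a (nearly neutral), M2a (positive
selection), M3 (discrete, 3 classes), M7 (beta), M8 (beta & ω), and
branch-site model A with its ω2 = 1 null.  The M7/M8 beta is discretized
into 10 equal-probability categories represented by their category
means.  Branch-site class weights follow the standard model-A
parameterization p2a = (1−p0−p1)·p0/(p0+p1), p2b = (1−p0−p1)·p1/(p0+p1);
internally the four weights are the product (a, 1−a) ⊗ (b, 1−b) with
a = p0/(p0+p1), b = p0+p1.

**Optimization.**  M0 is fitted by L-BFGS-B over log branch lengths,
log κ and log ω jointly.  All other models fix branch lengths at the M0
estimates (a documented speed choice; CODEML re-estimates per model) and
re-estimate κ by default (`branch_site_scan` fixes κ at the M0 value,
again for speed — its LRT compares two models treated identically, so
the test is unaffected).  The remaining ω-side parameters are optimized
by Nelder-Mead from a fixed, deterministic list of starting points,
while the class proportions are profiled out exactly at every step by an
inner EM: for free simplex weights the weight problem is concave, so EM
finds the global optimum; the branch-site product weights use the same
EM from three inner starts.  Bounds: ω0 ∈ [1e-4, 1), ω2 ∈ [1, 999],
κ ∈ [0.05, 99]; estimates pressed against a bound are reported exactly
at the bound (e.g. 999.0).  Nelder-Mead tolerances (xatol 1e-3,
fatol 1e-4) resolve log-likelihood differences far below anything a
χ²-based LRT can distinguish.

LRTs use 2Δℓ (clamped at 0) against the χ² upper tail with df equal to
the parameter-count difference: M0–M3 df 4, M1a–M2a df 2, M7–M8 df 2,
branch-site A vs null df 1.  Sites under positive selection are
identified by naive empirical Bayes (NEB) posteriors by default, with a
coarse-grid Bayes empirical Bayes variant (uniform 10-point grid per
free mixture proportion, ω at the MLE, grid points weighted by data
likelihood) as an option; the reporting threshold is a posterior of
0.95.  Full Yang–Wong–Nielsen BEB integration is out of scope.

## Domain co-evolution (mirror tree)

Each annotated region is translated and a pairwise protein distance
matrix built under pairwise deletion, with either the p-distance or its
Poisson correction −ln(1−p) (default; the distance family a standard
protein-distance tool would apply, the exact published setting being
unknowable).  The statistic is the Pearson correlation over the
n(n−1)/2 upper-triangle entries.  Inference is a one-tailed-upper Mantel
test permuting rows and columns of one matrix jointly; the identity
permutation is counted via the (1+k)/(n_perm+1) convention.  When
n! ≤ n_perm the null is enumerated exhaustively and the p-value is
exact.  The "linear" and "Mantel" correlations use the same
vectorization here and so coincide by construction; no Euclidean
re-transformation is applied to matrices that are already evolutionary
distances.  Phylogenetic correction (projection or partial-Mantel
methods) is deliberately not applied; the shared tree inflates the
baseline correlation at ρ = 0, which is why monotonicity in ρ, not the
absolute r at ρ = 0, is the tested property.

## Trees

Neighbor joining with the Studier–Keppler Q criterion, lowest-index
tie-breaking (bit-reproducible output) and negative branch-length
estimates clamped to zero; bootstrap support is the percentage of
column-resampled replicates containing each internal split of the
reference tree.  Topologies are compared by Robinson–Foulds split
counts.  Maximum-likelihood protein trees are out of scope.

## Codon usage

Wright's effective number of codons with Leu/Ser/Arg treated as single
six-fold families: per family F̂ = (nΣp² − 1)/(n − 1) for n ≥ 2
(singleton families excluded), class averages F̄_k, a missing Ile class
imputed as (F̄₂+F̄₄)/2, ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ capped to
[20, 61].  The mutation-only expectation is ENC* = 2 + s + 29/(s²+(1−s)²)
at GC3 = s; note its true maximum is at s ≈ 0.5022, not exactly 0.5,
because of the linear term.  GC3 is reported over synonymously variable
codons (Met/Trp excluded) with an all-positions variant alongside, since
published tools differ.  CAI is the geometric mean of Sharp–Li relative
adaptiveness weights; weights derived from a reference set replace zero
counts by 0.5 before taking the within-family ratio.  Group comparisons
use the exact two-sided Mann–Whitney U test — family-sized groups
(6–7 genes) make a nonparametric exact test the defensible choice.  Its
p-values are discrete, hence sub-uniform under the null; tests assert
level validity rather than continuous uniformity.

## Duplication and gene-conversion scans

Flanking-gene conservation: all-vs-all Needleman–Wunsch global
alignments (BLOSUM62, gap open 10 / extend 0.5 — needle-style defaults),
identity and similarity as percentages over all alignment columns (gap
columns count against both; similarity = identical or positive BLOSUM62
score).  Reciprocal-best pairs clearing identity ≥ 70% and
similarity ≥ 85% count as conserved; ≥ 3 conserved pairs call a
segmental duplication.  Alignment E-values are not computed
(Karlin–Altschul statistics are ill-defined for global alignment).

Gene conversion: the alignment is condensed to polymorphic columns; each
sequence pair's fragment score is its longest mismatch-free run of
agreement across those columns (no mismatches tolerated within a
fragment).  The null records, for each joint permutation of the
polymorphic columns, the maximum pairwise fragment score; pair p-values
are Bonferroni-corrected over pairs, and the column-permutation null is
enumerated exhaustively when small enough.  A structural caveat follows
from the global-max null: when the alignment mixes very similar pairs
(recently diverged orthologs) with distant ones, the similar pairs
dominate the null and mask tracts between distant paralogs.  The scan is
therefore most powerful — and in the package's positive control is run —
on the paralog set of a single genome, which is also the scenario in
which gene conversion operates.

## Phenotype statistics

Tolerance index per stressed seedling, TI = (L_stress − mean L_control)
/ mean L_control, using the control-arm mean as baseline because
seedlings are not paired across plates.  Genotype groups are compared by
one-way ANOVA; pairwise comparisons are pooled-variance t-tests using
the ANOVA mean square error with N−k df, Bonferroni-multiplied and
capped at 1, with compact-letter displays at α = 0.01 (the significance
level used for root-growth assays).

## The synthetic-data generator

The simulator is the package's ground-truth source.  It emulates:

- a 3-species tree (two close relatives at 0.06 substitutions/codon to
  their split, a deeper outlier at 0.16) with n ortholog groups created
  by duplications spaced 0.08 apart on the stem and one optional
  lineage-specific loss; the default is 4 groups / 11 genes, and the
  `al-family` preset 7 groups / 20 genes (7+7+6 per species);
- three regions (130 / 70 / 50 codons: DUF-like, linker, PHD-like) whose
  per-branch lognormal rate multipliers share a fraction ρ of their
  log-variance (σ_b = 0.5, ρ = 0.8 by default) — the co-evolution dial;
- an ω regime: M0, M2a, or branch-site A (default p0 = 0.81, p1 = 0.09,
  ω0 = 0.07, ω2 = 5 on one foreground clade — i.e. 10% of sites under
  clade-restricted positive selection, against a strongly purifying
  background like the ω ≈ 0.07–0.09 background the family shows);
- κ = 2 and a third-position composition of GC3 = 0.43, shifted to 0.55
  on the outlier species' terminal branches (the GC3/codon-bias
  contrast); neither κ nor π is reported for the real family, so these
  are field-typical defaults.

It does **not** simulate indels (alignments are gap-free; gap handling
is exercised by hand-built fixtures), intron structure, pseudogenes,
alignment error, or among-site rate variation beyond the ω classes.
Passing tests therefore demonstrate correct recovery under the model's
own assumptions — clean in-frame alignments of modest divergence — not
robustness to misalignment or model violation.

## Problem sizes and determinism

Simulation-based checks use 500-codon alignments on 8–11 taxa, 20
replicates for power/calibration rates, 50 per ρ level for the
co-evolution gradient, and 2000 permutations for conversion scans —
sizes at which every stage's signal is comfortably identifiable while a
full run of the suite remains a desk-scale computation.  All stochastic
components take explicit seeds (simulator, Mantel and conversion
permutations, bootstrap); optimizer starting points are fixed lists, so
every reported number is bit-reproducible given the same inputs and
seed.

## Known limitations

- Branch lengths are not re-estimated per mixture model; strongly
  misspecified M0 lengths would bias downstream fits.
- The grid BEB is a coarse stand-in for full BEB; posteriors for weakly
  informed sites differ from CODEML's.
- The Mantel test is not phylogenetically corrected; r at ρ = 0 is well
  above zero because the regions share a tree.
- The conversion scan's global-max null is conservative for distant
  pairs in mixed-divergence alignments (see above).
- The real family's published numbers (correlation coefficients, table
  likelihoods, identities, group p-values) depend on undeposited
  sequences and a manually adjusted alignment and are not reproducible
  from public data; the package's claims are therefore validated against
  simulated ground truth plus the arithmetic worked examples computable
  from printed values.
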