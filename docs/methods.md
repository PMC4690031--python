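# Methods

This note records the models, conventions and design choices behind
`cubkit`, in the spirit of a statistical software methods appendix.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Sequence handling and QC

CDS are read as given: frame 0 of the supplied sequence is the reading
frame, and no ORF re-detection or strand inference is attempted.
Sequences are canonicalized to uppercase DNA (U→T). Four QC flags are
computed per record:

- `TOO_SHORT` (< 300 nt by default) — always dropped. Short CDS carry
  too few codons for stable indices; 300 nt (100 codons) is the
  conventional transcriptome-study threshold.
- `NOT_TRIPLET`, `INTERNAL_STOP` — tallied, dropped only on request.
  Automated ORF reconstruction from assembled transcripts plausibly
  produces frame errors, so a strict default would silently discard
  real signal; both behaviours are exposed as switches.
- `HAS_AMBIGUITY` — never drops a gene. Counting skips only the
  affected triplet (and tallies it), preserving maximal signal.

Codon counting takes consecutive non-overlapping triplets, discards a
trailing 1–2 nt remainder, and counts a terminal stop codon into the
raw count vector; every index downstream excludes stop codons, so this
choice only affects raw composition (GC3 over all codons includes the
stop third position, GC3s never does).

## Indices

**RSCU.** Six-fold amino acids (Leu, Ser, Arg) are treated as single
k = 6 families, giving 18 multi-codon families over 59 informative
codons — the accounting that matches the 59-axis correspondence
analysis convention. Unobserved families yield missing RSCU rather
than 0, distinguishing "amino acid absent" from "codon avoided". Met
and Trp are reported as 1.0 when observed.

**ENC.** Wright's estimator: per family with n ≥ 2 counted codons,
`F̂ = (nΣp̂² − 1)/(n − 1)`; families with `F̂ ≤ 0` are omitted; class
means over degeneracy classes {2, 3, 4, 6}; `F̄₃ = (F̄₂ + F̄₄)/2` when
Ile is not estimable; `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`,
capped at 61. If a whole class among {2, 4, 6} is inestimable the gene
gets a flagged missing value instead of an extrapolation. Genes with
fewer than 30 counted codons are flagged missing. Values below 20 are
reported as computed: short, highly biased genes can legitimately fall
below the asymptotic floor, which is how published transcriptome
analyses come to report minima such as 14.

**The expected-ENC curve and its small bias.** The null curve
`ENC_exp(s) = 2 + s + 29/(s² + (1−s)²)` is an intentional closed-form
approximation: at s = 0.5 it gives 60.5 while the exact
uniform-mutation null is 61, and across mid-range s it sits roughly
half an ENC unit below the exact null. Consequently, genes simulated
under *pure* compositional pressure concentrate marginally **above**
the curve — their deviations `(ENC_exp − ENC_obs)/ENC_exp` centre
slightly below zero (median ≈ −0.005 under the default generator), and
the modal 0.1-wide histogram bin is [−0.1, 0), not [0, 0.1). Real
transcriptomes typically peak in [0, 0.1) because weak translational
selection depresses observed ENC everywhere; a positive modal bin is
therefore evidence of selection, not a property of the mutation-only
null. The acceptance suite asserts the positive modal bin for a
mutation-only genome as an external expectation and that assertion
fails by design of the mathematics; it is kept, rather than weakened,
to document the distinction.

**CAI.** Relative adaptiveness `w(c) = RSCU_ref(c)/max_family RSCU_ref`
from a pooled reference; codons unobserved in the reference are floored
at w = 0.01 so the geometric mean cannot collapse to zero; CAI is the
count-weighted geometric mean of w over a gene's codons with Met, Trp
and stops excluded, hence length-invariant under fixed codon
proportions. Because no external expression data is assumed, the
reference set is built internally: seed with the 5% of genes with
lowest ENC (most biased), compute CAI for all genes, re-select the top
5% by CAI, recompute weights — one refinement iteration, deterministic
(ties break on gene id). A user-supplied reference can replace this via
`weights_from_reference`. The construction only affects gene *ranking*,
which is all the optimal-codon procedure consumes.

## Multivariate analyses

**Neutrality plot.** OLS regression of GC12 on GC3 (slope, intercept)
with a separate Spearman rank correlation; reporting both avoids
conflating the regression slope with the rank statistic. Slope near 1
with significant positive correlation indicates a shared mutational
pressure across codon positions.

**Correspondence analysis.** Performed on the gene × 59-codon RSCU
matrix (the CodonW convention — ordinating RSCU rather than raw
counts; a raw-count matrix can be passed through the same function).
Standard decomposition: correspondence matrix, chi-square standardized
residuals, SVD, principal coordinates for rows and columns, per-axis
inertia fractions. Four axes are reported by default. CA axes are
sign-arbitrary; Axis 1 is oriented so its Spearman correlation with
gene GC3 is non-negative, which makes correlation tables reproducible
in sign; other axes orient the largest-magnitude codon loading
positive.

**Correlation table.** Pairwise-complete Spearman rho with two-sided
p-values over GC12, GC3, GC-all, ENC, CAI, Axis 1 and protein length,
starred at 0.05/0.01 in the report.

## Optimal codons

Genes are ranked by CAI; the top and bottom `floor(0.05 N)` genes
(minimum 1; N ≥ 40 required) form the high/low-expression datasets.
Each informative codon is tested with a Pearson 2×2 chi-square
(df = 1, no continuity correction by default; Yates available) of
codon vs **the other codons of its own family**, high group vs low
group — the family-relative contrast that matches an RSCU comparison.
A codon is optimal when p < 0.01 *and* its high-minus-low RSCU
difference is ≥ 0.08: significance alone is insufficient at pooled-
count scales where trivial differences are significant, and the
direction requirement makes at most one codon per two-fold family
eligible. No multiple-testing correction is applied by default,
mirroring common practice in this literature; Bonferroni/BH are
available as options.

**A documented confound.** In genomes where the preferred-codon set
leans toward one base composition (e.g. A/T-ending), the extreme-CAI
tails differ not only in selection but also in GC3: the high-CAI tail
is dragged toward the composition of the preferred set. The group
contrast then mixes selection with composition — some compositional
hitch-hikers pass both thresholds, and preferred codons ending in the
disfavoured base can be missed. The ground-truth recovery tests
therefore evaluate the chi-square rule on the generator's true
expression groups (where recovery of the planted set is exact at the
default effect size), and evaluate the CAI partition separately by its
label purity. Interpreting real optimal-codon lists requires the same
caution.

## Synthetic genomes

The generator emulates an AT-rich plant transcriptome CDS collection.
Per gene: protein length from a log-normal (median ≈ 220 codons,
σ = 0.45, clipped to [100, 3000]); a third-position GC target `t` from
Beta(3.0, 4.12) — wide enough to span roughly 5–90% GC3 with the Beta
mean chosen so realized overall GC averages ≈ 0.44; a first/second-
position target `0.5 + 0.85 (t − 0.5)` (coupling < 1: a weaker shared
pressure, yielding neutrality slopes ≈ 0.8); amino acids drawn from a
uniform baseline re-weighted by each family's mutational mass under
the gene's base composition (mutation acts on all positions, so the
neutrality-plot structure emerges mechanistically rather than by
construction); codons within a family drawn ∝ mutational weight ×
exp(s · 1[preferred]); a uniformly chosen stop appended. The default
planted preferred set is one codon per multi-codon family, taken as
the most-used high-group codon of each family in the bundled published
comparison table (a realistic A/T-leaning set for a eudicot).
Selection strength is bimodal by default — s = 1 in a quarter of
genes, 0 elsewhere — and the expression label marks the selected
class.

What the generator does *not* emulate: assembly artifacts, UTR/intron
contamination, non-uniform amino-acid usage of any particular
proteome, expression-level variation within the selected class, or
strand-asymmetric mutation (PR2 points centre on (0.5, 0.5) under the
default symmetric mutational model). Passing tests on synthetic
genomes therefore demonstrate correctness of the estimators and of
ground-truth recovery under the stated model, not biological claims
about any real transcriptome.

Problem sizes used by the test and acceptance suites — 400–2,000 genes
per genome, ~10⁴ codons per family for law-of-large-numbers checks,
50-gene instances for dual-implementation oracles — were chosen as the
smallest scales at which the asserted statistical properties are
stable across seeds.

## Numerical conventions

- Missing values are NaN throughout; they propagate rather than
  defaulting.
- Percentages are rendered to 1 decimal and RSCU to 3 decimals in
  reports, matching the conventional table formatting of this
  literature.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  same spec and seed reproduce a genome byte-identically, and the
  pipeline's TSV outputs are byte-identical across reruns on the same
  input.
- The analysis pipeline itself is deterministic; its `seed` parameter
  exists for provenance in the run manifest and for the simulator.
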