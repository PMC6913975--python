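# Methods

## Codon counting and the genetic code

All metrics consume per-CDS codon counts under NCBI translation table 11
(bacterial). Under table 11 the 64 codons split into 61 sense codons and 3
stops; the 20 amino acids fall into degeneracy classes of nine 2-fold, one
3-fold (Ile), five 4-fold, three 6-fold (Leu, Ser, Arg) and two 1-fold
(Met, Trp) families. Counting is frame-0 and non-overlapping; the terminal
stop is trimmed before counting so Nc, GC and RSCU share one denominator;
internal stops are counted and warned about but do not abort (pseudogene-
like inputs still process); codons containing N are skipped and tallied
separately. Lower-case and RNA input are normalised to upper-case DNA.
Alternative start codons (GTG/TTG) are counted as their literal triplet —
the per-codon count tables this package is designed around tally literal
codons — but the secondary-structure aligner accepts them as Met at
position 1 when the protein shows M.

## Effective number of codons

Wright's estimator. Per family, the bias-corrected homozygosity
F̂ = (n·Σp̂ᵢ² − 1)/(n − 1) is the probability that two codons drawn without
replacement are identical; it requires n ≥ 2. Nc = 2 + 9/F̄₂ + 1/F̄₃ +
5/F̄₄ + 3/F̄₆ over class means of the defined F̂ values.

Rare-amino-acid handling is the one genuinely open design point (the
classical command-line tools do not document theirs): families with n < 2
are excluded from their class mean; an undefined Ile class is imputed as
(F̄₂+F̄₄)/2 and an undefined 6-fold class as F̄₄ (Wright's published
fallback hierarchy); if the 2-fold or 4-fold class is wholly undefined —
or its mean homozygosity is 0, which would make the estimator singular —
Nc is undefined (NaN with a logged diagnostic). The imputation can be
switched off (`fallback=False`), in which case any undefined class makes
Nc undefined; this toggle exists because different legacy tools plausibly
round differently on short genes. Nc is clipped to [20, 61]; uniform usage
gives a raw value ≈ 61.4 (the finite-n bias correction overshoots), which
the cap returns as 61, matching the convention of published tables that
print Nc = 61 exactly.

A note on invariances: Nc is exactly invariant to monotone relabelling of
codons within families, but only asymptotically invariant to scaling all
counts by a constant — the bias correction drifts O(1/n) per family, so a
×10 scaling can move Nc by >1 unit on gene-sized tables (~300 codons) and
becomes negligible (<0.5 units) only once every codon is observed ~150+
times. Tests assert the property in that regime.

## GC metrics

`gc_positional` returns the G+C fraction overall and at each codon
position over counted sense codons. `gc3_synonymous` (GC3s) restricts the
third position to degenerate families, excluding Met and Trp whose third
base is fixed; this is the abscissa used on the Nc-plot, and the
convention of the classical codon-usage tools. The two can differ by
several percentage points because Met and Trp both end in G.

## Nc-plot and neutrality plot

The mutation-only expectation Nc*(s) = 2 + s + 29/(s² + (1−s)²), clipped
at 61, is the null curve: a gene whose synonymous composition reflects
third-position GC alone should sit on it, and genes well below it are
candidates for translational selection. The neutrality plot regresses
(GC1+GC2)/2 on GC3 by ordinary least squares; a slope near 1 indicates
directional mutation pressure acting on all positions, near 0 that
selection pins the first two positions.

z-scores use the population (N-denominator) standard deviation, since the
genome's annotated genes are the entire population, not a sample.
Percent-below uses strict inequality. Correlations are Spearman with
midrank ties (p from the t approximation); polynomial fits (degree 1-3)
are unweighted least squares reporting R² and the residual standard error
SEE = √(SSE/(n−d−1)). Genes with undefined Nc are excluded pairwise and
logged.

## Core-codon rank tests

For each degenerate amino acid, the per-species usage values of each codon
form one group; 2-fold families are tested with Mann-Whitney, larger
families with Kruskal-Wallis (df = k−1), both on pooled midranks with tie
correction. The reported U is min(U₁, U₂) so that U ≤ n₁n₂/2, the
convention of bench statistics software. The Mann-Whitney p-value is exact
(full enumeration of group assignments over the midranks) when
n₁+n₂ ≤ 12, otherwise a tie-corrected normal approximation without
continuity correction; on two groups the tie-corrected H equals that z²,
which the tests verify numerically. Inputs default to raw per-CDS counts;
a per-1000-codon frequency mode is provided because cohorts with unequal
gene lengths would otherwise confound length with preference. The family
significance call uses α = 0.001.

## Factorial ANOVA

Lifestyle (P/NP) × Gram (positive/negative/variable) is an unbalanced
crossed design, so the two-way ANOVA with interaction uses hierarchical
(Type II) sums of squares, fitted via OLS. Spreadsheet two-factor ANOVA —
the tool this analysis class historically used — requires balanced cells,
so an unbalanced Type II fit is the defensible replacement rather than an
exact re-enactment. Empty cells drop the interaction with a warning; a
constant response reports zero factor SS and p = 1. The single
Gram-variable species is excluded from Gram-factor analyses by default
(flag-controlled). Post-hoc pairwise level comparisons are t tests on the
residual mean square, Holm-Šidák adjusted within each factor (step-down:
sorted ascending, adjusted p₍ᵢ₎ = 1 − (1−p₍ᵢ₎)^(m−i+1), monotonised).
Per-response significance uses α = 0.01.

## Secondary-structure stratification

The triple alignment pairs codon i with residue i and markup symbol i
after trimming the stop; translation is verified at every position and any
mismatch, length disagreement or non-H/E/C symbol fails loudly with the
position. Markup is an input (a FASTA-like file of H/E/C strings): the
structure predictor is an external trained model and predicting structure
is out of scope. Stratified counts are asserted to sum back to the
whole-CDS table; per-class RSCU flags empty families as unused rather than
reporting them as maximally biased zeros.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
bacterial biology in detail.

* **Mutational mode**: third position G/C with probability s (uniform
  within {G,C} and {A,T}); 6-fold families choose their 2-fold/4-fold
  first-two-base block with probability proportional to block size; Ile is
  renormalised over its three legal codons. Synonymous GC3 then converges
  to s (all-sense GC3 does not: Met/Trp have fixed G third bases and Ile
  is truncated — the tests therefore calibrate on GC3s).
* **Selected mode**: per-family codon probabilities drawn once per gene
  from a symmetric Dirichlet(α); α → ∞ is uniform usage (Nc → 61), small α
  concentrates usage (Nc → 20s). An optional preferred codon per amino
  acid with weight w ≥ 1 plants a cohort-wide core-codon set.
* **Cohorts**: species receive lifestyle and Gram labels by
  largest-remainder allocation of the configured proportions (defaults
  mirror a 143-species study design: 75:68 NP:P, 43:99:1
  positive:negative:variable). Effects are multiplicative shifts tied to a
  factor level, targeting an amino acid (composition) or codon
  (within-family weight). Genomes default to heterogeneous mutational
  usage — per-species s uniform in ±0.15 around the centre, per-gene
  jitter σ = 0.05, and a 25% admixture of selection-biased genes
  (Dirichlet α = 0.5) standing in for the highly expressed tail — so
  genome Nc distributions have realistic spread instead of piling at the
  61 cap. The focal gene defaults to selected mode α = 0.3 (clearly more
  biased than its genome) and the housekeeping reference to α = 0.25
  (slightly more biased still). All randomness flows from one seed through
  SeedSequence spawning with one stream per species, so generation is
  reproducible and order-independent.

What the generator does **not** emulate: phylogenetic correlation between
species, indels or length variation (genes are fixed-length unless
configured), realistic amino-acid composition (uniform over 20 by
default), or coupling between a species' GC and its focal gene's selected-
mode preferences (the Dirichlet is symmetric by design). Passing tests
therefore demonstrate correctness of the statistical machinery and
calibration under the stated models — not that real cohorts will show any
particular effect size.

## Problem sizes and tolerances

Oracle-equivalence tests run ≥200 random small instances per statistic at
1e-8 (1e-9 for ANOVA sums of squares). Null calibration uses 200 cohorts
of 30 species (binomial 99% band around α for the scan; KS distance < 0.1
for ANOVA p uniformity); power uses 100 cohorts of 60 species with the
×1.5 serine shift (≥90% detection at p < 0.01); generator calibration uses
200 genes of 300 codons (mean Nc within 2 units of the curve at s = 0.5).
These sizes were chosen so the full suite completes in well under a minute
of statistical simulation while keeping Monte-Carlo error far from the
acceptance bands. The acceptance script's study-scale cohort uses 143
species × 40 genome genes of 300 codons.

## Known limitations

* Nc on very short CDS depends on the rare-amino-acid fallback; printed
  values from legacy tools may differ in the second decimal.
* The exact Mann-Whitney enumeration is quadratic-exponential in sample
  size and is therefore reserved for n₁+n₂ ≤ 12; above that the normal
  approximation (no continuity correction) is used.
* Type II sums of squares are one of several defensible choices for
  unbalanced factorial data; with a strong interaction present, main-effect
  tests should be read with the usual caution.
* The pipeline compares one focal and one reference gene per species; it
  does not model within-species replication.
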