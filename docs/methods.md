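# Methods

## Allelotyping model

Peak areas of the two allele-specific extension products are proportional
to the amounts of the alleles in the template, so their ratio compares
allele abundance within a heterozygote.  Two systematic facts shape the
analysis:

1. **Detection bias.** The assay detects the two products with different
   efficiency, so even 1:1 genomic DNA yields a ratio *b* ≠ 1 (≈1.78 for
   the AT:G assay shipped as the example).  Because the bias is
   multiplicative and template-independent, the pooled gDNA ratio mean
   calibrates it away: cDNA ratios are interpreted relative to that
   baseline, not relative to 1.
2. **Replicate noise and sporadic failures.** Replicate reactions scatter
   multiplicatively; occasional reactions fail in ways that produce wild
   ratios.  Outliers are removed by Tukey fences (values outside
   Q1 − k·IQR … Q3 + k·IQR, k = 1.5) — once on the pooled gDNA ratios
   (the baseline is a cohort-level constant) and per sample on cDNA ratios
   (the per-sample replicate count n in the report reflects sample-level
   exclusions).

Analysis is on raw ratios, not log-ratios, matching how such summaries are
conventionally reported for this assay; the numerator allele is
configurable, and swapping it inverts every replicate ratio exactly (note
that aggregate folds are only approximately reciprocal, since the mean of
reciprocals is not the reciprocal of the mean — the shipped reference
baselines 1.78431 (AT:G) and 0.56723 (G:AT) illustrate the gap).

### Tests and intervals

Each sample's filtered cDNA ratios are compared with the baseline by a
one-sample two-tailed t test (df = n − 1); the 95% CI of the difference of
means is d̂ ± t₀.₉₇₅,ₙ₋₁ · SE.  Comparing against the *pooled* baseline
constant is what "pairing with a cohort mean" reduces to; an optional
`replicate_paired` mode instead pairs cDNA replicate i with the same
individual's gDNA replicate i and runs a paired t test.  Stratum tests
(population, male, female, and their `*_edited` restrictions to samples
with zero cDNA exclusions) pool member samples' included replicate ratios —
accepting the pseudo-replication this implies, because that is how such
summary tables account N = replicates — with a `sample_means` mode as the
statistically cleaner sensitivity analysis.  Per-sample calls use raw
p < α (α = 0.05, two-tailed); a Bonferroni switch exists but defaults off.

### A known calibration caveat

Treating the pooled baseline as a *known* constant understates uncertainty:
with 35 × 8 gDNA replicates at ~8% replicate CV, the baseline mean's SE is
the same size as the pooled cDNA SE, so the stratum CI's true null coverage
is approximately P(|Z| < 1.96/√2) ≈ 83%, not 95% (measured ≈78/100 on null
simulations).  The `include_baseline_error` option adds the baseline's
sampling variance to the test SE, restoring ≈94/100 coverage.  It defaults
off because the constant-baseline form is what the reference summaries use;
users drawing inferential conclusions from stratum CIs should switch it on.
Per-sample significance in the shipped reference table could not be
reconstructed from its printed summaries under any of these test variants;
the pipeline reports its own p-values and they are verified against an
independent closed-form t computation instead.

## Synthetic cohorts

`simulate_cohort` emulates the replicate design: per individual, R
replicate reactions (default 8) on each template.  Expected ratios are
*b* for gDNA and *b·eᵢ* for cDNA with eᵢ ~ LogNormal(ln m, s²); every
replicate ratio is multiplied by LogNormal(0, cv²) noise and, with
probability p, by an outlier shock (factor F or 1/F with equal
probability — one-sided multiplicative shocks give the IQR filter
realistic work).  Areas are emitted as ratio-consistent pairs: the
denominator-allele area is drawn lognormally around an arbitrary nominal
intensity and the numerator area is area × ratio, so every downstream
statistic is scale-free by construction.

Defaults are the example study's conditions: 35 samples, 8 replicates,
b = 1.78, effect median m = 1.16 with s = 0.15 (between-individual fold
spread consistent with per-sample folds ranging ~0.39–1.53), cv = 0.08,
p = 0.03 with F = 2.5 (≈3% of replicates excluded, matching the reported
exclusion counts), male fraction 19/35.  What the generator does *not*
emulate: mass spectra themselves, PCR efficiency drift between templates,
genotyping error, or correlated replicate failures — so green simulation
tests demonstrate correctness of the statistics under the stated noise
model, not robustness to every real-data pathology.  Recovery checks set
s = 0 so that "the true population fold" is a single number.

Degenerate inputs: with zero simulated noise all ratios are equal up to
1-ulp division error, and the zero-IQR fences may then exclude ties
arbitrarily; the surviving mean is unaffected.  `tukey_filter` refuses
fewer than 4 values (fences are undefined); samples with fewer than 4 cDNA
ratios skip filtering, and fewer than 3 usable ratios flags the sample
untestable rather than dropping it.  Quartiles use linear interpolation
between order statistics; the numpy method name is configurable because
quartile conventions differ between software.

## In-silico PCR-RFLP

Primer annealing requires an exact 3'-terminal match (polymerase
extension) and tolerates up to `max_mismatch` internal substitutions
(default 1, the engineered change).  The amplicon carries *primer-derived*
bases at mismatch positions — this is the essential mechanism by which the
deliberately mismatched reverse primer writes a GTAC (RsaI) site into the
G-allele product: the variant G supplies the G, the primer supplies TAC.
The AT allele interrupts the site, leaves the product uncut, and is 1 bp
longer (2-nt vs 1-nt variant).  Digestion scans the plus strand left to
right, cutting non-overlapping sites 2 bases in (GT^AC); GTAC is its own
reverse complement, so plus-strand scanning is complete.  Genotype calls
compare fragment-length *sets* within a bp tolerance (default 0; a gel
band reveals neither copy number nor sub-tolerance size differences):
homozygote = one allele's pattern, heterozygote = the union, else no-call.
Synthetic references rejection-sample their random filler so no spurious
GTAC or duplicate primer site confounds the design.

## Consensus motif scanning

Motifs are IUPAC consensus strings matched for *presence* on both strands
(minus-strand hits are positions where the reverse-complemented pattern
matches the plus strand), with all overlapping occurrences reported.
Position-weight-matrix scoring is deliberately out of scope: the matrix
scores attached to such predictions come from proprietary/unpublished
matrices and cannot be reproduced; presence/absence per allele can.
Classification is purely count-based: shared, allele-specific, or absent.

Two scanning contexts ship for the example variant: the EMSA probe
including its 4-nt labelling tag, and the tag-less genomic core.  The
probe context is the default for reproducing the published five-motif
pattern because the SRY heptamer TGAGTTT spans the tag/flank junction —
on the tag-less core it is absent from both strands.  Coordinates are
0-based, plus-strand, half-open.

## Reporter assay

Firefly/Renilla per-well ratios cancel transfection efficiency exactly
(scaling both channels of a well by any constant changes nothing — a
tested invariant).  Within each experiment, construct activity is the
construct's mean well ratio over the control's mean well ratio, making the
control identically 1.  Construct-vs-control comparisons use per-
experiment relative activities as observations (experiments, not wells,
are independent), Welch's two-tailed t by default with a pooled-variance
switch, and a per-well mode as a sensitivity analysis.  Two constant equal
groups are reported as t = 0, p = 1 rather than 0/0.  Note that
ratio-of-means estimators carry a small O(cv²) upward bias (~+0.5% at 5%
well CV); the simulation tests account for it.

## Problem sizes

Monte-Carlo checks use 200 seeds for recovery bias, 100 seeds each for CI
coverage and reporter power, and ≥1000 cases per fuzzed invariant
(digest conservation, strand duality, label symmetry, scale invariance,
t-oracle agreement); the full suite and the acceptance script each run in
well under a minute of compute per stage.
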