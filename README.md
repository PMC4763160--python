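# asekit

A toolkit for characterizing a single cis-regulatory variant end to end:
allele-specific expression (ASE) inference from replicate mass-spectrometry
peak areas, in-silico PCR-RFLP genotyping, allele-aware consensus motif
scanning, and dual-luciferase reporter normalization.  The built-in worked
example is rs386770867, a combined AT/G insertion-substitution in the
5'-UTR of *SETDB2* on chromosome 13q14.

## Who it is for

Groups running allelotyping experiments (MassARRAY/hME-style assays in
which extension-product peak areas are proportional to allele amounts) who
need the downstream statistics: detection-bias calibration, outlier
handling, per-individual and stratified tests, and fold-change calls —
plus the wet-lab design logic (mismatch-primer RFLP, motif presence,
reporter assays) that usually accompanies such a study.

## The model

For a heterozygote, genomic DNA carries the two alleles 1:1, so the
observed gDNA peak-area ratio measures only the assay's allele-detection
bias *b*.  Pooling all heterozygotes' gDNA replicate ratios, removing
values outside Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR), and averaging
gives the baseline *b̂*.  For individual *i* with filtered cDNA replicate
ratios r₁…rₙ, the pipeline reports

- diff of means  d̂ᵢ = r̄ᵢ − b̂, with 95% CI  d̂ᵢ ± t₀.₉₇₅,ₙ₋₁·SE(r̄ᵢ),
- a one-sample two-tailed t test of r̄ᵢ against b̂ (df = n − 1),
- fold change  f̂ᵢ = r̄ᵢ / b̂  (>1 ⇒ numerator-allele overexpression),
- an overexpressed-allele call at p < α (default 0.05).

Strata (population, male, female, each also restricted to samples with no
excluded cDNA replicates) pool member samples' included replicate ratios
and run the same test.  A synthetic-data generator reproduces the whole
design — multiplicative detection bias, lognormal per-sample effects and
replicate noise, sporadic outlier shocks — so every stage is testable with
known ground truth.

## Worked example

```python
from asekit import SimulationConfig, simulate_cohort, run_allelotype

peaks, truth = simulate_cohort(SimulationConfig(seed=1))
result = run_allelotype(peaks)
print(f"{result.baseline.mean_ratio:.4f}")       # 1.7909
pop = {c.stratum: c for c in result.strata}["population"]
print(f"{pop.fold_change:.4f}  {pop.p_value:.2e}")  # 1.1428  1.37e-21
```

The baseline recovers the simulated detection bias (1.78): a gDNA AT:G
ratio of ~1.79 despite 1:1 template is pure assay bias.  The population
fold change of ~1.14 against a generating median effect of 1.16 says the
AT allele is transcribed ~14–16% above its genomic share — preferential
AT-allele expression — at p ≈ 10⁻²¹.

The `examples/` directory holds one short script per capability
(allelotyping, published-table arithmetic, RFLP genotyping, motif
scanning, luciferase normalization); each prints its numbers with a note
on what they mean.  The same functionality is exposed as a thin CLI:

```bash
asekit simulate --n-samples 35 --seed 1 --out peaks.tsv
asekit allelotype --peaks peaks.tsv --out report.tsv
```

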