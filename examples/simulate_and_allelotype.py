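"""Simulate an allelotyping cohort and run the full ASE pipeline.

Generates 35 heterozygotes x 8 replicate reactions per template with a
gDNA allele-detection bias of 1.78 and a true population expression fold of
1.16, then estimates the pooled gDNA baseline, tests every sample and
stratum against it, and prints the headline numbers.
"""

from asekit import SimulationConfig, run_allelotype, simulate_cohort

config = SimulationConfig(seed=1)
peaks, truth = simulate_cohort(config)
result = run_allelotype(peaks)

b = result.baseline
print(f"pooled gDNA baseline: {b.mean_ratio:.4f} "
      f"(n={b.n_used}, excluded={b.n_excluded})")
# The baseline recovers the simulated detection bias (1.78): genomic DNA is
# 1:1 in template, so any departure from 1 is assay bias, not expression.

called = [s for s in result.samples if s.overexpressed_allele != "none"]
print(f"samples with significant allele-specific expression: "
      f"{len(called)}/{len(result.samples)}")

for c in result.strata:
    print(f"{c.stratum:>18}: fold={c.fold_change:.4f} "
          f"diff={c.diff_of_means:+.4f} p={c.p_value:.3g} "
          f"call={c.overexpressed_allele}")
# Stratum folds are mean cDNA ratio / baseline: ~1.16 for the population
# means the numerator (AT) allele is transcribed ~16% above its gDNA-implied
# share, i.e. preferential AT-allele expression.
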