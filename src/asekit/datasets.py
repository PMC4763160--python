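"""Packaged reference data.

Published per-sample and per-stratum allelotype summary statistics for the
35 individuals heterozygous for rs386770867 (replicate counts before/after
outlier exclusion, mean cDNA AT:G ratio, difference of means against the
pooled gDNA baseline, 95% CI half-width and bounds, significance, the
overexpressed-allele call, and fold change).  The study deposits no raw
peak-area data, so these printed summaries — together with the
full-precision pooled gDNA baseline constants — are the reference surface
for consistency checks.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Pooled gDNA AT:G peak-area ratio mean across all heterozygotes after
#: 1.5xIQR outlier exclusion (full precision as published), and the same
#: baseline computed with the G allele as numerator.
GDNA_BASELINE_AT_G = 1.78431493189407
GDNA_BASELINE_G_AT = 0.567229238822408

#: Rounded headline numbers: baseline, population fold change, samples.
GDNA_BASELINE_ROUNDED = 1.78
N_HETEROZYGOTES = 35
REPLICATES_PER_TEMPLATE = 8


def load_reference_allelotype() -> pd.DataFrame:
    """Load the published allelotype summary table.

    Columns: ``row_id kind N n mean_cdna diff_of_means ci_half_width lower
    upper sig overexpressed_allele fold_change``; ``kind`` is ``sample`` for
    the 35 per-heterozygote rows and ``stratum`` for the population / sex
    rows (``*_edited`` strata use only samples with no excluded cDNA
    replicates).
    """
    path = resources.files("asekit.data").joinpath("rs386770867_allelotype.tsv")
    with resources.as_file(path) as fh:
        return pd.read_csv(fh, sep="\t")
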