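"""Allele-specific expression inference from replicate peak-area ratios.

The pipeline quantifies preferential allele expression in heterozygotes from
mass-spectrometry peak areas.  Genomic DNA carries the two alleles 1:1, so
the pooled gDNA peak-area ratio measures the assay's allele-detection bias;
deviation of an individual's cDNA ratio from that baseline indicates
allele-specific expression.  Steps:

1. per-replicate allele ratios (numerator allele configurable);
2. Tukey 1.5xIQR outlier exclusion — once on the pooled gDNA ratios, and
   per sample on cDNA ratios;
3. pooled gDNA baseline mean;
4. per-sample and stratified one-sample two-tailed t tests of the filtered
   cDNA ratios against the constant baseline, with 95% CIs of the
   difference of means, fold change (mean cDNA ratio / baseline) and an
   overexpressed-allele call at p < alpha;
5. a report table mirroring the per-sample / per-stratum summary layout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GDNA = "gDNA"
CDNA = "cDNA"

STRATA = (
    "population",
    "population_edited",
    "male",
    "male_edited",
    "female",
    "female_edited",
)

REPORT_COLUMNS = [
    "Sample",
    "N",
    "n",
    "MeanCDNA",
    "DiffOfMeans",
    "CIHalfWidth",
    "Lower",
    "Upper",
    "Sig",
    "OverexpressedAllele",
    "FoldChange",
]


class PeakTableError(ValueError):
    """A record-level problem in the input peak table (e.g. failed well)."""


@dataclass(frozen=True)
class AllelotypeConfig:
    """Analysis settings.

    alpha: two-tailed significance threshold for allele calls.
    iqr_k: Tukey fence multiplier.
    quartile_method: quantile interpolation passed to numpy (default
        ``linear``, i.e. interpolation between order statistics).
    numerator_allele / denominator_allele: which allele's area goes on top.
    pairing_mode: ``pooled_baseline`` tests cDNA ratios against the constant
        pooled gDNA mean; ``replicate_paired`` pairs cDNA replicate i with
        the same individual's gDNA replicate i.
    pooling_mode: stratum tests pool ``replicates`` across member samples
        (default) or use per-``sample_means`` as observations.
    bonferroni: divide alpha by the number of samples for per-sample calls.
    include_baseline_error: add the baseline mean's sampling variance to the
        test SE (Welch-style).  Off by default: the published summaries
        treat the pooled gDNA mean as a known constant, which understates
        CI width (see docs); this flag provides the calibrated alternative.
    """

    alpha: float = 0.05
    iqr_k: float = 1.5
    quartile_method: str = "linear"
    numerator_allele: str = "AT"
    denominator_allele: str = "G"
    pairing_mode: str = "pooled_baseline"
    pooling_mode: str = "replicates"
    bonferroni: bool = False
    include_baseline_error: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.iqr_k < 0:
            raise ValueError("iqr_k must be >= 0")
        if self.pairing_mode not in ("pooled_baseline", "replicate_paired"):
            raise ValueError(f"unknown pairing_mode: {self.pairing_mode}")
        if self.pooling_mode not in ("replicates", "sample_means"):
            raise ValueError(f"unknown pooling_mode: {self.pooling_mode}")


@dataclass(frozen=True)
class BaselineEstimate:
    """Pooled gDNA ratio mean correcting allele-detection bias."""

    mean_ratio: float
    n_used: int
    n_excluded: int
    sd: float = math.nan

    @property
    def sem(self) -> float:
        """Standard error of the baseline mean (nan if sd unknown)."""
        return self.sd / math.sqrt(self.n_used)


@dataclass
class SampleSummary:
    """Per-heterozygote allelotype result (one report row)."""

    sample_id: str
    N: int
    n: int
    mean_cdna_ratio: float
    diff_of_means: float
    ci_half_width: float
    ci_lower: float
    ci_upper: float
    p_value: float
    overexpressed_allele: str
    fold_change: float
    testable: bool = True
    sex: str = "unknown"


@dataclass
class CohortSummary:
    """Stratum-level allelotype result (population / sex strata)."""

    stratum: str
    N: int
    n: int
    n_samples: int
    mean_cdna_ratio: float
    diff_of_means: float
    ci_half_width: float
    ci_lower: float
    ci_upper: float
    p_value: float
    overexpressed_allele: str
    fold_change: float


@dataclass
class AllelotypeResult:
    """Full pipeline output: baseline, per-sample and stratum summaries."""

    baseline: BaselineEstimate
    samples: list[SampleSummary]
    strata: list[CohortSummary]
    ratios: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def fold_change(mean_ratio: float, baseline: float) -> float:
    """Fold change of a mean cDNA allele ratio over the gDNA baseline."""
    return mean_ratio / baseline


def diff_of_means(mean_ratio: float, baseline: float) -> float:
    """Difference of means (cDNA - gDNA baseline)."""
    return mean_ratio - baseline


def ci_bounds(diff: float, half_width: float) -> tuple[float, float]:
    """(lower, upper) of a symmetric confidence interval around ``diff``."""
    return diff - half_width, diff + half_width


def compute_ratios(peaks: pd.DataFrame, numerator: str = "AT") -> pd.DataFrame:
    """Per-replicate allele peak-area ratios.

    Returns one row per input record with columns ``sample_id template
    replicate ratio included sex``; all rows start included.  Raises
    :class:`PeakTableError` identifying the offending well if any area is
    missing or nonpositive (a failed assay well must be handled upstream,
    not silently propagated).
    """
    if numerator not in ("AT", "G"):
        raise ValueError(f"unknown numerator allele: {numerator}")
    num_col = f"area_{numerator}"
    den_col = "area_G" if numerator == "AT" else "area_AT"
    areas = peaks[[num_col, den_col]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(areas) & (areas > 0), axis=1)
    if bad.any():
        row = peaks.iloc[int(np.flatnonzero(bad)[0])]
        raise PeakTableError(
            "nonpositive or missing peak area for sample "
            f"{row['sample_id']} {row['template']} replicate {row['replicate']}"
        )
    out = peaks[["sample_id", "template", "replicate"]].copy()
    out["ratio"] = areas[:, 0] / areas[:, 1]
    out["included"] = True
    out["sex"] = peaks["sex"] if "sex" in peaks.columns else "unknown"
    return out


def tukey_filter(
    values, k: float = 1.5, method: str = "linear"
) -> tuple[list[float], list[float]]:
    """Split values into (included, excluded) by Tukey fences Q1/Q3 ± k·IQR.

    Quartiles are computed by the given numpy interpolation method on the
    full input; order is preserved within each output list.  Requires at
    least 4 values (fences are not meaningful on smaller sets).
    """
    values = [float(v) for v in values]
    if len(values) < 4:
        raise ValueError(f"need >= 4 values to compute Tukey fences, got {len(values)}")
    q1, q3 = np.percentile(values, [25, 75], method=method)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    included = [v for v in values if lo <= v <= hi]
    excluded = [v for v in values if not (lo <= v <= hi)]
    return included, excluded


def estimate_baseline(
    gdna_ratios, k: float = 1.5, method: str = "linear"
) -> BaselineEstimate:
    """Pooled gDNA baseline: one Tukey pass over all heterozygotes' gDNA
    ratios together, then the arithmetic mean of the survivors."""
    gdna_ratios = np.asarray(list(gdna_ratios), dtype=float)
    if gdna_ratios.size < 4:
        raise ValueError("need >= 4 pooled gDNA ratios for a baseline")
    included, excluded = tukey_filter(gdna_ratios, k=k, method=method)
    if len(included) < 2:
        raise ValueError("fewer than 2 gDNA ratios survive outlier exclusion")
    return BaselineEstimate(
        mean_ratio=float(np.mean(included)),
        n_used=len(included),
        n_excluded=len(excluded),
        sd=float(np.std(included, ddof=1)),
    )


def _one_sample_test(values: np.ndarray, mu: float, alpha: float, extra_var: float = 0.0):
    """Mean, diff, CI half-width and two-tailed p of values vs constant mu.

    ``extra_var`` adds a known variance (e.g. the baseline mean's sampling
    variance) to the squared SE; df stays n-1.
    """
    n = values.size
    mean = float(np.mean(values))
    diff = mean - mu
    sd = float(np.std(values, ddof=1))
    se = math.sqrt(sd * sd / n + extra_var)
    if se == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        half = 0.0
    else:
        t_stat = diff / se
        p = float(2 * stats.t.sf(abs(t_stat), n - 1))
        half = float(stats.t.ppf(1 - alpha / 2, n - 1) * se)
    return mean, diff, half, p


def _allele_call(diff: float, p: float, alpha: float, config: AllelotypeConfig) -> str:
    if not np.isfinite(p) or p >= alpha:
        return "none"
    return config.numerator_allele if diff > 0 else config.denominator_allele


def test_sample(
    cdna_ratios,
    baseline: BaselineEstimate,
    sample_id: str = "",
    config: AllelotypeConfig | None = None,
    *,
    prefiltered: bool = False,
    alpha: float | None = None,
) -> SampleSummary:
    """Test one sample's cDNA ratios against the pooled gDNA baseline.

    Ratios are Tukey-filtered per sample (when at least 4 are supplied and
    ``prefiltered`` is false), then compared with the constant baseline mean
    by a one-sample two-tailed t test with df = n-1; the 95% CI of the
    difference of means is t_{1-alpha/2, n-1} x SE.  Samples with fewer than
    3 surviving replicates are flagged untestable rather than dropped.
    """
    config = config or AllelotypeConfig()
    use_alpha = alpha if alpha is not None else config.alpha
    values = np.asarray(list(cdna_ratios), dtype=float)
    n_total = values.size
    if not prefiltered and n_total >= 4:
        included, _ = tukey_filter(values, k=config.iqr_k, method=config.quartile_method)
        values = np.asarray(included)
    n = values.size
    if n < 3:
        mean = float(np.mean(values)) if n else math.nan
        return SampleSummary(
            sample_id=sample_id,
            N=n_total,
            n=n,
            mean_cdna_ratio=mean,
            diff_of_means=mean - baseline.mean_ratio if n else math.nan,
            ci_half_width=math.nan,
            ci_lower=math.nan,
            ci_upper=math.nan,
            p_value=math.nan,
            overexpressed_allele="none",
            fold_change=mean / baseline.mean_ratio if n else math.nan,
            testable=False,
        )
    extra_var = 0.0
    if config.include_baseline_error and math.isfinite(baseline.sd):
        extra_var = baseline.sem**2
    mean, diff, half, p = _one_sample_test(values, baseline.mean_ratio, use_alpha, extra_var)
    lower, upper = ci_bounds(diff, half)
    return SampleSummary(
        sample_id=sample_id,
        N=n_total,
        n=n,
        mean_cdna_ratio=mean,
        diff_of_means=diff,
        ci_half_width=half,
        ci_lower=lower,
        ci_upper=upper,
        p_value=p,
        overexpressed_allele=_allele_call(diff, p, use_alpha, config),
        fold_change=fold_change(mean, baseline.mean_ratio),
        testable=True,
    )


test_sample.__test__ = False  # keep pytest from collecting the API name


def _paired_sample(
    cdna: pd.DataFrame, gdna: pd.DataFrame, baseline, config, sample_id: str
) -> SampleSummary:
    """Replicate-paired variant: paired t on (cDNA_i - gDNA_i) by replicate index."""
    merged = cdna.merge(gdna, on="replicate", suffixes=("_c", "_g"))
    diffs = (merged["ratio_c"] - merged["ratio_g"]).to_numpy(dtype=float)
    n = diffs.size
    mean_c = float(cdna["ratio"].mean())
    if n < 3:
        return test_sample(
            cdna["ratio"], baseline, sample_id, config, prefiltered=True
        )
    _, diff, half, p = _one_sample_test(diffs, 0.0, config.alpha)
    lower, upper = ci_bounds(diff, half)
    return SampleSummary(
        sample_id=sample_id,
        N=n,
        n=n,
        mean_cdna_ratio=mean_c,
        diff_of_means=diff,
        ci_half_width=half,
        ci_lower=lower,
        ci_upper=upper,
        p_value=p,
        overexpressed_allele=_allele_call(diff, p, config.alpha, config),
        fold_change=fold_change(mean_c, baseline.mean_ratio),
        testable=True,
    )


def summarize_cohort(
    ratios: pd.DataFrame,
    samples: list[SampleSummary],
    baseline: BaselineEstimate,
    config: AllelotypeConfig | None = None,
) -> list[CohortSummary]:
    """Stratified tests: population, male, female, each also in an ``edited``
    version restricted to samples whose cDNA had zero excluded replicates.

    Stratum tests pool the included cDNA replicate ratios of member samples
    and run the same one-sample test against the baseline (``sample_means``
    mode uses per-sample mean ratios as the observations instead).  N counts
    replicates before exclusion, n after.  Strata with fewer than 2 member
    samples are omitted with a warning.
    """
    config = config or AllelotypeConfig()
    by_sample = {s.sample_id: s for s in samples}
    cdna = ratios[ratios["template"] == CDNA]
    sex_of = cdna.groupby("sample_id")["sex"].first().to_dict()
    out: list[CohortSummary] = []
    for stratum in STRATA:
        base = stratum.removesuffix("_edited")
        edited = stratum.endswith("_edited")
        member_ids = [
            sid
            for sid in by_sample
            if (base == "population" or sex_of.get(sid) == base)
            and (not edited or by_sample[sid].n == by_sample[sid].N)
        ]
        if len(member_ids) < 2:
            warnings.warn(
                f"stratum {stratum!r} has fewer than 2 samples; omitted", stacklevel=2
            )
            continue
        sub = cdna[cdna["sample_id"].isin(member_ids)]
        if config.pooling_mode == "replicates":
            values = sub.loc[sub["included"], "ratio"].to_numpy(dtype=float)
        else:
            values = np.array([by_sample[sid].mean_cdna_ratio for sid in member_ids])
        extra_var = 0.0
        if config.include_baseline_error and math.isfinite(baseline.sd):
            extra_var = baseline.sem**2
        mean, diff, half, p = _one_sample_test(
            values, baseline.mean_ratio, config.alpha, extra_var
        )
        lower, upper = ci_bounds(diff, half)
        out.append(
            CohortSummary(
                stratum=stratum,
                N=int(sum(by_sample[sid].N for sid in member_ids)),
                n=int(sum(by_sample[sid].n for sid in member_ids)),
                n_samples=len(member_ids),
                mean_cdna_ratio=mean,
                diff_of_means=diff,
                ci_half_width=half,
                ci_lower=lower,
                ci_upper=upper,
                p_value=p,
                overexpressed_allele=_allele_call(diff, p, config.alpha, config),
                fold_change=fold_change(mean, baseline.mean_ratio),
            )
        )
    return out


def run_allelotype(
    peaks: pd.DataFrame, config: AllelotypeConfig | None = None
) -> AllelotypeResult:
    """Run the full pipeline on a replicate peak-area table."""
    config = config or AllelotypeConfig()
    config.validate()
    ratios = compute_ratios(peaks, numerator=config.numerator_allele)

    gdna_mask = ratios["template"] == GDNA
    baseline = estimate_baseline(
        ratios.loc[gdna_mask, "ratio"], k=config.iqr_k, method=config.quartile_method
    )
    # Mark pooled-gDNA exclusions on the ratio table for bookkeeping.
    g_vals = ratios.loc[gdna_mask, "ratio"].to_numpy(dtype=float)
    q1, q3 = np.percentile(g_vals, [25, 75], method=config.quartile_method)
    lo, hi = q1 - config.iqr_k * (q3 - q1), q3 + config.iqr_k * (q3 - q1)
    ratios.loc[gdna_mask, "included"] = (g_vals >= lo) & (g_vals <= hi)

    samples: list[SampleSummary] = []
    n_samples = ratios.loc[ratios["template"] == CDNA, "sample_id"].nunique()
    alpha = config.alpha / n_samples if config.bonferroni else config.alpha
    for sample_id, group in ratios[ratios["template"] == CDNA].groupby(
        "sample_id", sort=True
    ):
        values = group["ratio"].to_numpy(dtype=float)
        if values.size >= 4:
            q1, q3 = np.percentile(values, [25, 75], method=config.quartile_method)
            lo, hi = q1 - config.iqr_k * (q3 - q1), q3 + config.iqr_k * (q3 - q1)
            keep = (values >= lo) & (values <= hi)
            ratios.loc[group.index, "included"] = keep
        else:
            keep = np.ones(values.size, dtype=bool)
        if config.pairing_mode == "replicate_paired":
            summary = _paired_sample(
                group.loc[group.index[keep]],
                ratios.loc[gdna_mask & (ratios["sample_id"] == sample_id)
                           & ratios["included"]],
                baseline,
                config,
                sample_id,
            )
            summary.N = int(values.size)
        else:
            summary = test_sample(
                values[keep], baseline, sample_id, config, prefiltered=True, alpha=alpha
            )
            summary.N = int(values.size)
        summary.sex = str(group["sex"].iloc[0])
        samples.append(summary)

    strata = summarize_cohort(ratios, samples, baseline, config)
    return AllelotypeResult(baseline=baseline, samples=samples, strata=strata, ratios=ratios)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _report_rows(samples: list[SampleSummary], strata: list[CohortSummary]):
    for s in samples:
        yield (s.sample_id, s.N, s.n, s.mean_cdna_ratio, s.diff_of_means,
               s.ci_half_width, s.ci_lower, s.ci_upper, s.p_value,
               s.overexpressed_allele, s.fold_change)
    for c in strata:
        yield (c.stratum, c.N, c.n, c.mean_cdna_ratio, c.diff_of_means,
               c.ci_half_width, c.ci_lower, c.ci_upper, c.p_value,
               c.overexpressed_allele, c.fold_change)


def render_allelotype_report(
    samples: list[SampleSummary],
    strata: list[CohortSummary] = (),
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Build (and optionally write as TSV) the summary report table.

    Numeric columns are rounded to 4 decimal places; the significance column
    keeps 4 significant digits (p-values span many orders of magnitude).
    An empty input yields a header-only table/file.
    """
    rows = []
    for (sid, N, n, mean, diff, half, lower, upper, p, allele, fold) in _report_rows(
        list(samples), list(strata)
    ):
        rows.append(
            {
                "Sample": sid,
                "N": N,
                "n": n,
                "MeanCDNA": round(mean, 4),
                "DiffOfMeans": round(diff, 4),
                "CIHalfWidth": round(half, 4),
                "Lower": round(lower, 4),
                "Upper": round(upper, 4),
                "Sig": float(f"{p:.4g}") if np.isfinite(p) else math.nan,
                "OverexpressedAllele": allele if allele != "none" else "N/A",
                "FoldChange": round(fold, 4),
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if path is not None:
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return report


def baseline_sidecar(result: AllelotypeResult) -> dict:
    """JSON-serializable sidecar with the baseline and stratum membership."""
    return {
        "baseline": {
            "mean_ratio": result.baseline.mean_ratio,
            "n_used": result.baseline.n_used,
            "n_excluded": result.baseline.n_excluded,
        },
        "strata": {
            c.stratum: {"n_samples": c.n_samples, "N": c.N, "n": c.n}
            for c in result.strata
        },
    }
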