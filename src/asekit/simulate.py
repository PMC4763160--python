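"""Synthetic allelotyping cohorts and allele-specific reference sequences.

The generator emulates the replicate structure of a MassARRAY/hME
allelotyping experiment: for each heterozygous individual, eight replicate
genotyping reactions on genomic DNA and eight on cDNA, each yielding a pair
of allele peak areas.  Genomic DNA carries the two alleles 1:1, yet the
observed AT:G peak-area ratio is not 1 — the assay detects the two extension
products with different efficiency.  That multiplicative detection bias *b*
(default 1.78) multiplies every ratio; cDNA ratios are additionally
multiplied by the individual's true allelic-expression effect e_i, so the
gDNA pool calibrates the bias away downstream.

Noise is multiplicative and lognormal (intensity ratios are positive and
scale-free), and sporadic outliers are one-sided multiplicative shocks so
that interquartile-range filtering has realistic work to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequences import (
    ALLELE_AT,
    ALLELE_G,
    FORWARD_PRIMER,
    REVERSE_PRIMER_SITE_NATIVE,
    VARIANT_FLANK5,
)

PEAK_COLUMNS = ["sample_id", "template", "replicate", "area_AT", "area_G", "sex"]

#: Arbitrary nominal intensity of the allele-2 (G) peak; absolute scale is
#: irrelevant downstream (every statistic is a ratio of areas).
_NOMINAL_AREA = 10_000.0
_AREA_SIGMA = 0.25


class ConfigError(ValueError):
    """A simulation configuration field is out of range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic allelotyping cohort.

    Defaults reproduce the design of the rs386770867 study: 35 heterozygotes,
    8 replicate reactions per template, gDNA AT:G detection bias 1.78, a
    population allelic-expression fold of 1.16 with modest between-individual
    spread, 8% replicate-level coefficient of variation, ~3% outlying
    replicates, and a 19:16 male:female split.
    """

    n_samples: int = 35
    replicates_per_template: int = 8
    bias_b: float = 1.78
    ase_effect_median: float = 1.16
    ase_effect_sd_log: float = 0.15
    replicate_cv: float = 0.08
    outlier_prob: float = 0.03
    outlier_factor: float = 2.5
    male_fraction: float = 19 / 35
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.replicates_per_template < 2:
            raise ConfigError("replicates_per_template must be >= 2")
        if not self.bias_b > 0:
            raise ConfigError("bias_b must be > 0")
        if not self.ase_effect_median > 0:
            raise ConfigError("ase_effect_median must be > 0")
        if self.ase_effect_sd_log < 0:
            raise ConfigError("ase_effect_sd_log must be >= 0")
        if self.replicate_cv < 0:
            raise ConfigError("replicate_cv must be >= 0")
        if not 0 <= self.outlier_prob < 0.5:
            raise ConfigError("outlier_prob must lie in [0, 0.5)")
        if not self.outlier_factor > 0 or self.outlier_factor == 1:
            raise ConfigError("outlier_factor must be positive and != 1")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigError("male_fraction must lie in [0, 1]")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate peak areas for a cohort of heterozygotes.

    Returns ``(peaks, truth)``: *peaks* has one row per replicate reaction
    with columns ``sample_id template replicate area_AT area_G sex``; *truth*
    records each individual's generating allelic-expression effect e_i.
    Per-replicate expected AT:G ratios are ``bias_b`` for gDNA and
    ``bias_b * e_i`` for cDNA, with e_i ~ LogNormal(ln median, sd_log²);
    every ratio is multiplied by LogNormal(0, cv²) noise and, with
    probability ``outlier_prob``, by ``outlier_factor`` or its inverse.
    Byte-identical output for identical config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_rows = []
    for i in range(config.n_samples):
        sample_id = f"S{i + 1:03d}"
        effect = float(
            rng.lognormal(np.log(config.ase_effect_median), config.ase_effect_sd_log)
        )
        sex = "male" if rng.random() < config.male_fraction else "female"
        truth_rows.append({"sample_id": sample_id, "true_ase_effect": effect, "sex": sex})
        for template, template_effect in (("gDNA", 1.0), ("cDNA", effect)):
            for rep in range(1, config.replicates_per_template + 1):
                ratio = config.bias_b * template_effect
                ratio *= float(np.exp(rng.normal(0.0, config.replicate_cv)))
                if rng.random() < config.outlier_prob:
                    shock = config.outlier_factor
                    if rng.random() < 0.5:
                        shock = 1.0 / shock
                    ratio *= shock
                area_g = _NOMINAL_AREA * float(np.exp(rng.normal(0.0, _AREA_SIGMA)))
                rows.append(
                    {
                        "sample_id": sample_id,
                        "template": template,
                        "replicate": rep,
                        "area_AT": area_g * ratio,
                        "area_G": area_g,
                        "sex": sex,
                    }
                )
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "true_ase_effect", "sex"])
    return peaks, truth


# ---------------------------------------------------------------------------
# Allele-specific reference sequences
# ---------------------------------------------------------------------------

_MIN_FLANK = 40
_PAD5 = 5  # random bases upstream of the forward primer


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n else ""


def simulate_reference(
    flank5_len: int = 60, flank3_len: int = 60, seed: int = 0
) -> dict[str, str]:
    """Build plus-strand reference sequences for both alleles of rs386770867.

    Each sequence is ``flank5`` + allele + ``flank3`` where the flanks embed,
    in order, the forward genotyping primer, random spacer, the published
    15-nt variant flanks, and the native annealing site of the mismatch
    reverse primer.  The two sequences are identical except at the variant
    (AT vs G), so the AT reference is exactly one base longer.  Random
    filler is rejection-sampled so neither template contains a GTAC site and
    each primer anneals at a single position.  Deterministic given seed.
    """
    if flank5_len < _MIN_FLANK or flank3_len < _MIN_FLANK:
        raise ValueError(
            f"flank lengths must be >= {_MIN_FLANK} to place both primers "
            f"(got {flank5_len}, {flank3_len})"
        )
    spacer_len = flank5_len - _PAD5 - len(FORWARD_PRIMER) - len(VARIANT_FLANK5)
    pad3_len = flank3_len - len(REVERSE_PRIMER_SITE_NATIVE)
    if spacer_len < 0 or pad3_len < 0:
        raise ValueError("flank too short to place primers")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        pad5 = _random_dna(rng, _PAD5)
        spacer = _random_dna(rng, spacer_len)
        pad3 = _random_dna(rng, pad3_len)
        flank5 = pad5 + FORWARD_PRIMER + spacer + VARIANT_FLANK5
        flank3 = REVERSE_PRIMER_SITE_NATIVE + pad3
        refs = {allele: flank5 + allele + flank3 for allele in (ALLELE_AT, ALLELE_G)}
        if all("GTAC" not in seq for seq in refs.values()) and all(
            seq.count(FORWARD_PRIMER) == 1 for seq in refs.values()
        ):
            return refs
    raise RuntimeError("could not sample GTAC-free filler sequence")  # pragma: no cover


def write_reference_fasta(refs: dict[str, str], path: str | Path) -> None:
    """Write the two allele references as a FASTA file."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=f"rs386770867_{allele}", description="")
        for allele, seq in refs.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_reference_fasta(path: str | Path) -> dict[str, str]:
    """Read allele references written by :func:`write_reference_fasta`."""
    from Bio.SeqIO import parse as seqio_parse

    refs = {}
    for record in seqio_parse(str(path), "fasta"):
        allele = record.id.rsplit("_", 1)[-1]
        refs[allele] = str(record.seq).upper()
    return refs


def write_peak_table(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a replicate peak-area table as TSV."""
    peaks.to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a replicate peak-area TSV (columns ``sample_id template replicate
    area_AT area_G sex``)."""
    peaks = pd.read_csv(path, sep="\t")
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return peaks


def simulate_reporter_wells(
    effects: dict[str, float],
    control: str = "pGL3",
    n_experiments: int = 3,
    wells_per_construct: int = 3,
    cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate dual-luciferase well measurements.

    ``effects`` maps construct name to its true activity relative to the
    control (the control itself is implicitly 1).  Each experiment draws its
    own transfection efficiency per well (Renilla channel); firefly = renilla
    x construct effect x lognormal(0, cv²) noise.
    """
    rng = np.random.default_rng(seed)
    all_effects = {control: 1.0, **effects}
    rows = []
    for exp in range(1, n_experiments + 1):
        for construct, effect in all_effects.items():
            for _ in range(wells_per_construct):
                renilla = 1000.0 * float(np.exp(rng.normal(0.0, 0.3)))
                firefly = renilla * effect * float(np.exp(rng.normal(0.0, cv)))
                rows.append(
                    {
                        "construct": construct,
                        "experiment": f"exp{exp}",
                        "firefly": firefly,
                        "renilla": renilla,
                    }
                )
    return pd.DataFrame(rows)
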