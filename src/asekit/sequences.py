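"""Reference sequences and motif definitions for the rs386770867 AT/G variant.

rs386770867 is a combined insertion/substitution (AT vs G) in the 5'-UTR of
*SETDB2*, ~492 bp upstream of the start codon.  The constants here are the
published assay sequences around the variant: the 15-nt flanks used to build
double-stranded EMSA probes, the PCR-RFLP primer pair whose reverse primer
carries a deliberate A->T change that engineers an RsaI site (GT^AC) onto the
G allele only, and the consensus transcription-factor motifs predicted to
bind one or both alleles.
"""

from __future__ import annotations

import re

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

ALLELE_AT = "AT"
ALLELE_G = "G"
ALLELES = (ALLELE_AT, ALLELE_G)

#: 15-nt flanks immediately 5' and 3' of the variant on the plus strand.
VARIANT_FLANK5 = "GAGTTTCCAACCTCC"
VARIANT_FLANK3 = "TTCAGCCTGTCTGTC"

#: 4-nt tag prepended to the EMSA oligonucleotides to aid radiolabelling.
PROBE_TAG = "GACT"

#: Full sense-strand EMSA probe per allele (tag + 15-nt flank + allele + 15-nt flank).
EMSA_PROBES = {
    allele: PROBE_TAG + VARIANT_FLANK5 + allele + VARIANT_FLANK3 for allele in ALLELES
}

#: PCR-RFLP genotyping primers. The reverse primer's penultimate base is a
#: deliberate mismatch (A->T relative to the genomic sequence) so that the
#: amplicon of the G allele, and only the G allele, acquires a GTAC RsaI site.
FORWARD_PRIMER = "CGACAGTTCCTCTAGCCG"
REVERSE_PRIMER = "CTGAGACAGACAGGCTGTA"

#: Plus-strand genomic sequence covered by the reverse primer (the native
#: template the mismatch primer anneals to): the 3' flank plus four further
#: downstream bases implied by the primer itself.
REVERSE_PRIMER_SITE_NATIVE = VARIANT_FLANK3 + "TCAG"

RSAI_RECOGNITION = "GTAC"
RSAI_CUT_OFFSET = 2  # RsaI cuts GT^AC

#: Consensus motifs predicted around the variant, as (name, IUPAC pattern).
#: YY1's pentamer requires the AT allele; the v-Myb site reads on the minus
#: strand of the G allele; the remaining three sit in shared sequence.
CONSENSUS_MOTIFS = (
    ("SRY", "TGAGTTT"),
    ("HS$IL_06", "TTCC"),
    ("HS$GMCSF_04_YY1", "CATTT"),
    ("HS$GG_12", "CTGTC"),
    ("v-Myb", "CTGAACGGAGG"),
)

_DNA_RE = re.compile(r"^[ACGT]+$")


def is_dna(seq: str) -> bool:
    """True if ``seq`` is a nonempty uppercase unambiguous DNA string."""
    return bool(_DNA_RE.match(seq))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return str(Seq(seq).reverse_complement())


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC consensus into a regular expression.

    Each ambiguity code expands to a character class, e.g. ``W`` -> ``[AT]``.
    """
    parts = []
    for base in pattern.upper():
        # standard IUPAC nucleotide codes only (no 'X' extension)
        if base not in "ACGTMRWSYKVHDBN":
            raise ValueError(f"not an IUPAC DNA code: {base!r}")
        values = ambiguous_dna_values[base]
        parts.append(values if len(values) == 1 else f"[{values}]")
    return re.compile("".join(parts))
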