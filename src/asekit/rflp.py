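"""In-silico PCR-RFLP genotyping.

Models the engineered-mismatch genotyping assay for rs386770867: a reverse
primer carrying a deliberate A->T change anneals across the variant so that
the PCR product of the G allele — and only the G allele — contains an RsaI
recognition site (GT^AC).  Digesting the amplicons therefore cuts the G
product into two fragments while the AT product (one base longer, because
the variant is AT vs G) stays intact, and genotypes are read off the
fragment-length pattern.

Primer annealing follows the polymerase-extension rule: the primer's
3'-terminal base must match the template exactly; internal substitutions up
to ``max_mismatch`` (default 1, the engineered change) are tolerated.
Amplicons carry primer-derived bases at mismatch positions — that is what
writes the restriction site into the product.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .sequences import (
    FORWARD_PRIMER,
    REVERSE_PRIMER,
    RSAI_CUT_OFFSET,
    RSAI_RECOGNITION,
    is_dna,
    revcomp,
)


class AmplificationError(ValueError):
    """A primer failed to locate uniquely, or the primer pair is misordered."""


@dataclass(frozen=True)
class PrimerPair:
    """A genotyping primer pair with a substitution tolerance."""

    forward: str = FORWARD_PRIMER
    reverse: str = REVERSE_PRIMER
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < 15:
                raise ValueError(f"{name} primer shorter than 15 nt")
            if not is_dna(primer):
                raise ValueError(f"{name} primer must be uppercase ACGT")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class PrimerMatch:
    """One acceptable annealing position (0-based, plus-strand, half-open)."""

    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """An in-silico PCR product for one allele."""

    allele: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DigestResult:
    """Fragments of a restriction digest; concatenation restores the input."""

    enzyme: str
    recognition: str
    cut_offset: int
    fragments: tuple[str, ...]

    @property
    def fragment_lengths(self) -> tuple[int, ...]:
        return tuple(len(f) for f in self.fragments)


@dataclass(frozen=True)
class GenotypeCall:
    """A genotype read from a fragment-length pattern."""

    sample_id: str
    call: str  # e.g. "AT/AT", "AT/G", "G/G", "no-call"


def locate_primer(
    template: str,
    primer: str,
    orientation: str = "forward",
    max_mismatch: int = 1,
) -> list[PrimerMatch]:
    """All positions where a primer can anneal and extend.

    A forward primer is compared directly with the plus strand; a reverse
    primer is compared via its reverse complement.  At most ``max_mismatch``
    substitutions are tolerated, and the primer's 3'-terminal base (the last
    base for forward orientation, the first base of the reverse complement
    for reverse orientation) must match exactly — polymerases do not extend
    a mispaired 3' end.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    if len(template) < len(primer):
        raise ValueError("template shorter than primer")
    probe = primer if orientation == "forward" else revcomp(primer)
    three_prime_index = len(probe) - 1 if orientation == "forward" else 0
    matches = []
    for start in range(len(template) - len(probe) + 1):
        window = template[start : start + len(probe)]
        if window[three_prime_index] != probe[three_prime_index]:
            continue
        mm = sum(a != b for a, b in zip(window, probe))
        if mm <= max_mismatch:
            matches.append(PrimerMatch(start, start + len(probe), mm))
    return matches


def _unique_match(template, primer, orientation, max_mismatch) -> PrimerMatch:
    matches = locate_primer(template, primer, orientation, max_mismatch)
    if len(matches) != 1:
        where = [m.start for m in matches]
        raise AmplificationError(
            f"{orientation} primer must anneal at exactly one site; "
            f"found {len(matches)} (starts {where})"
        )
    return matches[0]


def amplify(template: str, primers: PrimerPair, allele: str = "") -> Amplicon:
    """Amplify the span between the primer pair's outer ends.

    The product runs from the forward primer's 5' end to the reverse
    primer's 5' end (on the plus strand), with primer-derived bases
    substituted over the template at any mismatch position — reproducing how
    a mismatch primer writes its engineered base into every product copy.
    """
    fwd = _unique_match(template, primers.forward, "forward", primers.max_mismatch)
    rev = _unique_match(template, primers.reverse, "reverse", primers.max_mismatch)
    if not fwd.end <= rev.start:
        raise AmplificationError(
            "primer sites overlap or are misordered "
            f"(forward {fwd.start}-{fwd.end}, reverse {rev.start}-{rev.end})"
        )
    product = (
        primers.forward
        + template[fwd.end : rev.start]
        + revcomp(primers.reverse)
    )
    return Amplicon(allele=allele, sequence=product)


def digest(
    sequence: str,
    recognition: str = RSAI_RECOGNITION,
    cut_offset: int = RSAI_CUT_OFFSET,
    enzyme: str = "RsaI",
) -> DigestResult:
    """Cut a sequence at every non-overlapping recognition site.

    Sites are scanned left to right; each match is cut ``cut_offset`` bases
    into the site (RsaI: GT^AC).  A sequence without sites yields itself as
    a single fragment.
    """
    if not 0 <= cut_offset <= len(recognition):
        raise ValueError("cut_offset must lie within the recognition site")
    cuts = []
    pos = sequence.find(recognition)
    while pos != -1:
        cuts.append(pos + cut_offset)
        pos = sequence.find(recognition, pos + len(recognition))
    fragments = []
    prev = 0
    for cut in cuts:
        fragments.append(sequence[prev:cut])
        prev = cut
    fragments.append(sequence[prev:])
    return DigestResult(
        enzyme=enzyme,
        recognition=recognition,
        cut_offset=cut_offset,
        fragments=tuple(f for f in fragments if f),
    )


def expected_patterns(
    references: dict[str, str], primers: PrimerPair | None = None, **digest_kwargs
) -> dict[str, tuple[int, ...]]:
    """Per-allele expected fragment-length patterns from reference sequences."""
    primers = primers or PrimerPair()
    return {
        allele: digest(amplify(ref, primers, allele).sequence, **digest_kwargs
                       ).fragment_lengths
        for allele, ref in references.items()
    }


def call_genotype(
    fragment_lengths,
    expected: dict[str, tuple[int, ...]],
    sample_id: str = "",
    tolerance: int = 0,
) -> GenotypeCall:
    """Call a genotype from an observed fragment-length pattern.

    Homozygote when the observed lengths match one allele's pattern, ordered
    heterozygote when they match the union of both patterns; anything else
    is a no-call.  ``tolerance`` (bp) mimics gel resolution: two lengths are
    indistinguishable when they differ by at most ``tolerance``, and
    patterns are compared as sets of distinguishable lengths (a gel band
    does not reveal copy number).
    """
    alleles = sorted(expected)
    if len(alleles) != 2:
        raise ValueError("expected patterns for exactly 2 alleles")
    if len(set(map(tuple, map(sorted, expected.values())))) != len(alleles):
        raise ValueError("expected patterns must be distinct")

    def matches(observed, pattern) -> bool:
        observed, pattern = set(observed), set(pattern)
        return all(
            any(abs(o - p) <= tolerance for p in pattern) for o in observed
        ) and all(any(abs(o - p) <= tolerance for o in observed) for p in pattern)

    observed = sorted(Counter(int(x) for x in fragment_lengths))
    a1, a2 = alleles
    if matches(observed, expected[a1]):
        call = f"{a1}/{a1}"
    elif matches(observed, expected[a2]):
        call = f"{a2}/{a2}"
    elif matches(observed, set(expected[a1]) | set(expected[a2])):
        call = f"{a1}/{a2}"
    else:
        call = "no-call"
    return GenotypeCall(sample_id=sample_id, call=call)
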