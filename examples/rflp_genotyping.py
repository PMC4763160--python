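"""In-silico PCR-RFLP genotyping of the AT/G variant.

Builds synthetic reference sequences for both alleles, amplifies each with
the engineered-mismatch primer pair, digests the products with RsaI
(GT^AC), and calls genotypes from the fragment patterns — including a
simulated heterozygote lane pooling both alleles' fragments.
"""

from asekit import (
    PrimerPair,
    amplify,
    call_genotype,
    digest,
    expected_patterns,
    simulate_reference,
)

refs = simulate_reference(seed=7)
primers = PrimerPair()

for allele, template in refs.items():
    amplicon = amplify(template, primers, allele)
    frags = digest(amplicon.sequence)
    print(f"{allele:>2} allele: amplicon {amplicon.length} bp -> "
          f"fragments {frags.fragment_lengths}")
# The reverse primer's deliberate A->T change writes a GTAC site into the G
# product only, so the G amplicon cuts into two fragments while the AT
# amplicon (1 bp longer, AT vs G at the variant) stays intact.

patterns = expected_patterns(refs, primers)
for observed, label in [
    (patterns["AT"], "AT homozygote lane"),
    (patterns["G"], "G homozygote lane"),
    (tuple(patterns["AT"]) + tuple(patterns["G"]), "heterozygote lane"),
]:
    call = call_genotype(observed, patterns)
    print(f"{label:>22}: fragments {sorted(observed)} -> {call.call}")
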