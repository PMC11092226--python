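"""Build a pseudo-genome: filter variants, substitute SNP alleles.

Substituting the alternate parent's SNP alleles into the reference gives
hybrid reads from either allele an equal-identity mapping target,
removing reference bias from allele counting.  Only confident variants
(allele frequency >= 0.9, depth >= 20) are used, and only SNPs (indels
would shift coordinates).
"""

from asel.pseudogenome import FilterThresholds, build_pseudogenome, filter_variants, snps_only
from asel.types import VariantRecord

reference = {"chr1": "ACGTACGTACGTACGT"}
variants = [
    VariantRecord("chr1", 3, "G", "T", allele_frequency=0.98, depth=45),   # kept
    VariantRecord("chr1", 6, "C", "A", allele_frequency=0.80, depth=100),  # AF too low
    VariantRecord("chr1", 9, "A", "G", allele_frequency=1.00, depth=12),   # too shallow
    VariantRecord("chr1", 12, "TA", "T", allele_frequency=1.0, depth=60),  # indel, excluded
]

kept = filter_variants(variants, FilterThresholds())
substitutable = snps_only(kept)
pseudo = build_pseudogenome(reference, substitutable)

print(f"variants in: {len(variants)};  after AF/depth filter: {len(kept)};  "
      f"SNPs substituted: {len(substitutable)}")
print(f"reference: {reference['chr1']}")
print(f"pseudo:    {pseudo['chr1']}")
# only position 3 (G->T) changes; lengths are identical by construction.
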