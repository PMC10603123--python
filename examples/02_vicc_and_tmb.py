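"""VICC oncogenicity scoring and tumor mutational burden.

Scores an uncurated oncogene indel the way a curator would assert it:
two moderate criteria (domain location, in-frame length change in a known
oncogene) and three supporting ones (single-etiology malignancy, absence
from population databases, hotspot listing). Then computes TMB for a
"silent" fusion-driven genome.
"""

from mtb_interpret import CriterionEvidence, tmb, vicc_score
from mtb_interpret.core_io import GenomicInterval
from mtb_interpret.small_variants import SmallVariant, VariantType

criteria = [
    CriterionEvidence("OM1", note="critical region of a functional domain"),
    CriterionEvidence("OM2", note="in-frame indel in a known oncogene"),
    CriterionEvidence("OP2", note="gene drives a single-etiology malignancy"),
    CriterionEvidence("OP3", note="absent from gnomAD"),
    CriterionEvidence("OP4", note="hotspot with low amino-acid change count"),
]
result = vicc_score(criteria)
print(f"VICC score:     {result.score} points -> {result.classification.value}")

variants = [
    SmallVariant(
        gene="G", hgvs_p="", interval=GenomicInterval("1", 1000 + i, 1000 + i),
        ref="A", alt="T", variant_type=VariantType.SNV,
        consequence="missense", dna_af=0.4,
    )
    for i in range(23)
]
burden = tmb(variants)
print(f"TMB:            {burden.per_mbp:.1f} non-synonymous mutations per coding Mbp "
      f"({burden.qualifying} variants / {burden.footprint_mbp} Mbp)")
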