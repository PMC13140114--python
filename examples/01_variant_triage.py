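"""Evidence-tiered variant triage and NRF2 activation calling.

Builds a handful of annotated ctDNA variant calls for one case, runs the
filter cascade (panel of normals, support/VAF hard filters, population-
frequency pruning) and classifies the survivors' relation to NRF2 activity.
"""

from ctdna_nrf2 import CodonScoreTable, VariantRecord, triage_variants
from ctdna_nrf2.records import ClinvarClass, Consequence

variants = [
    # KEAP1 nonsense with oncogenic evidence: kept at only 2 unique reads
    VariantRecord(case_id="P1", gene="KEAP1", chrom="chr19", pos=10_600_000,
                  ref="A", alt="T", vaf=0.021, alt_reads=2,
                  protein_change="p.K216*", codon=216,
                  consequence=Consequence.NONSENSE, fathmm=0.998),
    # NFE2L2 hotspot missense, codon scored hyperactive
    VariantRecord(case_id="P1", gene="NFE2L2", chrom="chr2", pos=178_098_800,
                  ref="G", alt="C", vaf=0.121, alt_reads=55,
                  protein_change="p.D77H", codon=77,
                  consequence=Consequence.MISSENSE,
                  clinvar_class=ClinvarClass.LIKELY_ONCOGENIC),
    # VUS with 4 supporting reads: fails the >= 5-read hard filter
    VariantRecord(case_id="P1", gene="LRP1B", chrom="chr2", pos=140_000_000,
                  ref="C", alt="T", vaf=0.004, alt_reads=4,
                  consequence=Consequence.MISSENSE, fathmm=0.42),
    # germline leak: ~0.5 VAF and common in population databases
    VariantRecord(case_id="P1", gene="TP53", chrom="chr17", pos=7_675_000,
                  ref="G", alt="A", vaf=0.49, alt_reads=480,
                  consequence=Consequence.MISSENSE, pop_freq=3e-4),
    # PCR artifact already present in the panel of normals
    VariantRecord(case_id="P1", gene="NF1", chrom="chr17", pos=31_200_000,
                  ref="T", alt="G", vaf=0.002, alt_reads=2,
                  consequence=Consequence.MISSENSE, in_pon=True),
]

# codon-level NRF2 activity scores (arbitrary scale, threshold 1.0)
scores = CodonScoreTable(entries={("NFE2L2", 77): [1.5, 2.0]}, threshold=1.0)

result = triage_variants(variants, scores)

print(f"{len(variants)} input variants -> {len(result.filtered)} retained")
for v, call in result.calls:
    print(f"  {v.gene} {v.protein_change:10s} VAF {v.vaf:5.1%}  ->  "
          f"{call.call}  ({call.rationale})")
print("case NRF2 status:", result.case_status)
# The two pathway variants survive (relaxed oncogenic-evidence filter) and
# mark the case NRF2-positive; the weakly supported VUS, the ~50% VAF
# population variant and the panel-of-normals artifact are removed.
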