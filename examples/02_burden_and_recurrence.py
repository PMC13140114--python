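"""Blood-based tumor mutational burden, ctDNA concentration, recurrence.

bTMB counts all detected mutations over the panel territory; ctDNA
concentration is plasma cfDNA times the mean VAF of the case's pathogenic
variants; recurrence matches oncogenic variants across timepoints by
protein change.
"""

from ctdna_nrf2 import (
    CaseRecord,
    VariantRecord,
    compute_btmb,
    ctdna_concentration,
    detect_recurrent,
)
from ctdna_nrf2.records import Consequence, Timepoint


def v(pchg, vaf, tp=Timepoint.DIAGNOSIS, pos=1000):
    return VariantRecord(case_id="P1", gene="KEAP1", chrom="chr19", pos=pos,
                         ref="A", alt="T", vaf=vaf, alt_reads=20,
                         protein_change=pchg, timepoint=tp,
                         consequence=Consequence.MISSENSE, fathmm=0.995)


case = CaseRecord(case_id="P1", panel_size_mb=0.3,
                  cfdna_ng_ml={Timepoint.DIAGNOSIS: 27.6})

diagnosis = [v("p.T609K", 0.105), v("p.G480W", 0.076, pos=2000)]
followup = [v("p.T609K", 0.031, tp=Timepoint.FOLLOWUP)]

burden = compute_btmb(diagnosis, case.panel_size_mb)
print(f"bTMB: {burden.raw_count} mutations = {burden.per_mb:.1f}/Mb "
      f"over a {case.panel_size_mb} Mb panel")

conc = ctdna_concentration(case, Timepoint.DIAGNOSIS, diagnosis)
print(f"ctDNA concentration: 27.6 ng/ml x mean VAF "
      f"{(0.105 + 0.076) / 2:.3f} = {conc:.3f} ng/ml")

recurrent = detect_recurrent(diagnosis, followup)
print(f"recurrent at follow-up: {[r.protein_change for r in recurrent]}")
# p.T609K persists into the follow-up sample (a treatment-resistant clone
# signature); p.G480W is no longer detected.
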