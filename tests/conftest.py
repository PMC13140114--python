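"""Shared fixtures: the published-cohort variant table encoded as records,
its codon activity-score table, and a 73-case clinical frame."""

from __future__ import annotations

import pytest

from ctdna_nrf2.records import CaseRecord, ClinvarClass, Consequence, VariantRecord
from ctdna_nrf2.triage import CodonScoreTable


def _v(case, gene, pchg, csq, vaf_pct, codon=None, **kw):
    defaults = dict(
        chrom="chr19" if gene == "KEAP1" else "chr2",
        pos=10_000_000 + (codon or 1) * 3,
        ref="A",
        alt="T",
        alt_reads=max(2, int(round(vaf_pct * 10))),
        fathmm=0.995,
        clinvar_class=ClinvarClass.ABSENT,
    )
    defaults.update(kw)
    return VariantRecord(
        case_id=case, gene=gene, protein_change=pchg, codon=codon,
        consequence=csq, vaf=vaf_pct / 100.0, **defaults,
    )


@pytest.fixture(scope="session")
def cohort_table_variants() -> list[VariantRecord]:
    """The cohort's 14 pathway-mutated cases, one row set per case.

    Thirteen cases carry activating / likely-activating / unscored putative
    variants; one case carries only Neh2-domain NFE2L2 frameshifts (likely
    loss of function). VAFs are the published percentages.
    """
    M, N, F, I = (Consequence.MISSENSE, Consequence.NONSENSE,
                  Consequence.FRAMESHIFT, Consequence.INFRAME_INS)
    rows = [
        _v("C01", "NFE2L2", "p.D77H", M, 12.1, codon=77),
        _v("C02", "NFE2L2", "p.E34ins", I, 2.1, codon=34),
        # one case carrying both a scored and an unscored KEAP1 missense
        _v("C03", "KEAP1", "p.P278A", M, 5.5, codon=278),
        _v("C03", "KEAP1", "p.S142F", M, 5.0, codon=142),
        _v("C04", "KEAP1", "p.T609K", M, 10.5, codon=609),
        _v("C05", "KEAP1", "p.K323A", M, 3.0, codon=323),
        _v("C06", "KEAP1", "p.F190S", M, 2.9, codon=190),
        _v("C07", "KEAP1", "p.G480W", M, 7.6, codon=480),
        _v("C08", "CUL3", "p.R751*", N, 1.9, codon=751),
        _v("C09", "NFE2L2", "p.W24R", M, 7.7, codon=24),
        _v("C10", "NFE2L2", "p.D77H", M, 5.4, codon=77),
        _v("C11", "KEAP1", "p.M147V", M, 1.2, codon=147),
        _v("C12", "KEAP1", "p.K216*", N, 2.1, codon=216),
        _v("C13", "KEAP1", "p.R413fs", F, 30.0, codon=413),
        # the single likely-LOF case: two Neh2-domain frameshifts
        _v("C14", "NFE2L2", "p.I28fs", F, 4.1, codon=28),
        _v("C14", "NFE2L2", "p.L30fs", F, 4.0, codon=30),
    ]
    return rows


@pytest.fixture(scope="session")
def cohort_codon_scores() -> CodonScoreTable:
    """Activity scores for the codons matched in the reference data.

    Synthetic stand-in on an arbitrary scale: every matched codon scores
    above the hyperactivity threshold (as observed); the novel codons 142,
    147, 190 and 609 are absent.
    """
    above = [1.4, 1.8, 2.1]
    entries = {
        ("NFE2L2", 24): above, ("NFE2L2", 34): above, ("NFE2L2", 77): above,
        ("KEAP1", 278): above, ("KEAP1", 323): above, ("KEAP1", 480): above,
    }
    return CodonScoreTable(entries=entries, threshold=1.0)


@pytest.fixture(scope="session")
def cohort_cases() -> list[CaseRecord]:
    """73 cases; C01-C14 are the pathway-mutated ones."""
    cases = [CaseRecord(case_id=f"C{i:02d}", sex="male" if i <= 53 else "female")
             for i in range(1, 74)]
    return cases
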