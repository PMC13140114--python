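"""Variant filter cascade and NRF2 activation classification."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdna_nrf2.records import ClinvarClass, Consequence, VariantRecord
from ctdna_nrf2.triage import (
    CodonScoreTable,
    FilterConfig,
    NRF2Call,
    apply_hard_filters,
    case_nrf2_status,
    classify_nrf2,
    evidence_tier,
    remove_panel_of_normals,
    triage_variants,
)


def make_variant(**kw) -> VariantRecord:
    base = dict(
        case_id="X", gene="TP53", chrom="chr17", pos=100, ref="A", alt="T",
        vaf=0.05, alt_reads=10, consequence=Consequence.MISSENSE,
    )
    base.update(kw)
    return VariantRecord(**base)


# -- panel of normals --------------------------------------------------------


def test_panel_of_normals_removal_keeps_order_and_clean_records():
    clean1 = make_variant(pos=1)
    dirty = make_variant(pos=2, in_pon=True)
    clean2 = make_variant(pos=3)
    assert remove_panel_of_normals([dirty, clean1, dirty, clean2]) == [clean1, clean2]
    assert remove_panel_of_normals([]) == []
    assert remove_panel_of_normals([dirty, dirty]) == []


# -- evidence tiering --------------------------------------------------------


@pytest.mark.parametrize(
    "fathmm, clinvar, expected",
    [
        (0.995, ClinvarClass.ABSENT, "oncogenic_evidence"),
        (0.99, ClinvarClass.ABSENT, "oncogenic_evidence"),  # threshold inclusive
        (None, ClinvarClass.LIKELY_ONCOGENIC, "oncogenic_evidence"),
        (None, ClinvarClass.DRUG_RESPONSE, "oncogenic_evidence"),
        (0.5, ClinvarClass.OTHER, "vus"),
        (None, ClinvarClass.ABSENT, "vus"),
        (0.98, ClinvarClass.OTHER, "vus"),
    ],
)
def test_evidence_tier(fathmm, clinvar, expected):
    v = make_variant(fathmm=fathmm, clinvar_class=clinvar)
    assert evidence_tier(v, FilterConfig()) == expected


# -- hard filters ------------------------------------------------------------


@pytest.mark.parametrize(
    "kw, retained",
    [
        (dict(alt_reads=4, fathmm=None), False),  # VUS below read floor
        (dict(alt_reads=5, vaf=0.10, fathmm=None), True),
        (dict(alt_reads=2, vaf=0.021, fathmm=0.995), True),  # relaxed oncogenic
        (dict(alt_reads=1, vaf=0.021, fathmm=0.995), False),
        (dict(alt_reads=10, vaf=0.50, fathmm=None), False),  # VUS germline-range VAF
        (dict(alt_reads=10, vaf=0.50, fathmm=0.995), True),  # oncogenic has no VAF cap
        (dict(alt_reads=10, vaf=0.10, fathmm=0.995, pop_freq=2e-5), False),  # pop prune
        (dict(alt_reads=10, vaf=0.10, fathmm=0.995, pop_freq=5e-6), True),
    ],
)
def test_hard_filter_rules(kw, retained):
    v = make_variant(**kw)
    assert (apply_hard_filters([v]) == [v]) is retained


def test_silent_variants_survive_filters_for_burden():
    v = make_variant(consequence=Consequence.SILENT, alt_reads=12, vaf=0.1)
    assert apply_hard_filters([v]) == [v]


def _variant_strategy():
    return st.builds(
        make_variant,
        vaf=st.floats(0.0, 1.0),
        alt_reads=st.integers(0, 50),
        fathmm=st.one_of(st.none(), st.floats(0.0, 1.0)),
        clinvar_class=st.sampled_from(list(ClinvarClass)),
        pop_freq=st.one_of(st.none(), st.floats(0.0, 1e-3)),
        in_pon=st.booleans(),
    )


@settings(max_examples=100, derandomize=True)
@given(st.lists(_variant_strategy(), max_size=20))
def test_filter_idempotence_and_oracle(variants):
    """Filtering is idempotent and equals a brute-force predicate per record."""
    config = FilterConfig()
    once = apply_hard_filters(variants, config)
    assert apply_hard_filters(once, config) == once

    def keep(v):  # written-out filter predicate, independently re-evaluated
        onco = (v.fathmm is not None and v.fathmm >= 0.99) or v.clinvar_class in {
            ClinvarClass.ONCOGENIC, ClinvarClass.LIKELY_ONCOGENIC,
            ClinvarClass.DRUG_RESPONSE,
        }
        support = v.alt_reads >= 2 if onco else (v.alt_reads >= 5 and v.vaf < 0.45)
        return support and (v.pop_freq is None or v.pop_freq <= 1e-5)

    assert once == [v for v in variants if keep(v)]


@settings(max_examples=50, derandomize=True)
@given(st.lists(_variant_strategy(), max_size=20), st.integers(5, 12))
def test_raising_vus_read_floor_is_monotone(variants, stricter):
    base = set(map(id, apply_hard_filters(variants, FilterConfig(min_reads_vus=5))))
    strict = set(map(id, apply_hard_filters(
        variants, FilterConfig(min_reads_vus=stricter))))
    assert strict <= base


def test_negative_read_count_rejected():
    v = make_variant()
    object.__setattr__(v, "alt_reads", -1)  # bypass record validation
    with pytest.raises(ValueError):
        apply_hard_filters([v])


# -- NRF2 classification -----------------------------------------------------


@pytest.fixture
def scores():
    return CodonScoreTable(
        entries={("NFE2L2", 77): [1.5, 2.0], ("KEAP1", 278): [1.2],
                 ("KEAP1", 500): [0.2, 0.3]},
        threshold=1.0,
    )


@pytest.mark.parametrize(
    "kw, expected",
    [
        (dict(gene="NFE2L2", codon=77, consequence=Consequence.MISSENSE), "activating"),
        (dict(gene="KEAP1", codon=413, consequence=Consequence.FRAMESHIFT),
         "likely_activating"),
        (dict(gene="CUL3", codon=751, consequence=Consequence.NONSENSE),
         "likely_activating"),
        (dict(gene="KEAP1", codon=609, consequence=Consequence.MISSENSE),
         "putative_activating_unknown"),
        (dict(gene="NFE2L2", codon=28, consequence=Consequence.FRAMESHIFT),
         "likely_lof"),
        (dict(gene="NFE2L2", codon=300, consequence=Consequence.FRAMESHIFT),
         "putative_activating_unknown"),  # truncation outside Neh2
        (dict(gene="TP53", codon=175, consequence=Consequence.MISSENSE),
         "not_pathway"),
        (dict(gene="KEAP1", codon=278, consequence=Consequence.SILENT),
         "not_pathway"),
        (dict(gene="KEAP1", codon=500, consequence=Consequence.MISSENSE),
         "putative_activating_unknown"),  # scored but below threshold
    ],
)
def test_classify_nrf2(scores, kw, expected):
    assert classify_nrf2(make_variant(**kw), scores).call == expected


def test_classify_silent_rationale(scores):
    call = classify_nrf2(
        make_variant(gene="KEAP1", consequence=Consequence.SILENT), scores)
    assert call.rationale == "silent"


def test_neh2_window_configurable(scores):
    v = make_variant(gene="NFE2L2", codon=90, consequence=Consequence.FRAMESHIFT)
    assert classify_nrf2(v, scores).call == "putative_activating_unknown"
    assert classify_nrf2(v, scores, neh2_window=(1, 100)).call == "likely_lof"


def test_case_status_aggregation(scores):
    lof = (make_variant(gene="NFE2L2"), NRF2Call("likely_lof"))
    unknown = (make_variant(gene="KEAP1"), NRF2Call("putative_activating_unknown"))
    act = (make_variant(gene="KEAP1"), NRF2Call("likely_activating"))
    assert case_nrf2_status([lof]) == "negative"
    assert case_nrf2_status([unknown]) == "positive"
    assert case_nrf2_status([unknown], include_unknown=False) == "negative"
    assert case_nrf2_status([lof, act]) == "positive"
    assert case_nrf2_status([]) == "negative"


# -- cohort-table reproduction ----------------------------------------------


def test_cohort_table_counts(cohort_table_variants, cohort_codon_scores):
    """The encoded reference cohort yields 14 pathway-mutated cases, 13
    positive, and a single likely-LOF-only negative case."""
    result = triage_variants(cohort_table_variants, cohort_codon_scores)
    assert len(result.filtered) == len(cohort_table_variants)  # all pass filters
    assert len(result.case_status) == 14
    positive = [c for c, s in result.case_status.items() if s == "positive"]
    assert len(positive) == 13
    assert result.case_status["C14"] == "negative"
    # classification totality: every filtered pathway variant got one call
    assert len(result.calls) == len(cohort_table_variants)


def test_cohort_table_without_unknowns_drops_unscored_cases(
    cohort_table_variants, cohort_codon_scores
):
    result = triage_variants(
        cohort_table_variants, cohort_codon_scores, include_unknown=False)
    positive = sum(1 for s in result.case_status.values() if s == "positive")
    # C04 (T609K), C06 (F190S) and C11 (M147V) carry only unscored variants
    assert positive == 10


def test_external_exclusion_list(cohort_table_variants, cohort_codon_scores):
    """Per-variant exclusion (wet-lab-refuted calls) removes the case."""
    result = triage_variants(
        cohort_table_variants, cohort_codon_scores,
        exclude_protein_changes=[("KEAP1", "p.M147V")],
    )
    assert "C11" not in result.case_status
    assert sum(1 for s in result.case_status.values() if s == "positive") == 12
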