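"""Post-calling somatic variant triage and NRF2 activation classification.

The filter cascade mirrors targeted-cfDNA practice: (1) drop variants seen
in the platform-specific panel of normals; (2) apply hard support/VAF
filters to variants of unknown significance while keeping a relaxed,
evidence-based filter for variants with oncogenic annotation (high FATHMM
score or an oncogenic/drug-response ClinVar class); (3) prune putative
germline leakage by population allele frequency. Variants in the NRF2
pathway genes (NFE2L2, KEAP1, CUL3) are then classified for their predicted
relation to NRF2 activity using a codon-level transcriptomic activity-score
table and consequence-based rules: truncations of the KEAP1/CUL3 repressors
likely activate NRF2, whereas a frameshift inside the NFE2L2 Neh2 domain
(which mediates KEAP1 binding) abolishes rather than activates signalling.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .records import (
    NRF2_PATHWAY_GENES,
    ONCOGENIC_CLINVAR,
    Consequence,
    VariantRecord,
)

__all__ = [
    "FilterConfig",
    "CodonScoreTable",
    "NRF2Call",
    "remove_panel_of_normals",
    "evidence_tier",
    "apply_hard_filters",
    "classify_nrf2",
    "case_nrf2_status",
    "triage_variants",
]

EvidenceTier = Literal["oncogenic_evidence", "vus"]

TRUNCATING = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})
INFRAME = frozenset(
    {Consequence.MISSENSE, Consequence.INFRAME_INS, Consequence.INFRAME_DEL}
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the post-calling filter cascade.

    Defaults encode the study design: VUS require >= 5 unique supporting
    reads and VAF < 0.45 (germline heterozygous calls cluster at ~0.5),
    oncogenic-evidence variants only >= 2 unique reads; FATHMM >= 0.99
    counts as oncogenic evidence; population frequency above 1:100,000
    (GnomAD/ExAC) marks residual germline; reporting floor 1% VAF.
    """

    min_reads_vus: int = 5
    max_vaf_vus: float = 0.45
    min_reads_oncogenic: int = 2
    fathmm_threshold: float = 0.99
    pop_freq_threshold: float = 1e-5
    min_vaf_report: float = 0.01
    min_reads_per_strand: int = 2

    def __post_init__(self) -> None:
        if self.min_reads_vus < self.min_reads_oncogenic:
            raise ValueError("min_reads_vus must be >= min_reads_oncogenic")
        if not 0 < self.max_vaf_vus <= 1:
            raise ValueError("max_vaf_vus must lie in (0, 1]")
        if not 0 <= self.fathmm_threshold <= 1:
            raise ValueError("fathmm_threshold must lie in [0, 1]")
        if self.pop_freq_threshold < 0 or self.min_vaf_report < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class CodonScoreTable:
    """Codon-level NRF2 activity scores with a hyperactivity threshold.

    ``entries`` maps (gene, codon) to the activity scores observed for
    alterations of that codon; a variant whose codon's aggregate score
    exceeds ``threshold`` is considered NRF2-activating. The table is
    consumed as input — its derivation from transcriptomic data is upstream
    of this package.
    """

    entries: dict[tuple[str, int], list[float]]
    threshold: float
    aggregate: Literal["mean", "median"] = "mean"

    def __post_init__(self) -> None:
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise ValueError("threshold must be finite")
        for key, scores in self.entries.items():
            if len(scores) == 0:
                raise ValueError(f"empty score list for {key}")

    def score(self, gene: str, codon: int) -> Optional[float]:
        """Aggregate activity score for (gene, codon); None when unscored."""
        scores = self.entries.get((gene, codon))
        if scores is None:
            return None
        if self.aggregate == "median":
            return float(statistics.median(scores))
        return float(statistics.fmean(scores))

    def is_hyperactive(self, gene: str, codon: int) -> Optional[bool]:
        s = self.score(gene, codon)
        return None if s is None else s > self.threshold


@dataclass(frozen=True)
class NRF2Call:
    """Predicted relation of one variant to NRF2 activity."""

    call: Literal[
        "activating",
        "likely_activating",
        "putative_activating_unknown",
        "likely_lof",
        "not_pathway",
    ]
    rationale: str = ""

    POSITIVE_CALLS = frozenset({"activating", "likely_activating"})


def remove_panel_of_normals(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Drop variants flagged in the platform-specific panel of normals."""
    return [v for v in variants if not v.in_pon]


def evidence_tier(variant: VariantRecord, config: FilterConfig | None = None) -> EvidenceTier:
    """Tier a variant as carrying oncogenic evidence or as a VUS.

    Oncogenic evidence means FATHMM score at/above the threshold, or a
    categorical oncogenic / likely-oncogenic / drug-response ClinVar class.
    """
    config = config or FilterConfig()
    if variant.fathmm is not None and variant.fathmm >= config.fathmm_threshold:
        return "oncogenic_evidence"
    if variant.clinvar_class in ONCOGENIC_CLINVAR:
        return "oncogenic_evidence"
    return "vus"


def _passes_support(variant: VariantRecord, config: FilterConfig) -> bool:
    tier = evidence_tier(variant, config)
    if variant.reads_per_strand is not None:
        if min(variant.reads_per_strand) < config.min_reads_per_strand:
            return False
    if tier == "oncogenic_evidence":
        return variant.alt_reads >= config.min_reads_oncogenic
    return (
        variant.alt_reads >= config.min_reads_vus
        and variant.vaf < config.max_vaf_vus
    )


def apply_hard_filters(
    variants: Sequence[VariantRecord], config: FilterConfig | None = None
) -> list[VariantRecord]:
    """Apply the support/VAF hard filters and population-frequency pruning.

    Assumes panel-of-normals removal has already run. A record is retained
    when it is a VUS with >= ``min_reads_vus`` unique reads and VAF below
    ``max_vaf_vus``, or carries oncogenic evidence with >=
    ``min_reads_oncogenic`` unique reads; records whose population allele
    frequency exceeds ``pop_freq_threshold`` are then removed as putative
    germline. Silent variants are retained here (they count toward the
    mutational burden) and excluded later at classification.
    """
    config = config or FilterConfig()
    for v in variants:
        if v.alt_reads < 0:
            raise ValueError(f"negative read count on {v.case_id}/{v.gene}")
    kept = [v for v in variants if _passes_support(v, config)]
    kept = [
        v
        for v in kept
        if v.pop_freq is None or v.pop_freq <= config.pop_freq_threshold
    ]
    return kept


def classify_nrf2(
    variant: VariantRecord,
    scores: CodonScoreTable,
    neh2_window: tuple[int, int] = (1, 86),
) -> NRF2Call:
    """Classify a filtered variant's predicted relation to NRF2 activity.

    Rules: non-pathway genes are ``not_pathway``; NFE2L2 truncations within
    the Neh2 domain window are ``likely_lof`` (loss of the KEAP1-binding
    domain inactivates NRF2); KEAP1/CUL3 truncations are
    ``likely_activating`` (repressor loss of function); missense/in-frame
    variants with a scored codon above the hyperactivity threshold are
    ``activating``; missense variants at unscored codons are
    ``putative_activating_unknown``.
    """
    if variant.gene not in NRF2_PATHWAY_GENES:
        return NRF2Call("not_pathway", "gene outside NFE2L2/KEAP1/CUL3")
    if variant.consequence is Consequence.SILENT:
        return NRF2Call("not_pathway", "silent")
    if variant.gene == "NFE2L2" and variant.consequence in TRUNCATING:
        lo, hi = neh2_window
        if variant.codon is not None and lo <= variant.codon <= hi:
            return NRF2Call(
                "likely_lof",
                f"NFE2L2 {variant.consequence.value} within Neh2 domain "
                f"(codons {lo}-{hi}) abolishes KEAP1 binding",
            )
        return NRF2Call(
            "putative_activating_unknown",
            "NFE2L2 truncation outside the Neh2 window; effect unresolved",
        )
    if variant.gene in {"KEAP1", "CUL3"} and variant.consequence in TRUNCATING:
        return NRF2Call(
            "likely_activating",
            f"{variant.gene} {variant.consequence.value}: repressor loss of function",
        )
    if variant.consequence in INFRAME:
        if variant.codon is not None:
            hyper = scores.is_hyperactive(variant.gene, variant.codon)
            if hyper is True:
                return NRF2Call(
                    "activating",
                    f"codon {variant.codon} activity score above hyperactivity threshold",
                )
            if hyper is False:
                return NRF2Call(
                    "putative_activating_unknown",
                    f"codon {variant.codon} scored below hyperactivity threshold; "
                    "activation unresolved",
                )
        return NRF2Call(
            "putative_activating_unknown",
            "codon absent from activity-score table",
        )
    return NRF2Call(
        "putative_activating_unknown",
        f"{variant.consequence.value} consequence not covered by scoring rules",
    )


def case_nrf2_status(
    calls: Sequence[tuple[VariantRecord, NRF2Call]],
    include_unknown: bool = True,
) -> Literal["positive", "negative"]:
    """Aggregate per-variant calls to a case-level NRF2 mutation status.

    A case is positive when any variant is activating or likely activating;
    putative unscored variants count as positive by default (the cohort's
    unscored KEAP1 variants were retained as putative activating events). A
    case whose only pathway variant is likely LOF is negative.
    """
    positive_calls = set(NRF2Call.POSITIVE_CALLS)
    if include_unknown:
        positive_calls.add("putative_activating_unknown")
    for _, call in calls:
        if call.call in positive_calls:
            return "positive"
    return "negative"


@dataclass
class TriageResult:
    """Bundle of the full cascade on one variant table."""

    filtered: list[VariantRecord]
    calls: list[tuple[VariantRecord, NRF2Call]] = field(default_factory=list)
    case_status: dict[str, str] = field(default_factory=dict)


def triage_variants(
    variants: Sequence[VariantRecord],
    scores: CodonScoreTable,
    config: FilterConfig | None = None,
    include_unknown: bool = True,
    exclude_protein_changes: Iterable[tuple[str, str]] = (),
    neh2_window: tuple[int, int] = (1, 86),
) -> TriageResult:
    """Run the full cascade: PoN removal, hard filters, NRF2 classification.

    ``exclude_protein_changes`` lists (gene, protein_change) pairs excluded
    on external (e.g. wet-lab) evidence; they are dropped from pathway
    classification but not from the filtered variant set.
    """
    config = config or FilterConfig()
    filtered = apply_hard_filters(remove_panel_of_normals(variants), config)
    excluded = set(exclude_protein_changes)
    calls = [
        (v, classify_nrf2(v, scores, neh2_window))
        for v in filtered
        if v.gene in NRF2_PATHWAY_GENES
        and (v.gene, v.protein_change) not in excluded
    ]
    by_case: dict[str, list[tuple[VariantRecord, NRF2Call]]] = {}
    for v, c in calls:
        if c.call == "not_pathway":  # silent pathway-gene variants
            continue
        by_case.setdefault(v.case_id, []).append((v, c))
    status = {
        cid: case_nrf2_status(case_calls, include_unknown=include_unknown)
        for cid, case_calls in by_case.items()
    }
    return TriageResult(filtered=filtered, calls=calls, case_status=status)
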