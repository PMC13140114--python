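"""Blood-based tumor mutational burden, ctDNA concentration and recurrence.

bTMB counts all detected mutations of one case/timepoint (silent included)
over the targeted territory; it is reported both as a raw count (comparable
to panel counts in public cohorts) and per megabase. ctDNA concentration is
estimated as plasma cfDNA concentration times the mean VAF of the case's
pathogenic/likely-pathogenic variants. Longitudinal recurrence matches
variants across timepoints by (gene, protein change), falling back to
genomic coordinates when no protein change is annotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .records import CaseRecord, Timepoint, VariantRecord

__all__ = ["BurdenResult", "compute_btmb", "ctdna_concentration", "detect_recurrent"]


@dataclass(frozen=True)
class BurdenResult:
    raw_count: int
    per_mb: float
    timepoint: Optional[Timepoint] = None


def compute_btmb(
    variants: Sequence[VariantRecord],
    panel_size_mb: float,
    timepoint: Optional[Timepoint] = None,
) -> BurdenResult:
    """Blood-based TMB of one case/timepoint variant set.

    ``variants`` are post-QC records of a single case and timepoint, silent
    variants included. Raw count is the number of records; density is
    count / panel size (mutations/Mb).
    """
    if panel_size_mb <= 0:
        raise ValueError(f"panel_size_mb must be > 0, got {panel_size_mb}")
    n = len(variants)
    return BurdenResult(raw_count=n, per_mb=n / panel_size_mb, timepoint=timepoint)


def ctdna_concentration(
    case: CaseRecord,
    timepoint: Timepoint,
    pathogenic_variants: Sequence[VariantRecord],
) -> Optional[float]:
    """ctDNA concentration (ng/ml) = cfDNA concentration x mean VAF.

    The mean runs over the case's pathogenic/likely-pathogenic variants at
    the timepoint. Returns 0 for a measured case with no pathogenic
    variants, and None when the cfDNA measurement itself is missing (an
    absent measurement is not a zero tumor fraction).
    """
    timepoint = Timepoint(timepoint)
    cfdna = case.cfdna_ng_ml.get(timepoint)
    if cfdna is None:
        return None
    if not pathogenic_variants:
        return 0.0
    mean_vaf = sum(v.vaf for v in pathogenic_variants) / len(pathogenic_variants)
    return cfdna * mean_vaf


def detect_recurrent(
    diagnosis_variants: Sequence[VariantRecord],
    later_variants: Sequence[VariantRecord],
) -> list[VariantRecord]:
    """Variants of a later timepoint that recur from diagnosis.

    Both inputs are filtered oncogenic-evidence variants of one case.
    Matching is by (gene, HGVS-p); records lacking a protein change fall
    back to (chrom, pos, ref, alt). Returns the later-timepoint records, in
    their input order.
    """
    diagnosis_keys = {v.match_key for v in diagnosis_variants}
    return [v for v in later_variants if v.match_key in diagnosis_keys]
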