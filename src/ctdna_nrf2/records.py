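"""Core record types shared across the pipeline.

A :class:`VariantRecord` is one somatic variant call from a targeted cfDNA
panel, post variant calling and annotation (the upstream caller and
annotators are out of scope; their outputs are this pipeline's input).
A :class:`CaseRecord` is one patient with clinical covariates and
per-timepoint plasma cfDNA concentrations.

Conventions: genomic coordinates are 1-based inclusive (MAF convention);
variant allele fractions are stored as fractions in [0, 1] — percent
columns in MAF dialects are converted at read time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Timepoint(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    FOLLOWUP = "followup"
    PROGRESSION = "progression"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    SPLICE = "splice"
    SILENT = "silent"
    OTHER = "other"


class ClinvarClass(str, enum.Enum):
    ONCOGENIC = "oncogenic"
    LIKELY_ONCOGENIC = "likely_oncogenic"
    DRUG_RESPONSE = "drug_response"
    OTHER = "other"
    ABSENT = "absent"


#: ClinVar classes that count as oncogenic evidence for the relaxed filter.
ONCOGENIC_CLINVAR = frozenset(
    {ClinvarClass.ONCOGENIC, ClinvarClass.LIKELY_ONCOGENIC, ClinvarClass.DRUG_RESPONSE}
)

#: Genes whose somatic alteration can stabilise the NRF2 transcription factor.
NRF2_PATHWAY_GENES = frozenset({"NFE2L2", "KEAP1", "CUL3"})


@dataclass
class VariantRecord:
    """One somatic variant with coordinates, consequence, support and evidence.

    ``vaf`` is the variant allele fraction in [0, 1]; ``alt_reads`` the number
    of deduplicated reads supporting the alternate allele. ``fathmm`` and
    ``pop_freq`` may be absent (None) when the respective annotator produced
    no value; ``in_pon`` flags membership in the platform-specific panel of
    normals.
    """

    case_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    alt_reads: int
    timepoint: Timepoint = Timepoint.DIAGNOSIS
    cdna_change: str = ""
    protein_change: str = ""
    codon: Optional[int] = None
    consequence: Consequence = Consequence.OTHER
    reads_per_strand: Optional[tuple[int, int]] = None
    fathmm: Optional[float] = None
    clinvar_class: ClinvarClass = ClinvarClass.ABSENT
    pop_freq: Optional[float] = None
    in_pon: bool = False

    def __post_init__(self) -> None:
        self.timepoint = Timepoint(self.timepoint)
        self.consequence = Consequence(self.consequence)
        self.clinvar_class = ClinvarClass(self.clinvar_class)
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must lie in [0, 1], got {self.vaf}")
        if self.alt_reads < 0:
            raise ValueError(f"alt_reads must be non-negative, got {self.alt_reads}")
        if self.pos < 1:
            raise ValueError(f"pos is 1-based and must be >= 1, got {self.pos}")
        if self.reads_per_strand is not None:
            fwd, rev = self.reads_per_strand
            if fwd < 0 or rev < 0:
                raise ValueError("strand read counts must be non-negative")
            if self.alt_reads < max(fwd, rev):
                raise ValueError("alt_reads must be >= each per-strand count")
        if self.fathmm is not None and not 0.0 <= self.fathmm <= 1.0:
            raise ValueError(f"fathmm score must lie in [0, 1], got {self.fathmm}")
        if self.pop_freq is not None and not 0.0 <= self.pop_freq <= 1.0:
            raise ValueError(f"pop_freq must lie in [0, 1], got {self.pop_freq}")

    @property
    def genomic_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def match_key(self) -> tuple:
        """Longitudinal matching key: HGVS-p primary, genomic coordinates as
        fallback when no protein change is annotated."""
        if self.protein_change:
            return ("p", self.gene, self.protein_change)
        return ("g",) + self.genomic_key


@dataclass
class CaseRecord:
    """One patient: clinical covariates plus per-timepoint cfDNA levels."""

    case_id: str
    sex: str = "unknown"  # male / female / unknown
    age: Optional[float] = None
    stage: Optional[str] = None  # I, II, III, IV
    smoking: Optional[str] = None  # never / ex / current
    histology: Optional[str] = None  # LUAD / LUSC / NSCLC_NOS
    cfdna_ng_ml: dict[Timepoint, float] = field(default_factory=dict)
    panel_size_mb: float = 0.3

    def __post_init__(self) -> None:
        self.cfdna_ng_ml = {Timepoint(k): float(v) for k, v in self.cfdna_ng_ml.items()}
        for tp, conc in self.cfdna_ng_ml.items():
            if conc <= 0:
                raise ValueError(f"cfDNA concentration at {tp.value} must be > 0")
        if self.panel_size_mb <= 0:
            raise ValueError("panel_size_mb must be > 0")
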