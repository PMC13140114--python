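"""Synthetic cohorts and trajectory ensembles with known ground truth.

The cohort generator emulates the statistical structure of a targeted-panel
ctDNA study of inoperable NSCLC: ~18% of cases carry an NRF2-pathway
(NFE2L2/KEAP1/CUL3) activating mutation; somatic driver VAFs follow a
Beta(2, 40) prior (median ~4%, range mostly 1-30%); SMARCA4 mutations
co-occur with NRF2 status with a configurable odds ratio; contaminants are
injected with their telltale signatures — PCR artifacts with 1-4 supporting
reads, and germline leakage near 0.5 VAF with population allele frequencies
above 1:100,000. Truth labels are recorded per variant so triage recovery
is measurable.

The trajectory generator samples Gaussian-network equilibrium ensembles:
frames are the reference structure plus displacements whose per-axis
covariance is kT * pseudoinverse(Kirchhoff), giving closed-form targets for
every downstream statistic. The mutant condition rescales the spring
constants incident to the mutation site; ligand atoms follow a discrete
Ornstein-Uhlenbeck drift around their initial pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import CaseRecord, ClinvarClass, Consequence, Timepoint, VariantRecord
from .triage import CodonScoreTable
from .trajectory import TrajectoryEnsemble

__all__ = [
    "CohortSpec",
    "TrajectorySpec",
    "gen_cohort",
    "gen_gnm_trajectory",
    "default_codon_scores",
    "helix_coords",
    "gnm_covariance",
]

# (gene, codon, protein change, consequence) mix echoing the observed cohort:
# scored hotspot missense, unscored novel missense, and repressor truncations.
_PATHWAY_VARIANT_MIX = [
    ("NFE2L2", 77, "p.D77H", Consequence.MISSENSE, 3),
    ("NFE2L2", 24, "p.W24R", Consequence.MISSENSE, 1),
    ("NFE2L2", 34, "p.E34ins", Consequence.INFRAME_INS, 1),
    ("KEAP1", 278, "p.P278A", Consequence.MISSENSE, 1),
    ("KEAP1", 323, "p.K323A", Consequence.MISSENSE, 1),
    ("KEAP1", 480, "p.G480W", Consequence.MISSENSE, 1),
    ("KEAP1", 609, "p.T609K", Consequence.MISSENSE, 1),
    ("KEAP1", 190, "p.F190S", Consequence.MISSENSE, 1),
    ("KEAP1", 216, "p.K216*", Consequence.NONSENSE, 1),
    ("KEAP1", 413, "p.R413fs", Consequence.FRAMESHIFT, 1),
    ("CUL3", 751, "p.R751*", Consequence.NONSENSE, 1),
]

#: Codons carried by the synthetic activity-score table (unscored novel
#: codons 147/190/609 deliberately absent, as in the study cohort).
_SCORED_CODONS = [
    ("NFE2L2", 24), ("NFE2L2", 34), ("NFE2L2", 77), ("NFE2L2", 79),
    ("KEAP1", 278), ("KEAP1", 323), ("KEAP1", 480), ("KEAP1", 511),
    ("CUL3", 52),
]

_BACKGROUND_GENES = [
    "TP53", "CSMD3", "NF1", "LRP1B", "EGFR", "KRAS", "STK11", "PTEN",
    "RB1", "PIK3CA", "BRAF", "MET", "ALK", "FAT1", "ARID1A",
]


def default_codon_scores(threshold: float = 1.0, seed: int = 0) -> CodonScoreTable:
    """Synthetic stand-in for the codon-level NRF2 activity-score table.

    Scores for known activating codons are drawn above the hyperactivity
    threshold (as every matched codon in the study cohort scored); novel
    codons are simply absent. Scale is arbitrary.
    """
    rng = np.random.default_rng(seed)
    entries = {
        key: [float(x) for x in
              np.round(threshold + rng.uniform(0.2, 1.5, size=rng.integers(2, 6)), 3)]
        for key in _SCORED_CODONS
    }
    return CodonScoreTable(entries=entries, threshold=threshold)


@dataclass
class CohortSpec:
    """Study conditions of the synthetic cohort.

    Defaults encode the cohort the pipeline was designed around: 73 cases,
    18% NRF2-pathway prevalence, strong SMARCA4 co-occurrence, Beta(2, 40)
    somatic VAFs, ~1000x deduplicated depth, a few PCR artifacts and
    occasional germline leakage per case, on a ~0.3 Mb panel.
    """

    n_cases: int = 73
    nrf2_prevalence: float = 0.18
    smarca4_cooccurrence_or: float = 8.0
    smarca4_base_rate: float = 0.08
    vaf_beta_params: dict = field(default_factory=lambda: {
        "somatic": (2.0, 40.0),
        "germline": (200.0, 200.0),
    })
    mean_depth: float = 1000.0
    depth_sd: float = 200.0
    min_depth: int = 400
    background_rate: float = 4.0  # somatic passenger/driver variants per case
    artifact_rate: float = 3.0  # PCR-artifact variants per case (1-4 reads)
    germline_rate: float = 1.0  # germline contaminants escaping the PoN
    germline_misannotation_rate: float = 0.02  # germline with oncogenic ClinVar class
    silent_fraction: float = 0.2  # silent share of background somatic calls
    followup_fraction: float = 0.25  # cases with a follow-up sample
    persistence: float = 0.5  # probability an oncogenic variant recurs
    panel_size_mb: float = 0.3
    min_vaf: float = 0.012
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.nrf2_prevalence, self.smarca4_base_rate,
                  self.followup_fraction, self.persistence,
                  self.germline_misannotation_rate, self.silent_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.smarca4_cooccurrence_or <= 0:
            raise ValueError("odds ratio must be positive")


def _draw_vaf(rng: np.random.Generator, a: float, b: float, floor: float) -> float:
    for _ in range(1000):
        v = float(rng.beta(a, b))
        if v >= floor:
            return v
    return floor


def _draw_depth(rng: np.random.Generator, spec: CohortSpec) -> int:
    return int(max(spec.min_depth, rng.normal(spec.mean_depth, spec.depth_sd)))


def _alt_reads(rng: np.random.Generator, depth: int, vaf: float) -> int:
    return int(rng.binomial(depth, vaf))


def gen_cohort(
    spec: CohortSpec,
    scores: Optional[CodonScoreTable] = None,
) -> tuple[list[CaseRecord], list[VariantRecord], dict]:
    """Generate a synthetic cohort with per-variant truth labels.

    Returns ``(cases, variants, truth)`` where ``truth`` holds
    ``origin`` (a list aligned with ``variants``; one of pathway /
    smarca4 / background / germline / artifact), ``case_nrf2`` (case_id ->
    bool) and ``case_smarca4`` (case_id -> bool). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    scores = scores or default_codon_scores()
    a_som, b_som = spec.vaf_beta_params["somatic"]
    a_ger, b_ger = spec.vaf_beta_params["germline"]

    q = spec.smarca4_base_rate
    odds_pos = spec.smarca4_cooccurrence_or * q / (1 - q)
    p_smarca4_pos = odds_pos / (1 + odds_pos)

    mix_weights = np.array([w for *_, w in _PATHWAY_VARIANT_MIX], dtype=float)
    mix_weights /= mix_weights.sum()

    cases: list[CaseRecord] = []
    variants: list[VariantRecord] = []
    origin: list[str] = []
    case_nrf2: dict[str, bool] = {}
    case_smarca4: dict[str, bool] = {}
    pos_counter = 0

    for i in range(spec.n_cases):
        cid = f"SYN{i + 1:04d}"
        is_pos = bool(rng.random() < spec.nrf2_prevalence)
        is_smarca4 = bool(rng.random() < (p_smarca4_pos if is_pos else q))
        case_nrf2[cid] = is_pos
        case_smarca4[cid] = is_smarca4
        has_followup = rng.random() < spec.followup_fraction

        sex = "male" if (is_pos or rng.random() < 0.73) else "female"
        smoking = (
            rng.choice(["ex", "current"]) if is_pos
            else rng.choice(["never", "ex", "current"], p=[0.15, 0.45, 0.40])
        )
        cfdna = {Timepoint.DIAGNOSIS: float(np.exp(rng.normal(np.log(13.0), 1.1)))}
        if has_followup:
            cfdna[Timepoint.FOLLOWUP] = float(np.exp(rng.normal(np.log(13.0), 1.1)))
        cases.append(CaseRecord(
            case_id=cid,
            sex=sex,
            age=float(np.clip(rng.normal(69, 9), 40, 92)),
            stage=str(rng.choice(["III", "IV"], p=[0.4, 0.6]) if is_pos
                      else rng.choice(["I", "II", "III", "IV"], p=[0.04, 0.04, 0.32, 0.6])),
            smoking=str(smoking),
            histology=str(rng.choice(["LUSC", "LUAD", "NSCLC_NOS"], p=[0.4, 0.44, 0.16])),
            cfdna_ng_ml=cfdna,
            panel_size_mb=spec.panel_size_mb,
        ))

        case_variants: list[tuple[VariantRecord, str]] = []

        def add(v: VariantRecord, label: str) -> None:
            case_variants.append((v, label))

        if is_pos:
            pos_counter += 1
            gene, codon, pchg, csq, _w = _PATHWAY_VARIANT_MIX[
                int(rng.choice(len(_PATHWAY_VARIANT_MIX), p=mix_weights))
            ]
            vaf = _draw_vaf(rng, a_som, b_som, spec.min_vaf)
            depth = _draw_depth(rng, spec)
            if rng.random() < 0.8:
                fathmm, clinvar = float(rng.uniform(0.992, 1.0)), ClinvarClass.ABSENT
            else:
                fathmm, clinvar = None, ClinvarClass.LIKELY_ONCOGENIC
            add(VariantRecord(
                case_id=cid, gene=gene, chrom="chr2" if gene != "KEAP1" else "chr19",
                pos=int(1_000_000 + codon * 3), ref="A", alt="T",
                vaf=vaf, alt_reads=max(2, _alt_reads(rng, depth, vaf)),
                protein_change=pchg, codon=codon, consequence=csq,
                fathmm=fathmm, clinvar_class=clinvar,
            ), "pathway")

        if is_smarca4:
            vaf = _draw_vaf(rng, a_som, b_som, spec.min_vaf)
            depth = _draw_depth(rng, spec)
            add(VariantRecord(
                case_id=cid, gene="SMARCA4", chrom="chr19",
                pos=int(rng.integers(11_000_000, 11_100_000)), ref="C", alt="T",
                vaf=vaf, alt_reads=max(2, _alt_reads(rng, depth, vaf)),
                consequence=Consequence(rng.choice(["missense", "nonsense", "frameshift"])),
                fathmm=float(rng.uniform(0.992, 1.0)),
            ), "smarca4")

        for _ in range(rng.poisson(spec.background_rate)):
            gene = str(rng.choice(_BACKGROUND_GENES))
            vaf = _draw_vaf(rng, a_som, b_som, spec.min_vaf)
            depth = _draw_depth(rng, spec)
            silent = rng.random() < spec.silent_fraction
            oncogenic = (not silent) and rng.random() < 0.3
            add(VariantRecord(
                case_id=cid, gene=gene, chrom=f"chr{rng.integers(1, 23)}",
                pos=int(rng.integers(1, 200_000_000)), ref="G", alt="A",
                vaf=vaf, alt_reads=_alt_reads(rng, depth, vaf),
                consequence=Consequence.SILENT if silent else Consequence.MISSENSE,
                fathmm=float(rng.uniform(0.992, 1.0)) if oncogenic
                else float(rng.uniform(0.0, 0.9)),
            ), "background")

        for _ in range(rng.poisson(spec.germline_rate)):
            vaf = float(rng.beta(a_ger, b_ger))
            depth = _draw_depth(rng, spec)
            misannotated = rng.random() < spec.germline_misannotation_rate
            add(VariantRecord(
                case_id=cid, gene=str(rng.choice(_BACKGROUND_GENES)),
                chrom=f"chr{rng.integers(1, 23)}",
                pos=int(rng.integers(1, 200_000_000)), ref="T", alt="C",
                vaf=vaf, alt_reads=_alt_reads(rng, depth, vaf),
                consequence=Consequence.MISSENSE,
                pop_freq=float(10 ** rng.uniform(-4, -2)),
                clinvar_class=ClinvarClass.DRUG_RESPONSE if misannotated
                else ClinvarClass.OTHER,
                in_pon=bool(rng.random() < 0.3),
            ), "germline")

        for _ in range(rng.poisson(spec.artifact_rate)):
            reads = int(rng.integers(1, 5))
            depth = _draw_depth(rng, spec)
            add(VariantRecord(
                case_id=cid, gene=str(rng.choice(_BACKGROUND_GENES)),
                chrom=f"chr{rng.integers(1, 23)}",
                pos=int(rng.integers(1, 200_000_000)), ref="C", alt="G",
                vaf=min(1.0, reads / depth), alt_reads=reads,
                consequence=Consequence.MISSENSE,
                in_pon=bool(rng.random() < 0.5),
            ), "artifact")

        for v, label in case_variants:
            variants.append(v)
            origin.append(label)

        if has_followup:
            from dataclasses import replace
            for v, label in case_variants:
                if label in {"pathway", "smarca4", "background"} and rng.random() < spec.persistence:
                    new_vaf = _draw_vaf(rng, a_som, b_som, spec.min_vaf)
                    depth = _draw_depth(rng, spec)
                    variants.append(replace(
                        v, timepoint=Timepoint.FOLLOWUP, vaf=new_vaf,
                        alt_reads=max(2, _alt_reads(rng, depth, new_vaf)),
                    ))
                    origin.append(label)

    truth = {
        "origin": origin,
        "case_nrf2": case_nrf2,
        "case_smarca4": case_smarca4,
        "n_positive_truth": pos_counter,
    }
    return cases, variants, truth


# ---------------------------------------------------------------------------
# trajectory ensembles


@dataclass
class TrajectorySpec:
    """Study conditions of the synthetic trajectory ensembles.

    Five replicas per condition by default, as in replicated MD practice.
    ``perturbation`` multiplies the spring constants of contacts incident to
    ``mutation_site`` in the mutant network (values < 1 soften the site,
    raising its fluctuations). kT defaults to 0.6 (kcal/mol at ~300 K) with
    gamma 1 kcal/mol/A^2, giving realistic ~1 A alpha-carbon fluctuations.
    """

    n_residues: int = 60
    cutoff: float = 7.0
    gamma: float = 1.0
    kT: float = 0.6
    n_replicas: int = 5
    n_frames: int = 500
    mutation_site: Optional[int] = None  # residue index; default N // 2
    perturbation: float = 0.25
    n_ligand_atoms: int = 0
    ou_theta: float = 0.1
    ou_sigma: float = 0.3
    mutant_ligand_scale: float = 1.0  # multiplies OU sigma in the mutant
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicas < 2:
            raise ValueError("n_replicas must be >= 2")
        if self.perturbation <= 0:
            raise ValueError("perturbation must be positive")
        if self.mutation_site is None:
            self.mutation_site = self.n_residues // 2


def helix_coords(n_residues: int, radius: float = 2.3, rise: float = 1.5,
                 turn_deg: float = 100.0) -> np.ndarray:
    """Ideal alpha-helix C-alpha trace (connected at the 7 A GNM cutoff)."""
    theta = np.deg2rad(turn_deg) * np.arange(n_residues)
    return np.column_stack([
        radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n_residues)
    ])


def _weighted_kirchhoff(coords: np.ndarray, cutoff: float, gamma: float,
                        site: Optional[int] = None, scale: float = 1.0) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    w = np.where((dist <= cutoff) & (dist > 0), gamma, 0.0)
    if site is not None and scale != 1.0:
        w[site, :] *= scale
        w[:, site] *= scale
    k = -w
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    return k


def gnm_covariance(kirchhoff: np.ndarray, kT: float) -> np.ndarray:
    """Per-axis equilibrium covariance kT * pseudoinverse(Kirchhoff)."""
    return kT * np.linalg.pinv(kirchhoff, hermitian=True)


def _sample_frames(rng: np.random.Generator, reference: np.ndarray,
                   kirchhoff: np.ndarray, kT: float, n_frames: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(kirchhoff)
    tol = 1e-8 * max(vals[-1], 1e-30)
    keep = vals > tol
    if keep.sum() < len(vals) - 1:
        raise ValueError("contact graph of the base structure is disconnected")
    amp = np.sqrt(kT / vals[keep])  # mode displacement std, Angstrom
    modes = vecs[:, keep]
    if kT == 0:
        return np.repeat(reference[None], n_frames, axis=0)
    z = rng.standard_normal((n_frames, keep.sum(), 3))
    disp = np.einsum("nm,fmk->fnk", modes, z * amp[None, :, None])
    return reference[None] + disp


def _sample_ligand(rng: np.random.Generator, base: np.ndarray, n_frames: int,
                   theta: float, sigma: float) -> np.ndarray:
    frames = np.empty((n_frames,) + base.shape)
    frames[0] = base
    for t in range(1, n_frames):
        eps = rng.standard_normal(base.shape)
        frames[t] = frames[t - 1] + theta * (base - frames[t - 1]) + sigma * eps
    return frames


def gen_gnm_trajectory(
    spec: TrajectorySpec,
) -> tuple[dict[str, TrajectoryEnsemble], np.ndarray, dict[str, np.ndarray]]:
    """Sample wild-type and mutant trajectory ensembles from elastic networks.

    Frames are equilibrium draws ``reference + displacement`` with per-axis
    covariance kT * pinv(Kirchhoff) (eigendecomposition sampling, zero modes
    excluded, i.e. the network's centre of mass is pinned). The mutant
    network rescales springs incident to the mutation site by
    ``spec.perturbation``. Returns ``(ensembles, reference, kirchhoffs)``
    with conditions "wt" and "mut"; deterministic given ``spec.seed``.
    """
    reference = helix_coords(spec.n_residues)
    kirchhoffs = {
        "wt": _weighted_kirchhoff(reference, spec.cutoff, spec.gamma),
        "mut": _weighted_kirchhoff(reference, spec.cutoff, spec.gamma,
                                   site=spec.mutation_site, scale=spec.perturbation),
    }
    lig_base = None
    if spec.n_ligand_atoms > 0:
        phi = 2 * np.pi * np.arange(spec.n_ligand_atoms) / spec.n_ligand_atoms
        centre = reference[spec.mutation_site] + np.array([4.0, 0.0, 0.0])
        lig_base = centre + 1.5 * np.column_stack(
            [np.cos(phi), np.sin(phi), np.zeros_like(phi)]
        )
    seeds = np.random.SeedSequence(spec.seed).spawn(2)
    ensembles: dict[str, TrajectoryEnsemble] = {}
    for (cond, k), ss in zip(kirchhoffs.items(), seeds):
        rng = np.random.default_rng(ss)
        replicas, ligands = [], []
        lig_sigma = spec.ou_sigma * (spec.mutant_ligand_scale if cond == "mut" else 1.0)
        for _ in range(spec.n_replicas):
            replicas.append(_sample_frames(rng, reference, k, spec.kT, spec.n_frames))
            if lig_base is not None:
                ligands.append(_sample_ligand(rng, lig_base, spec.n_frames,
                                              spec.ou_theta, lig_sigma))
        ensembles[cond] = TrajectoryEnsemble(
            condition=cond,
            replicas=replicas,
            residue_ids=list(range(1, spec.n_residues + 1)),
            ligand_coords=ligands if lig_base is not None else None,
        )
    return ensembles, reference, kirchhoffs
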