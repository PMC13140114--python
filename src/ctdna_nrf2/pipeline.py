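"""End-to-end orchestration: triage -> burden -> cohort statistics (+ optional
trajectory comparison), with TSV/JSON outputs and a provenance block."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as nio
from .burden import compute_btmb, ctdna_concentration, detect_recurrent
from .records import NRF2_PATHWAY_GENES, CaseRecord, Consequence, Timepoint, VariantRecord
from .stats import pairwise_cooccurrence
from .trajectory import (
    bootstrap_eigs,
    compare_rmsf,
    gnm_spectra_over_trajectory,
    hausdorff_matrix,
    ligand_rmsd_test,
    pooled_nonzero_eigenvalues,
    rmsf_profile,
    top_split_labels,
    ward_cluster,
)
from .triage import CodonScoreTable, FilterConfig, evidence_tier, triage_variants

logger = logging.getLogger("ctdna_nrf2")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    include_unknown: bool = True
    neh2_window: tuple[int, int] = (1, 86)
    exclude_protein_changes: tuple[tuple[str, str], ...] = ()
    panel_size_mb: float = 0.3
    gnm_cutoff: float = 7.0
    gnm_gamma: float = 1.0
    gnm_stride: int = 100
    n_boot: int = 1000
    min_cases_for_cooccurrence: int = 2
    seed: int = 0
    output_dir: str = "pipeline_out"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _variant_calls_frame(result) -> pd.DataFrame:
    rows = [
        {
            "case_id": v.case_id, "timepoint": v.timepoint.value, "gene": v.gene,
            "protein_change": v.protein_change, "vaf": v.vaf,
            "call": c.call, "rationale": c.rationale,
        }
        for v, c in result.calls
    ]
    return pd.DataFrame(
        rows, columns=["case_id", "timepoint", "gene", "protein_change",
                       "vaf", "call", "rationale"]
    )


def run_pipeline(
    config: PipelineConfig,
    maf_path,
    clinical_path,
    codon_scores_path,
    trajectory_dirs: Optional[dict[str, Sequence]] = None,
) -> dict:
    """Run triage, burden and cohort statistics; write outputs; return summary.

    ``trajectory_dirs`` optionally maps condition labels to lists of
    multi-model PDB replica paths for the trajectory comparison stage.
    Outputs are deterministic for identical inputs and seeds.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("reading inputs")
    variants = nio.read_maf(maf_path)
    cases = nio.read_clinical(clinical_path)
    scores = nio.read_codon_scores(codon_scores_path)
    case_by_id = {c.case_id: c for c in cases}

    result = triage_variants(
        variants, scores, config.filters,
        include_unknown=config.include_unknown,
        exclude_protein_changes=config.exclude_protein_changes,
        neh2_window=config.neh2_window,
    )
    nio.write_maf(result.filtered, out / "filtered.maf.tsv")
    calls_df = _variant_calls_frame(result)
    calls_df.to_csv(out / "nrf2_variant_calls.tsv", sep="\t", index=False)
    status_df = pd.DataFrame(
        [{"case_id": c.case_id,
          "nrf2_status": result.case_status.get(c.case_id, "negative")}
         for c in cases]
    )
    status_df.to_csv(out / "nrf2_case_status.tsv", sep="\t", index=False)

    # burden per case/timepoint: raw counts on all detected (pre-filter,
    # post-PoN) and on filtered variants; ctDNA concentration from filtered
    # pathogenic/likely-pathogenic variants.
    from .triage import remove_panel_of_normals

    detected = remove_panel_of_normals(variants)
    pathogenic = [
        v for v in result.filtered
        if evidence_tier(v, config.filters) == "oncogenic_evidence"
        and v.consequence is not Consequence.SILENT
    ]
    burden_rows = []
    for c in cases:
        for tp in Timepoint:
            det = [v for v in detected if v.case_id == c.case_id and v.timepoint is tp]
            filt = [v for v in result.filtered
                    if v.case_id == c.case_id and v.timepoint is tp]
            if not det and tp not in c.cfdna_ng_ml:
                continue
            path_tp = [v for v in pathogenic if v.case_id == c.case_id and v.timepoint is tp]
            conc = ctdna_concentration(c, tp, path_tp)
            b_det = compute_btmb(det, c.panel_size_mb, tp)
            b_filt = compute_btmb(filt, c.panel_size_mb, tp)
            burden_rows.append({
                "case_id": c.case_id, "timepoint": tp.value,
                "raw_count_detected": b_det.raw_count,
                "per_mb_detected": b_det.per_mb,
                "raw_count_filtered": b_filt.raw_count,
                "per_mb_filtered": b_filt.per_mb,
                "ctdna_ng_ml": "" if conc is None else conc,
            })
    burden_df = pd.DataFrame(burden_rows)
    burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)

    # longitudinal recurrence of oncogenic-evidence variants
    recurrence_rows = []
    for c in cases:
        diag = [v for v in pathogenic
                if v.case_id == c.case_id and v.timepoint is Timepoint.DIAGNOSIS]
        for tp in (Timepoint.FOLLOWUP, Timepoint.PROGRESSION):
            later = [v for v in pathogenic if v.case_id == c.case_id and v.timepoint is tp]
            if later or diag:
                rec = detect_recurrent(diag, later)
                recurrence_rows.append({
                    "case_id": c.case_id, "timepoint": tp.value,
                    "n_diagnosis": len(diag), "n_later": len(later),
                    "n_recurrent": len(rec),
                })
    rec_df = pd.DataFrame(recurrence_rows)
    rec_df.to_csv(out / "recurrence.tsv", sep="\t", index=False)

    # gene x case pathogenic mutation matrix -> co-occurrence tests, with
    # the NRF2 pathway collapsed to one pseudo-gene column
    diag_path = [v for v in pathogenic if v.timepoint is Timepoint.DIAGNOSIS]
    genes = sorted({("NRF2_pathway" if v.gene in NRF2_PATHWAY_GENES else v.gene)
                    for v in diag_path})
    matrix = pd.DataFrame(False, index=[c.case_id for c in cases], columns=genes)
    for v in diag_path:
        col = "NRF2_pathway" if v.gene in NRF2_PATHWAY_GENES else v.gene
        matrix.loc[v.case_id, col] = True
    keep = [g for g in genes if matrix[g].sum() >= config.min_cases_for_cooccurrence]
    cooc_df = pairwise_cooccurrence(matrix[keep]) if len(keep) >= 2 else pd.DataFrame()
    cooc_df.to_csv(out / "cooccurrence.tsv", sep="\t", index=False)

    summary: dict = {
        "n_cases": len(cases),
        "n_variants_input": len(variants),
        "n_variants_filtered": len(result.filtered),
        "n_pathway_mutated_cases": len(result.case_status),
        "n_nrf2_positive_cases": sum(
            1 for s in result.case_status.values() if s == "positive"
        ),
        "nrf2_positive_fraction": (
            sum(1 for s in result.case_status.values() if s == "positive") / len(cases)
            if cases else 0.0
        ),
    }

    if trajectory_dirs:
        summary["trajectory"] = _run_trajectory_stage(config, trajectory_dirs, out)

    summary["provenance"] = {
        "inputs": {
            "maf": _sha256(maf_path),
            "clinical": _sha256(clinical_path),
            "codon_scores": _sha256(codon_scores_path),
        },
        "seed": config.seed,
        "filters": asdict(config.filters),
        "panel_size_mb": config.panel_size_mb,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out / "summary.json")
    return summary


def _run_trajectory_stage(config: PipelineConfig, trajectory_dirs, out: Path) -> dict:
    """Trajectory comparison on two conditions of multi-model PDB replicas."""
    conditions = sorted(trajectory_dirs)
    if len(conditions) != 2:
        raise ValueError("trajectory stage expects exactly two conditions")
    frames_by_cond: dict[str, list[np.ndarray]] = {}
    ligand_by_cond: dict[str, list] = {}
    for cond in conditions:
        frames_by_cond[cond], ligand_by_cond[cond] = [], []
        for p in trajectory_dirs[cond]:
            fr, lig, _resids = nio.read_trajectory_pdb(p)
            frames_by_cond[cond].append(fr)
            ligand_by_cond[cond].append(lig)

    # RMSF comparison
    profiles = {c: np.array([rmsf_profile(f) for f in frames_by_cond[c]])
                for c in conditions}
    cmp_res = compare_rmsf(profiles[conditions[0]], profiles[conditions[1]])
    pd.DataFrame({
        "residue": cmp_res.residue_ids,
        f"rmsf_{conditions[0]}": cmp_res.mean_a,
        f"rmsf_{conditions[1]}": cmp_res.mean_b,
        "t": cmp_res.t, "p_raw": cmp_res.p_raw, "p_bonferroni": cmp_res.p_adj,
        "significant": cmp_res.significant,
    }).to_csv(out / "rmsf_comparison.tsv", sep="\t", index=False)

    # Hausdorff distances + Ward clustering
    all_frames = [f for c in conditions for f in frames_by_cond[c]]
    labels = [f"{c}_rep{i + 1}" for c in conditions
              for i in range(len(frames_by_cond[c]))]
    dist = hausdorff_matrix(all_frames, labels=labels)
    nio.write_distance_matrix(dist, out / "hausdorff_matrix.tsv")
    link = ward_cluster(dist)
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(nio.linkage_to_newick(link, dist.labels) + "\n")
    split = top_split_labels(link)
    cond_of = np.array([l.rsplit("_rep", 1)[0] for l in labels])
    separates = all(len(set(cond_of[split == k])) == 1 for k in np.unique(split))

    # GNM eigenvalue bootstrap
    pooled = {
        c: pooled_nonzero_eigenvalues([
            s for f in frames_by_cond[c]
            for s in gnm_spectra_over_trajectory(
                f, stride=config.gnm_stride, cutoff=config.gnm_cutoff,
                gamma=config.gnm_gamma)
        ])
        for c in conditions
    }
    densities, overlap = bootstrap_eigs(pooled, n_boot=config.n_boot, seed=config.seed)
    dens_df = pd.DataFrame({"eigenvalue": densities[conditions[0]].grid})
    for c in conditions:
        dens_df[f"density_{c}"] = densities[c].density
    dens_df.to_csv(out / "gnm_bootstrap_density.tsv", sep="\t", index=False)

    traj_summary = {
        "n_significant_rmsf_residues": int(cmp_res.significant.sum()),
        "top_split_separates_conditions": bool(separates),
        "eigenvalue_density_overlap": overlap,
    }

    if all(l is not None for ligs in ligand_by_cond.values() for l in ligs):
        from .trajectory import TrajectoryEnsemble

        ens = {
            c: TrajectoryEnsemble(
                condition=c, replicas=frames_by_cond[c],
                residue_ids=list(range(frames_by_cond[c][0].shape[1])),
                ligand_coords=ligand_by_cond[c],
            )
            for c in conditions
        }
        lig_res = ligand_rmsd_test(ens[conditions[0]], ens[conditions[1]])
        traj_summary["ligand_rmsd_t"] = lig_res.statistic
        traj_summary["ligand_rmsd_p"] = lig_res.p_two_sided
    return traj_summary
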