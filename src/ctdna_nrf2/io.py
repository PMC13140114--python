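"""Readers and writers for the pipeline's tabular and structural formats.

Variant tables travel as MAF-like TSV (1-based inclusive coordinates;
percent VAF columns are converted to fractions at read time), clinical and
codon-score tables as TSV, trajectories as multi-model PDB (parsed with
MDAnalysis), dendrograms as Newick text.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import CaseRecord, ClinvarClass, Consequence, Timepoint, VariantRecord
from .triage import CodonScoreTable
from .trajectory import DistanceMatrix, TrajectoryEnsemble

__all__ = [
    "read_maf", "write_maf",
    "read_clinical", "write_clinical",
    "read_codon_scores", "write_codon_scores",
    "read_trajectory_pdb", "write_trajectory_pdb",
    "linkage_to_newick", "write_distance_matrix", "read_distance_matrix",
]

_CSQ_TO_MAF = {
    Consequence.MISSENSE: "Missense_Mutation",
    Consequence.NONSENSE: "Nonsense_Mutation",
    Consequence.FRAMESHIFT: "Frame_Shift_Del",
    Consequence.INFRAME_INS: "In_Frame_Ins",
    Consequence.INFRAME_DEL: "In_Frame_Del",
    Consequence.SPLICE: "Splice_Site",
    Consequence.SILENT: "Silent",
    Consequence.OTHER: "Other",
}
_MAF_TO_CSQ = {v: k for k, v in _CSQ_TO_MAF.items()}
_MAF_TO_CSQ.update({
    "Frame_Shift_Ins": Consequence.FRAMESHIFT,
    "Nonstop_Mutation": Consequence.OTHER,
    "Translation_Start_Site": Consequence.OTHER,
})

REQUIRED_MAF_COLUMNS = [
    "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
    "Tumor_Seq_Allele2", "Variant_Classification", "HGVSc", "HGVSp",
    "t_alt_count", "VAF",
]


def _parse_optional_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _s(value) -> str:
    """String field with NaN/None normalised to empty."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


def read_maf(path, vaf_unit: str = "auto") -> list[VariantRecord]:
    """Read a MAF-like TSV into variant records.

    ``vaf_unit`` is "fraction", "percent", or "auto" (percent assumed when
    any value exceeds 1, as in tables printing "VAF %"). Raises a parse
    error naming the offending line for malformed rows.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MAF columns {missing}")
    # float() per cell: pandas' fast to_numeric path is not bit-exact
    vafs = [float(x) if _s(x) else math.nan for x in df["VAF"]]
    if vaf_unit == "percent" or (
        vaf_unit == "auto" and any(v > 1 for v in vafs if not math.isnan(v))
    ):
        vafs = [v / 100.0 for v in vafs]
    records = []
    for i, row in df.iterrows():
        try:
            codon = _parse_optional_float(row.get("Codon"))
            records.append(VariantRecord(
                case_id=_s(row.get("Tumor_Sample_Barcode")),
                timepoint=Timepoint(_s(row.get("Timepoint")) or "diagnosis"),
                gene=str(row["Hugo_Symbol"]),
                chrom=str(row["Chromosome"]),
                pos=int(row["Start_Position"]),
                ref=str(row["Reference_Allele"]),
                alt=str(row["Tumor_Seq_Allele2"]),
                cdna_change=_s(row.get("HGVSc")),
                protein_change=_s(row.get("HGVSp")),
                codon=int(codon) if codon is not None else None,
                consequence=_MAF_TO_CSQ.get(str(row["Variant_Classification"]),
                                            Consequence.OTHER),
                vaf=vafs[i],
                alt_reads=int(row["t_alt_count"]),
                fathmm=_parse_optional_float(row.get("FATHMM")),
                clinvar_class=ClinvarClass(_s(row.get("CLINVAR_CLASS")) or "absent"),
                pop_freq=_parse_optional_float(row.get("POP_AF")),
                in_pon=_s(row.get("IN_PON")).strip().lower() in {"1", "true", "yes"},
            ))
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed record at line {i + 2}: {exc}") from exc
    return records


def write_maf(variants: Sequence[VariantRecord], path) -> None:
    """Write variant records as MAF-like TSV (VAF as fraction, full precision)."""
    rows = []
    for v in variants:
        rows.append({
            "Hugo_Symbol": v.gene,
            "Chromosome": v.chrom,
            "Start_Position": v.pos,
            "Reference_Allele": v.ref,
            "Tumor_Seq_Allele2": v.alt,
            "Variant_Classification": _CSQ_TO_MAF[v.consequence],
            "HGVSc": v.cdna_change,
            "HGVSp": v.protein_change,
            "Codon": "" if v.codon is None else v.codon,
            "t_alt_count": v.alt_reads,
            "VAF": repr(v.vaf),
            "Tumor_Sample_Barcode": v.case_id,
            "Timepoint": v.timepoint.value,
            "FATHMM": "" if v.fathmm is None else repr(v.fathmm),
            "CLINVAR_CLASS": v.clinvar_class.value,
            "POP_AF": "" if v.pop_freq is None else repr(v.pop_freq),
            "IN_PON": "true" if v.in_pon else "false",
        })
    pd.DataFrame(rows, columns=list(rows[0]) if rows else REQUIRED_MAF_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


_CLINICAL_TP_COLUMNS = {
    "cfdna_diagnosis": Timepoint.DIAGNOSIS,
    "cfdna_followup": Timepoint.FOLLOWUP,
    "cfdna_progression": Timepoint.PROGRESSION,
}


def read_clinical(path) -> list[CaseRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "case_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must carry a case_id column")
    cases = []
    for i, row in df.iterrows():
        try:
            cfdna = {}
            for col, tp in _CLINICAL_TP_COLUMNS.items():
                val = _parse_optional_float(row.get(col))
                if val is not None:
                    cfdna[tp] = val
            age = _parse_optional_float(row.get("age"))
            cases.append(CaseRecord(
                case_id=str(row["case_id"]),
                sex=_s(row.get("sex")) or "unknown",
                age=age,
                stage=_s(row.get("stage")) or None,
                smoking=_s(row.get("smoking")) or None,
                histology=_s(row.get("histology")) or None,
                cfdna_ng_ml=cfdna,
                panel_size_mb=_parse_optional_float(row.get("panel_size_mb")) or 0.3,
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed clinical row at line {i + 2}: {exc}") from exc
    return cases


def write_clinical(cases: Sequence[CaseRecord], path) -> None:
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id, "sex": c.sex,
            "age": "" if c.age is None else repr(c.age),
            "stage": c.stage or "", "smoking": c.smoking or "",
            "histology": c.histology or "", "panel_size_mb": repr(c.panel_size_mb),
        }
        for col, tp in _CLINICAL_TP_COLUMNS.items():
            row[col] = repr(c.cfdna_ng_ml[tp]) if tp in c.cfdna_ng_ml else ""
        rows.append(row)
    cols = ["case_id", "sex", "age", "stage", "smoking", "histology",
            "panel_size_mb", *_CLINICAL_TP_COLUMNS]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_codon_scores(path) -> CodonScoreTable:
    """Read a codon activity-score TSV (gene, codon, score; one score per row).

    The hyperactivity threshold travels in a ``#threshold=<value>`` header
    comment line.
    """
    threshold = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#threshold="):
                threshold = float(line.strip().split("=", 1)[1])
            elif not line.startswith("#"):
                break
    if threshold is None:
        raise ValueError(f"{path}: missing '#threshold=' header line")
    df = pd.read_csv(path, sep="\t", comment="#")
    entries: dict[tuple[str, int], list[float]] = {}
    for _, row in df.iterrows():
        entries.setdefault((str(row["gene"]), int(row["codon"])), []).append(
            float(row["score"])
        )
    return CodonScoreTable(entries=entries, threshold=threshold)


def write_codon_scores(table: CodonScoreTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#threshold={table.threshold!r}\n")
        fh.write("gene\tcodon\tscore\n")
        for (gene, codon), scores in sorted(table.entries.items()):
            for s in scores:
                fh.write(f"{gene}\t{codon}\t{float(s)!r}\n")


# ---------------------------------------------------------------------------
# multi-model PDB trajectories (via MDAnalysis)


def write_trajectory_pdb(
    frames: np.ndarray,
    path,
    ligand_frames: Optional[np.ndarray] = None,
    chain: str = "A",
) -> None:
    """Write an (F, N, 3) alpha-carbon trajectory as a multi-model PDB.

    Protein residues are written as CA atoms (resname ALA); optional ligand
    atoms as resname LIG on chain L.
    """
    import MDAnalysis as mda

    frames = np.asarray(frames, dtype=float)
    n_res = frames.shape[1]
    n_lig = 0 if ligand_frames is None else ligand_frames.shape[1]
    n_atoms = n_res + n_lig
    u = mda.Universe.empty(
        n_atoms, n_residues=n_res + (1 if n_lig else 0),
        atom_resindex=list(range(n_res)) + [n_res] * n_lig,
        residue_segindex=[0] * (n_res + (1 if n_lig else 0)),
        trajectory=True,
    )
    u.add_TopologyAttr("name", ["CA"] * n_res + [f"L{i + 1}" for i in range(n_lig)])
    u.add_TopologyAttr("resname", ["ALA"] * n_res + (["LIG"] if n_lig else []))
    u.add_TopologyAttr("resid", list(range(1, n_res + 1)) + ([n_res + 1] if n_lig else []))
    u.add_TopologyAttr("chainIDs", [chain] * n_res + ["L"] * n_lig)
    u.add_TopologyAttr("elements", ["C"] * n_atoms)
    with mda.Writer(str(path), n_atoms, multiframe=True) as writer:
        for t in range(frames.shape[0]):
            coords = frames[t]
            if n_lig:
                coords = np.vstack([coords, ligand_frames[t]])
            u.atoms.positions = coords
            writer.write(u.atoms)


def read_trajectory_pdb(
    path,
    chain: Optional[str] = None,
    ligand_resname: str = "LIG",
) -> tuple[np.ndarray, Optional[np.ndarray], list[int]]:
    """Read a multi-model PDB into alpha-carbon (and optional ligand) frames.

    Selects atoms named CA with blank or 'A' altloc, optionally restricted
    to ``chain``; ligand atoms are selected by residue name. Returns
    ``(frames, ligand_frames_or_None, residue_ids)``.
    """
    import MDAnalysis as mda
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDB topology guessing chatter
        u = mda.Universe(str(path))
    sel = f"name CA and not resname {ligand_resname}"
    if chain:
        sel += f" and chainID {chain}"
    ca = u.select_atoms(sel)
    if hasattr(ca, "altLocs"):
        keep = np.isin(ca.altLocs, ["", "A"])
        ca = ca[keep]
    lig = u.select_atoms(f"resname {ligand_resname}")
    frames, lig_frames = [], []
    for _ in u.trajectory:
        frames.append(ca.positions.copy())
        if len(lig):
            lig_frames.append(lig.positions.copy())
    return (
        np.array(frames, dtype=float),
        np.array(lig_frames, dtype=float) if lig_frames else None,
        ca.resids.tolist(),
    )


def ensemble_to_pdbs(ens: TrajectoryEnsemble, directory, prefix: str = "") -> list[Path]:
    """Write each replica of an ensemble to ``<dir>/<prefix><cond>_repN.pdb``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rep in enumerate(ens.replicas):
        lig = ens.ligand_coords[i] if ens.ligand_coords is not None else None
        p = directory / f"{prefix}{ens.condition}_rep{i + 1}.pdb"
        write_trajectory_pdb(rep, p, ligand_frames=lig)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# dendrograms and distance matrices


def linkage_to_newick(linkage_matrix: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(linkage_matrix)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    pd.DataFrame(dist.matrix, index=dist.labels, columns=dist.labels).to_csv(
        path, sep="\t", float_format="%.17g", index_label="label"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return DistanceMatrix(labels=list(df.columns), matrix=df.to_numpy(dtype=float))
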