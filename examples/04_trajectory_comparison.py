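"""Comparative trajectory statistics for a wild-type vs mutant receptor.

Samples replica ensembles from a known elastic network whose mutant variant
softens the springs at one residue, then runs the comparison battery:
per-residue RMSF t-tests, Hausdorff/Ward replica clustering, GNM eigenvalue
bootstrap, and the ligand-stability t-test.
"""

import numpy as np

from ctdna_nrf2 import (
    TrajectorySpec,
    bootstrap_eigs,
    compare_rmsf,
    gen_gnm_trajectory,
    gnm_spectra_over_trajectory,
    hausdorff_matrix,
    ligand_rmsd_test,
    rmsf_profile,
    top_split_labels,
    ward_cluster,
)
from ctdna_nrf2.trajectory import pooled_nonzero_eigenvalues

spec = TrajectorySpec(n_residues=30, n_frames=500, n_replicas=5,
                      perturbation=0.05, n_ligand_atoms=6,
                      mutant_ligand_scale=2.0, seed=11)
ens, reference, kirchhoffs = gen_gnm_trajectory(spec)
print(f"sampled 2 x {spec.n_replicas} replicas of {spec.n_frames} frames, "
      f"{spec.n_residues} residues; mutation softens springs at residue "
      f"{spec.mutation_site} to {spec.perturbation}x")

# 1. per-residue RMSF differential test (Bonferroni-corrected)
prof = {c: np.array([rmsf_profile(f) for f in ens[c].replicas]) for c in ens}
cmp_res = compare_rmsf(prof["wt"], prof["mut"])
hits = np.flatnonzero(cmp_res.significant)
print(f"RMSF: {len(hits)} residues significant at alpha=0.05 after "
      f"Bonferroni -> indices {hits.tolist()}")

# 2. Hausdorff distances between replicas, Ward clustering
dm = hausdorff_matrix(ens["wt"].replicas + ens["mut"].replicas,
                      labels=[f"wt{i}" for i in range(5)] + [f"mut{i}" for i in range(5)])
split = top_split_labels(ward_cluster(dm))
print(f"Ward top split: {dict(zip(dm.labels, split.tolist()))}")

# 3. GNM eigenvalue bootstrap density overlap
pooled = {c: pooled_nonzero_eigenvalues(
    [s for f in ens[c].replicas for s in gnm_spectra_over_trajectory(f, stride=25)])
    for c in ens}
_, overlap = bootstrap_eigs(pooled, n_boot=500, seed=11)
print(f"bootstrapped eigenvalue density overlap wt/mut: {overlap:.3f}")

# 4. ligand stability
lig = ligand_rmsd_test(ens["wt"], ens["mut"])
print(f"ligand RMSD t-test: t = {lig.statistic:.2f}, p = {lig.p_two_sided:.3g}")
# Expect the mutated residue (and its contact neighbourhood) among the RMSF
# hits, a clean wt/mut top split, and significant ligand destabilisation
# (drift amplified 2x). The eigenvalue densities reflect the instantaneous
# contact topology of sampled frames, so a localised softening shifts them
# only slightly (overlap just below 1).
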