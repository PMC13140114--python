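"""Superposition, RMSF statistics, Hausdorff/Ward geometry, GNM spectra and
ligand stability tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ctdna_nrf2.simulate import TrajectorySpec, gen_gnm_trajectory, helix_coords
from ctdna_nrf2.trajectory import (
    DistanceMatrix,
    TrajectoryEnsemble,
    bootstrap_eigs,
    build_gnm,
    compare_rmsf,
    directed_hausdorff,
    eig_spectrum,
    gnm_spectra_over_trajectory,
    hausdorff_matrix,
    kabsch_superpose,
    ligand_rmsd_test,
    rmsf_profile,
    top_split_labels,
    ward_cluster,
)

rng = np.random.default_rng(101)


# -- Kabsch superposition ----------------------------------------------------


def test_kabsch_identity_and_rigid_invariance():
    ref = rng.normal(size=(10, 3))
    _, rmsd = kabsch_superpose(ref, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    rot = Rotation.random(random_state=7).as_matrix()
    moved = ref @ rot.T + np.array([5.0, -3.0, 2.0])
    coords, rmsd = kabsch_superpose(moved, ref)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(coords, ref, atol=1e-9)


def test_kabsch_beats_brute_force_rotation_grid():
    """The closed-form optimum is never worse than a dense rotation search."""
    ref = rng.normal(size=(4, 3))
    mobile = ref @ Rotation.random(random_state=11).as_matrix().T \
        + rng.normal(scale=0.3, size=(4, 3))
    _, rmsd = kabsch_superpose(mobile, ref)
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    grid = Rotation.create_group("O")  # octahedral rotations, coarse cover
    candidates = [Rotation.random(random_state=s) for s in range(300)]
    best = min(
        np.sqrt(np.mean(np.sum((mob_c @ r.as_matrix().T - ref_c) ** 2, axis=1)))
        for r in list(grid) + candidates
    )
    assert rmsd <= best + 1e-12


def test_kabsch_rotation_is_proper_even_for_mirrored_input():
    ref = rng.normal(size=(6, 3))
    mirrored = ref * np.array([-1.0, 1.0, 1.0])
    coords, rmsd = kabsch_superpose(mirrored, ref)
    assert rmsd > 0.0  # a reflection must not be used to undo the mirror


def test_kabsch_shape_errors():
    with pytest.raises(ValueError):
        kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(4, 3)))
    with pytest.raises(ValueError):
        kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


# -- RMSF --------------------------------------------------------------------


def test_rmsf_constant_trajectory_is_zero():
    frames = np.repeat(helix_coords(12)[None], 5, axis=0)
    assert np.allclose(rmsf_profile(frames), 0.0, atol=1e-12)


def test_rmsf_homogeneity():
    base = helix_coords(15)
    disp = rng.normal(size=(50, 15, 3))
    r1 = rmsf_profile(base[None] + disp, superpose=False)
    r2 = rmsf_profile(base[None] + 2 * disp, superpose=False)
    assert np.allclose(r2, 2 * r1, rtol=1e-12)


def test_rmsf_iid_gaussian_limit():
    """i.i.d. unit-variance displacements per coordinate give RMSF -> sqrt(3)."""
    frames = rng.standard_normal((2000, 150, 3))
    prof = rmsf_profile(frames)
    assert prof.mean() == pytest.approx(np.sqrt(3.0), rel=0.02)


def test_rmsf_requires_multiple_frames():
    with pytest.raises(ValueError):
        rmsf_profile(np.zeros((1, 5, 3)))


def test_compare_rmsf_single_residue_bonferroni_factor_one():
    a = np.array([[1.0], [1.2], [0.9]])
    b = np.array([[1.6], [1.8], [1.5]])
    res = compare_rmsf(a, b)
    assert res.p_adj[0] == pytest.approx(res.p_raw[0])


def test_compare_rmsf_detects_inflated_residue():
    spec = TrajectorySpec(n_residues=20, n_frames=2000, n_replicas=5,
                          perturbation=0.1, seed=13)
    ens, _, _ = gen_gnm_trajectory(spec)
    pa = np.array([rmsf_profile(f) for f in ens["wt"].replicas])
    pb = np.array([rmsf_profile(f) for f in ens["mut"].replicas])
    res = compare_rmsf(pa, pb)
    assert res.significant[spec.mutation_site]


def test_compare_rmsf_degenerate_zero_variance():
    same = np.ones((3, 4))
    res = compare_rmsf(same, same)
    assert np.all(res.p_raw == 1.0) and res.degenerate.all()
    shifted = np.full((3, 4), 2.0)
    res2 = compare_rmsf(same, shifted)
    assert np.all(res2.p_raw == 0.0)


# -- Hausdorff geometry ------------------------------------------------------


def test_directed_hausdorff_by_inspection():
    a = np.zeros((1, 1, 3))
    b = np.array([[[3.0, 0, 0]], [[4.0, 0, 0]]])
    assert directed_hausdorff(a, a) == 0.0
    assert directed_hausdorff(a, b) == pytest.approx(3.0)
    assert directed_hausdorff(b, a) == pytest.approx(4.0)
    with pytest.raises(ValueError):
        directed_hausdorff(np.zeros((0, 1, 3)), b)


def brute_hausdorff(a, b):
    def frame_rmsd(p, q):
        return np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1)))

    return max(min(frame_rmsd(p, q) for q in b) for p in a)


def test_directed_hausdorff_matches_double_loop_oracle():
    for seed in range(5):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=(5, 7, 3)), r.normal(size=(5, 7, 3))
        assert directed_hausdorff(a, b) == pytest.approx(
            brute_hausdorff(a, b), abs=1e-12)


def test_hausdorff_matrix_properties():
    reps = [rng.normal(size=(6, 8, 3)) for _ in range(4)]
    reps.append(reps[0].copy())  # identical replica pair
    dm = hausdorff_matrix(reps)
    m = dm.matrix
    assert np.allclose(m, m.T) and np.all(np.diag(m) == 0) and np.all(m >= 0)
    assert m[0, 4] == pytest.approx(0.0, abs=1e-6)  # superposition round-off
    # element-wise oracle on the globally superposed frames
    from ctdna_nrf2.trajectory import _kabsch_batch

    aligned = [_kabsch_batch(r, reps[0][0])[0] for r in reps]
    for i in range(5):
        for j in range(i + 1, 5):
            expected = max(brute_hausdorff(aligned[i], aligned[j]),
                           brute_hausdorff(aligned[j], aligned[i]))
            # sqrt of the expanded quadratic loses half the digits near zero
            assert m[i, j] == pytest.approx(expected, abs=1e-7)


def test_hausdorff_matrix_permutation_relabels_consistently():
    reps = [rng.normal(size=(4, 6, 3)) for _ in range(3)]
    ref = reps[0][0]
    d1 = hausdorff_matrix(reps, labels=list("abc"), reference=ref).matrix
    perm = [2, 0, 1]
    d2 = hausdorff_matrix([reps[i] for i in perm],
                          labels=[list("abc")[i] for i in perm],
                          reference=ref).matrix
    assert np.allclose(d2, d1[np.ix_(perm, perm)])


# -- Ward clustering ---------------------------------------------------------


def test_ward_two_tight_pairs_split_at_top():
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    d = np.abs(pts[:, None] - pts[None, :])
    link = ward_cluster(DistanceMatrix(labels=list("abcd"), matrix=d))
    labels = top_split_labels(link)
    assert labels[0] == labels[1] != labels[2] == labels[3]
    assert np.all(np.diff(link[:, 2]) >= 0)  # nondecreasing merge heights


def test_ward_duplicate_point_merges_first_at_zero_height():
    pts = np.array([0.0, 0.0, 5.0, 9.0])
    d = np.abs(pts[:, None] - pts[None, :])
    link = ward_cluster(DistanceMatrix(labels=list("abcd"), matrix=d))
    assert sorted(link[0, :2].astype(int).tolist()) == [0, 1]
    assert link[0, 2] == 0.0


def test_ward_needs_two_items():
    with pytest.raises(ValueError):
        ward_cluster(DistanceMatrix(labels=["a"], matrix=np.zeros((1, 1))))


# -- Gaussian network model --------------------------------------------------


def test_gnm_three_residue_chain_spectrum():
    coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0.0]])
    spec = eig_spectrum(build_gnm(coords, cutoff=7.0, gamma=1.0))
    assert np.allclose(spec.eigenvalues, [0.0, 1.0, 3.0])
    assert spec.n_zero_modes == 1


def test_gnm_triangle_and_gamma_scaling():
    side = 4.0
    coords = side * np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    for gamma in (1.0, 2.5):
        spec = eig_spectrum(build_gnm(coords, cutoff=7.0, gamma=gamma))
        assert np.allclose(spec.eigenvalues, [0.0, 3 * gamma, 3 * gamma])


def test_gnm_below_cutoff_gives_empty_network():
    coords = np.array([[0, 0, 0], [50.0, 0, 0], [0, 50.0, 0]])
    model = build_gnm(coords, cutoff=7.0)
    assert np.all(model.matrix == 0)
    assert eig_spectrum(model).n_zero_modes == 3
    with pytest.raises(ValueError):
        build_gnm(coords, cutoff=0.0)


def test_gnm_zero_modes_count_connected_components():
    import networkx as nx

    for seed in range(5):
        r = np.random.default_rng(seed)
        coords = r.uniform(0, 25, size=(20, 3))
        model = build_gnm(coords, cutoff=7.0)
        vals = np.linalg.eigvalsh(model.matrix)
        assert vals.min() > -1e-9  # positive semidefinite
        g = nx.from_numpy_array((model.matrix != 0) & ~np.eye(20, dtype=bool))
        assert eig_spectrum(model).n_zero_modes == nx.number_connected_components(g)


def test_gnm_spectra_over_trajectory_strides():
    frames = np.repeat(helix_coords(10)[None], 8, axis=0)  # rigid trajectory
    spectra = gnm_spectra_over_trajectory(frames, stride=2)
    assert len(spectra) == 4
    for s in spectra[1:]:
        assert np.allclose(s.eigenvalues, spectra[0].eigenvalues)
    assert len(gnm_spectra_over_trajectory(frames, stride=8)) == 1
    with pytest.raises(ValueError):
        gnm_spectra_over_trajectory(frames, stride=0)


# -- bootstrap densities -----------------------------------------------------


def test_bootstrap_deterministic_given_seed():
    pooled = {"wt": rng.gamma(2, 1, 200), "mut": rng.gamma(2.2, 1, 200)}
    d1, o1 = bootstrap_eigs(pooled, n_boot=50, seed=42)
    d2, o2 = bootstrap_eigs(pooled, n_boot=50, seed=42)
    assert o1 == o2
    for c in pooled:
        assert np.array_equal(d1[c].density, d2[c].density)
    _, o3 = bootstrap_eigs(pooled, n_boot=50, seed=43)
    assert o3 != o1  # different stream actually used


def test_bootstrap_overlap_extremes():
    base = rng.gamma(2, 1, 300)
    _, same = bootstrap_eigs({"wt": base, "mut": base.copy()}, n_boot=100, seed=1)
    assert same >= 0.95
    _, disjoint = bootstrap_eigs({"wt": base, "mut": base + 1000.0},
                                 n_boot=50, seed=1)
    assert disjoint == pytest.approx(0.0, abs=1e-6)


def test_bootstrap_densities_normalised_and_errors():
    pooled = {"wt": rng.gamma(2, 1, 100), "mut": rng.gamma(2, 1, 100)}
    dens, _ = bootstrap_eigs(pooled, n_boot=20, seed=3)
    for d in dens.values():
        assert np.trapezoid(d.density, d.grid) == pytest.approx(1.0, abs=1e-3)
    with pytest.raises(ValueError):
        bootstrap_eigs(pooled, n_boot=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_eigs({"wt": np.ones(5), "mut": pooled["mut"]}, n_boot=5, seed=1)


# -- ligand stability --------------------------------------------------------


def _ligand_ensembles(scale_mut=1.0, seed=0, n_frames=100):
    wt_spec = TrajectorySpec(n_residues=15, n_frames=n_frames, n_replicas=4,
                             n_ligand_atoms=5, mutant_ligand_scale=scale_mut,
                             seed=seed)
    ens, _, _ = gen_gnm_trajectory(wt_spec)
    return ens


def test_ligand_rmsd_requires_ligand():
    ens = _ligand_ensembles()
    bare = TrajectoryEnsemble(condition="wt", replicas=ens["wt"].replicas,
                              residue_ids=ens["wt"].residue_ids)
    with pytest.raises(ValueError):
        ligand_rmsd_test(bare, ens["mut"])


def test_ligand_rmsd_identical_dynamics_degenerate():
    ens = _ligand_ensembles()
    res = ligand_rmsd_test(ens["wt"], ens["wt"])
    assert res.p_two_sided == 1.0


def test_ligand_rmsd_power_against_drift_amplification():
    rejected = 0
    for seed in range(10):
        ens = _ligand_ensembles(scale_mut=5.0, seed=100 + seed)
        rejected += ligand_rmsd_test(ens["wt"], ens["mut"]).p_two_sided < 0.05
    assert rejected >= 9


def test_ligand_rmsd_null_level():
    ps = []
    for seed in range(40):
        ens = _ligand_ensembles(scale_mut=1.0, seed=200 + seed, n_frames=50)
        ps.append(ligand_rmsd_test(ens["wt"], ens["mut"]).p_two_sided)
    assert np.mean(np.array(ps) < 0.05) <= 0.125  # ~level alpha, MC slack
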