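"""Comparative statistics on MD trajectory ensembles of wild-type vs mutant
protein structures.

Works on alpha-carbon coordinate ensembles (several independent replicas per
condition): Kabsch superposition, per-residue RMSF with pooled-variance
t-tests and Bonferroni correction, directed Hausdorff distances between
trajectories under a frame-RMSD metric with Ward clustering of the replica
distance matrix, Gaussian-network (GNM) Kirchhoff eigenspectra with
non-parametric bootstrap density comparison, and ligand RMSD stability
testing. These are the ingredients for deciding whether a point mutation
shifts a receptor's conformational landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import TestResult

__all__ = [
    "TrajectoryEnsemble",
    "KirchhoffModel",
    "EigSpectrum",
    "RMSFComparison",
    "DistanceMatrix",
    "BootstrapDensity",
    "kabsch_superpose",
    "rmsf_profile",
    "compare_rmsf",
    "directed_hausdorff",
    "hausdorff_matrix",
    "ward_cluster",
    "top_split_labels",
    "build_gnm",
    "eig_spectrum",
    "gnm_spectra_over_trajectory",
    "bootstrap_eigs",
    "ligand_rmsd_test",
]


@dataclass
class TrajectoryEnsemble:
    """Condition-labelled set of replica trajectories.

    Each replica is an (F, N, 3) array of alpha-carbon coordinates in
    Angstrom; ``ligand_coords`` optionally carries per-replica (F, M, 3)
    ligand atom coordinates recorded in the same laboratory frame.
    """

    condition: str
    replicas: list[np.ndarray]
    residue_ids: Sequence[int]
    ligand_coords: Optional[list[np.ndarray]] = None

    def __post_init__(self) -> None:
        self.replicas = [np.asarray(r, dtype=float) for r in self.replicas]
        n = len(self.residue_ids)
        for r in self.replicas:
            if r.ndim != 3 or r.shape[1] != n or r.shape[2] != 3:
                raise ValueError(f"replica shape {r.shape} != (F, {n}, 3)")
            if r.shape[0] < 2:
                raise ValueError("each replica needs at least 2 frames")
            if not np.isfinite(r).all():
                raise ValueError("coordinates must be finite")
        if self.ligand_coords is not None:
            self.ligand_coords = [np.asarray(c, dtype=float) for c in self.ligand_coords]
            if len(self.ligand_coords) != len(self.replicas):
                raise ValueError("one ligand trajectory per replica required")
            for rep, lig in zip(self.replicas, self.ligand_coords):
                if lig.shape[0] != rep.shape[0] or lig.shape[2] != 3:
                    raise ValueError("ligand frames must align with protein frames")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


# ---------------------------------------------------------------------------
# superposition and RMSF


def _kabsch_batch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotations of a stack of frames onto one reference.

    ``mobile`` is (F, N, 3), ``reference`` (N, 3). Returns the superposed
    stack and per-frame RMSDs. Vectorised over frames via stacked SVDs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    single = mobile.ndim == 2
    if single:
        mobile = mobile[None]
    if mobile.shape[1:] != reference.shape:
        raise ValueError(
            f"atom count mismatch: mobile {mobile.shape[1:]} vs reference {reference.shape}"
        )
    ref_c = reference - reference.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=1, keepdims=True)
    h = np.einsum("fni,nj->fij", mob_c, ref_c)  # covariance per frame
    u, s, vt = np.linalg.svd(h)
    if np.any(s[:, -1] < 1e-10 * np.maximum(s[:, 0], 1e-30)):
        warnings.warn("degenerate (near-collinear) point set in superposition",
                      RuntimeWarning, stacklevel=3)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    corr = np.repeat(np.eye(3)[None], len(mobile), axis=0)
    corr[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", np.transpose(vt, (0, 2, 1)), corr,
                    np.transpose(u, (0, 2, 1)))
    aligned = np.einsum("fij,fnj->fni", rot, mob_c) + reference.mean(axis=0)
    rmsd = np.sqrt(np.mean(np.sum((aligned - reference) ** 2, axis=2), axis=1))
    return (aligned[0], float(rmsd[0])) if single else (aligned, rmsd)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Superpose one conformation onto a reference by the Kabsch algorithm.

    Returns ``(coords, rmsd)`` where ``coords`` minimise RMSD to the
    reference over all proper rigid transforms (rotation determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    return _kabsch_batch(mobile, reference)


def rmsf_profile(frames: np.ndarray, superpose: bool = True) -> np.ndarray:
    """Per-residue root-mean-square fluctuation of one replica (Angstrom).

    Frames are first superposed to the replica's mean structure (two rounds
    of mean-then-superpose, the usual fixed-point shortcut); RMSF_i is then
    sqrt(mean_t |r_i(t) - <r_i>|^2).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("frames must be (F>=2, N, 3)")
    if superpose:
        for _ in range(2):
            mean = frames.mean(axis=0)
            frames, _rmsd = _kabsch_batch(frames, mean)
    mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


@dataclass
class RMSFComparison:
    """Per-residue RMSF differential test between two conditions."""

    residue_ids: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05
    degenerate: np.ndarray = field(default=None)  # zero pooled variance flags


def compare_rmsf(
    group_a: Sequence[np.ndarray],
    group_b: Sequence[np.ndarray],
    residue_ids: Optional[Sequence[int]] = None,
    alpha: float = 0.05,
) -> RMSFComparison:
    """Residue-wise two-sample t-test on per-replica RMSF profiles.

    ``group_a``/``group_b`` are per-replica RMSF vectors (one per replica,
    >= 2 replicas per condition). Pooled-variance (equal-variance Student)
    t-tests per residue, Bonferroni-corrected over all residues; a residue
    is significant when the adjusted p falls below ``alpha``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("per-replica RMSF profiles must share residue count")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 replicas per condition")
    n_res = a.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():  # zero pooled variance: p=1 if means agree else 0
        equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate] = np.where(equal_means[degenerate], 1.0, 0.0)
        t[degenerate & ~equal_means] = np.inf
    p_adj = np.minimum(1.0, p * n_res)
    return RMSFComparison(
        residue_ids=np.arange(n_res) if residue_ids is None else np.asarray(residue_ids),
        mean_a=a.mean(axis=0),
        mean_b=b.mean(axis=0),
        t=t,
        p_raw=p,
        p_adj=p_adj,
        significant=p_adj < alpha,
        alpha=alpha,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# trajectory geometry: Hausdorff distances and clustering


def _cross_rmsd(traj_a: np.ndarray, traj_b: np.ndarray) -> np.ndarray:
    """All-pairs frame RMSD matrix between two superposed trajectories."""
    fa = traj_a.reshape(traj_a.shape[0], -1)
    fb = traj_b.reshape(traj_b.shape[0], -1)
    n_atoms = traj_a.shape[1]
    sq = (
        np.sum(fa**2, axis=1)[:, None]
        + np.sum(fb**2, axis=1)[None, :]
        - 2.0 * fa @ fb.T
    )
    return np.sqrt(np.maximum(sq, 0.0) / n_atoms)


def directed_hausdorff(traj_a: np.ndarray, traj_b: np.ndarray) -> float:
    """Directed Hausdorff distance h(A->B) between two frame sets (Angstrom).

    Frames must already be superposed to one shared reference; the
    inter-frame metric is alpha-carbon RMSD without per-pair refitting.
    h(A->B) = max over frames a of min over frames b of RMSD(a, b).
    """
    traj_a = np.asarray(traj_a, dtype=float)
    traj_b = np.asarray(traj_b, dtype=float)
    if traj_a.size == 0 or traj_b.size == 0:
        raise ValueError("empty trajectory")
    return float(_cross_rmsd(traj_a, traj_b).min(axis=1).max())


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(m, m.T) or np.any(np.diag(m) != 0) or np.any(m < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, "
                             "zero-diagonal")
        self.matrix = m


def hausdorff_matrix(
    replicas: Sequence[np.ndarray],
    labels: Optional[Sequence[str]] = None,
    reference: Optional[np.ndarray] = None,
) -> DistanceMatrix:
    """Symmetrised Hausdorff distance matrix over replica trajectories.

    D(i, j) = max(h(i->j), h(j->i)). When ``reference`` is given (default:
    first frame of the first replica), every frame of every replica is
    first globally superposed to it so that inter-replica frame RMSDs are
    comparable.
    """
    if len(replicas) < 2:
        raise ValueError("need at least 2 replicas")
    if labels is None:
        labels = [f"rep{i}" for i in range(len(replicas))]
    if reference is None:
        reference = np.asarray(replicas[0], dtype=float)[0]
    aligned = [_kabsch_batch(np.asarray(r, dtype=float), reference)[0] for r in replicas]
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cross = _cross_rmsd(aligned[i], aligned[j])
            h_ij = cross.min(axis=1).max()
            h_ji = cross.min(axis=0).max()
            d[i, j] = d[j, i] = max(h_ij, h_ji)
    return DistanceMatrix(labels=list(labels), matrix=d)


def ward_cluster(dist: DistanceMatrix) -> np.ndarray:
    """Ward's hierarchical clustering of a precomputed distance matrix.

    Agglomerates under the Ward minimum-variance criterion via
    Lance-Williams updates on the squared distances (the ward.D2
    convention). Returns the standard 4-column linkage matrix; merge
    heights are nondecreasing.
    """
    if len(dist.labels) < 2:
        raise ValueError("clustering needs at least 2 items")
    return linkage(squareform(dist.matrix, checks=False), method="ward")


def top_split_labels(linkage_matrix: np.ndarray) -> np.ndarray:
    """Cluster labels (1/2) from cutting the dendrogram at its top split."""
    return fcluster(linkage_matrix, t=2, criterion="maxclust")


# ---------------------------------------------------------------------------
# Gaussian network model


@dataclass
class KirchhoffModel:
    """Distance-cutoff elastic-network Kirchhoff (graph Laplacian) matrix."""

    n: int
    cutoff: float
    gamma: float
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.n, self.n):
            raise ValueError("Kirchhoff matrix shape mismatch")
        self.matrix = m


@dataclass
class EigSpectrum:
    """Eigenvalue spectrum of a Kirchhoff matrix, ascending."""

    eigenvalues: np.ndarray
    n_zero_modes: int

    @property
    def nonzero(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero_modes:]


def build_gnm(coords: np.ndarray, cutoff: float = 7.0, gamma: float = 1.0) -> KirchhoffModel:
    """Build the GNM Kirchhoff matrix from alpha-carbon coordinates.

    Residues i != j within ``cutoff`` Angstrom are connected by a spring of
    constant ``gamma``: Gamma_ij = -gamma, and Gamma_ii holds minus the row
    sum. Defaults (7.0 A, gamma 1) are the standard alpha-carbon GNM
    settings.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (N>=2, 3)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    contact = (dist <= cutoff) & (dist > 0)
    k = np.where(contact, -gamma, 0.0)
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    return KirchhoffModel(n=len(coords), cutoff=cutoff, gamma=gamma, matrix=k)


def eig_spectrum(model: KirchhoffModel, zero_tol: float = 1e-8) -> EigSpectrum:
    """Ascending eigenvalues; zero modes detected at ``zero_tol`` x lambda_max."""
    vals = np.linalg.eigvalsh(model.matrix)
    lam_max = max(vals[-1], 0.0)
    tol = zero_tol * lam_max if lam_max > 0 else zero_tol
    n_zero = int(np.sum(np.abs(vals) <= tol))
    vals = np.where(np.abs(vals) <= tol, 0.0, vals)
    return EigSpectrum(eigenvalues=vals, n_zero_modes=n_zero)


def gnm_spectra_over_trajectory(
    frames: np.ndarray,
    stride: int = 100,
    cutoff: float = 7.0,
    gamma: float = 1.0,
) -> list[EigSpectrum]:
    """One Kirchhoff eigenspectrum per sampled frame of a replica.

    Frames are sampled every ``stride`` steps starting from the first; each
    sampled conformation's contact topology defines its own Kirchhoff
    matrix. Zero modes are excluded from downstream pooled spectra.
    """
    frames = np.asarray(frames, dtype=float)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return [
        eig_spectrum(build_gnm(frames[i], cutoff=cutoff, gamma=gamma))
        for i in range(0, frames.shape[0], stride)
    ]


def pooled_nonzero_eigenvalues(spectra: Sequence[EigSpectrum]) -> np.ndarray:
    """Concatenate non-zero-mode eigenvalues over sampled spectra."""
    return np.concatenate([s.nonzero for s in spectra]) if spectra else np.array([])


# ---------------------------------------------------------------------------
# bootstrap density comparison


@dataclass
class BootstrapDensity:
    """Bootstrap-averaged eigenvalue density of one condition on a grid."""

    condition: str
    n_boot: int
    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        area = np.trapezoid(self.density, self.grid)
        if abs(area - 1.0) > 1e-3:
            raise ValueError(f"density must integrate to 1, got {area}")


def _binned_kde(draws: np.ndarray, edges: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian KDE evaluated by histogram binning + kernel convolution."""
    counts, _ = np.histogram(draws, bins=edges)
    dx = edges[1] - edges[0]
    half = int(np.ceil(4 * bandwidth / dx))
    xs = np.arange(-half, half + 1) * dx
    kernel = np.exp(-0.5 * (xs / bandwidth) ** 2)
    kernel /= kernel.sum()
    dens = np.convolve(counts / (len(draws) * dx), kernel, mode="same")
    return dens


def bootstrap_eigs(
    pooled: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
    grid_size: int = 512,
) -> tuple[dict[str, BootstrapDensity], float]:
    """Non-parametric bootstrap of pooled eigenvalue spectra per condition.

    Each of ``n_boot`` iterations resamples a condition's pooled eigenvalues
    with replacement at the original size and contributes a Gaussian kernel
    density (Scott bandwidth, computed once from the original sample) on a
    grid shared across conditions; per-condition densities are the bootstrap
    averages. Returns the densities and the overlap coefficient
    integral(min over conditions) between the two conditions (1 when more
    than two are given is not supported). Deterministic given ``seed``:
    each condition draws from an independent substream.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(pooled) != 2:
        raise ValueError("exactly two conditions required for the overlap")
    arrays = {c: np.asarray(v, dtype=float).ravel() for c, v in pooled.items()}
    for c, v in arrays.items():
        if v.size < 10:
            raise ValueError(f"condition {c!r} needs >= 10 pooled eigenvalues")
    lo = min(v.min() for v in arrays.values())
    hi = max(v.max() for v in arrays.values())
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    # widen so kernel mass is captured at the edges
    bws = {c: max(v.std(ddof=1), 1e-9 * span, 1e-12) * v.size ** (-1 / 5)
           for c, v in arrays.items()}
    pad = 4 * max(bws.values())
    edges = np.linspace(lo - pad, hi + pad, grid_size + 1)
    grid = 0.5 * (edges[:-1] + edges[1:])
    seeds = np.random.SeedSequence(seed).spawn(len(arrays))
    densities: dict[str, BootstrapDensity] = {}
    for (cond, vals), ss in zip(sorted(arrays.items()), seeds):
        rng = np.random.default_rng(ss)
        acc = np.zeros(grid_size)
        for _ in range(n_boot):
            resample = rng.choice(vals, size=vals.size, replace=True)
            acc += _binned_kde(resample, edges, bws[cond])
        dens = acc / n_boot
        dens /= np.trapezoid(dens, grid)  # renormalise residual edge loss
        densities[cond] = BootstrapDensity(condition=cond, n_boot=n_boot,
                                           grid=grid, density=dens)
    f1, f2 = (densities[c].density for c in sorted(densities))
    overlap = float(np.trapezoid(np.minimum(f1, f2), grid))
    return densities, min(max(overlap, 0.0), 1.0)


# ---------------------------------------------------------------------------
# ligand stability


def _replica_ligand_rmsd(protein: np.ndarray, ligand: np.ndarray) -> float:
    """Mean ligand RMSD to its first-frame pose, in the protein frame.

    Each frame's protein coordinates are superposed to the replica's first
    frame and the same rigid transform is applied to the ligand before
    computing RMSD to the first-frame ligand pose.
    """
    ref = protein[0]
    ref_centroid = ref.mean(axis=0)
    prot_c = protein - protein.mean(axis=1, keepdims=True)
    h = np.einsum("fni,nj->fij", prot_c, ref - ref_centroid)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(vt, (0, 2, 1)),
                                  np.transpose(u, (0, 2, 1))))
    corr = np.repeat(np.eye(3)[None], len(protein), axis=0)
    corr[:, 2, 2] = np.sign(det)
    rot = np.einsum("fij,fjk,fkl->fil", np.transpose(vt, (0, 2, 1)), corr,
                    np.transpose(u, (0, 2, 1)))
    lig_c = ligand - protein.mean(axis=1, keepdims=True)
    lig_aligned = np.einsum("fij,fmj->fmi", rot, lig_c) + ref_centroid
    rmsd = np.sqrt(np.mean(np.sum((lig_aligned - lig_aligned[0]) ** 2, axis=2), axis=1))
    return float(rmsd.mean())


def ligand_rmsd_test(ens_a: TrajectoryEnsemble, ens_b: TrajectoryEnsemble) -> TestResult:
    """Equal-variance t-test on per-replica mean ligand RMSD between conditions.

    Per replica, the ligand's RMSD to its first-frame pose (after
    protein-frame superposition) is averaged over frames; the per-replica
    means of the two conditions are compared with a pooled-variance Student
    t-test. Raises when either ensemble lacks ligand coordinates.
    """
    for ens in (ens_a, ens_b):
        if ens.ligand_coords is None:
            raise ValueError(f"ensemble {ens.condition!r} has no ligand coordinates")
    means_a = [_replica_ligand_rmsd(p, l) for p, l in zip(ens_a.replicas, ens_a.ligand_coords)]
    means_b = [_replica_ligand_rmsd(p, l) for p, l in zip(ens_b.replicas, ens_b.ligand_coords)]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(means_a, means_b, equal_var=True)
    if not np.isfinite(p):  # degenerate: zero pooled variance
        equal = np.isclose(np.mean(means_a), np.mean(means_b))
        t, p = (0.0, 1.0) if equal else (np.inf, 0.0)
    return TestResult(
        statistic=float(t),
        p_two_sided=float(p),
        effect=float(np.mean(means_a) - np.mean(means_b)),
        effect_name="mean_ligand_rmsd_difference",
    )
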