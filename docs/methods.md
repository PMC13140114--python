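# Methods

This note records the models, conventions and design choices behind
`ctdna_nrf2`, in the spirit of a statistical-methods appendix: what each
stage assumes, which parameters matter, what the synthetic generators do and
do not emulate, and where numerical choices were genuinely open.

## Variant triage

The triage cascade assumes its input is the *output* of a somatic caller on
targeted cfDNA sequencing, already annotated (FATHMM score, ClinVar class,
population allele frequency, panel-of-normals membership as columns). It
performs no calling, realignment or annotation itself.

Order of operations: (1) remove panel-of-normals variants; (2) tier each
record — *oncogenic evidence* when FATHMM >= `fathmm_threshold` (default
0.99, inclusive) or the ClinVar class is oncogenic/likely-oncogenic/
drug-response, otherwise *VUS*; (3) retain VUS only with >= 5 deduplicated
supporting reads and VAF < 0.45 (heterozygous germline calls cluster near
0.5), retain oncogenic-evidence records with >= 2 reads and no VAF cap (a
truncal driver can legitimately exceed 0.45 in a high-tumor-fraction
sample); (4) prune records with population allele frequency above 1e-5.
Silent variants pass the same support filters and are *retained* — they
count toward the mutational burden — but are excluded from pathway
classification. A per-strand minimum (2 reads per strand) applies only when
strand counts are present, since many MAF dialects do not carry the split.

VAF is stored internally as a fraction in [0, 1]; percent-valued `VAF`
columns (as clinical tables often print) are detected and converted at read
time. Coordinates are 1-based inclusive (MAF convention).

NRF2 classification is total on filtered pathway-gene variants: every
NFE2L2/KEAP1/CUL3 record receives exactly one call. The Neh2 window
defaults to codons 1–86 (the domain boundary is configurable because domain
definitions name the domain, not exact coordinates). The codon activity
score aggregates by *mean* (a median switch exists). A scored codon at or
below the hyperactivity threshold maps to *putative activating (unknown)*
with an explanatory rationale — the call enumeration has no dedicated
"scored non-activating" value, and in practice matched codons of
pathway-mutated tumors score high. Case positivity counts *activating*,
*likely activating* and, by default, *putative activating (unknown)*
variants (novel unscored KEAP1 missense variants are retained as putative
drivers pending functional evidence); a case whose only pathway variant is
*likely LOF* is negative. Variants refuted by external (e.g. wet-lab)
evidence can be excluded per (gene, protein change) without changing the
rules.

## Burden metrics

bTMB is reported both as a raw count (comparable to panel mutation counts
in public cohorts) and per megabase of panel territory, since normalisation
conventions differ across studies; the pipeline emits counts on both the
post-panel-of-normals "detected" set and the fully filtered set. ctDNA
concentration multiplies the cfDNA concentration by the mean VAF over
pathogenic/likely-pathogenic variants (post-filter); it is 0 for a measured
case with no pathogenic variants and explicitly *absent* (not 0) when the
cfDNA measurement is missing. Recurrence matches on (gene, HGVS-p) with a
(chrom, pos, ref, alt) fallback, HGVS-p being the unit in which clinical
mutation tables report variants.

## Cohort statistics

Fisher's exact test is two-sided by minimum-likelihood summation (the
convention of the dominant statistical packages), with the sample odds
ratio ad/bc as the effect (infinite on zero cells; a conditional-MLE OR is
deliberately not substituted). Pairwise co-occurrence tests all unordered
gene pairs of a boolean case x gene matrix of pathogenic calls and reports
*raw* p-values (a Benjamini–Hochberg column is optional), matching common
co-mutation-analysis practice. Mann–Whitney U uses exact enumeration for
combined samples of <= 12 tie-free observations and the tie- and
continuity-corrected normal approximation otherwise. ROC analysis uses all
distinct thresholds, trapezoidal AUC (equal to U/(n1·n0) with midrank
ties), and resolves Youden-J ties toward the *lowest* threshold — on an
ordinal marker this maximises sensitivity and reproduces "score >= 2"-style
cut-points.

## Trajectory comparison

All trajectory statistics operate on alpha-carbon coordinates only.

*Superposition.* Kabsch via SVD with a determinant correction so the
rotation is always proper (a mirrored conformation is never "fixed" by a
reflection); batched over frames with stacked SVDs. RMSF superposes frames
to the replica mean with two mean–superpose rounds (the usual fixed-point
shortcut) before computing sqrt(mean |r_i(t) − <r_i>|²).

*RMSF differential testing.* The unit of replication is the *replica*, not
the frame: per residue, an equal-variance two-sample t-test on per-replica
RMSF values (n = replicas per condition), Bonferroni-corrected over
residues at alpha = 0.05. Zero pooled variance is degenerate and flagged
(p = 1 when means agree, 0 otherwise).

*Hausdorff/Ward.* Every frame of every replica is globally superposed once
to a single reference (first frame of the first replica); the inter-frame
metric is plain RMSD without per-pair refitting — O(F²) per pair and
standard path-similarity practice. Replica distances are symmetrised as
max(h(i→j), h(j→i)), satisfying identity and symmetry (the triangle
inequality is not asserted). Clustering uses the Ward criterion via
Lance–Williams updates on squared distances (ward.D2 convention, scipy's
`linkage(..., "ward")` on the condensed matrix). The cross-frame RMSD is
evaluated through the expanded quadratic form, which halves the available
precision near zero (~1e-8 absolute on coincident frames) — irrelevant at
physical distances.

*Gaussian network model.* Kirchhoff matrix with the field-standard
alpha-carbon defaults, cutoff 7.0 Å and uniform spring constant gamma = 1;
zero modes are detected at a relative tolerance of 1e-8 x lambda_max and
equal the number of connected components of the contact graph. Spectra are
computed per sampled frame (stride 100 by default) — computing them per
replica mean structure is an alternative mode the pipeline does not
currently expose, and per-frame sampling is what makes the pooled spectrum
sensitive to conformational redistribution.

*Eigenvalue bootstrap.* Each of 1000 iterations resamples a condition's
pooled non-zero eigenvalues with replacement at original size. The density
estimate is a *binned* Gaussian KDE: a histogram on a grid shared across
conditions, convolved with a Gaussian kernel of Scott bandwidth computed
once from the original sample; per-condition densities are bootstrap
averages, renormalised to unit area on the grid (tolerance 1e-3). A binned
KDE is used because an exact pairwise KDE over 10^3 iterations of 10^4
pooled eigenvalues costs O(10^9) kernel evaluations for no statistical
gain. Conditions draw from independent substreams of the user seed, so
results are bit-reproducible. The summary statistic is the overlap
coefficient ∫ min(f_wt, f_mut) in [0, 1].

*Ligand stability.* Per replica, each frame's protein is superposed to the
replica's first frame, the transform is applied to the ligand, and ligand
RMSD to the first-frame pose is averaged over frames; condition means are
compared with an equal-variance t-test across replicas.

## Synthetic generators

*Cohort.* 73 cases by default with 18 % NRF2-pathway prevalence; pathway
variants are drawn from a consequence mix echoing observed cohorts (scored
hotspot missense, unscored novel missense, repressor truncations) with
oncogenic annotation (FATHMM ~ U(0.992, 1) or a likely-oncogenic ClinVar
class). SMARCA4 mutations couple to NRF2 status through a configurable odds
ratio (default 8) on a base rate of 0.08. Somatic VAFs follow Beta(2, 40)
(median ~4 %, mostly 1–30 %) floored at 1.2 % — just above a 1 % reporting
limit; supporting reads are Binomial(depth, VAF) at ~1000x (SD 200,
truncated at 400) deduplicated depth. Contaminants carry their telltale
signatures: PCR artifacts with 1–4 supporting reads (Poisson mean 3 per
case, half already in the panel of normals), germline leakage at
Beta(200, 200) VAF (~0.5) with population frequencies 1e-4–1e-2 (Poisson
mean 1 per case). Background somatic passengers (Poisson mean 4 per case,
20 % silent) populate common NSCLC driver genes. cfDNA concentrations are
log-normal (median ~13 ng/ml, sigma 1.1 — right-skewed with a heavy tail,
as plasma measurements are). A quarter of cases get a follow-up sample in
which each somatic variant persists with probability 0.5.

What the generator does *not* emulate: sequencing reads themselves, subclonal
structure/CCF, copy number, tumor-fraction biology linking VAF to stage, or
errors in the annotation columns beyond a 2 % germline ClinVar
misannotation rate (which population-frequency pruning still removes — so
near-perfect triage specificity on this generator shows the *stated rules*
are implemented correctly, not that real cohorts would triage this
cleanly).

*Trajectories.* Frames are equilibrium draws from the Gaussian network
itself: reference + displacement with per-axis covariance
kT·pinv(Kirchhoff), sampled over non-zero modes (centre of mass pinned), on
an ideal alpha-helix reference (connected at the 7 Å cutoff). Defaults
kT = 0.6, gamma = 1 give ~1 Å fluctuations. The mutant rescales springs
incident to the mutation site (default residue N/2) by `perturbation`.
Ligand atoms follow a discrete Ornstein–Uhlenbeck drift about their initial
ring pose (theta = 0.1, sigma = 0.3 per step), with the mutant's sigma
scaled by `mutant_ligand_scale`. Because sampling is exactly Gaussian with
a closed-form covariance, every downstream statistic has an analytic or
brute-force target; what passing tests show is correctness of the
statistics, not realism of force-field dynamics (no anisotropy,
anharmonicity, solvent or kinetics).

## Calibration of the simulation-based checks

Problem sizes were chosen to make the targeted effects measurable with
clean margins. RMSF site recovery uses the generator at 0.25x spring
softening, 5 replicas, 5000 frames (the softened site's variance rises
~4-fold; recovered in 10/10 pilot runs). The Ward/Hausdorff separation
check uses 0.05x softening at 200 frames: whole-chain frame-RMSD geometry
dilutes a single-residue change across the shared global modes, so a
stronger local perturbation is the regime where trajectory geometry — as
opposed to the per-residue RMSF test — separates conditions (100 % of pilot
reps; at 0.25x the landscapes overlap too much for geometric clustering,
which is itself an honest property of the metric). The null family-wise
error check runs 1000 generator replicates (20 residues, 100 frames,
5 v 5); its assertion carries a one-sided 95 % binomial Monte Carlo
allowance (~0.011) on top of alpha = 0.05 because the quantity is itself a
simulation estimate. Covariance recovery and the iid-RMSF limit use 10^4
frames, where the expected relative errors (~1 % Frobenius, ~0.7 % on mean
RMSF including the ~0.5 % superposition bias at N = 200) sit well inside
the 5 % and 1 % bands.

## Known limitations

- The filter cascade treats annotations as given; discordant or missing
  annotations degrade tiering (absent FATHMM and ClinVar means VUS).
- NRF2 calls for non-truncating variants depend entirely on the supplied
  codon score table; codons absent from it surface as "unknown" and are
  counted positive by default — set `include_unknown=False` for a
  conservative reading.
- Hausdorff distances are computed without per-pair refitting; ensembles
  whose replicas drift globally would need the (quadratically more
  expensive) refit variant.
- The eigenvalue bootstrap compares densities through a single overlap
  coefficient; it is a descriptive comparison, not a hypothesis test.
- Multi-model PDB is the only trajectory format read natively; convert
  binary formats upstream (MDAnalysis can resave DCD/XTC as PDB).
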