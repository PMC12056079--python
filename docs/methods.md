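# Methods

`fcpair` analyses paired resting-state fMRI-like data — two scans per
subject, one in a drug-naive state and one after sustained medication — at
three complementary levels: individual connections, subnetwork patterns,
and voxel-wise graph centrality. This note documents the models, the
defaults and why they were chosen, the synthetic data the package is
validated on, and the known limitations.

## First-level model

Each scan is a frames × channels matrix (26 ROI traces, or voxels on a 3D
grid) with six rigid-body motion parameters and mean white-matter (WM) and
CSF signals as nuisance regressors. Cleaning for ROI connectivity applies,
in order: discard of the first 4 frames (magnetisation equilibration),
high-pass at 0.01 Hz, regression of the motion parameters, regression of
WM/CSF, low-pass at 0.20 Hz, and standardisation to zero mean and unit
sample (n−1) SD. The centrality variant applies motion and WM/CSF
regression first and a single 0.01–0.2 Hz band-pass afterwards.

Numerical choices:

* **Filters** are zero-phase forward–backward second-order Butterworth
  sections, one per cutoff. The effective amplitude response is
  |H(f)|² = 1/(1 + (f/f_c)⁴) per edge, which the tests verify against the
  closed form. A high-pass always removes the DC component explicitly.
* **Regression** always includes an intercept (the convention is stated
  here because the stage order alone does not determine it); residuals are
  orthogonal to the regressors to ~1e−10. Rank-deficient designs are
  rejected with the offending columns named.
* **Standardisation** uses the sample (n−1) SD so that the dot product of
  standardised series equals the Pearson correlation.
* Connectivity is the raw Pearson r (26 × 26, 325 unique edges); Fisher-z
  is deliberately not applied anywhere downstream, matching how the
  correlation matrices are consumed by the permutation and classification
  stages.

## Medicated-scan selection

When a subject has several post-medication scans, one is chosen so the
cohort's treatment durations are maximally homogeneous subject to a
≥ 12-month floor: the assignment minimising the population (divide-by-n)
variance of selected durations. The optimiser exploits a structural fact:
in an optimal assignment with mean μ*, each subject's selected duration is
their eligible candidate nearest μ* (otherwise swapping reduces the sum of
squares about μ*, hence the variance). Sweeping all candidate-midpoint
intervals therefore visits every potentially optimal assignment; this is
exact and O(K²) in the total candidate count, unlike exhaustive product
enumeration, which is kept only as a brute-force oracle for tests. Ties are
broken by the lexicographically smallest scan-id vector. Summary statistics
use type-7 (linear-interpolation) quantiles; IQR = Q3 − Q1.

## Edge-wise inference: permutation GLM with nuisance covariates

Per edge, the within-subject contrast Y (medicated − naive, one value per
subject) follows Y = Xβ + Nγ + ε with X a column of ones (the mean
medication effect) and N the nuisance covariates: change in disease
duration, baseline age, gender (0/1, not standardised — least squares is
affine invariant). Because Y is not exchangeable under the null in the
presence of covariates, the null is built by the Freedman–Lane device: fit
the nuisance-only model, permute its residuals, add the fitted nuisance
signal back, refit the full model, and collect the refitted β̂ as the null
statistic. The observed statistic is likewise the full-model β̂ (the
nuisance-adjusted mean contrast), not a t-ratio. Two-sided p-values count
permuted |T_j| ≥ |T_0| with the +1/+1 correction, so p ≥ 1/(n_perm+1) and
exactness is preserved. Benjamini–Hochberg FDR adjusts across the 325
edges. One permutation operator per iteration is shared across edges
(standard whole-matrix practice; the marginal null per edge is unchanged).

**Calibration caveat.** With a non-pivotal statistic and free residual
shuffling, the permutation variance understates the sampling variance of β̂
at small n (by roughly a residual-degrees-of-freedom factor and a
mean-centring factor). At n = 29 with the covariate distributions used
here, the measured per-edge type-I error at α = 0.05 is ≈ 0.062 (Monte
Carlo over 200 null cohorts; ≈ 0.060 for Gaussian responses). The package
implements the scheme as stated because the downstream conclusions rest on
FDR-corrected decisions, where this mild inflation is immaterial; a
sign-flipping variant (`scheme="sign_flip"`), the usual choice for
one-sample designs, is available behind a flag and calibrates to ≈ 0.05.

## Network-level classification

The three subnetworks (cerebellum, basal ganglia + thalamus, motor cortex;
hemispheres merged) define six edge masks — three within-network blocks and
three between-network blocks — that partition the 325 edges. Per mask, each
scan's edge values form a feature vector. The classifier pipeline per
leave-one-subject-out fold (both scans of the held-out subject removed) is:
standardise features on the training fold, project onto principal
components of the training covariance (all components for within-network
masks; n_features − 1 for between-network masks, capped at the training
rank n_train − 1 since 64 features exceed 56 training samples), then fit a
soft-margin linear SVM, f(x) = wᵀx + b, with box constraint C = 1. Held-out
decision scores are pooled across folds; accuracy, sensitivity and
specificity come from pooled predictions with the medicated state as the
positive class, and the AUC from the pooled scores (rank statistic, ties
averaged).

Significance uses label permutation: the class labels of all 2n scans are
freely reshuffled and the entire cross-validation is refit per permutation
(fold transforms are label-independent and cached; only the SVM refits).
The observed accuracy is called significant if it exceeds the 97.5th
percentile of the permutation accuracies; the reported p is the +1/+1
proportion of null accuracies ≥ observed. Across the six masks, p-values
are BH-FDR adjusted. A within-subject label-swap permutation variant and a
fit-once ("global") transform variant exist behind flags for sensitivity
analyses; both defaults follow the leakage-free, free-shuffle reading.

Per-subject classification scores (the medicated scan's signed distance to
the held-out decision boundary) can be correlated with clinical measures
(Pearson r, two-sided p) to check that classification is not driven by
disease severity.

## Eigenvector centrality mapping

For voxel-level scans, the similarity matrix A is the element-wise absolute
Pearson correlation between cleaned voxel time series within the scan's
coverage mask. A is non-negative, so by Perron–Frobenius its leading
eigenvector is non-negative; that eigenvector, unit-normalised, is the EC
map. It is computed by power iteration from a uniform positive start
(deterministic — no RNG), relative-residual tolerance 1e−10, at most 10,000
iterations. Below `dense_voxel_limit` (default 8192) voxels A is
materialised once; above it, the iteration recomputes A in row chunks
(default 512 rows) so memory stays bounded — the two paths are verified
identical in tests. The similarity pass runs in double precision below 10⁴
voxels and single above. Zero-variance voxels inside coverage are excluded
from the graph and logged.

Per subject, ΔEC = EC_medicated − EC_naive is defined only where both scans
cover the voxel. Voxels with ΔEC defined for at least 15 subjects enter the
group analysis (the coverage threshold accommodates incomplete posterior
coverage). A two-sided one-sample t-test against zero runs per voxel over
its covering subjects (minimum 3; zero-variance voxels are flagged with
p = 1). Clusters are connected components (26-neighbourhood by default; 6
and 18 selectable) of voxels with p ≤ 0.005 and a common t sign, retained
when strictly larger than 10 voxels (a ≥ rule is selectable — small printed
clusters are sensitive to this choice, so it is exposed, not hidden). At
the cluster level, each subject's mean ΔEC over the cluster's voxels is
tested against zero and BH-FDR adjusts across clusters at α = 0.005.
Cluster means are reported ×10³ in rendered tables. The same machinery
correlates ΔEC maps with clinical-score changes (per-voxel Pearson r,
cluster-level r on cluster-mean ΔEC).

## Synthetic cohorts

The generator provides the only data the package is tested on; it emulates
the acquisition design (two conditions per subject, 210 frames at
TR = 2.4 s, 26 bilateral ROIs in three networks of 8/8/10) and the
statistical features the analyses rely on, with known ground truth.

* **Latent covariance.** A block-structured base correlation: 0.55 within
  motor cortex, 0.35 within cerebellum and within basal ganglia, 0.10
  between networks, +0.20 for homotopic (left/right same-region) pairs;
  each subject adds a small symmetric perturbation (SD 0.04) and the
  result is projected to the nearest unit-diagonal SPD matrix.
* **Medication effect.** In `distributed` mode, a single rank-3 random
  pattern on the cerebellum × basal-ganglia block (drawn once per cohort,
  RMS-normalised) is added to the medicated-state covariance, scaled by
  `effect_magnitude` and a per-subject responsiveness factor
  (N(1, 0.25), floored at 0). No single edge carries the effect — the
  motivation for a rank ≥ 3 pattern — and nearly every edge of the 64-edge
  block is shifted. `single_edge` and `null` modes exist for calibration.
  The reference magnitude 0.025 (per-edge RMS correlation shift, well
  under the ≈ 0.1 SD of a paired edge-contrast) was fixed once by a coarse
  Monte-Carlo scan: it reproduces the qualitative regime of interest —
  cross-validated accuracy ≈ 0.8, classifier permutation-significant,
  univariate stage null after FDR — and was not adjusted afterwards.
* **Nuisance.** Linear drift (amplitude 0.4 × U(0.5, 1.5) per channel),
  six AR(1) (ρ = 0.9) motion series mixed through random loadings
  (amplitude 0.3), and low-order Fourier WM/CSF common signals (amplitudes
  0.5/0.4). Amplitudes are large enough that skipping nuisance regression
  measurably distorts connectivity, giving the cleaning stages real
  leverage. The tissue signals are generated orthogonal to the motion
  series within each scan: the pipeline regresses motion first and WM/CSF
  second, and with mutually correlated smooth nuisance processes that
  stepwise order would re-introduce motion-correlated signal no matter how
  it is implemented — the orthogonalised sources keep the stage order
  coherent while preserving the cleaning workload.
* **Clinical covariates.** Ages U(45, 75); gender Bernoulli(18/29);
  disease duration at the naive visit U(6, 30) months plus a U(24, 48)
  visit gap; treatment durations U(12, 44) months. Scores are integer,
  clipped to instrument ranges (e.g. motor exam 0–132, cognitive screen
  0–30). By default scores are independent of the connectivity effect
  (`clinical_effect_correlation = 0`), matching the observed null
  score–classifier correlations; the coupling is configurable.
* **Voxel grids.** Default 12³ lattice split into 3×3×3 box parcels. Every
  voxel mixes a global signal (loading 0.5), its parcel's common signal
  (0.6) and unit noise; in the medicated condition the centre "hub" parcel
  gains +0.35 global loading, which raises its voxels' centrality. A
  posterior slab (lowest quarter of the second axis) is masked out in a
  configurable fraction of subjects (default 0.3), in both of their scans,
  to exercise the coverage threshold.

What the generator does **not** emulate: spatial autocorrelation beyond
the parcel structure, haemodynamic dynamics, scanner drift
non-stationarity, motion–signal interaction (spikes), site effects, or any
anatomical geometry. Passing tests therefore demonstrate the statistical
machinery — calibration, recoverability, determinism — under the assumed
generative structure, not performance on real scanner data.

## Calibration studies and study sizes

`fcpair.calibration` recomputes the operating characteristics end to end;
the test suite asserts them and `scripts/acceptance.py` reports them. The
study sizes are the package's own choices: type-I error of the edge-wise
GLM over 100–300 null cohorts of 29 subjects at 500 permutations;
dissociation (classifier significance vs zero FDR edges) over 20
distributed-effect cohorts at 500 permutations; the classifier null
false-positive rate over 200 ten-subject null cohorts at 200 permutations;
hub recovery over 20 twenty-subject voxel cohorts. Permutation counts below
the 10,000 default trade resolution of small p-values for replication
count, which is the right trade for rate estimation.

## Determinism

Every stochastic component takes an explicit seed (`CohortConfig.seed`,
`fit(seed=...)`); the EC eigensolver is deterministic by construction.
Identical configuration and seeds reproduce cohorts, connectivity matrices
and permutation results byte-for-byte, and the CLI writes SHA-256 digests
of every output to the run manifest so reruns can be verified.

## Known limitations

* The edge-wise permutation scheme is mildly anticonservative at small n
  (see above); use the sign-flip flag when exact one-sample calibration
  matters more than literal fidelity to the stated procedure.
* The between-network PCA rule (n_features − 1) is rank-capped; with more
  training subjects than features the cap is inactive.
* Cluster anatomy is not labelled; clusters are reported by geometry and
  parcel overlap only.
* The voxel pipeline assumes a common grid across subjects; no
  registration is performed or modelled.
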