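# Methods

This note documents the models implemented in `anesnet`, the defaults and
their rationale, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Brain-state classification

Burst-suppression appears in BOLD fMRI as quasi-periodic, spatially global
signal peaks over cortex and striatum. The classifier treats the first
temporal principal component (PC1) of the standardized voxel × time matrix
as the hemodynamic burst correlate and reduces state assignment to two
segment-level features: the number of detected PC1 peaks and the PC1
skewness.

*Standardization.* Each voxel has its per-run mean removed and the
concatenated series divided by one pooled ("joint") SD computed across all
runs. This removes inter-run offsets without rescaling runs individually,
so amplitude differences between runs — the signal of interest — survive
into the PCA. Zero-variance voxels are zeroed and excluded.

*Peak detection.* PC1 is smoothed with a Gaussian (σ = 10 s), and a
baseline — the centered rolling maximum of the rolling minimum, window
300 s — is subtracted. The max-of-min construction tracks slow drift while
ignoring transients narrower than the window. The residue is divided by its
maximum, so peak heights are relative to the largest burst in the dataset;
this is why runs should be classified jointly (concatenated): a run with no
bursts, normalized against itself, would amplify noise into spurious peaks.
Detection uses `scipy.signal.find_peaks` with height 0.15, width 10
samples, distance 4 samples, rel_height 1. Width and distance are
interpreted in samples of the TR-resolution series (at TR 2 s: 20 s and
8 s); this convention is exposed in `PeakDetectionParams`.

*Rolling windows* are centered with edge truncation (the window shrinks
near boundaries); reflection padding is selectable via `edge_mode`. On
monotone signals the truncated operator reproduces the signal away from the
edges; pandas' even-length centered windows are asymmetric by one sample,
which is irrelevant at the 150-sample windows used.

*Segmentation and rules.* The timeline is cut into non-overlapping 5-min
segments within runs; trailing partial segments are dropped with a warning.
States: 0 peaks → `no_bursts`; 1 → `single_burst`; ≥ 2 peaks with skewness
< 0.25 → `no_suppressions`, otherwise `burst_suppression`. The
no-suppressions rule is applied uniformly to all segments (a
generalization of its original post-hoc use on a single subject).

*Skewness source.* Skewness is the bias-uncorrected Fisher–Pearson sample
skewness. By default it is computed on the **raw** PC1 within the segment
(`skew_on="raw"`); computing it on the smoothed, baseline-subtracted trace
is selectable (`skew_on="normalized"`). Skewness is shift/scale invariant,
so the two differ only through the 10-s smoothing, which widens bursts and
compresses the skewness range: on simulated data raw-PC1 skewness separates
burst-suppression (median ≈ 2.7) from continuous oscillations (≈ 0) far
more sharply, which motivates the default.

*Flat signals* (residue ≤ 0 everywhere) yield zero peaks and an all-zero
normalized trace rather than an error.

## Evoked responses

Series are scaled to percent of their temporal mean (mean → 100). The GLM
design is [task regressor | Legendre polynomials 0..K], with
K = 1 + ⌊run_seconds/150⌋ (≈ one drift term per 2.5 min, common fMRI
practice). The task regressor is the stimulus boxcar convolved with a
gamma-variate HRF and peak-normalized, so the fitted β is the response
amplitude in %BOLD; t = β/SE with dof = n_time − n_regressors. The HRF is
t^5·exp(−t) scaled to unit peak (mode 5 s, < 1% of peak by 30 s), a
standard primate/rodent hemodynamic time course; peak time and support are
arguments.

Peri-stimulus epochs span −10 … +50 s around onsets; each epoch is
re-expressed as 100·(x − b)/b with b the mean over the pre-stimulus part,
and epochs clipped by run edges are dropped. Response metrics are the
maximum and the trapezoidal integral of the average trace over 0–30 s.
Paired comparisons use the two-sided paired t-test; identical samples
return (t = 0, p = 1) and a constant nonzero difference (zero within-pair
variance) raises as degenerate rather than returning an infinite statistic.

Cluster reporting thresholds a Z map at |Z| > 2 and two-sided normal
p < 0.05 (uncorrected), groups voxels by face adjacency
("nearest-neighbor"; edge/corner adjacency selectable), separately per
sign so touching positive and negative regions never merge, and discards
clusters below 50 voxels. Group maps are voxel-wise one-sample or
paired-difference t maps with dof = n − 1; zero-variance voxels are NaN
with a warning.

## Network analysis

Nodes are parcel means; adjacency is the Pearson matrix. Modularity uses
the signed weighted quality

Q(γ,{g}) = Σ_ij [A⁺_ij − γP⁺_ij] δ(g_i,g_j)/v⁺ − Σ_ij [A⁻_ij − γP⁻_ij] δ(g_i,g_j)/(v⁺+v⁻)

with A± the positive/negative parts (self-edges excluded), v± their total
weights, and P± the weighted configuration-model null s_i s_j / v within
each part (a uniform/permutation null is selectable). The asymmetric
normalization keeps Q in [−1, 1], reduces exactly to the Newman–Girvan
quality on nonnegative matrices, and lets correlation matrices be used
unthresholded. Density thresholding (default p = 0.2, keep the ⌈p·E⌉
strongest edges, ties broken lexicographically) is applied for the other
graph measures, not for modularity.

*Louvain* is implemented in-package as greedy node moving (including an
escape-to-new-community move) plus aggregation on the precomputed
modularity matrix; the search restarts 10 times with different random
visiting orders and keeps the best-Q partition, all deterministic given the
seed. An in-package implementation is required because the signed null is
part of the objective; networkx's Louvain serves as an independent
cross-check on positive graphs in the tests.

*Consensus* follows the association-matrix scheme: many Louvain runs, a
node × node co-classification frequency matrix, reclustered by the same
algorithm under the permutation null, iterated until the matrix is
block-binary (its connected components are then the stable partition).
This implements the fixed-point contract of hierarchical consensus without
its event-sampling internals.

*4-level GSR* regresses out the node-mean signal g, its first difference,
g², and the squared difference (all demeaned, plus an intercept) by OLS;
residuals are orthogonal to every regressor by construction, and collinear
or constant regressors are dropped with a warning. Band-pass filtering is a
zero-phase 4th-order Butterworth (0.005–0.12 Hz at TR 2 s).

*Homotopy and distance.* Inter-hemispheric correspondence pairs every
within-left edge (i, j) with the homologous within-right edge
(partner(i), partner(j)) and reports Spearman ρ plus a least-squares line —
one concrete reading of "the linear fit between the hemispheres"; a
profile-based alternative would correlate hemispheric mean rows instead.
Weight-vs-distance reports per-edge Euclidean centroid distance,
intra/inter-hemispheric flags, decile-binned mean weights and Spearman
ρ(weight, distance), both overall and intra-hemispheric (cross-hemisphere
homotopic edges are strong *and* long, so the decay signature lives in the
intra-hemispheric edges).

## Synthetic data

The generator produces the statistical regimes the analyses assume, each
with a ground-truth record for recovery testing:

- **burst_suppression** — event times from an equilibrium renewal process
  with gamma(shape 4) inter-event intervals (quasi-periodic:
  clustered-but-regular, not Poisson; the equilibrium start makes the
  expected count exactly rate × duration), a 30 s refractory keeping events
  resolvable after 10-s smoothing, default rate 1.2/min. Events are
  convolved with the HRF and added with per-voxel loadings ≈ 1 over a
  cortico-striatal fraction (default 80%) and exactly 0 over a "visual"
  remainder, emulating the visual-sparing burst-suppression network.
  Default amplitude/noise ratio 10.
- **single_burst / no_bursts** — the same model with exactly one or zero
  events.
- **no_suppressions** — a continuous narrowband (0.03–0.06 Hz) Gaussian
  oscillation on the same loading map; symmetric, so segment skewness is
  tightly concentrated near zero (|skew| < 0.25 in ≥ 95% of seeds), while
  still producing ≥ 2 detected peaks.
- **awake_like** — node signals drawn from a block covariance: within-module
  r = 0.6, between-module 0.1 (decaying with centroid distance, scale
  10 mm), homotopic partners r = 0.5, projected to the PSD cone and
  renormalized. Centroids sit on two mirrored 3-D grids with 4 modules per
  hemisphere, so homotopy and distance are well defined.
- **visual runs** — 30 s baseline plus five 30 s ON / 30 s OFF blocks
  (330 s = 165 volumes at TR 2 s); node signal =
  baseline·(1 + amplitude/100 · normalized boxcar⊗HRF) + noise, with noise
  in percent-of-baseline units so TSNR ≈ 100/noise_sd after scaling.

Noise is i.i.d. Gaussian per voxel with AR(1) temporal autocorrelation
(φ = 0.3). Not emulated: scanner artifacts, motion, field inhomogeneity,
physiological confounds, spatial noise correlations, and multi-subject
variability. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated assumptions, not robustness to real-data
nuisance structure.

## Problem sizes and tolerances

Recovery checks use desk-scale problems: 100 burst runs of 10 min at 120
voxels for peak detection; 40 concatenated 5-min segments for state
recovery; 24-node, 240-volume awake-like matrices (20 seeds, 20 consensus
runs) for module counts; exhaustive enumeration on 8 nodes and brute-force
summation on 6 nodes for the modularity oracle; 10,000 null simulations at
n = 8 for the t-test calibration. Modularity agreement is asserted to
1e−12; GSR orthogonality to 1e−8 relative; planted-amplitude recovery to
±0.05 %BOLD; type-I error to ±0.01.

## Known limitations

- Classification of a single isolated run is unreliable for `no_bursts`
  data (normalization against the run's own maximum); classify concatenated
  datasets.
- The consensus reclustering returns the last partition with
  `converged=False` if the co-classification matrix does not become
  block-binary within `max_iter` iterations.
- β and peri-stimulus peak agree only when the response follows the assumed
  HRF shape; amplitude conventions differ from other packages' β scales by
  the regressor normalization constant.
- The homotopic-edge reading of inter-hemispheric correspondence is one of
  several possible definitions (see above).
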