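# anesnet

Analysis tools for BOLD fMRI acquired under anesthesia: PCA-based
burst-suppression brain-state classification, block-design evoked-response
quantification, and state-dependent functional-network graph analysis —
together with a synthetic-data generator that plants ground truth for every
stage, so the whole pipeline can be exercised and validated end-to-end
without scanner data.

## Who this is for

Researchers analyzing resting-state or task fMRI from anesthetized animals
(e.g. isoflurane- or medetomidine-anesthetized primates and rodents), where
deep anesthesia produces *burst-suppression*: quasi-periodic bursts of
global activity separated by near-silent suppression periods. Because the
brain state drifts within and between runs, evoked responses and
functional-connectivity measures are only interpretable once each data
segment is assigned a state.

## The methods

**Brain-state classification.** Voxel time series over a cortico-striatal
mask are standardized across concatenated runs (per-run mean removal,
division by the joint SD), and the first temporal principal component (PC1)
of the voxel × time carpet matrix is taken as the hemodynamic correlate of
burst activity. PC1 is Gaussian-smoothed (σ = 10 s), a rolling
maximum-of-rolling-minimum baseline (300 s window) is subtracted, the
residue is scaled to [0, 1], and peaks are detected
(`scipy.signal.find_peaks`; height 0.15, width 10, distance 4,
rel_height 1). The timeline is split into non-overlapping 5-min segments
and each is classified from its peak count *n* and PC1 skewness *s*:
`no_bursts` (n = 0), `single_burst` (n = 1), and for n ≥ 2 either
`no_suppressions` (s < 0.25) or `burst_suppression` (s ≥ 0.25).

**Evoked responses.** Time series are scaled to percent of their mean, fit
with an OLS GLM whose task regressor is the ON boxcar convolved with a
gamma hemodynamic kernel (peak-normalized, so β reads in %BOLD) plus
Legendre drift terms; TSNR = mean(signal)/SD(residual). Peri-stimulus
epochs (−10 … +50 s) are baseline-normalized to ΔBOLD (%), averaged, and
summarized by the peak and the trapezoidal AUC over the 0–30 s stimulation
window, compared across conditions with paired t-tests. Suprathreshold
voxels (|Z| > 2, p < 0.05) are grouped into nearest-neighbor clusters with a
50-voxel minimum.

**Network analysis.** Parcel mean time series give node × node Pearson
adjacency matrices A. The signed weighted modularity

    Q(γ, {g_i}) = Σ_ij [A_ij − γ P_ij] δ(g_i, g_j)

with a configuration-model null P is optimized by an in-package Louvain
algorithm and stabilized by association-matrix consensus clustering.
Supporting operations: 4-level global signal regression (global mean, its
temporal derivative, and both squares), 0.005–0.12 Hz band-pass, matrix
reordering by module, density thresholding (keep the top 20% of edges),
inter-hemispheric (homotopic) edge correlation, distance-resolved edge
weights, and average strength.

The main entry points are sklearn-style estimators —
`BurstStateClassifier`, `BlockGLM`, `GlobalSignalRegressor`,
`BandpassFilter`, `LouvainCommunities`, `ConsensusCommunities` — with the
underlying functions exposed in `anesnet.states`, `anesnet.evoked`,
`anesnet.network`, `anesnet.simdata` and `anesnet.io`.

## Worked example

Classify three simulated 5-min runs (one quiet, two with planted burst
trains):

```python
import numpy as np
from anesnet import SimulationConfig, BurstStateClassifier, CarpetMatrix
from anesnet.simdata import simulate_state_run

blocks, bounds, cur = [], [], 0
for i, state in enumerate(["no_bursts", "burst_suppression", "burst_suppression"]):
    carpet, truth = simulate_state_run(
        SimulationConfig(state=state, seed=i, run_length_volumes=150))
    blocks.append(carpet.data)
    bounds.append((cur, cur + 150))
    cur += 150

carpet = CarpetMatrix(np.concatenate(blocks, axis=1), tr_seconds=2.0,
                      run_boundaries=bounds)
clf = BurstStateClassifier().fit(carpet)
print(clf.segments_[["segment", "run", "n_peaks", "skewness", "state"]])
print("PC1 explained variance ratio:", round(clf.pca_.explained_variance_ratio, 3))
```

prints

```
   segment  run  n_peaks  skewness              state
0        0    0        0 -0.127325          no_bursts
1        1    1        6  2.381760  burst_suppression
2        2    2        7  2.110608  burst_suppression
PC1 explained variance ratio: 0.669
```

The quiet run is labelled `no_bursts` (zero detected peaks, near-zero PC1
skewness); the runs with planted bursts show 6–7 detected peaks per 5-min
segment and strongly positive skewness, the burst-suppression signature.

The same analyses are available from the shell:

```bash
anesnet simulate --seed 7 --out sim/
anesnet classify --manifest runs.json --segment-seconds 300 --out out/
anesnet network --matrix A.tsv --parcellation parc.tsv --gamma 1.0 \
    --density 0.2 --consensus-runs 100 --seed 1 --out net/
anesnet run --seed 1 --out full/        # simulate -> classify -> evoked -> network
```

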