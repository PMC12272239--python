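"""Burst-suppression brain-state classification from the BOLD carpet matrix.

Under deep isoflurane anesthesia the cortex alternates between bursts of
activity and near-silent suppression periods.  In BOLD fMRI this appears as
quasi-periodic, globally synchronized signal peaks across a cortico-striatal
voxel set.  The classifier:

1. standardizes each voxel series across concatenated runs (per-run mean
   removal, division by the pooled standard deviation),
2. takes the first temporal principal component (PC1) of the voxel x time
   matrix as the hemodynamic correlate of burst activity,
3. detects burst peaks on PC1 after Gaussian smoothing and subtraction of a
   rolling max-of-rolling-min baseline,
4. splits the timeline into non-overlapping 5-minute segments and assigns
   each segment one of four states from its peak count and PC1 skewness:
   ``no_bursts`` (0 peaks), ``single_burst`` (1), and for >= 2 peaks either
   ``no_suppressions`` (skewness below 0.25) or ``burst_suppression``.

The class :class:`BurstStateClassifier` wraps the full chain as an estimator;
the module functions expose each step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import CarpetMatrix

__all__ = [
    "PeakDetectionParams",
    "PCResult",
    "standardize_runs",
    "temporal_pca",
    "detect_peaks",
    "segment_and_classify",
    "state_connectivity",
    "BurstStateClassifier",
]

STATE_NAMES = ("no_bursts", "single_burst", "burst_suppression", "no_suppressions")


@dataclass
class PeakDetectionParams:
    """Burst-peak detection settings.

    ``smooth_sigma_seconds`` and ``baseline_window_seconds`` are in seconds
    and converted to samples with the TR; ``height`` applies to the
    baseline-subtracted PC1 normalized to [0, 1]; ``width_samples`` and
    ``distance_samples`` are in samples of the TR-resolution series.
    """

    smooth_sigma_seconds: float = 10.0
    baseline_window_seconds: float = 300.0
    height: float = 0.15
    width_samples: float = 10.0
    distance_samples: float = 4.0
    rel_height: float = 1.0
    edge_mode: str = "truncate"  # or "reflect"

    def __post_init__(self) -> None:
        for name in ("smooth_sigma_seconds", "baseline_window_seconds",
                     "width_samples", "distance_samples", "rel_height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.height < 1.0:
            raise ValueError("height must lie in (0, 1)")
        if self.edge_mode not in ("truncate", "reflect"):
            raise ValueError("edge_mode must be 'truncate' or 'reflect'")


@dataclass
class PCResult:
    """First temporal principal component of the carpet matrix."""

    pc1: np.ndarray
    explained_variance_ratio: float
    correlation_map: np.ndarray


def standardize_runs(carpet: CarpetMatrix) -> CarpetMatrix:
    """Per-run mean removal, then division by the pooled (joint) SD per voxel.

    The pooled SD is a single number per voxel computed on the demeaned series
    concatenated across runs, so run boundaries carry no amplitude
    discontinuities into the PCA.  Voxels with zero joint SD are set to zero
    and flagged with a warning; downstream PCA ignores all-zero rows.
    """
    data = carpet.data.copy()
    for sl in carpet.run_slices():
        data[:, sl] -= data[:, sl].mean(axis=1, keepdims=True)
    sd = data.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance voxel(s) excluded from PCA mask")
        sd = np.where(dead, 1.0, sd)
    data /= sd[:, None]
    data[dead] = 0.0
    return CarpetMatrix(
        data,
        tr_seconds=carpet.tr_seconds,
        run_boundaries=list(carpet.run_boundaries),
        voxel_labels=carpet.voxel_labels,
        condition=carpet.condition,
    )


def temporal_pca(carpet: CarpetMatrix) -> PCResult:
    """PC1 of the (standardized) voxel x time matrix.

    PC1 is the first right-singular (temporal) component, sign-oriented so it
    correlates nonnegatively with the mean-across-voxels signal.  The
    correlation map holds each voxel's Pearson r with PC1.
    """
    x = carpet.data
    if x.shape[1] < 2:
        raise ValueError("need more than one time point for PCA")
    active = x.std(axis=1) > 0
    if not active.any():
        raise ValueError("degenerate carpet: all voxels have zero variance")
    xa = x[active] - x[active].mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(xa, full_matrices=False)
    pc1 = vt[0]
    evr = float(s[0] ** 2 / np.sum(s**2))
    mean_signal = xa.mean(axis=0)
    if mean_signal.std() > 0 and np.corrcoef(pc1, mean_signal)[0, 1] < 0:
        pc1 = -pc1
    corr = np.zeros(x.shape[0])
    pc1_c = pc1 - pc1.mean()
    denom_p = np.linalg.norm(pc1_c)
    rows = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    ok = norms > 0
    corr[ok] = rows[ok] @ pc1_c / (norms[ok] * denom_p)
    return PCResult(pc1=pc1, explained_variance_ratio=evr, correlation_map=corr)


def _rolling_extremum(x: np.ndarray, window: int, how: str, edge_mode: str) -> np.ndarray:
    if edge_mode == "reflect":
        pad = window // 2
        xp = np.pad(x, pad, mode="reflect")
        ser = pd.Series(xp).rolling(window, center=True, min_periods=1)
        out = (ser.min() if how == "min" else ser.max()).to_numpy()
        return out[pad:pad + len(x)]
    ser = pd.Series(x).rolling(window, center=True, min_periods=1)
    return (ser.min() if how == "min" else ser.max()).to_numpy()


def rolling_baseline(x: np.ndarray, window: int, edge_mode: str = "truncate") -> np.ndarray:
    """Rolling maximum of the rolling minimum: a lower envelope that tracks
    slow baseline drift while ignoring transient peaks narrower than the
    window."""
    lo = _rolling_extremum(x, window, "min", edge_mode)
    return _rolling_extremum(lo, window, "max", edge_mode)


def detect_peaks(
    pc1: np.ndarray,
    tr: float,
    params: PeakDetectionParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect burst peaks on PC1; returns (peak indices, normalized PC1).

    Pipeline: Gaussian smoothing (sigma in seconds / TR), baseline removal by
    a centered rolling max-of-rolling-min (window in seconds / TR, shrinking
    at the edges), normalization of the residue to [0, 1] by its maximum, and
    local-maximum search with the height/width/distance/rel_height thresholds.
    A flat signal yields zero peaks and an all-zero normalized trace.
    """
    params = params or PeakDetectionParams()
    pc1 = np.asarray(pc1, dtype=float)
    window = max(int(round(params.baseline_window_seconds / tr)), 1)
    if pc1.size < window:
        raise ValueError(
            f"series of {pc1.size} samples shorter than the baseline window "
            f"({window} samples)"
        )
    sigma = params.smooth_sigma_seconds / tr
    smoothed = gaussian_filter1d(pc1, sigma=sigma, mode="nearest")
    baseline = rolling_baseline(smoothed, window, params.edge_mode)
    residue = smoothed - baseline
    top = residue.max()
    if top <= 0:
        return np.array([], dtype=int), np.zeros_like(pc1)
    normalized = residue / top
    peaks, _ = find_peaks(
        normalized,
        height=params.height,
        width=params.width_samples,
        distance=max(params.distance_samples, 1),
        rel_height=params.rel_height,
    )
    return peaks, normalized


def segment_and_classify(
    peaks: np.ndarray,
    pc1_normalized: np.ndarray,
    tr: float,
    segment_seconds: float = 300.0,
    skew_threshold: float = 0.25,
    run_boundaries: list[tuple[int, int]] | None = None,
    conditions: list[str] | None = None,
    skew_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Split the timeline into fixed-length segments and classify each.

    Segmentation proceeds within runs; trailing partial segments are dropped
    with a warning.  Skewness is the (bias-uncorrected) Fisher-Pearson sample
    skewness of the segment's PC1 values — by default the raw PC1 passed via
    ``skew_values`` (falling back to ``pc1_normalized``); skewness is
    shift/scale invariant, so the choice only matters through the smoothing
    baked into the normalized trace.  Returns a table with columns segment,
    run, condition, start, end, n_peaks, skewness, state.
    """
    pc1_normalized = np.asarray(pc1_normalized, dtype=float)
    skew_series = (np.asarray(skew_values, dtype=float)
                   if skew_values is not None else pc1_normalized)
    if skew_series.shape != pc1_normalized.shape:
        raise ValueError("skew_values must align with pc1_normalized")
    peaks = np.asarray(peaks, dtype=int)
    seg_len = int(round(segment_seconds / tr))
    if seg_len < 2:
        raise ValueError("segment too short for the TR")
    if run_boundaries is None:
        run_boundaries = [(0, pc1_normalized.size)]
    rows = []
    seg_idx = 0
    for run_id, (start, end) in enumerate(run_boundaries):
        n_full = (end - start) // seg_len
        if (end - start) % seg_len:
            warnings.warn(
                f"run {run_id}: dropping trailing partial segment of "
                f"{(end - start) % seg_len} volumes"
            )
        for k in range(n_full):
            a, b = start + k * seg_len, start + (k + 1) * seg_len
            n_peaks = int(np.sum((peaks >= a) & (peaks < b)))
            seg = skew_series[a:b]
            skew = float(stats.skew(seg, bias=True)) if seg.std() > 0 else 0.0
            if n_peaks == 0:
                state = "no_bursts"
            elif n_peaks == 1:
                state = "single_burst"
            elif skew < skew_threshold:
                state = "no_suppressions"
            else:
                state = "burst_suppression"
            rows.append(
                {
                    "segment": seg_idx,
                    "run": run_id,
                    "condition": conditions[run_id] if conditions else "",
                    "start": a,
                    "end": b,
                    "n_peaks": n_peaks,
                    "skewness": skew,
                    "state": state,
                }
            )
            seg_idx += 1
    return pd.DataFrame(rows)


def state_connectivity(
    carpet: CarpetMatrix,
    segments: pd.DataFrame,
    voxel_to_node: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-state node x node connectivity from classified segments.

    Voxel series are averaged within parcels, a Pearson matrix is computed
    per segment, and segments are combined within each state by Fisher
    z-averaging (back-transformed; diagonal set to 1).  States without
    segments are omitted with a warning.
    """
    voxel_to_node = np.asarray(voxel_to_node)
    node_ids = np.unique(voxel_to_node)
    node_ts = np.vstack([
        carpet.data[voxel_to_node == nid].mean(axis=0) for nid in node_ids
    ])
    out: dict[str, np.ndarray] = {}
    for state in STATE_NAMES:
        segs = segments[segments["state"] == state]
        if segs.empty:
            warnings.warn(f"state {state!r} has no segments; omitted")
            continue
        zs = []
        for _, row in segs.iterrows():
            block = node_ts[:, int(row["start"]):int(row["end"])]
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(block)
            r = np.nan_to_num(r, nan=0.0)
            np.fill_diagonal(r, 0.0)
            zs.append(np.arctanh(np.clip(r, -0.999999, 0.999999)))
        mat = np.tanh(np.mean(zs, axis=0))
        np.fill_diagonal(mat, 1.0)
        out[state] = mat
    return out


class BurstStateClassifier(ClusterMixin, BaseEstimator):
    """End-to-end brain-state classifier over a voxel x time carpet matrix.

    ``fit`` runs standardization, temporal PCA, peak detection and
    segmentation; ``labels_`` holds the per-segment state.  Input ``X`` may be
    a :class:`~anesnet.containers.CarpetMatrix` or a plain (n_voxels, n_time)
    array (then ``tr_seconds`` and a single run are assumed).

    Parameters mirror :class:`PeakDetectionParams` plus the segmentation
    settings; all are plain scalars so the estimator composes with sklearn
    model-selection utilities.

    Attributes
    ----------
    pca_ : PCResult
    peaks_ : ndarray of peak sample indices
    pc1_normalized_ : ndarray
    segments_ : DataFrame (one row per 5-min segment)
    labels_ : ndarray of per-segment state strings
    """

    def __init__(
        self,
        tr_seconds: float = 2.0,
        segment_seconds: float = 300.0,
        skew_threshold: float = 0.25,
        smooth_sigma_seconds: float = 10.0,
        baseline_window_seconds: float = 300.0,
        height: float = 0.15,
        width_samples: float = 10.0,
        distance_samples: float = 4.0,
        rel_height: float = 1.0,
        edge_mode: str = "truncate",
        skew_on: str = "raw",
    ):
        self.skew_on = skew_on
        self.tr_seconds = tr_seconds
        self.segment_seconds = segment_seconds
        self.skew_threshold = skew_threshold
        self.smooth_sigma_seconds = smooth_sigma_seconds
        self.baseline_window_seconds = baseline_window_seconds
        self.height = height
        self.width_samples = width_samples
        self.distance_samples = distance_samples
        self.rel_height = rel_height
        self.edge_mode = edge_mode

    def _peak_params(self) -> PeakDetectionParams:
        return PeakDetectionParams(
            smooth_sigma_seconds=self.smooth_sigma_seconds,
            baseline_window_seconds=self.baseline_window_seconds,
            height=self.height,
            width_samples=self.width_samples,
            distance_samples=self.distance_samples,
            rel_height=self.rel_height,
            edge_mode=self.edge_mode,
        )

    def fit(self, X, y=None):
        if isinstance(X, CarpetMatrix):
            carpet = X
        else:
            carpet = CarpetMatrix(np.asarray(X, dtype=float), tr_seconds=self.tr_seconds)
        tr = carpet.tr_seconds
        self.standardized_ = standardize_runs(carpet)
        self.pca_ = temporal_pca(self.standardized_)
        self.peaks_, self.pc1_normalized_ = detect_peaks(
            self.pca_.pc1, tr, self._peak_params()
        )
        if self.skew_on not in ("raw", "normalized"):
            raise ValueError("skew_on must be 'raw' or 'normalized'")
        skew_values = self.pca_.pc1 if self.skew_on == "raw" else self.pc1_normalized_
        self.segments_ = segment_and_classify(
            self.peaks_,
            self.pc1_normalized_,
            tr,
            segment_seconds=self.segment_seconds,
            skew_threshold=self.skew_threshold,
            run_boundaries=carpet.run_boundaries,
            skew_values=skew_values,
        )
        self.labels_ = self.segments_["state"].to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
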