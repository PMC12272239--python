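"""Block-design evoked-response quantification.

Covers percent-signal scaling, the gamma-block GLM (task regressor = ON
boxcar convolved with a gamma hemodynamic kernel, peak-normalized so the
fitted coefficient reads directly in percent BOLD), temporal SNR,
peri-stimulus trace extraction with baseline normalization, peak/AUC response
metrics, paired comparisons between conditions, voxel-cluster reporting on a
Z map, and group-level t maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .simdata import gamma_hrf

__all__ = [
    "EventDesign",
    "PeristimulusTrace",
    "GLMResult",
    "scale_to_percent",
    "block_regressor",
    "glm_block",
    "tsnr",
    "extract_peristimulus",
    "response_metrics",
    "paired_compare",
    "cluster_report",
    "group_ttest",
    "BlockGLM",
]


@dataclass
class EventDesign:
    """Stimulus timing for one run: onsets/durations in seconds, half-open
    event intervals [onset, onset + duration)."""

    onsets: np.ndarray
    durations: np.ndarray
    run_length_volumes: int
    tr: float

    def __post_init__(self) -> None:
        self.onsets = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        durations = np.asarray(self.durations, dtype=float)
        if durations.ndim == 0:
            durations = np.full(self.onsets.size, float(durations))
        self.durations = durations
        if self.durations.shape != self.onsets.shape:
            raise ValueError("onsets and durations must align")
        run_seconds = self.run_length_volumes * self.tr
        if np.any(self.onsets < 0) or np.any(self.onsets + self.durations > run_seconds):
            raise ValueError("events must lie within the run")
        order = np.argsort(self.onsets)
        ends = (self.onsets + self.durations)[order]
        if np.any(self.onsets[order][1:] < ends[:-1]):
            raise ValueError("events must not overlap")

    @classmethod
    def from_events_table(cls, events: pd.DataFrame, run_length_volumes: int, tr: float):
        return cls(events["onset"].to_numpy(), events["duration"].to_numpy(),
                   run_length_volumes, tr)

    @property
    def run_seconds(self) -> float:
        return self.run_length_volumes * self.tr


@dataclass
class PeristimulusTrace:
    """Baseline-normalized event-locked average in percent BOLD change."""

    time: np.ndarray          # seconds relative to stimulus onset
    values: np.ndarray        # %BOLD change
    n_epochs_averaged: int


@dataclass
class GLMResult:
    beta: np.ndarray
    tstat: np.ndarray
    residual_sd: np.ndarray
    dof: int


def scale_to_percent(ts: np.ndarray) -> np.ndarray:
    """Scale each series by its mean to percent-of-mean units (mean -> 100)."""
    ts = np.asarray(ts, dtype=float)
    mean = ts.mean(axis=-1, keepdims=True)
    if np.any(mean <= 0):
        raise ValueError("time series mean must be positive for percent scaling")
    return 100.0 * ts / mean


def block_regressor(design: EventDesign, hrf: np.ndarray | None = None) -> np.ndarray:
    """ON boxcar convolved with the HRF, peak-normalized.

    With percent-scaled data the fitted coefficient of this regressor is the
    response amplitude in %BOLD.
    """
    if hrf is None:
        hrf = gamma_hrf(design.tr)
    n = design.run_length_volumes
    t = np.arange(n) * design.tr
    boxcar = np.zeros(n)
    for onset, dur in zip(design.onsets, design.durations):
        boxcar[(t >= onset) & (t < onset + dur)] = 1.0
    reg = np.convolve(boxcar, hrf)[:n]
    peak = np.abs(reg).max()
    if peak == 0:
        raise ValueError("empty design: regressor is identically zero")
    return reg / peak


def _legendre_drift(n_vol: int, order: int) -> np.ndarray:
    """Legendre polynomials 0..order evaluated on [-1, 1] (column 0 = intercept)."""
    x = np.linspace(-1.0, 1.0, n_vol)
    return np.polynomial.legendre.legvander(x, order)


def default_detrend_order(run_seconds: float) -> int:
    return 1 + int(run_seconds // 150)


def glm_block(
    ts: np.ndarray,
    design: EventDesign,
    hrf: np.ndarray | None = None,
    detrend_order: int | None = None,
) -> GLMResult:
    """OLS fit of [task regressor + Legendre drift + intercept] per series.

    ``ts`` is (n_time,) or (n_series, n_time).  Returns the task regressor's
    coefficient, its t statistic (= beta / SE), the residual SD and the
    residual degrees of freedom (n_time - n_regressors).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n_time = ts.shape[1]
    if n_time != design.run_length_volumes:
        raise ValueError("time series length does not match the design")
    if detrend_order is None:
        detrend_order = default_detrend_order(design.run_seconds)
    task = block_regressor(design, hrf)
    drift = _legendre_drift(n_time, detrend_order)
    X = np.column_stack([task, drift])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(j)
        names = ["task"] + [f"legendre{k}" for k in range(detrend_order + 1)]
        raise ValueError(f"design matrix rank deficient; collinear columns: "
                         f"{[names[j] for j in bad]}")
    dof = n_time - X.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = ts @ X @ xtx_inv.T          # (n_series, n_regressors)
    resid = ts - coef @ X.T
    sigma2 = np.sum(resid**2, axis=1) / dof
    se = np.sqrt(sigma2 * xtx_inv[0, 0])
    beta = coef[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    return GLMResult(beta=beta.squeeze(), tstat=tstat.squeeze(),
                     residual_sd=np.sqrt(sigma2).squeeze(), dof=dof)


def tsnr(signal_ts: np.ndarray, residual_ts: np.ndarray) -> float:
    """Temporal SNR: mean of the signal over the SD of the residual noise."""
    signal_ts = np.asarray(signal_ts, dtype=float)
    residual_ts = np.asarray(residual_ts, dtype=float)
    sd = residual_ts.std()
    if sd == 0:
        raise ValueError("zero residual SD: TSNR undefined (infinite)")
    return float(signal_ts.mean() / sd)


def extract_peristimulus(
    ts_pct: np.ndarray,
    design: EventDesign,
    window: tuple[float, float] = (-10.0, 50.0),
) -> PeristimulusTrace:
    """Event-locked average, baseline-normalized to %BOLD change.

    Each epoch spanning ``window`` seconds around an onset is re-expressed as
    ``100 * (x - baseline) / baseline`` with baseline the mean over the
    pre-stimulus part of the window; epochs clipped by the run edges are
    dropped with a warning.
    """
    ts_pct = np.asarray(ts_pct, dtype=float)
    if ts_pct.ndim != 1:
        raise ValueError("extract_peristimulus expects a single series")
    tr = design.tr
    pre = int(round(-window[0] / tr))
    post = int(round(window[1] / tr))
    epochs = []
    for onset in design.onsets:
        center = int(round(onset / tr))
        a, b = center - pre, center + post + 1
        if a < 0 or b > ts_pct.size:
            warnings.warn(f"epoch at onset {onset}s clipped by run edges; dropped")
            continue
        epoch = ts_pct[a:b]
        baseline = epoch[:pre].mean()
        if baseline == 0:
            raise ValueError("zero pre-stimulus baseline")
        epochs.append(100.0 * (epoch - baseline) / baseline)
    if not epochs:
        raise ValueError("no complete peri-stimulus epochs in the run")
    time = (np.arange(-pre, post + 1)) * tr
    return PeristimulusTrace(time=time, values=np.mean(epochs, axis=0),
                             n_epochs_averaged=len(epochs))


def response_metrics(trace: PeristimulusTrace, stim_window: tuple[float, float] = (0.0, 30.0)):
    """Peak %BOLD and trapezoidal AUC of the trace during stimulation.

    Returns ``(peak_pct, auc)`` with the peak the maximum over the stimulus
    window and the AUC its trapezoidal integral (%BOLD x s).
    """
    lo, hi = stim_window
    if trace.time.min() > lo or trace.time.max() < hi:
        raise ValueError("trace does not cover the stimulus window")
    sel = (trace.time >= lo) & (trace.time <= hi)
    peak = float(trace.values[sel].max())
    auc = float(np.trapezoid(trace.values[sel], trace.time[sel]))
    return peak, auc


def paired_compare(metrics_a: np.ndarray, metrics_b: np.ndarray) -> tuple[float, float, int]:
    """Two-sided paired Student t-test; returns (t, p, n).

    Identical samples give (0, 1, n); a constant nonzero difference has an
    undefined standard error and raises.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if diff.std(ddof=1) == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0, n
        raise ValueError("degenerate comparison: constant nonzero difference "
                         "(undefined standard error)")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), n


_STRUCTURES = {"faces": 1, "edges": 2, "corners": 3}


def cluster_report(
    stat_map: np.ndarray,
    z_threshold: float = 2.0,
    p_threshold: float = 0.05,
    min_cluster: int = 50,
    connectivity: str = "faces",
) -> pd.DataFrame:
    """Group suprathreshold voxels of a Z map into clusters.

    Voxels with |Z| above ``z_threshold`` and a two-sided normal p below
    ``p_threshold`` are grouped by the chosen adjacency (default nearest
    neighbors = face connectivity), separately per sign; clusters smaller
    than ``min_cluster`` voxels are discarded.  Rows: size, peak_stat,
    peak coordinate, sign.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = ndimage.generate_binary_structure(stat_map.ndim, _STRUCTURES[connectivity])
    pvals = 2.0 * stats.norm.sf(np.abs(stat_map))
    supra = (np.abs(stat_map) > z_threshold) & (pvals < p_threshold)
    rows = []
    for sign in (1, -1):
        mask = supra & (np.sign(stat_map) == sign)
        labelled, n_clusters = ndimage.label(mask, structure=structure)
        for lab in range(1, n_clusters + 1):
            idx = np.nonzero(labelled == lab)
            size = idx[0].size
            if size < min_cluster:
                continue
            vals = stat_map[idx]
            k = int(np.argmax(np.abs(vals)))
            rows.append(
                {
                    "size": int(size),
                    "peak_stat": float(vals[k]),
                    "peak_coord": tuple(int(ax[k]) for ax in idx),
                    "sign": sign,
                }
            )
    rows.sort(key=lambda r: -r["size"])
    return pd.DataFrame(rows, columns=["size", "peak_stat", "peak_coord", "sign"])


def group_ttest(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None = None,
    paired: bool = False,
) -> np.ndarray:
    """Voxel-wise group t map (dof = n - 1).

    One-sample t against zero on ``maps_a`` (subjects on the first axis), or
    the paired-difference t when ``maps_b`` is supplied with ``paired=True``.
    Voxels with zero between-subject variance are flagged NaN with a warning.
    """
    a = np.asarray(maps_a, dtype=float)
    if a.shape[0] < 2:
        raise ValueError("need at least two subjects")
    if maps_b is not None:
        b = np.asarray(maps_b, dtype=float)
        if b.shape != a.shape:
            raise ValueError("subject map grids do not match")
        if not paired:
            raise ValueError("two-sample comparison supported only as paired")
        a = a - b
    n = a.shape[0]
    mean = a.mean(axis=0)
    sd = a.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} voxel(s) with zero variance flagged NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, mean / (sd / np.sqrt(n)))
    return t


class BlockGLM:
    """sklearn-style estimator for the gamma-block GLM.

    ``fit(X, design)`` accepts (n_series, n_time) percent-scaled data and
    exposes ``beta_``, ``tstat_``, ``residual_sd_`` and ``dof_``.
    """

    def __init__(self, detrend_order: int | None = None, hrf: np.ndarray | None = None):
        self.detrend_order = detrend_order
        self.hrf = hrf

    def get_params(self, deep: bool = True) -> dict:
        return {"detrend_order": self.detrend_order, "hrf": self.hrf}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in ("detrend_order", "hrf"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, design: EventDesign):
        res = glm_block(X, design, hrf=self.hrf, detrend_order=self.detrend_order)
        self.beta_ = np.atleast_1d(res.beta)
        self.tstat_ = np.atleast_1d(res.tstat)
        self.residual_sd_ = np.atleast_1d(res.residual_sd)
        self.dof_ = res.dof
        return self

    def predict(self, design: EventDesign) -> np.ndarray:
        """Fitted task component (beta x peak-normalized regressor) per series."""
        reg = block_regressor(design, self.hrf)
        return self.beta_[:, None] * reg[None, :]
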