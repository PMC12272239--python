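"""Synthetic BOLD generators with planted ground truth.

Each generator emulates one statistical regime the analysis stages assume:

* ``burst_suppression`` — a quasi-periodic burst train, convolved with a
  hemodynamic response kernel, added to a cortico-striatal subset of voxels
  (sparing a "visual" subset), on top of autocorrelated Gaussian noise.
* ``single_burst`` / ``no_bursts`` — the same model with exactly one or zero
  planted events.
* ``no_suppressions`` — a continuous band-limited Gaussian oscillation shared
  across the same loading map, which has near-zero skewness (the signature the
  classifier uses to separate it from burst-suppression).
* ``awake_like`` — samples from a block-structured covariance with a fixed
  number of modules per hemisphere, homotopic cross-hemisphere coupling and
  distance-decaying weights, mirroring awake resting-state network structure.

All outputs are reproducible bit-for-bit from the configuration seed, and a
:class:`SyntheticGroundTruth` record accompanies every run so recovery tests
can score the downstream estimators against the planted quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .containers import CarpetMatrix, Parcellation

__all__ = [
    "SimulationConfig",
    "StimulusDesign",
    "SyntheticGroundTruth",
    "simulate_burst_train",
    "gamma_hrf",
    "simulate_state_run",
    "simulate_visual_run",
    "make_parcellation",
]

STATES = ("burst_suppression", "single_burst", "no_bursts", "no_suppressions", "awake_like")

#: shape of the gamma-distributed inter-burst intervals ("quasi-periodic":
#: clustered-but-regular events rather than a memoryless Poisson train)
BURST_INTERVAL_SHAPE = 4.0


@dataclass
class SimulationConfig:
    """Generative knobs for one synthetic run.

    ``burst_amplitude`` and ``noise_sd`` are in the same (arbitrary) signal
    units, so their ratio is the burst SNR; the default ratio of 10 puts the
    burst regressor far above the noise floor, the regime in which the
    PCA-based detector is expected to operate cleanly.
    """

    n_voxels: int = 120
    n_nodes: int = 24
    tr_seconds: float = 2.0
    run_length_volumes: int = 150
    state: str = "burst_suppression"
    burst_rate: float = 1.2          # events per minute
    burst_amplitude: float = 10.0
    noise_sd: float = 1.0
    bs_loading_fraction: float = 0.8  # remainder is the zero-loading "visual" set
    module_count_per_hemisphere: int = 4
    homotopic_r: float = 0.5
    distance_decay_scale: float = 10.0  # mm
    ar1_phi: float = 0.3
    burst_refractory_seconds: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.run_length_volumes < 2:
            raise ValueError("run_length_volumes must be >= 2")
        if not 0.0 <= self.bs_loading_fraction <= 1.0:
            raise ValueError("bs_loading_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_nodes % 2:
            raise ValueError("n_nodes must be even (half per hemisphere)")


@dataclass
class StimulusDesign:
    """30 s baseline followed by ON/OFF blocks (defaults: 5 x 30 s ON / 30 s OFF)."""

    baseline_seconds: float = 30.0
    on_seconds: float = 30.0
    off_seconds: float = 30.0
    n_blocks: int = 5

    @property
    def total_seconds(self) -> float:
        return self.baseline_seconds + self.n_blocks * (self.on_seconds + self.off_seconds)

    def n_volumes(self, tr: float) -> int:
        return int(round(self.total_seconds / tr))

    def onsets(self) -> np.ndarray:
        """Stimulus onsets in seconds from run start."""
        period = self.on_seconds + self.off_seconds
        return self.baseline_seconds + period * np.arange(self.n_blocks)

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onsets(),
                "duration": np.full(self.n_blocks, self.on_seconds),
                "trial_type": ["visual"] * self.n_blocks,
            }
        )


@dataclass
class SyntheticGroundTruth:
    """Planted quantities recorded alongside every generated run."""

    burst_times: list[float] = field(default_factory=list)
    voxel_loadings: np.ndarray | None = None
    burst_regressor: np.ndarray | None = None
    module_assignment: np.ndarray | None = None
    hemisphere: np.ndarray | None = None
    centroid: np.ndarray | None = None
    response_amplitude: np.ndarray | None = None
    covariance: np.ndarray | None = None
    state: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.burst_times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("burst_times must be strictly increasing")


def simulate_burst_train(
    rate: float,
    duration: float,
    refractory: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[float]:
    """Sample quasi-periodic burst event times on ``[0, duration)``.

    Inter-event intervals are ``refractory`` plus a gamma variate of shape
    :data:`BURST_INTERVAL_SHAPE` whose mean is set so the overall mean interval
    equals ``60 / rate`` seconds (events per minute).  Shape > 1 makes the
    train clustered-but-regular rather than Poisson.  The first event is drawn
    from the equilibrium (residual-life) distribution, so the expected count
    over a window of length T is exactly ``rate * T / 60``.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if refractory < 0:
        raise ValueError("refractory must be nonnegative")
    if rate == 0:
        return []
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean_interval = 60.0 / rate
    excess = max(mean_interval - refractory, 1e-9)
    scale = excess / BURST_INTERVAL_SHAPE
    # equilibrium start: residual life U * J with J a length-biased interval;
    # for J = refractory + gamma(k) the length-biased law is the mixture
    # (refractory * gamma(k) + mean_excess * gamma(k+1)) / (refractory + mean_excess)
    if rng.uniform() < refractory / (refractory + excess):
        j = refractory + rng.gamma(BURST_INTERVAL_SHAPE, scale)
    else:
        j = refractory + rng.gamma(BURST_INTERVAL_SHAPE + 1, scale)
    times: list[float] = []
    t = rng.uniform() * j
    while t < duration:
        times.append(float(t))
        t += refractory + rng.gamma(BURST_INTERVAL_SHAPE, scale)
    return times


def gamma_hrf(tr: float, duration: float = 30.0, peak_seconds: float = 5.0) -> np.ndarray:
    """Gamma-variate hemodynamic response kernel sampled at ``tr``.

    The kernel is ``t**(a-1) * exp(-t/b)`` with the mode placed at
    ``peak_seconds`` and unit peak.  With the defaults (peak 5 s, 30 s
    support) it has decayed below 1% of its peak by the end of its support.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration < tr:
        raise ValueError("duration must be at least one TR")
    shape = 6.0
    scale = peak_seconds / (shape - 1.0)
    t = np.arange(0.0, duration + tr / 2, tr)
    h = t ** (shape - 1.0) * np.exp(-t / scale)
    peak = h.max()
    if peak <= 0:  # duration < first sample past zero cannot occur for tr>0
        raise ValueError("degenerate HRF")
    return h / peak


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, phi: float) -> np.ndarray:
    """i.i.d.-per-voxel AR(1) noise with stationary standard deviation ``sd``."""
    white = rng.standard_normal(shape)
    if phi == 0:
        return sd * white
    innov_sd = np.sqrt(1.0 - phi**2)
    out = np.empty(shape)
    out[:, 0] = white[:, 0]
    for t in range(1, shape[1]):
        out[:, t] = phi * out[:, t - 1] + innov_sd * white[:, t]
    return sd * out


def _events_to_regressor(times: list[float], n_vol: int, tr: float, hrf: np.ndarray) -> np.ndarray:
    """Delta train at event times convolved with the HRF, unit peak if nonzero."""
    impulses = np.zeros(n_vol)
    for t in times:
        idx = int(round(t / tr))
        if 0 <= idx < n_vol:
            impulses[idx] += 1.0
    reg = np.convolve(impulses, hrf)[:n_vol]
    peak = np.abs(reg).max()
    return reg / peak if peak > 0 else reg


def _voxel_labels(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Region/hemisphere tags and burst loadings: high for the cortico-striatal
    fraction, exactly zero for the "visual" remainder."""
    n = cfg.n_voxels
    n_loaded = int(round(cfg.bs_loading_fraction * n))
    region = np.empty(n, dtype=object)
    # cortico-striatal loaded set: alternate cortex/striatum tags
    region[:n_loaded] = np.where(np.arange(n_loaded) % 3 == 2, "striatum", "cortex")
    region[n_loaded:] = "visual_cortex"
    hemisphere = np.where(np.arange(n) % 2 == 0, "L", "R")
    loadings = np.zeros(n)
    loadings[:n_loaded] = 1.0 + 0.2 * rng.standard_normal(n_loaded)
    loadings[:n_loaded] = np.clip(loadings[:n_loaded], 0.3, None)
    labels = pd.DataFrame({"region": region, "hemisphere": hemisphere})
    return labels, loadings


def make_parcellation(
    n_nodes: int = 24,
    module_count_per_hemisphere: int = 4,
    spacing_mm: float = 4.0,
) -> tuple[Parcellation, np.ndarray]:
    """Deterministic parcellation on two mirrored 3-D grids.

    Nodes within a hemisphere are laid out along a spatial axis and chunked
    into ``module_count_per_hemisphere`` contiguous modules; the right
    hemisphere mirrors the left in x, so homotopy and Euclidean distance are
    both well defined.  Returns the parcellation and the planted whole-brain
    module assignment (module ids shared across hemispheres, contiguous
    from 1).
    """
    if n_nodes % 2:
        raise ValueError("n_nodes must be even")
    per_hemi = n_nodes // 2
    if module_count_per_hemisphere > per_hemi:
        raise ValueError("more modules than nodes per hemisphere")
    # lay nodes on a y/z grid, offset hemispheres in +-x
    side = int(np.ceil(np.sqrt(per_hemi)))
    iy, iz = np.divmod(np.arange(per_hemi), side)
    rows = []
    modules = np.zeros(n_nodes, dtype=int)
    module_of = (np.arange(per_hemi) * module_count_per_hemisphere) // per_hemi + 1
    for h_idx, (hemi, sign) in enumerate((("L", -1.0), ("R", 1.0))):
        for k in range(per_hemi):
            node_id = h_idx * per_hemi + k
            partner = (1 - h_idx) * per_hemi + k
            rows.append(
                {
                    "id": node_id,
                    "name": f"{hemi}_m{module_of[k]}_n{k}",
                    "hemisphere": hemi,
                    "partner": partner,
                    "x": sign * (8.0 + 2.0 * module_of[k]),
                    "y": spacing_mm * iy[k] + 1.5 * module_of[k],
                    "z": spacing_mm * iz[k],
                    "class": "subcortical" if module_of[k] == module_count_per_hemisphere else "cortical",
                }
            )
            modules[node_id] = module_of[k]
    parc = Parcellation(pd.DataFrame(rows))
    return parc, modules


def _awake_covariance(cfg: SimulationConfig, parc: Parcellation, modules: np.ndarray) -> np.ndarray:
    """Block covariance: within-module 0.6, between 0.1, homotopic coupling,
    all decaying with centroid distance; projected to the PSD cone and
    renormalized to unit diagonal."""
    n = parc.n_nodes
    cent = parc.centroids()
    hemi = parc.table["hemisphere"].to_numpy()
    partner = parc.partner_positions()
    d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
    same_mod = modules[:, None] == modules[None, :]
    same_hemi = hemi[:, None] == hemi[None, :]
    c = np.where(same_mod, 0.6, 0.1) * np.exp(-d / cfg.distance_decay_scale)
    # cross-hemisphere structure is homotopic, not distance-driven
    cross = ~same_hemi
    c[cross] = np.where(same_mod[cross], 0.6 * cfg.homotopic_r, 0.05)
    is_partner = np.zeros((n, n), dtype=bool)
    is_partner[np.arange(n), partner] = True
    c[is_partner] = cfg.homotopic_r
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    # PSD projection
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-6, None)
    c = v @ np.diag(w) @ v.T
    dsqrt = np.sqrt(np.diag(c))
    c = c / np.outer(dsqrt, dsqrt)
    return c


def simulate_state_run(cfg: SimulationConfig) -> tuple[CarpetMatrix, SyntheticGroundTruth]:
    """Generate one resting-state run in the regime named by ``cfg.state``."""
    rng = np.random.default_rng(cfg.seed)
    n_vol = cfg.run_length_volumes
    duration = n_vol * cfg.tr_seconds

    if cfg.state == "awake_like":
        parc, modules = make_parcellation(cfg.n_nodes, cfg.module_count_per_hemisphere)
        cov = _awake_covariance(cfg, parc, modules)
        chol = np.linalg.cholesky(cov)
        data = chol @ rng.standard_normal((cfg.n_nodes, n_vol))
        labels = parc.table[["hemisphere"]].copy()
        labels["region"] = parc.table["name"]
        carpet = CarpetMatrix(data, tr_seconds=cfg.tr_seconds, voxel_labels=labels,
                              condition="awake")
        truth = SyntheticGroundTruth(
            module_assignment=modules,
            hemisphere=parc.table["hemisphere"].to_numpy(),
            centroid=parc.centroids(),
            covariance=cov,
            state=cfg.state,
        )
        return carpet, truth

    labels, loadings = _voxel_labels(cfg, rng)
    hrf = gamma_hrf(cfg.tr_seconds)
    noise = _ar1_noise(rng, (cfg.n_voxels, n_vol), cfg.noise_sd, cfg.ar1_phi)

    if cfg.state == "no_bursts":
        burst_times: list[float] = []
        regressor = np.zeros(n_vol)
        data = noise
    elif cfg.state == "single_burst":
        burst_times = [duration / 2.0]
        regressor = _events_to_regressor(burst_times, n_vol, cfg.tr_seconds, hrf)
        data = cfg.burst_amplitude * np.outer(loadings, regressor) + noise
    elif cfg.state == "burst_suppression":
        burst_times = simulate_burst_train(
            cfg.burst_rate, duration, refractory=cfg.burst_refractory_seconds, seed=rng
        )
        regressor = _events_to_regressor(burst_times, n_vol, cfg.tr_seconds, hrf)
        data = cfg.burst_amplitude * np.outer(loadings, regressor) + noise
    elif cfg.state == "no_suppressions":
        # continuous narrowband oscillation: symmetric => skew ~ 0; the narrow
        # band (0.03-0.06 Hz) keeps the sample skewness tight around zero
        burst_times = []
        fs = 1.0 / cfg.tr_seconds
        sos = sp_signal.butter(4, [0.03, 0.06], btype="bandpass", fs=fs, output="sos")
        raw = rng.standard_normal(n_vol + 400)
        osc = sp_signal.sosfiltfilt(sos, raw)[200:200 + n_vol]
        osc = osc / osc.std()
        regressor = osc
        data = cfg.burst_amplitude * np.outer(loadings, osc) + noise
    else:  # pragma: no cover - guarded by SimulationConfig
        raise ValueError(cfg.state)

    carpet = CarpetMatrix(data, tr_seconds=cfg.tr_seconds, voxel_labels=labels,
                          condition=cfg.state)
    truth = SyntheticGroundTruth(
        burst_times=burst_times,
        voxel_loadings=loadings,
        burst_regressor=regressor,
        state=cfg.state,
    )
    return carpet, truth


def simulate_visual_run(
    cfg: SimulationConfig,
    design: StimulusDesign | None = None,
    amplitudes: np.ndarray | None = None,
    baseline_mean: float = 500.0,
) -> tuple[CarpetMatrix, SyntheticGroundTruth, pd.DataFrame]:
    """Generate a block-design visual-stimulation run (node x time, raw units).

    Each node's signal is ``baseline_mean * (1 + amplitude/100 * r(t))`` plus
    Gaussian noise, where ``r`` is the ON boxcar convolved with the HRF and
    peak-normalized, so ``amplitude`` is the planted percent-BOLD response.
    ``cfg.noise_sd`` is interpreted in percent of baseline so that, after
    percent scaling, the residual standard deviation is about ``noise_sd``.
    """
    design = design or StimulusDesign()
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    if amplitudes is None:
        amplitudes = np.full(cfg.n_nodes, 1.0)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (cfg.n_nodes,):
        raise ValueError("amplitudes must have one entry per node")
    rng = np.random.default_rng(cfg.seed)
    n_vol = design.n_volumes(cfg.tr_seconds)
    t = np.arange(n_vol) * cfg.tr_seconds
    boxcar = np.zeros(n_vol)
    for onset in design.onsets():
        boxcar[(t >= onset) & (t < onset + design.on_seconds)] = 1.0
    hrf = gamma_hrf(cfg.tr_seconds)
    reg = np.convolve(boxcar, hrf)[:n_vol]
    reg = reg / reg.max()
    noise = rng.standard_normal((cfg.n_nodes, n_vol)) * (cfg.noise_sd / 100.0 * baseline_mean)
    data = baseline_mean * (1.0 + amplitudes[:, None] / 100.0 * reg[None, :]) + noise
    labels = pd.DataFrame(
        {
            "region": [f"node{i}" for i in range(cfg.n_nodes)],
            "hemisphere": np.where(np.arange(cfg.n_nodes) % 2 == 0, "L", "R"),
        }
    )
    carpet = CarpetMatrix(data, tr_seconds=cfg.tr_seconds, voxel_labels=labels,
                          condition="visual")
    truth = SyntheticGroundTruth(response_amplitude=amplitudes, burst_regressor=reg,
                                 state="visual")
    return carpet, truth, design.events_table()
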