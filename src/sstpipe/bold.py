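"""Synthetic ROI-level BOLD generator with known ground truth.

Each region-of-interest timeseries is built as

    baseline + sum_c (canonical_c * beta_c + derivative_c * beta_dc)
             + sinusoidal drift + AR(1) noise,

where the condition regressors come from the same HRF convolution machinery
the analysis uses, so a noiseless run is recovered exactly by the first-level
GLM.  Optional per-ROI voxel blocks share the ROI signal (scaled per voxel)
plus independent noise, providing fixtures for probability-weighted
extraction and tSNR computation.  The drift is a sinusoid with period longer
than the analysis high-pass cutoff, so its attenuation by the filter is
analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .designs import DatasetDesign
from .hrf import HRFParams, build_condition_regressor
from .race import TrialRecord

__all__ = [
    "ROISpec", "NoiseSpec", "SyntheticRun",
    "synthesize_run", "synthesize_voxel_block", "default_roi_roster",
]

ROI_NAMES = ("IFG", "M1", "preSMA", "caudate", "GPe", "GPi",
             "putamen", "SN", "STN", "Tha", "VTA")
CONDITIONS = ("GO", "FS", "SS")


@dataclass(frozen=True)
class ROISpec:
    """One region of interest with probabilistic voxel membership.

    ``true_betas`` maps condition -> (canonical amplitude, derivative
    amplitude) in arbitrary signal units; it is the ground truth that
    recovery tests compare against.
    """

    name: str
    hemisphere: str  # "left" | "right"
    n_voxels: int = 20
    voxel_prob_weights: Optional[np.ndarray] = None
    voxel_volume_mm3: float = 3.375
    true_betas: dict = field(default_factory=lambda: {c: (0.0, 0.0) for c in CONDITIONS})

    def __post_init__(self) -> None:
        if self.name not in ROI_NAMES:
            raise ValueError(f"unknown ROI {self.name!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if self.n_voxels < 1:
            raise ValueError("n_voxels >= 1 required")
        if self.voxel_volume_mm3 <= 0:
            raise ValueError("voxel_volume_mm3 must be positive")
        if self.voxel_prob_weights is not None:
            w = np.asarray(self.voxel_prob_weights, dtype=float)
            if w.size != self.n_voxels or np.any(w <= 0) or np.any(w > 1):
                raise ValueError("weights must be n_voxels values in (0, 1]")

    @property
    def weights(self) -> np.ndarray:
        if self.voxel_prob_weights is None:
            return np.ones(self.n_voxels)
        return np.asarray(self.voxel_prob_weights, dtype=float)

    @property
    def key(self) -> str:
        return f"{self.name}-{'l' if self.hemisphere == 'left' else 'r'}"


@dataclass(frozen=True)
class NoiseSpec:
    """Additive noise model: white/AR(1) noise plus slow sinusoidal drift."""

    sigma: float = 1.0
    ar1_phi: float = 0.3
    drift_amp: float = 2.0
    drift_period_s: float = 300.0
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if not -1 < self.ar1_phi < 1:
            raise ValueError("|ar1_phi| must be < 1")
        if self.sigma < 0 or self.drift_amp < 0:
            raise ValueError("sigma and drift_amp must be non-negative")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")


@dataclass
class SyntheticRun:
    """One synthesised run: ROI timeseries, optional voxel blocks, events."""

    roi_timeseries: pd.DataFrame  # volumes x ROI-key columns
    events: list[TrialRecord]
    confounds: pd.DataFrame
    tr_s: float
    ground_truth: dict  # roi key -> ROISpec, plus "noise" -> NoiseSpec
    voxel_blocks: dict = field(default_factory=dict)  # roi key -> (voxels x volumes)


def _ar1_noise(n: int, sigma: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1) series with innovation SD ``sigma``, started from stationarity."""
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    x[0] = eps[0] / np.sqrt(1.0 - phi * phi) if phi != 0 else eps[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def synthesize_voxel_block(mean: float, sd: float, n_voxels: int, n_volumes: int,
                           seed: int) -> np.ndarray:
    """i.i.d. Gaussian voxel block of shape (n_voxels, n_volumes)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full((n_voxels, n_volumes), float(mean))
    return rng.normal(mean, sd, size=(n_voxels, n_volumes))


def run_duration_volumes(events: Sequence[TrialRecord], tr_s: float,
                         tail_s: float = 32.0) -> int:
    """Number of volumes needed to cover the events plus an HRF tail."""
    last = max(t.onset_s for t in events) if events else 0.0
    return int(np.ceil((last + tail_s) / tr_s))


def synthesize_run(
    design: DatasetDesign,
    roispecs: Sequence[ROISpec],
    noise: NoiseSpec,
    events: Sequence[TrialRecord],
    seed: int,
    hrf: HRFParams | None = None,
    n_volumes: int | None = None,
    with_voxel_blocks: bool = False,
) -> SyntheticRun:
    """Generate one run of ROI BOLD data from an event list.

    Each ROI gets its own AR(1) noise stream and drift phase; voxel blocks
    (when requested) share the ROI signal scaled by the membership
    probability of each voxel, plus independent white noise.
    """
    if not events:
        raise ValueError("no events supplied")
    hrf = hrf or HRFParams()
    tr = design.tr_s
    if n_volumes is None:
        n_volumes = run_duration_volumes(events, tr)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB01D]))
    t_vol = np.arange(n_volumes) * tr

    regressors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    import warnings

    for cond in CONDITIONS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regressors[cond] = build_condition_regressor(
                events, cond, design.lock, tr, n_volumes, hrf
            )

    series: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    for spec in roispecs:
        signal = np.full(n_volumes, float(noise.baseline))
        for cond in CONDITIONS:
            can, der = regressors[cond]
            b_can, b_der = spec.true_betas.get(cond, (0.0, 0.0))
            signal = signal + b_can * can + b_der * der
        phase = rng.uniform(0, 2 * np.pi)
        drift = noise.drift_amp * np.sin(2 * np.pi * t_vol / noise.drift_period_s + phase)
        eta = _ar1_noise(n_volumes, noise.sigma, noise.ar1_phi, rng) if noise.sigma > 0 \
            else np.zeros(n_volumes)
        roi_series = signal + drift + eta
        series[spec.key] = roi_series
        if with_voxel_blocks:
            w = spec.weights
            vox_noise = rng.normal(0.0, noise.sigma, size=(spec.n_voxels, n_volumes)) \
                if noise.sigma > 0 else np.zeros((spec.n_voxels, n_volumes))
            blocks[spec.key] = w[:, None] * roi_series[None, :] + vox_noise

    confounds = _synth_confounds(n_volumes, tr, rng)
    gt = {spec.key: spec for spec in roispecs}
    gt["noise"] = noise
    return SyntheticRun(
        roi_timeseries=pd.DataFrame(series),
        events=list(events),
        confounds=confounds,
        tr_s=tr,
        ground_truth=gt,
        voxel_blocks=blocks,
    )


def _synth_confounds(n_volumes: int, tr_s: float,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Low-amplitude smooth nuisance columns standing in for motion/FD/DVARS."""
    t = np.arange(n_volumes) * tr_s
    cols = {}
    for i in range(6):
        period = rng.uniform(40.0, 200.0)
        cols[f"motion_{i}"] = 0.05 * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
    cols["framewise_displacement"] = np.abs(rng.normal(0.1, 0.03, size=n_volumes))
    cols["dvars"] = np.abs(rng.normal(1.0, 0.1, size=n_volumes))
    return pd.DataFrame(cols)


def default_roi_roster(
    effect_betas: dict | None = None,
    n_voxels: int = 20,
    voxel_volume_mm3: float = 3.375,
    seed: int = 0,
) -> list[ROISpec]:
    """The 11-region x 2-hemisphere roster with optional per-ROI effects.

    ``effect_betas`` maps ROI key (e.g. ``"STN-l"``) or bare ROI name to a
    ``{condition: (beta, beta_derivative)}`` dict; unlisted regions get null
    effects.  Membership probabilities are drawn once from U(0.5, 1).
    """
    rng = np.random.default_rng(seed)
    effect_betas = effect_betas or {}
    roster = []
    for name in ROI_NAMES:
        for hemi in ("left", "right"):
            key = f"{name}-{'l' if hemi == 'left' else 'r'}"
            betas = effect_betas.get(key, effect_betas.get(name))
            spec = ROISpec(
                name=name, hemisphere=hemi, n_voxels=n_voxels,
                voxel_prob_weights=rng.uniform(0.5, 1.0, size=n_voxels),
                voxel_volume_mm3=voxel_volume_mm3,
                true_betas={c: tuple(betas.get(c, (0.0, 0.0))) for c in CONDITIONS}
                if betas else {c: (0.0, 0.0) for c in CONDITIONS},
            )
            roster.append(spec)
    return roster
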