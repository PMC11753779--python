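"""Canonical double-gamma haemodynamic response function and regressors.

The HRF is the difference of two gamma densities — a positive peak around
5–6 s and a later undershoot around 16 s scaled down by the
peak/undershoot ratio — normalised to a maximum of 1.  Event regressors are
built by placing unit impulses on a fine oversampling grid, convolving with
the HRF (and with its finite-difference temporal derivative for the
derivative column), and sampling at the volume acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .race import TrialRecord

__all__ = ["HRFParams", "double_gamma_hrf", "build_condition_regressor"]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF shape parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0
    derivative_dt_s: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s", "undershoot_delay_s", "peak_dispersion_s",
            "undershoot_dispersion_s", "peak_undershoot_ratio", "duration_s",
            "derivative_dt_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.duration_s <= self.undershoot_delay_s:
            raise ValueError("duration_s must cover the undershoot")


def double_gamma_hrf(params: HRFParams, t_grid_s: np.ndarray) -> np.ndarray:
    """Evaluate the peak-normalised double-gamma HRF on a time grid.

    ``h(t) = g(t; delay1/disp1, disp1) - g(t; delay2/disp2, disp2) / ratio``
    with gamma densities ``g``, then divided by its maximum.
    """
    t = np.asarray(t_grid_s, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("t_grid_s must be non-negative and increasing")
    peak = stats.gamma.pdf(
        t, params.peak_delay_s / params.peak_dispersion_s,
        scale=params.peak_dispersion_s,
    )
    under = stats.gamma.pdf(
        t, params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s,
    )
    h = peak - under / params.peak_undershoot_ratio
    # normalise against the true maximum (dense reference grid), so that the
    # shape does not depend on how coarsely the caller samples it
    ref_t = np.arange(0.0, params.duration_s, 0.01)
    ref = (
        stats.gamma.pdf(ref_t, params.peak_delay_s / params.peak_dispersion_s,
                        scale=params.peak_dispersion_s)
        - stats.gamma.pdf(ref_t,
                          params.undershoot_delay_s / params.undershoot_dispersion_s,
                          scale=params.undershoot_dispersion_s)
        / params.peak_undershoot_ratio
    )
    return h / ref.max()


def _event_onsets(events: Sequence[TrialRecord], condition: str, lock: str) -> np.ndarray:
    """Onset times (s) for one condition under go- or stop-signal locking."""
    onsets = []
    for t in events:
        label = _condition_of(t)
        if label != condition:
            continue
        onset = t.onset_s
        if lock == "stop" and label in ("FS", "SS"):
            if t.ssd_ms is None:
                raise ValueError("stop-locked events require an SSD")
            onset = onset + t.ssd_ms / 1000.0
        onsets.append(onset)
    return np.asarray(onsets, dtype=float)


def _condition_of(t: TrialRecord) -> str:
    if t.trial_type == "go":
        return "GO"
    return "FS" if t.outcome == "FS" else "SS"


def build_condition_regressor(
    events: Sequence[TrialRecord],
    condition: str,
    lock: str,
    tr_s: float,
    n_volumes: int,
    hrf: HRFParams | None = None,
    oversample_dt_s: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolved regressor (canonical, temporal-derivative) for one condition.

    Events are modelled as zero-duration impulses on an oversampling grid
    (default 0.1 s), convolved with the HRF, and sampled at volume times
    ``0, TR, 2 TR, ...``.  A condition with no events yields all-zero
    columns.

    Returns
    -------
    (canonical, derivative) : two arrays of length ``n_volumes``
    """
    if lock not in ("go", "stop"):
        raise ValueError("lock must be 'go' or 'stop'")
    if condition not in ("GO", "FS", "SS"):
        raise ValueError("condition must be GO, FS or SS")
    hrf = hrf or HRFParams()
    onsets = _event_onsets(events, condition, lock)
    if onsets.size == 0:
        import warnings

        warnings.warn(f"no events for condition {condition}; zero regressor",
                      stacklevel=2)
        zero = np.zeros(n_volumes)
        return zero, zero.copy()

    dt = oversample_dt_s
    run_dur = n_volumes * tr_s
    n_fine = int(np.ceil((run_dur + hrf.duration_s) / dt)) + 1
    stick = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(stick, idx[idx < n_fine], 1.0)

    kernel_t = np.arange(0.0, hrf.duration_s + dt / 2, dt)
    kernel = double_gamma_hrf(hrf, kernel_t)
    d_dt = hrf.derivative_dt_s
    kernel_shift = double_gamma_hrf(hrf, kernel_t + d_dt)
    dkernel = (kernel_shift - kernel) / d_dt

    fine = np.convolve(stick, kernel)[:n_fine]
    dfine = np.convolve(stick, dkernel)[:n_fine]

    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    return fine[vol_idx], dfine[vol_idx]
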