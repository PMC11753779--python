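"""Independent horse-race simulator for the stop-signal task.

On every trial a *go* process races toward a response; on stop trials a
*stop* process starts at go onset + SSD and, if it finishes first, the
response is inhibited.  Go finishing times are ex-Gaussian (normal +
exponential, the standard choice for response-time modelling, with an
analytic CDF that serves as an oracle in the tests).  The stop latency is
ex-Gaussian too; setting its sigma and tau to zero makes it deterministic and
equal to the true SSRT, which is how parameter-recovery studies are run.

The stop-signal delay is adapted by the classic +/-step staircase: a failed
stop lowers the SSD by one step (easier to stop next time), a successful stop
raises it, so stopping accuracy converges to ~50% and the SSD distribution
tracks the subject's SSRT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .designs import DatasetDesign

logger = logging.getLogger(__name__)

_TRUNCATION_RESAMPLE_CAP = 100

# Trial outcome labels
GO_CORRECT = "GO_correct"
GO_ERROR = "GO_error"
GO_OMISSION = "GO_omission"
FS = "FS"  # failed stop: responded despite the stop signal
SS = "SS"  # successful stop: inhibited


@dataclass(frozen=True)
class RaceParams:
    """Parameters of the independent race between go and stop processes.

    All times in milliseconds.  ``stop_sigma = stop_tau = 0`` makes the stop
    latency deterministic (equal to the true SSRT).
    """

    go_mu: float = 400.0
    go_sigma: float = 50.0
    go_tau: float = 60.0
    stop_mu: float = 200.0
    stop_sigma: float = 0.0
    stop_tau: float = 0.0
    p_go_omission: float = 0.0
    p_choice_error: float = 0.0

    def __post_init__(self) -> None:
        if self.go_sigma <= 0:
            raise ValueError("go_sigma must be positive")
        if self.stop_sigma < 0 or self.stop_tau < 0 or self.go_tau < 0:
            raise ValueError("sigma/tau parameters must be non-negative")
        for p in (self.p_go_omission, self.p_choice_error):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TrialRecord:
    """One fully labelled stop-signal trial."""

    index: int
    trial_type: str  # "go" | "stop"
    direction: str  # "left" | "right"
    onset_s: float
    ssd_ms: Optional[float] = None
    staircase_id: Optional[int] = None
    response: Optional[str] = None  # "left" | "right" | None
    rt_ms: Optional[float] = None
    outcome: Optional[str] = None


def _draw_positive_exgauss(mu: float, sigma: float, tau: float,
                           rng: np.random.Generator) -> float:
    """Ex-Gaussian draw truncated at zero by resampling (cap 100 redraws)."""
    if sigma == 0 and tau == 0:
        return mu
    for _ in range(_TRUNCATION_RESAMPLE_CAP):
        x = rng.normal(mu, sigma) if sigma > 0 else mu
        if tau > 0:
            x += rng.exponential(tau)
        if x > 0:
            return x
    logger.warning(
        "finishing-time draw stayed non-positive after %d redraws; clamping",
        _TRUNCATION_RESAMPLE_CAP,
    )
    return max(x, 1e-3)


def simulate_race_trial(params: RaceParams, ssd_ms: Optional[float],
                        rng: np.random.Generator,
                        direction: str = "left") -> tuple[Optional[str], Optional[float], str]:
    """Race go and stop processes on one trial.

    Parameters
    ----------
    params : RaceParams
    ssd_ms : float or None
        Stop-signal delay; ``None`` marks a go trial.
    rng : numpy Generator
    direction : str
        The direction of the go stimulus (determines the correct response).

    Returns
    -------
    (response, rt_ms, outcome)
        ``response`` is the pressed side or ``None``; ``rt_ms`` the observed
        reaction time for responses; ``outcome`` one of ``GO_correct``,
        ``GO_error``, ``GO_omission``, ``FS``, ``SS``.
    """
    if ssd_ms is not None and ssd_ms < 0:
        raise ValueError("ssd_ms must be non-negative on stop trials")

    omitted = params.p_go_omission > 0 and rng.random() < params.p_go_omission
    if omitted:
        # the go process never reaches threshold; on a stop trial that is an
        # automatic successful stop
        return (None, None, SS if ssd_ms is not None else GO_OMISSION)

    go_time = _draw_positive_exgauss(params.go_mu, params.go_sigma,
                                     params.go_tau, rng)

    if ssd_ms is not None:
        stop_time = ssd_ms + _draw_positive_exgauss(
            params.stop_mu, params.stop_sigma, params.stop_tau, rng
        ) if (params.stop_sigma > 0 or params.stop_tau > 0) else ssd_ms + params.stop_mu
        if go_time >= stop_time:
            return (None, None, SS)
        # go won: signal-respond trial; the RT is the go finishing time
        resp = _response_side(direction, params, rng)
        return (resp, go_time, FS)

    resp = _response_side(direction, params, rng)
    outcome = GO_CORRECT if resp == direction else GO_ERROR
    return (resp, go_time, outcome)


def _response_side(direction: str, params: RaceParams,
                   rng: np.random.Generator) -> str:
    if params.p_choice_error > 0 and rng.random() < params.p_choice_error:
        return "right" if direction == "left" else "left"
    return direction


def update_staircase(ssd_ms: float, outcome: str, design: DatasetDesign) -> float:
    """One step of the +/-step SSD staircase, clipped to the design bounds.

    A failed stop (FS) makes stopping easier next time (SSD - step); a
    successful stop (SS) makes it harder (SSD + step).
    """
    if outcome == FS:
        new = ssd_ms - design.ssd_step_ms
    elif outcome == SS:
        new = ssd_ms + design.ssd_step_ms
    else:
        raise ValueError(f"staircase updates only on stop outcomes, got {outcome!r}")
    return float(np.clip(new, design.ssd_min_ms, design.ssd_max_ms))


def generate_trial_sequence(design: DatasetDesign, seed: int) -> list[TrialRecord]:
    """Build the trial-order scaffold of a session (no outcomes yet).

    The designed number of stop trials (nearest integer to
    ``total_trials * stop_fraction``, ties toward more stops) is placed at
    seed-randomised positions; directions are balanced; onsets increase by a
    uniformly jittered inter-trial interval; stop trials are assigned to the
    interleaved staircases round-robin in order of occurrence.
    """
    rng = np.random.default_rng(seed)
    n_total = design.total_trials
    if n_total <= 0:
        raise ValueError("design has no trials")
    n_stop = design.n_stop_trials
    if abs(n_total * design.stop_fraction - round(n_total * design.stop_fraction)) > 1e-9:
        logger.info("stop count %.2f rounded to %d", n_total * design.stop_fraction, n_stop)

    is_stop = np.zeros(n_total, dtype=bool)
    is_stop[rng.permutation(n_total)[:n_stop]] = True

    directions = np.array(["left", "right"])[
        rng.permutation(np.arange(n_total) % 2)
    ]

    iti = design.iti_model
    gaps = iti.mean_s + rng.uniform(-iti.jitter_s, iti.jitter_s, size=n_total)
    onsets = np.concatenate([[0.0], np.cumsum(gaps[:-1])])

    trials: list[TrialRecord] = []
    stop_seen = 0
    for i in range(n_total):
        stair = None
        if is_stop[i]:
            stair = stop_seen % design.n_staircases
            stop_seen += 1
        trials.append(TrialRecord(
            index=i,
            trial_type="stop" if is_stop[i] else "go",
            direction=str(directions[i]),
            onset_s=float(onsets[i]),
            staircase_id=stair,
        ))
    return trials


def simulate_session(design: DatasetDesign, params: RaceParams,
                     seed: int) -> list[TrialRecord]:
    """Simulate one complete session: sequence, race outcomes, staircases.

    Staircases evolve independently; every trial comes back fully labelled.
    The result is a deterministic function of ``(design, params, seed)``.
    """
    trials = generate_trial_sequence(design, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    ssd = [design.start_ssd_ms] * design.n_staircases

    for t in trials:
        if t.trial_type == "stop":
            t.ssd_ms = ssd[t.staircase_id]
            t.response, t.rt_ms, t.outcome = simulate_race_trial(
                params, t.ssd_ms, rng, t.direction
            )
            ssd[t.staircase_id] = update_staircase(t.ssd_ms, t.outcome, design)
        else:
            t.response, t.rt_ms, t.outcome = simulate_race_trial(
                params, None, rng, t.direction
            )
    return trials


def split_runs(trials: Sequence[TrialRecord], n_runs: int) -> list[list[TrialRecord]]:
    """Split a session into ``n_runs`` consecutive runs of (near-)equal size.

    Onsets are re-referenced so each run starts at 0 s.
    """
    import copy

    n = len(trials)
    base, extra = divmod(n, n_runs)
    runs: list[list[TrialRecord]] = []
    start = 0
    for r in range(n_runs):
        size = base + (1 if r < extra else 0)
        chunk = [copy.copy(t) for t in trials[start:start + size]]
        if chunk:
            t0 = chunk[0].onset_s
            for t in chunk:
                t.onset_s -= t0
        runs.append(chunk)
        start += size
    return runs
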