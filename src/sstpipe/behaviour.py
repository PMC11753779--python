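"""Behavioural summaries, SSRT estimation, QC exclusions, RT comparisons.

The stop-signal reaction time (SSRT) is estimated by the integration method
with go-omission replacement: omitted go trials are assigned the slowest
observed go RT, the go-RT distribution is sorted, and the SSRT is the RT at
rank ``ceil(N * p(respond|signal))`` minus the mean SSD.  Exclusion criteria
follow the standard QC battery for staircased stop-signal data:

1. more than 10% go omissions,
2. stopping accuracy below 35% or above 65%,
3. go accuracy below 95%,
4. mean failed-stop RT longer than mean go RT (race-model violation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .bayes import jzs_correlation_log10_bf, jzs_one_sample_log10_bf
from .race import FS, GO_CORRECT, GO_ERROR, GO_OMISSION, SS, TrialRecord

__all__ = [
    "BehaviouralSummary",
    "ExclusionReport",
    "summarize_behaviour",
    "estimate_ssrt_integration",
    "apply_exclusion_criteria",
    "paired_rt_comparison",
    "ssrt_go_correlation",
]


@dataclass
class BehaviouralSummary:
    """Descriptive statistics of one subject's stop-signal behaviour."""

    n_go: int
    n_stop: int
    median_go_rt_ms: Optional[float]
    median_fs_rt_ms: Optional[float]
    mean_go_rt_ms: Optional[float]
    mean_fs_rt_ms: Optional[float]
    go_omission_pct: float
    go_error_pct: float
    go_accuracy_pct: Optional[float]
    stop_accuracy_pct: Optional[float]
    mean_ssd_ms: Optional[float]
    median_ssd_ms: Optional[float]
    mean_ssrt_ms: Optional[float] = None
    p_respond_signal: Optional[float] = None


@dataclass
class ExclusionReport:
    subject: str
    excluded: bool
    criteria_failed: set[int] = field(default_factory=set)


def summarize_behaviour(trials: Sequence[TrialRecord]) -> BehaviouralSummary:
    """Summarise a trial set: medians over observed RTs, SSDs, accuracies.

    Medians are taken over observed responses only (omissions carry no RT).
    SSRT is filled in when the probability of responding to a signal lies
    strictly between 0 and 1; otherwise it is left absent.
    """
    go = [t for t in trials if t.trial_type == "go"]
    stop = [t for t in trials if t.trial_type == "stop"]
    if not go:
        raise ValueError("no go trials")

    go_rts = [t.rt_ms for t in go if t.rt_ms is not None]
    n_omit = sum(1 for t in go if t.outcome == GO_OMISSION)
    n_err = sum(1 for t in go if t.outcome == GO_ERROR)
    n_resp = len(go) - n_omit

    fs = [t for t in stop if t.outcome == FS]
    ss = [t for t in stop if t.outcome == SS]
    fs_rts = [t.rt_ms for t in fs if t.rt_ms is not None]
    ssds = [t.ssd_ms for t in stop if t.ssd_ms is not None]

    summary = BehaviouralSummary(
        n_go=len(go),
        n_stop=len(stop),
        median_go_rt_ms=float(np.median(go_rts)) if go_rts else None,
        median_fs_rt_ms=float(np.median(fs_rts)) if fs_rts else None,
        mean_go_rt_ms=float(np.mean(go_rts)) if go_rts else None,
        mean_fs_rt_ms=float(np.mean(fs_rts)) if fs_rts else None,
        go_omission_pct=100.0 * n_omit / len(go),
        go_error_pct=100.0 * n_err / len(go),
        go_accuracy_pct=(100.0 * (n_resp - n_err) / n_resp) if n_resp else None,
        stop_accuracy_pct=(100.0 * len(ss) / len(stop)) if stop else None,
        mean_ssd_ms=float(np.mean(ssds)) if ssds else None,
        median_ssd_ms=float(np.median(ssds)) if ssds else None,
    )
    if stop:
        p_respond = len(fs) / len(stop)
        summary.p_respond_signal = p_respond
        if 0.0 < p_respond < 1.0 and summary.mean_ssd_ms is not None:
            rts_with_flags = [(t.rt_ms, t.outcome == GO_OMISSION) for t in go]
            summary.mean_ssrt_ms = estimate_ssrt_integration(
                rts_with_flags, p_respond, summary.mean_ssd_ms
            )
    return summary


def estimate_ssrt_integration(
    go_rts_with_omission_flags: Sequence[tuple[Optional[float], bool]],
    p_respond_signal: float,
    mean_ssd_ms: float,
) -> float:
    """Integration-method SSRT with replacement of go omissions.

    Omitted go trials are assigned the maximum observed go RT; all go RTs
    (including choice errors) are sorted ascending, and the completion time
    of the stop process is the RT at rank ``ceil(N * p(respond|signal))``
    (1-based).  SSRT = that RT minus the mean SSD.
    """
    if not 0.0 < p_respond_signal < 1.0:
        raise ValueError(
            "p(respond|signal) on the boundary: SSRT undefined by integration"
        )
    observed = [rt for rt, om in go_rts_with_omission_flags if not om and rt is not None]
    if not observed:
        raise ValueError("no observed go RTs")
    max_rt = max(observed)
    rts = sorted(
        (max_rt if om or rt is None else rt)
        for rt, om in go_rts_with_omission_flags
    )
    n = len(rts)
    rank = min(max(math.ceil(n * p_respond_signal), 1), n)
    return float(rts[rank - 1] - mean_ssd_ms)


def apply_exclusion_criteria(summary: BehaviouralSummary, subject: str = "") -> ExclusionReport:
    """Evaluate the four QC criteria on a subject's aggregate behaviour.

    Criteria use strict inequalities: >10% omissions; stopping accuracy
    <35% or >65%; go accuracy <95%; mean failed-stop RT > mean go RT.
    Missing quantities (e.g. no failed stops) leave a criterion un-failed.
    """
    failed: set[int] = set()
    if summary.go_omission_pct > 10.0:
        failed.add(1)
    if summary.stop_accuracy_pct is not None and not (
        35.0 <= summary.stop_accuracy_pct <= 65.0
    ):
        failed.add(2)
    if summary.go_accuracy_pct is not None and summary.go_accuracy_pct < 95.0:
        failed.add(3)
    if (
        summary.mean_fs_rt_ms is not None
        and summary.mean_go_rt_ms is not None
        and summary.mean_fs_rt_ms > summary.mean_go_rt_ms
    ):
        failed.add(4)
    return ExclusionReport(subject=subject, excluded=bool(failed), criteria_failed=failed)


def paired_rt_comparison(
    fs_medians: Sequence[float], go_medians: Sequence[float],
    prior_scale: float = 0.707,
) -> tuple[float, float, float]:
    """Paired comparison of per-subject median failed-stop vs go RTs.

    Returns the paired t statistic, two-sided p, and the log10 JZS Bayes
    factor on the within-subject differences (Cauchy prior scale 0.707).
    """
    fs_arr = np.asarray(fs_medians, dtype=float)
    go_arr = np.asarray(go_medians, dtype=float)
    if fs_arr.size != go_arr.size or fs_arr.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    diff = fs_arr - go_arr
    if diff.std(ddof=1) == 0:
        if np.allclose(diff, 0):
            # no effect and no variance: t conventionally 0; BF from a
            # zero-t statistic at this n
            return 0.0, 1.0, jzs_ttest_log10_bf_zero(diff.size, prior_scale)
        raise ValueError("zero-variance non-zero differences: t undefined")
    t, p = stats.ttest_rel(fs_arr, go_arr)
    log10_bf = jzs_one_sample_log10_bf(diff, prior_scale=prior_scale)
    return float(t), float(p), log10_bf


def jzs_ttest_log10_bf_zero(n: int, prior_scale: float) -> float:
    from .bayes import jzs_ttest_log10_bf

    return jzs_ttest_log10_bf(0.0, n_eff=n, nu=n - 1.0, prior_scale=prior_scale)


def ssrt_go_correlation(
    mean_ssrts: Sequence[float], median_go_rts: Sequence[float]
) -> tuple[float, float, float]:
    """Pearson correlation between subjects' mean SSRT and median go RT.

    Returns (r, two-sided p, log10 JZS correlation Bayes factor).
    """
    x = np.asarray(mean_ssrts, dtype=float)
    y = np.asarray(median_go_rts, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    res = stats.pearsonr(x, y)
    log10_bf = jzs_correlation_log10_bf(x, y)
    return float(res.statistic), float(res.pvalue), log10_bf
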