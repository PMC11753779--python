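"""Dataset-aware group inference on subject-level contrast estimates.

Subjects from the five datasets are modelled as one-way variance groups:
within dataset *g*, subject estimates have known sampling variances (their
varcopes) plus a dataset-specific between-subject variance ``tau^2_g``
estimated by restricted maximum likelihood with a non-negativity constraint
— a tractable stand-in for FSL FLAME's Bayesian variance estimation.
Dataset means are precision-weighted; the overall effect averages the
dataset means with equal weight, so no single large dataset dominates.

Multiple comparisons across the ROI family of one contrast are handled by
Benjamini-Hochberg FDR; evidence per region is additionally graded by a JZS
Bayes factor (Cauchy prior scale 0.25 on the standardized effect, reflecting
the small effect sizes typical of ROI fMRI contrasts) and mapped onto a
modified Jeffreys scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .bayes import jzs_ttest_log10_bf

__all__ = [
    "GroupDesign", "GroupResult", "EvidenceResult",
    "fit_group_mixed_model", "fdr_bh", "jzs_contrast_bf", "interpret_log_bf",
]


@dataclass(frozen=True)
class GroupDesign:
    """Subject-to-dataset assignment defining the variance groups."""

    subjects: tuple
    datasets: tuple  # dataset label per subject

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.datasets):
            raise ValueError("one dataset label per subject required")
        labels, counts = np.unique(self.datasets, return_counts=True)
        if np.any(counts < 2):
            small = [str(l) for l, c in zip(labels, counts) if c < 2]
            raise ValueError(f"datasets with fewer than 2 subjects: {small}")

    @property
    def dataset_labels(self) -> list:
        seen = dict.fromkeys(self.datasets)
        return list(seen)

    def indicator(self) -> np.ndarray:
        """Subject x dataset dummy matrix."""
        labels = self.dataset_labels
        mat = np.zeros((len(self.subjects), len(labels)))
        for i, d in enumerate(self.datasets):
            mat[i, labels.index(d)] = 1.0
        return mat


@dataclass
class GroupResult:
    """Mixed-model summary for one ROI x hemisphere x contrast cell."""

    dataset_means: dict
    dataset_tau2: dict
    effect: float
    se: float
    z: float
    p: float
    fdr_reject: bool = False


@dataclass
class EvidenceResult:
    """Bayes-factor evidence grade for one cell."""

    log10_bf: float
    prior_scale: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.log10_bf):
            raise ValueError("log10 BF must be finite")
        if not self.label:
            self.label = interpret_log_bf(self.log10_bf)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """REML estimate of the between-subject variance with known v_i >= 0."""

    def neg_restricted_ll(tau2: float) -> float:
        w = 1.0 / (v + tau2)
        mu = (w * y).sum() / w.sum()
        return 0.5 * (
            np.log(v + tau2).sum()
            + np.log(w.sum())
            + (w * (y - mu) ** 2).sum()
        )

    spread = y.var(ddof=1) if y.size > 1 else 0.0
    upper = max(10.0 * spread, 10.0 * v.mean(), 1e-6)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10 * upper},
    )
    # the boundary tau2 = 0 is a legitimate REML solution; compare explicitly
    if neg_restricted_ll(0.0) <= res.fun:
        return 0.0
    return float(res.x)


def fit_group_mixed_model(
    copes: Sequence[float],
    varcopes: Sequence[float],
    group_design: GroupDesign,
    force_tau2: dict | None = None,
) -> GroupResult:
    """Two-stage mixed-effects fit with per-dataset variance groups.

    Per dataset the between-subject variance is estimated by REML
    (non-negative), subjects are weighted by ``1 / (varcope + tau^2_g)``,
    and the overall effect is the unweighted average of the dataset means,
    with variance propagated from the weighted-mean variances.  Two-sided p
    from the normal reference distribution of z.

    ``force_tau2`` pins selected datasets' variances (used by reduction
    tests); omitted datasets are still estimated.
    """
    y = np.asarray(copes, dtype=float)
    v = np.asarray(varcopes, dtype=float)
    if y.shape != v.shape or y.size != len(group_design.subjects):
        raise ValueError("copes/varcopes must match the group design")
    if np.any(v < 0):
        raise ValueError("varcopes must be non-negative")

    labels = group_design.dataset_labels
    ds = np.asarray(group_design.datasets)
    means: dict = {}
    tau2s: dict = {}
    variances = []
    for lab in labels:
        mask = ds == lab
        yg, vg = y[mask], v[mask]
        if force_tau2 is not None and lab in force_tau2:
            tau2 = float(force_tau2[lab])
        else:
            tau2 = _reml_tau2(yg, vg)
        w = 1.0 / (vg + tau2)
        if not np.all(np.isfinite(w)):
            raise ValueError(f"degenerate weights in dataset {lab!r}")
        mu = float((w * yg).sum() / w.sum())
        means[lab] = mu
        tau2s[lab] = tau2
        variances.append(1.0 / w.sum())

    g = len(labels)
    effect = float(np.mean(list(means.values())))
    var_effect = float(np.sum(variances) / g ** 2)
    if var_effect <= 0:
        raise ValueError("degenerate group model: zero variance everywhere")
    se = np.sqrt(var_effect)
    z = effect / se
    p = 2.0 * stats.norm.sf(abs(z))
    return GroupResult(dataset_means=means, dataset_tau2=tau2s,
                       effect=effect, se=se, z=float(z), p=float(p))


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up over one contrast's ROI family.

    Returns the rejection flags and the family's |z| threshold: the smallest
    |z| among rejected tests (equivalently, the |z| of the largest rejected
    p), or ``None`` when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    if not reject.any():
        return reject, None
    p_max_rejected = p[reject].max()
    z_threshold = float(stats.norm.isf(p_max_rejected / 2.0))
    return reject, z_threshold


def jzs_contrast_bf(
    subject_contrast_values: Sequence[float],
    dataset_labels: Sequence,
    prior_scale: float = 0.25,
) -> float:
    """log10 JZS Bayes factor for a condition effect with dataset blocks.

    The inputs are per-subject condition-difference estimates (the subject
    random effect is absorbed by the within-subject differencing).  Dataset
    enters as a nuisance block under both hypotheses: the grand effect is
    the unweighted mean of dataset means, its standard error comes from the
    within-dataset residual variance on ``N - G`` degrees of freedom, and the
    resulting t statistic feeds the one-dimensional JZS quadrature with the
    matching effective sample size ``G^2 / sum(1/n_g)``.
    """
    yv = np.asarray(subject_contrast_values, dtype=float)
    labels = np.asarray(dataset_labels)
    if yv.size != labels.size:
        raise ValueError("one dataset label per value required")
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 3):
        raise ValueError("each dataset needs at least 3 subjects")
    g = uniq.size
    n = yv.size
    ds_means = np.array([yv[labels == u].mean() for u in uniq])
    resid = yv - ds_means[np.searchsorted(uniq, labels)]
    s2 = float(resid @ resid / (n - g))
    if s2 == 0:
        raise ValueError("zero within-dataset variance: BF undefined")
    effect = float(ds_means.mean())
    n_eff = g ** 2 / np.sum(1.0 / counts)
    se = np.sqrt(s2 / n_eff)
    t = effect / se
    return jzs_ttest_log10_bf(t, n_eff=n_eff, nu=float(n - g),
                              prior_scale=prior_scale)


# Modified Jeffreys scale for log10 Bayes factors.  Intervals are half-open
# on the side away from zero, e.g. [1, 1.5) is "strong"; exactly 0 is "no
# evidence".
_JEFFREYS_STEPS = (0.5, 1.0, 1.5, 2.0)
_JEFFREYS_NAMES = ("Anecdotal", "Moderate", "Strong", "Very strong")


def interpret_log_bf(log10_bf: float) -> str:
    """Label a log10 Bayes factor on the modified Jeffreys scale."""
    if not np.isfinite(log10_bf):
        raise ValueError("log10 BF must be finite")
    if log10_bf == 0.0:
        return "No evidence"
    direction = "H1" if log10_bf > 0 else "H0"
    mag = abs(log10_bf)
    if mag >= _JEFFREYS_STEPS[-1]:
        return f"Extreme evidence for {direction}"
    for upper, name in zip(_JEFFREYS_STEPS, _JEFFREYS_NAMES):
        if mag < upper:
            return f"{name} evidence for {direction}"
    raise AssertionError("unreachable")
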