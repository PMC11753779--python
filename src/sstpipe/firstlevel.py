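"""ROI first-level analysis: extraction, tSNR, filtering, GLM, contrasts.

The run-level model regresses each ROI's (probability-weighted mean)
timeseries on condition regressors (canonical + temporal derivative for GO,
FS, SS), nuisance columns and an intercept, after removing slow drift with a
discrete-cosine high-pass basis (cutoff 1/128 Hz by default, applied
identically to data and regressors).  Serial correlation is handled by
single-lag AR(1) prewhitening estimated from the OLS residuals; run-level
contrast estimates are then combined within subject by inverse-variance
(fixed-effects) weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bold import CONDITIONS
from .designs import DatasetDesign
from .hrf import HRFParams, build_condition_regressor
from .race import TrialRecord

__all__ = [
    "DesignMatrix", "ContrastSpec", "RunGLMResult", "TSNRReport",
    "extract_roi_timeseries", "compute_tsnr", "dct_highpass",
    "build_design_matrix", "fit_run_glm", "compute_contrast",
    "fixed_effects_combine", "t_to_z", "CONTRASTS",
]


@dataclass
class DesignMatrix:
    """Volume x regressor matrix with labelled columns.

    Condition columns (canonical then derivative, per condition) precede
    nuisance columns; the intercept is last.
    """

    values: np.ndarray
    labels: list[str]
    tr_s: float
    highpass_cutoff_s: float = 128.0

    def column(self, label: str) -> int:
        return self.labels.index(label)


@dataclass(frozen=True)
class ContrastSpec:
    """Named contrast over the canonical condition columns (weights sum 0)."""

    name: str
    weights: dict  # condition -> weight on the canonical column

    def __post_init__(self) -> None:
        if abs(sum(self.weights.values())) > 1e-12:
            raise ValueError("contrast weights must sum to zero")

    def vector(self, labels: Sequence[str]) -> np.ndarray:
        w = np.zeros(len(labels))
        for cond, wt in self.weights.items():
            w[list(labels).index(cond)] = wt
        return w


CONTRASTS = (
    ContrastSpec("FS>GO", {"FS": 1.0, "GO": -1.0}),
    ContrastSpec("FS>SS", {"FS": 1.0, "SS": -1.0}),
    ContrastSpec("SS>GO", {"SS": 1.0, "GO": -1.0}),
)


@dataclass
class RunGLMResult:
    """Estimates for one ROI series in one run."""

    labels: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray
    residual_variance: float
    dof: float
    ar1_phi: float = 0.0
    contrasts: dict = field(default_factory=dict)  # name -> (cope, varcope, z)


@dataclass
class TSNRReport:
    """Per-ROI temporal SNR, hemisphere-averaged, voxel-volume corrected."""

    rows: pd.DataFrame  # columns: roi, tsnr_uncorrected, tsnr_corrected


def extract_roi_timeseries(voxel_block: np.ndarray, prob_weights: np.ndarray) -> np.ndarray:
    """Probability-weighted mean across voxels at each volume.

    Weights are normalised to sum to one; all-zero weights are rejected.
    """
    block = np.asarray(voxel_block, dtype=float)
    w = np.asarray(prob_weights, dtype=float)
    if block.ndim != 2 or w.shape != (block.shape[0],):
        raise ValueError("voxel_block must be (n_voxels, n_volumes) matching weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("membership weights sum to zero")
    return (w / total) @ block


def compute_tsnr(timeseries: np.ndarray, voxel_volume_mm3: float) -> tuple[float, float]:
    """Temporal SNR of a series: mean / sample SD, and its volume-corrected form.

    The corrected value divides by the volume of a single voxel, removing the
    trivial advantage of large voxels when comparing acquisitions.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two volumes")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant series: tSNR undefined")
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be positive")
    tsnr = float(x.mean() / sd)
    return tsnr, tsnr / voxel_volume_mm3


def dct_basis(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis: all components with period > cutoff.

    Column k (k = 0 is the constant) is ``cos(pi k (2t+1) / (2N))`` with
    frequency ``k / (2 N TR)``; components up to ``k = floor(2 N TR /
    cutoff)`` are below the cutoff frequency and span the drift subspace.
    """
    n = n_volumes
    k_max = int(np.floor(2.0 * n * tr_s / cutoff_s))
    t = np.arange(n)
    cols = [np.ones(n) / np.sqrt(n)]
    for k in range(1, k_max + 1):
        c = np.cos(np.pi * k * (2 * t + 1) / (2.0 * n))
        cols.append(c * np.sqrt(2.0 / n))
    return np.column_stack(cols)


def dct_highpass(data: np.ndarray, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Project out the sub-cutoff discrete-cosine subspace from each column.

    Removes the mean and all cosine components slower than ``1/cutoff_s`` Hz.
    The same operator must be applied to the data and to the design matrix's
    non-constant columns.
    """
    x = np.asarray(data, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    n = x.shape[0]
    if cutoff_s <= 2 * tr_s:
        raise ValueError("cutoff must exceed twice the TR")
    basis = dct_basis(n, tr_s, cutoff_s)
    if basis.shape[1] >= n:
        warnings.warn("too few volumes for the drift basis; returning input",
                      stacklevel=2)
        return data
    filtered = x - basis @ (basis.T @ x)
    return filtered[:, 0] if one_d else filtered


def build_design_matrix(
    events: Sequence[TrialRecord],
    design: DatasetDesign,
    n_volumes: int,
    confounds: Optional[pd.DataFrame] = None,
    hrf: HRFParams | None = None,
    lock: str | None = None,
    highpass_cutoff_s: float = 128.0,
    apply_highpass: bool = True,
) -> DesignMatrix:
    """Assemble the run design matrix: conditions, derivatives, nuisance, 1.

    Condition and nuisance columns are passed through the same discrete-
    cosine high-pass filter that the data receive; the intercept is appended
    unfiltered.
    """
    lock = lock or design.lock
    cols: list[np.ndarray] = []
    labels: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cond in CONDITIONS:
            can, der = build_condition_regressor(
                events, cond, lock, design.tr_s, n_volumes, hrf
            )
            cols += [can, der]
            labels += [cond, f"{cond}_td"]
    if confounds is not None:
        for name in confounds.columns:
            cols.append(confounds[name].to_numpy(dtype=float))
            labels.append(str(name))
    x = np.column_stack(cols)
    if apply_highpass:
        x = dct_highpass(x, design.tr_s, highpass_cutoff_s)
    x = np.column_stack([x, np.ones(n_volumes)])
    labels.append("intercept")
    return DesignMatrix(values=x, labels=labels, tr_s=design.tr_s,
                        highpass_cutoff_s=highpass_cutoff_s)


def _check_rank(x: np.ndarray, labels: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns to make the error actionable
        bad = []
        keep: list[int] = []
        for j in range(x.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(x[:, trial]) < len(trial):
                bad.append(labels[j])
            else:
                keep.append(j)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def t_to_z(t: float, dof: float) -> float:
    """Map a t statistic to a standard-normal deviate, tail-symmetrically.

    Works on the survival function of the smaller tail for numerical
    stability at large |t|.
    """
    if dof <= 0:
        raise ValueError("dof must be positive")
    sign = np.sign(t)
    p_tail = stats.t.sf(abs(t), dof)
    z = -stats.norm.ppf(p_tail) if p_tail > 0 else np.inf
    return float(sign * z)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = y.size - np.linalg.matrix_rank(x)
    sigma2 = float(resid @ resid / dof)
    xtx_inv = np.linalg.pinv(x.T @ x)
    return beta, sigma2 * xtx_inv, sigma2, float(dof)


def fit_run_glm(
    roi_series: np.ndarray,
    design: DesignMatrix,
    whiten: bool = True,
    highpass: bool = True,
    contrasts: Sequence[ContrastSpec] = CONTRASTS,
) -> RunGLMResult:
    """Fit the run-level GLM to one ROI series.

    With ``whiten`` the AR(1) coefficient is estimated from the OLS
    residuals (lag-1 Yule-Walker), both data and design are transformed
    (first row scaled by ``sqrt(1 - phi^2)``), and OLS is re-run on the
    whitened system.  Contrast estimates, variances and z values for the
    shipped contrasts are attached to the result.
    """
    y = np.asarray(roi_series, dtype=float)
    x = design.values
    if y.size != x.shape[0]:
        raise ValueError("series length does not match the design matrix")
    _check_rank(x, design.labels)
    if highpass:
        y = dct_highpass(y, design.tr_s, design.highpass_cutoff_s)

    beta, cov, sigma2, dof = _ols(y, x)
    phi = 0.0
    if whiten:
        resid = y - x @ beta
        denom = float(resid @ resid)
        if denom > 0:
            phi = float(resid[1:] @ resid[:-1] / denom)
        phi = float(np.clip(phi, -0.99, 0.99))
        yw = y.copy()
        xw = x.copy()
        yw[1:] = y[1:] - phi * y[:-1]
        xw[1:] = x[1:] - phi * x[:-1]
        scale = np.sqrt(1.0 - phi * phi)
        yw[0] *= scale
        xw[0] *= scale
        beta, cov, sigma2, dof = _ols(yw, xw)

    result = RunGLMResult(
        labels=list(design.labels), beta=beta, cov_beta=cov,
        residual_variance=sigma2, dof=dof, ar1_phi=phi,
    )
    for spec in contrasts:
        result.contrasts[spec.name] = compute_contrast(result, spec)
    return result


def compute_contrast(result: RunGLMResult, contrast: ContrastSpec) -> tuple[float, float, float]:
    """Contrast of parameter estimates: cope, varcope, z.

    Derivative and nuisance columns carry weight zero; z comes from the
    t(dof) -> N(0,1) cumulative-probability map.
    """
    w = contrast.vector(result.labels)
    if w.size != result.beta.size:
        raise ValueError("contrast length does not match the design")
    cope = float(w @ result.beta)
    varcope = float(w @ result.cov_beta @ w)
    if np.allclose(w, 0):
        return 0.0, 0.0, 0.0
    if varcope < 0:
        raise ValueError("negative contrast variance")
    if varcope == 0:
        # noiseless data: the estimate is exact, so the z statistic is
        # degenerate — signed infinity for a non-zero cope, zero otherwise
        return cope, 0.0, float(np.sign(cope) * np.inf) if cope != 0 else 0.0
    t = cope / np.sqrt(varcope)
    return cope, varcope, t_to_z(t, result.dof)


def fixed_effects_combine(
    copes: Sequence[float], varcopes: Sequence[float]
) -> tuple[float, float, float]:
    """Inverse-variance (fixed-effects) combination across runs.

    cope = sum(c_i / v_i) / sum(1 / v_i); varcope = 1 / sum(1 / v_i);
    z = cope / sqrt(varcope).
    """
    c = np.asarray(copes, dtype=float)
    v = np.asarray(varcopes, dtype=float)
    if c.size == 0 or c.size != v.size:
        raise ValueError("need matching non-empty cope/varcope vectors")
    if np.any(v <= 0):
        raise ValueError("varcopes must be positive")
    w = 1.0 / v
    cope = float((c * w).sum() / w.sum())
    varcope = float(1.0 / w.sum())
    return cope, varcope, float(cope / np.sqrt(varcope))


def tsnr_report(
    voxel_blocks: dict[str, np.ndarray],
    weights: dict[str, np.ndarray],
    voxel_volume_mm3: float,
) -> TSNRReport:
    """Hemisphere-averaged ROI tSNR table from per-ROI voxel blocks.

    Keys are ``name-l`` / ``name-r``; each ROI's extracted series yields an
    uncorrected tSNR, hemispheres are averaged, and the corrected value
    divides by the voxel volume.
    """
    per_roi: dict[str, list[float]] = {}
    for key, block in voxel_blocks.items():
        name = key.rsplit("-", 1)[0]
        series = extract_roi_timeseries(block, weights[key])
        tsnr, _ = compute_tsnr(series, voxel_volume_mm3)
        per_roi.setdefault(name, []).append(tsnr)
    rows = pd.DataFrame(
        {
            "roi": list(per_roi),
            "tsnr_uncorrected": [float(np.mean(v)) for v in per_roi.values()],
        }
    )
    rows["tsnr_corrected"] = rows["tsnr_uncorrected"] / voxel_volume_mm3
    return TSNRReport(rows=rows)
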