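"""ROI extraction, tSNR, DCT filtering, run GLM, contrasts, fixed effects."""

import numpy as np
import pytest
from scipy import stats

from sstpipe import (DATASET_DESIGNS, ContrastSpec, NoiseSpec, RaceParams,
                     build_design_matrix, compute_contrast, compute_tsnr,
                     dct_highpass, extract_roi_timeseries, fit_run_glm,
                     fixed_effects_combine, simulate_session, split_runs,
                     synthesize_run, t_to_z)
from sstpipe.bold import default_roi_roster
from sstpipe.firstlevel import RunGLMResult, dct_basis


class TestExtraction:
    def test_equal_weights_is_mean(self, rng):
        block = rng.normal(size=(5, 20))
        assert np.allclose(extract_roi_timeseries(block, np.ones(5)),
                           block.mean(axis=0))

    def test_single_voxel_identity(self, rng):
        block = rng.normal(size=(1, 15))
        assert np.allclose(extract_roi_timeseries(block, np.array([0.7])),
                           block[0])

    def test_hand_weighted_mean(self):
        block = np.array([[10.0], [20.0]])
        out = extract_roi_timeseries(block, np.array([0.8, 0.2]))
        assert out[0] == pytest.approx(12.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_timeseries(np.ones((2, 3)), np.zeros(2))


class TestTSNR:
    def test_hand_computed_example(self):
        series = np.array([99.0, 101.0, 99.0, 101.0])
        unc, cor = compute_tsnr(series, 3.375)
        assert unc == pytest.approx(86.6025, abs=1e-4)
        assert cor == pytest.approx(25.6600, abs=1e-4)

    def test_scale_invariance(self, rng):
        x = rng.normal(100, 5, size=50)
        unc, _ = compute_tsnr(x, 1.0)
        unc_scaled, _ = compute_tsnr(3.7 * x, 1.0)
        assert unc_scaled == pytest.approx(unc)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            compute_tsnr(np.full(10, 7.0), 1.0)


class TestDCTHighpass:
    def test_constant_removed(self):
        out = dct_highpass(np.full(100, 42.0), tr_s=2.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    @pytest.mark.parametrize("period_s,removed", [(300.0, True), (30.0, False)])
    def test_band_selectivity(self, period_s, removed):
        tr, n = 2.0, 300  # 600 s run
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * t / period_s)
        resid = dct_highpass(x, tr, 128.0)
        ratio = (resid @ resid) / (x @ x)
        if removed:
            assert ratio < 0.05
        else:
            assert ratio > 0.95

    def test_filter_equals_dct_nuisance_regression(self, rng):
        """Projection equivalence: filtering == including DCT columns."""
        tr, n = 2.0, 200
        y = rng.normal(size=n)
        x = rng.normal(size=(n, 3))
        basis = dct_basis(n, tr, 128.0)
        # OLS including DCT columns as nuisance
        full = np.column_stack([x, basis])
        beta_full, *_ = np.linalg.lstsq(full, y, rcond=None)
        # filter both sides, then fit
        yf = dct_highpass(y, tr, 128.0)
        xf = dct_highpass(x, tr, 128.0)
        beta_filt, *_ = np.linalg.lstsq(xf, yf, rcond=None)
        assert np.allclose(beta_filt, beta_full[:3], atol=1e-8)

    def test_cutoff_must_exceed_nyquist(self):
        with pytest.raises(ValueError):
            dct_highpass(np.ones(10), tr_s=2.0, cutoff_s=3.0)


@pytest.fixture(scope="module")
def synthetic_run():
    design = DATASET_DESIGNS["deHollander_7T"]
    trials = simulate_session(design, RaceParams(), seed=21)
    events = split_runs(trials, design.n_runs)[0]
    roster = default_roi_roster(
        {"STN": {"GO": (0.5, 0.1), "FS": (1.5, -0.2), "SS": (0.7, 0.0)}},
        n_voxels=4, seed=3,
    )
    stn = [r for r in roster if r.name == "STN" and r.hemisphere == "left"]
    return design, events, stn[0]


class TestRunGLM:
    def test_noiseless_recovery_exact(self, synthetic_run):
        design, events, spec = synthetic_run
        noise = NoiseSpec(sigma=0.0, ar1_phi=0.0, drift_amp=0.0)
        synth = synthesize_run(design, [spec], noise, events, seed=0)
        n_vol = synth.roi_timeseries.shape[0]
        dm = build_design_matrix(events, design, n_vol, confounds=synth.confounds)
        fit = fit_run_glm(synth.roi_timeseries.iloc[:, 0].to_numpy(), dm,
                          whiten=False)
        betas = dict(zip(fit.labels, fit.beta))
        for cond in ("GO", "FS", "SS"):
            b_can, b_der = spec.true_betas[cond]
            assert betas[cond] == pytest.approx(b_can, abs=1e-8)
            assert betas[f"{cond}_td"] == pytest.approx(b_der, abs=1e-8)

    def test_z_matches_independent_ols_oracle(self, rng):
        """White-noise data: z agrees with a brute-force linear-model fit."""
        n, k = 120, 4
        x = np.column_stack([rng.normal(size=(n, k - 1)), np.ones(n)])
        y = rng.normal(size=n)
        from sstpipe.firstlevel import DesignMatrix

        dm = DesignMatrix(values=x, labels=["GO", "FS", "SS", "intercept"],
                          tr_s=2.0)
        fit = fit_run_glm(y, dm, whiten=False, highpass=False)
        w = np.array([-1.0, 1.0, 0.0, 0.0])  # FS minus GO
        # oracle: textbook OLS contrast t statistic
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        dof = n - k
        s2 = resid @ resid / dof
        t_oracle = (w @ beta) / np.sqrt(s2 * w @ np.linalg.inv(x.T @ x) @ w)
        z_oracle = stats.norm.isf(stats.t.sf(t_oracle, dof)) if t_oracle > 0 \
            else -stats.norm.isf(stats.t.sf(-t_oracle, dof))
        cope, varcope, z = fit.contrasts["FS>GO"]
        assert z == pytest.approx(z_oracle, abs=1e-6)

    def test_whitening_removes_serial_correlation(self, synthetic_run):
        design, events, spec = synthetic_run
        noise = NoiseSpec(sigma=3.0, ar1_phi=0.4, drift_amp=0.0)
        rhos = []
        for seed in range(8):
            synth = synthesize_run(design, [spec], noise, events, seed=seed,
                                   n_volumes=2000)
            dm = build_design_matrix(events, design,
                                     synth.roi_timeseries.shape[0],
                                     confounds=synth.confounds)
            y = synth.roi_timeseries.iloc[:, 0].to_numpy()
            fit = fit_run_glm(y, dm, whiten=True)
            # residual autocorrelation after whitening
            yw = dct_highpass(y, design.tr_s)
            yw2 = yw.copy()
            yw2[1:] -= fit.ar1_phi * yw[:-1]
            xw = dm.values.copy()
            xw[1:] -= fit.ar1_phi * dm.values[:-1]
            resid = yw2 - xw @ fit.beta
            rhos.append((resid[1:] @ resid[:-1]) / (resid @ resid))
        assert abs(np.mean(rhos)) < 0.1

    def test_rank_deficiency_names_columns(self, rng):
        from sstpipe.firstlevel import DesignMatrix

        a = rng.normal(size=50)
        x = np.column_stack([a, a, np.ones(50)])
        dm = DesignMatrix(values=x, labels=["GO", "GO_copy", "intercept"], tr_s=2.0)
        with pytest.raises(np.linalg.LinAlgError, match="GO_copy"):
            fit_run_glm(rng.normal(size=50), dm, whiten=False, highpass=False)


class TestContrasts:
    def _result(self):
        return RunGLMResult(
            labels=["GO", "FS", "SS"], beta=np.array([1.0, 2.0, 0.0]),
            cov_beta=np.eye(3), residual_variance=1.0, dof=200.0,
        )

    def test_weights_must_sum_to_zero(self):
        with pytest.raises(ValueError):
            ContrastSpec("bad", {"FS": 1.0})

    def test_fs_gt_go_arithmetic(self):
        cope, varcope, _ = compute_contrast(
            self._result(), ContrastSpec("FS>GO", {"FS": 1.0, "GO": -1.0}))
        assert cope == pytest.approx(1.0)
        assert varcope == pytest.approx(2.0)

    def test_t_to_z_map(self):
        assert t_to_z(2.0, 200) == pytest.approx(1.99, abs=0.005)
        assert t_to_z(-2.0, 200) == pytest.approx(-t_to_z(2.0, 200))
        assert t_to_z(0.0, 10) == 0.0


class TestFixedEffects:
    def test_single_run_identity(self):
        cope, varcope, z = fixed_effects_combine([2.0], [4.0])
        assert (cope, varcope) == (2.0, 4.0)
        assert z == pytest.approx(1.0)

    def test_equal_variances_average(self):
        cope, varcope, _ = fixed_effects_combine([1.0, 3.0], [2.0, 2.0])
        assert cope == pytest.approx(2.0)
        assert varcope == pytest.approx(1.0)

    def test_hand_computed_inverse_variance(self):
        cope, varcope, _ = fixed_effects_combine([1.0, 3.0], [1.0, 2.0])
        assert cope == pytest.approx(5.0 / 3.0, abs=1e-3)
        assert varcope == pytest.approx(2.0 / 3.0, abs=1e-3)

    def test_non_positive_varcope_rejected(self):
        with pytest.raises(ValueError):
            fixed_effects_combine([1.0], [0.0])
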