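"""Group mixed model, FDR control, contrast Bayes factors, Jeffreys labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sstpipe import (GroupDesign, fdr_bh, fit_group_mixed_model,
                     interpret_log_bf, jzs_contrast_bf)


def one_sample_design(n, label="d0"):
    return GroupDesign(subjects=tuple(range(n)), datasets=(label,) * n)


class TestMixedModel:
    def test_reduces_to_one_sample_z_with_tau_zero(self, rng):
        """Equal varcopes and tau^2 pinned at 0: z is the plain one-sample z."""
        y = rng.normal(0.4, 1.0, size=25)
        v = np.full(25, 0.8)
        res = fit_group_mixed_model(y, v, one_sample_design(25),
                                    force_tau2={"d0": 0.0})
        z_closed_form = y.mean() / np.sqrt(0.8 / 25)
        assert res.z == pytest.approx(z_closed_form, abs=1e-8)
        assert res.effect == pytest.approx(y.mean(), abs=1e-12)

    def test_two_identical_datasets_symmetric(self, rng):
        y = rng.normal(0.5, 1.0, size=20)
        v = rng.uniform(0.5, 1.0, size=20)
        gd = GroupDesign(subjects=tuple(range(40)),
                         datasets=("a",) * 20 + ("b",) * 20)
        res = fit_group_mixed_model(np.concatenate([y, y]),
                                    np.concatenate([v, v]), gd)
        assert res.dataset_means["a"] == pytest.approx(res.dataset_means["b"])
        assert res.effect == pytest.approx(res.dataset_means["a"])

    def test_reml_recovers_between_subject_variance(self, rng):
        """tau^2 estimate is consistent at large n with known varcopes."""
        tau2_true = 2.0
        n = 4000
        v = rng.uniform(0.2, 0.6, size=n)
        y = rng.normal(0.0, np.sqrt(v + tau2_true))
        res = fit_group_mixed_model(y, v, one_sample_design(n))
        assert res.dataset_tau2["d0"] == pytest.approx(tau2_true, rel=0.15)

    def test_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign(subjects=(1, 2, 3), datasets=("a", "a", "b"))

    def test_effect_recovery_across_datasets(self, rng):
        """A common injected effect is recovered without bias at 30/dataset."""
        effect = 0.8
        labels, y, v = [], [], []
        for d in range(5):
            vi = rng.uniform(0.3, 0.7, size=30)
            yi = rng.normal(effect, np.sqrt(vi + 0.4))
            labels += [f"d{d}"] * 30
            y.append(yi)
            v.append(vi)
        gd = GroupDesign(subjects=tuple(range(150)), datasets=tuple(labels))
        res = fit_group_mixed_model(np.concatenate(y), np.concatenate(v), gd)
        assert res.effect == pytest.approx(effect, abs=3 * res.se)
        assert abs(res.effect - effect) / effect < 0.25


class TestFDR:
    def test_step_up_enumeration(self):
        reject, z_thr = fdr_bh([0.001, 0.02, 0.04, 0.2], q=0.05)
        assert reject.tolist() == [True, True, False, False]
        # threshold is the |z| of the largest rejected p (0.02)
        assert z_thr == pytest.approx(stats.norm.isf(0.01))

    def test_all_ones_no_rejections(self):
        reject, z_thr = fdr_bh([1.0, 1.0, 1.0])
        assert not reject.any() and z_thr is None

    def test_single_p_reduces_to_raw_threshold(self):
        reject, _ = fdr_bh([0.01], q=0.05)
        assert reject.tolist() == [True]

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])


class TestContrastBF:
    def test_null_data_favours_null(self, rng):
        vals = rng.normal(0.0, 1.0, size=100)
        vals -= vals.mean()
        labels = ["a"] * 50 + ["b"] * 50
        assert jzs_contrast_bf(vals, labels) < 0

    def test_single_dataset_matches_one_sample_bf(self, rng):
        from sstpipe.bayes import jzs_one_sample_log10_bf

        vals = rng.normal(0.3, 1.0, size=40)
        ours = jzs_contrast_bf(vals, ["a"] * 40, prior_scale=0.25)
        ref = jzs_one_sample_log10_bf(vals, prior_scale=0.25)
        assert ours == pytest.approx(ref, abs=1e-9)

    def test_dataset_offsets_are_nuisance(self, rng):
        """Shifting one dataset's values changes only the block means."""
        vals = rng.normal(0.5, 1.0, size=60)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        shifted = vals + np.where(labels == "b", 100.0, 0.0)
        # grand effect changes, but the within-block spread feeding the t
        # statistic must be identical
        base = jzs_contrast_bf(vals, labels)
        assert np.isfinite(jzs_contrast_bf(shifted, labels))
        recentred = shifted - np.where(labels == "b", 100.0, 0.0)
        assert jzs_contrast_bf(recentred, labels) == pytest.approx(base)

    def test_too_few_subjects_per_dataset_rejected(self):
        with pytest.raises(ValueError):
            jzs_contrast_bf([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])


class TestJeffreysScale:
    @pytest.mark.parametrize("value,label", [
        (2.5, "Extreme evidence for H1"),
        (2.0, "Extreme evidence for H1"),
        (1.7, "Very strong evidence for H1"),
        (1.5, "Very strong evidence for H1"),
        (1.2, "Strong evidence for H1"),
        (1.0, "Strong evidence for H1"),
        (0.7, "Moderate evidence for H1"),
        (0.5, "Moderate evidence for H1"),
        (0.2, "Anecdotal evidence for H1"),
        (0.0, "No evidence"),
        (-0.2, "Anecdotal evidence for H0"),
        (-0.5, "Moderate evidence for H0"),
        (-1.0, "Strong evidence for H0"),
        (-1.5, "Very strong evidence for H0"),
        (-2.0, "Extreme evidence for H0"),
        (-2.3, "Extreme evidence for H0"),
    ])
    def test_interval_mapping(self, value, label):
        assert interpret_log_bf(value) == label

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_partitions_the_real_line(self, x):
        labels = {interpret_log_bf(x)}
        assert len(labels) == 1
        assert interpret_log_bf(x) in {
            f"{name} evidence for {d}"
            for name in ("Anecdotal", "Moderate", "Strong", "Very strong", "Extreme")
            for d in ("H0", "H1")
        } | {"No evidence"}

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            interpret_log_bf(float("inf"))
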