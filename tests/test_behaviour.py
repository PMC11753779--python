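"""Behavioural summaries, SSRT integration method, exclusions, RT tests."""

import numpy as np
import pytest

from sstpipe import (DATASET_DESIGNS, RaceParams, estimate_ssrt_integration,
                     apply_exclusion_criteria, paired_rt_comparison,
                     simulate_session, ssrt_go_correlation, summarize_behaviour)
from sstpipe.behaviour import BehaviouralSummary

from conftest import make_trial


class TestSummarize:
    def test_hand_built_eight_trial_set(self, hand_built_trials):
        s = summarize_behaviour(hand_built_trials)
        assert s.median_go_rt_ms == 330
        assert s.median_fs_rt_ms == 290
        assert s.go_omission_pct == 20
        assert s.stop_accuracy_pct == pytest.approx(66.6667, abs=1e-3)
        assert s.mean_ssd_ms == 150
        assert s.median_ssd_ms == 150

    def test_all_successful_stops(self):
        trials = [
            make_trial(0, "go", response="left", rt_ms=400, outcome="GO_correct"),
            make_trial(1, "stop", ssd_ms=200, outcome="SS"),
            make_trial(2, "stop", ssd_ms=250, outcome="SS"),
        ]
        s = summarize_behaviour(trials)
        assert s.stop_accuracy_pct == 100
        assert s.median_fs_rt_ms is None
        assert s.mean_ssrt_ms is None  # p(respond) on the boundary

    def test_constant_go_rts(self):
        trials = [make_trial(i, "go", response="left", rt_ms=444,
                             outcome="GO_correct") for i in range(5)]
        trials.append(make_trial(5, "stop", ssd_ms=100, outcome="SS"))
        assert summarize_behaviour(trials).median_go_rt_ms == 444

    def test_no_go_trials_rejected(self):
        with pytest.raises(ValueError):
            summarize_behaviour([make_trial(0, "stop", ssd_ms=100, outcome="SS")])


class TestSSRTIntegration:
    def test_hand_enumerated_rank_rule(self):
        rts = [(300.0, False), (350.0, False), (400.0, False),
               (450.0, False), (500.0, False)]
        # rank = ceil(5 * 0.4) = 2 -> 350; SSRT = 350 - 150
        assert estimate_ssrt_integration(rts, 0.4, 150.0) == 200.0

    def test_degenerate_constant_distribution(self):
        rts = [(400.0, False)] * 7
        assert estimate_ssrt_integration(rts, 0.51, 100.0) == 300.0

    def test_omission_replacement_never_decreases_ssrt(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(10, 40)
            rts = rng.uniform(250, 700, size=n)
            flags = rng.random(n) < 0.2
            with_om = [(r, bool(f)) for r, f in zip(rts, flags)]
            dropped = [(r, False) for r, f in zip(rts, flags) if not f]
            if not any(not f for f in flags):
                continue
            p = float(rng.uniform(0.3, 0.7))
            assert estimate_ssrt_integration(with_om, p, 100.0) >= \
                estimate_ssrt_integration(dropped, p, 100.0)

    @pytest.mark.parametrize("p_bad", [0.0, 1.0])
    def test_boundary_p_respond_rejected(self, p_bad):
        with pytest.raises(ValueError):
            estimate_ssrt_integration([(300.0, False)], p_bad, 100.0)

    def test_recovers_deterministic_stop_latency(self):
        """Staircased simulation at 2,500 stop trials recovers the true SSRT."""
        design = DATASET_DESIGNS["deHollander_7T"].scaled(10_000)
        params = RaceParams(go_mu=400, go_sigma=50, go_tau=60, stop_mu=200)
        s = summarize_behaviour(simulate_session(design, params, seed=99))
        assert s.n_stop == 2500
        assert abs(s.mean_ssrt_ms - 200.0) < 10.0


class TestExclusions:
    def _summary(self, **kw):
        base = dict(n_go=300, n_stop=100, median_go_rt_ms=450.0,
                    median_fs_rt_ms=400.0, mean_go_rt_ms=460.0,
                    mean_fs_rt_ms=410.0, go_omission_pct=1.0, go_error_pct=1.0,
                    go_accuracy_pct=99.0, stop_accuracy_pct=50.0,
                    mean_ssd_ms=250.0, median_ssd_ms=250.0)
        base.update(kw)
        return BehaviouralSummary(**base)

    def test_omission_criterion(self):
        rep = apply_exclusion_criteria(self._summary(go_omission_pct=12.0))
        assert rep.excluded and rep.criteria_failed == {1}

    def test_stop_accuracy_criterion(self):
        rep = apply_exclusion_criteria(self._summary(stop_accuracy_pct=30.0))
        assert rep.criteria_failed == {2}
        rep = apply_exclusion_criteria(self._summary(stop_accuracy_pct=66.0))
        assert rep.criteria_failed == {2}

    def test_go_accuracy_criterion(self):
        rep = apply_exclusion_criteria(self._summary(go_accuracy_pct=94.0))
        assert rep.criteria_failed == {3}

    def test_race_violation_criterion(self):
        rep = apply_exclusion_criteria(self._summary(mean_fs_rt_ms=470.0))
        assert rep.criteria_failed == {4}

    def test_clean_subject_retained(self):
        rep = apply_exclusion_criteria(self._summary())
        assert not rep.excluded and rep.criteria_failed == set()

    def test_boundaries_use_strict_inequalities(self):
        rep = apply_exclusion_criteria(self._summary(
            go_omission_pct=10.0, stop_accuracy_pct=35.0, go_accuracy_pct=95.0))
        assert not rep.excluded


class TestRTComparisons:
    def test_identical_vectors_favour_null(self):
        t, p, bf = paired_rt_comparison([400.0] * 10, [400.0] * 10)
        assert t == 0.0
        assert bf < 0

    def test_large_consistent_difference_gives_strong_evidence(self, rng):
        go = rng.normal(450, 30, size=30)
        fs = go - 40 + rng.normal(0, 5, size=30)
        t, p, bf = paired_rt_comparison(fs, go)
        assert t < 0 and p < 1e-6
        assert bf > 1

    def test_doubling_n_strengthens_evidence(self):
        from scipy import stats as sps

        # construct differences with standardized effect exactly -0.5
        base = sps.norm.ppf((np.arange(25) + 0.5) / 25)
        base = (base - base.mean()) / base.std(ddof=1)
        diff = (-0.5 + base) * 10
        go = np.full(50, 450.0)
        _, _, bf_small = paired_rt_comparison(go[:25] + diff, go[:25])
        _, _, bf_big = paired_rt_comparison(go + np.concatenate([diff, diff]), go)
        assert bf_small > 0
        assert abs(bf_big) > abs(bf_small)

    def test_correlation_perfectly_collinear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, p, bf = ssrt_go_correlation(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert bf > 1

    def test_correlation_matches_textbook_formula(self):
        x = np.array([189.0, 209.0, 219.0, 256.0, 219.0])
        y = np.array([423.0, 466.0, 472.0, 626.0, 445.0])
        r, _, _ = ssrt_go_correlation(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        assert r == pytest.approx(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))

    def test_independent_data_favours_null_on_average(self, rng):
        bfs = []
        for _ in range(20):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            bfs.append(ssrt_go_correlation(x, y)[2])
        assert np.mean(bfs) < 0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ssrt_go_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
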