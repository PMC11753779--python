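import numpy as np
import pytest

from sstpipe import DATASET_DESIGNS, RaceParams, simulate_session
from sstpipe.race import TrialRecord


@pytest.fixture(scope="session")
def deterministic_params():
    """Race parameters with a deterministic 200 ms stop latency."""
    return RaceParams(go_mu=400, go_sigma=50, go_tau=60, stop_mu=200)


@pytest.fixture(scope="session")
def small_session(deterministic_params):
    """One full deHollander-style session (384 trials, 96 stops)."""
    return simulate_session(DATASET_DESIGNS["deHollander_7T"],
                            deterministic_params, seed=42)


def make_trial(index=0, trial_type="go", direction="left", onset_s=0.0,
               ssd_ms=None, response=None, rt_ms=None, outcome=None,
               staircase_id=None):
    """Hand-built trial records for enumeration tests."""
    return TrialRecord(index=index, trial_type=trial_type, direction=direction,
                       onset_s=onset_s, ssd_ms=ssd_ms, staircase_id=staircase_id,
                       response=response, rt_ms=rt_ms, outcome=outcome)


@pytest.fixture(scope="session")
def hand_built_trials():
    """Four observed go RTs, one omission, three stop trials (SS, SS, FS).

    Summary worked out by hand: median go RT 330, median FS RT 290,
    go omissions 20%, stop accuracy 66.7%, mean SSD 150.
    """
    return [
        make_trial(0, "go", response="left", rt_ms=300, outcome="GO_correct"),
        make_trial(1, "go", response="left", rt_ms=320, outcome="GO_correct"),
        make_trial(2, "go", response="left", rt_ms=340, outcome="GO_correct"),
        make_trial(3, "go", response="left", rt_ms=360, outcome="GO_correct"),
        make_trial(4, "go", outcome="GO_omission"),
        make_trial(5, "stop", ssd_ms=100, outcome="SS"),
        make_trial(6, "stop", ssd_ms=150, outcome="SS"),
        make_trial(7, "stop", ssd_ms=200, response="left", rt_ms=290, outcome="FS"),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
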