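"""Per-dataset task and acquisition parameters for the five stop-signal studies.

Each :class:`DatasetDesign` bundles what the simulator and the analysis need to
know about one dataset: repetition time, run structure, trial counts, the
stop-trial fraction, and the staircase configuration (number of interleaved
staircases, SSD bounds, step size).  The five shipped presets mirror the task
and acquisition tables of the multi-study stop-signal corpus this package
emulates (two 3T studies and three 7T studies with distinct TRs, trial counts
and SSD ranges).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ITIModel:
    """Uniform-jitter onset scheduling: gap = ``mean_s`` + U(-jitter, +jitter)."""

    mean_s: float = 4.0
    jitter_s: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_s - self.jitter_s <= 0:
            raise ValueError("ITI mean must exceed its jitter half-width")


@dataclass(frozen=True)
class DatasetDesign:
    """Task/acquisition parameters of one stop-signal dataset.

    Parameters
    ----------
    name : str
        Dataset label.
    tr_s : float
        Repetition time of the functional acquisition, seconds.
    n_runs : int
        Number of task runs per subject.
    total_trials : int
        Trials per subject summed over all runs.
    stop_fraction : float
        Proportion of trials carrying a stop signal, in (0, 1).
    n_staircases : int
        Number of interleaved SSD staircases.
    ssd_min_ms, ssd_max_ms : float
        Staircase bounds, milliseconds.
    ssd_start_ms : float or None
        Initial SSD of every staircase; defaults to the mid-range.
    ssd_step_ms : float
        Staircase step, milliseconds.
    iti_model : ITIModel
        Onset scheduling parameters.
    lock : str
        Event time-lock convention for the GLM stage: ``"go"`` locks all
        events to go-signal onset, ``"stop"`` locks FS/SS events to
        go onset + SSD.
    """

    name: str
    tr_s: float
    n_runs: int
    total_trials: int
    stop_fraction: float
    n_staircases: int
    ssd_min_ms: float
    ssd_max_ms: float
    ssd_start_ms: float | None = None
    ssd_step_ms: float = 50.0
    iti_model: ITIModel = field(default_factory=ITIModel)
    lock: str = "go"

    def __post_init__(self) -> None:
        if not 0 <= self.stop_fraction < 1:
            raise ValueError("stop_fraction must lie in [0, 1)")
        if self.ssd_min_ms > self.ssd_max_ms:
            raise ValueError("ssd_min_ms must not exceed ssd_max_ms")
        if self.ssd_step_ms <= 0:
            raise ValueError("ssd_step_ms must be positive")
        if self.total_trials <= 0:
            raise ValueError("total_trials must be positive")
        if self.n_staircases < 1:
            raise ValueError("need at least one staircase")
        if self.lock not in ("go", "stop"):
            raise ValueError("lock must be 'go' or 'stop'")
        start = self.start_ssd_ms
        if not self.ssd_min_ms <= start <= self.ssd_max_ms:
            raise ValueError("ssd_start_ms outside the staircase bounds")

    @property
    def start_ssd_ms(self) -> float:
        """Initial SSD: explicit value, or the mid-point of the bounds."""
        if self.ssd_start_ms is not None:
            return self.ssd_start_ms
        return 0.5 * (self.ssd_min_ms + self.ssd_max_ms)

    @property
    def n_stop_trials(self) -> int:
        """Designed stop-trial count: nearest integer, ties toward more stops."""
        import math

        x = self.total_trials * self.stop_fraction
        return int(math.floor(x + 0.5))

    @property
    def n_go_trials(self) -> int:
        return self.total_trials - self.n_stop_trials

    @property
    def trials_per_run(self) -> int:
        return self.total_trials // self.n_runs

    def scaled(self, total_trials: int) -> "DatasetDesign":
        """Copy of the design with a reduced/enlarged trial count (demo runs)."""
        return replace(self, total_trials=total_trials)


# The five shipped dataset presets.  TRs come from the acquisition table
# (2.0 / 2.0 / 2.0 / 1.38 / 3.0 s); trial counts, stop percentages, staircase
# counts and SSD ranges from the task table of the corpus.  Starting SSDs are
# not recorded there; the wide-range designs start at the conventional
# 200-250 ms (a mid-range start of 450-500 ms would spend a large share of
# the short sessions walking the staircase down), while Aron_3T's narrow
# 100-250 ms range keeps the mid-range default.
ARON_3T = DatasetDesign(
    name="Aron_3T", tr_s=2.0, n_runs=3, total_trials=384, stop_fraction=0.25,
    n_staircases=4, ssd_min_ms=100, ssd_max_ms=250,
)
POLDRACK_3T = DatasetDesign(
    name="Poldrack_3T", tr_s=2.0, n_runs=1, total_trials=128, stop_fraction=0.25,
    n_staircases=2, ssd_min_ms=0, ssd_max_ms=1000, ssd_start_ms=250,
)
DEHOLLANDER_7T = DatasetDesign(
    name="deHollander_7T", tr_s=2.0, n_runs=3, total_trials=384, stop_fraction=0.25,
    n_staircases=4, ssd_min_ms=0, ssd_max_ms=900, ssd_start_ms=200,
)
ISHERWOOD_7T = DatasetDesign(
    name="Isherwood_7T", tr_s=1.38, n_runs=2, total_trials=200, stop_fraction=0.25,
    n_staircases=1, ssd_min_ms=50, ssd_max_ms=900, ssd_start_ms=200,
)
MILETIC_7T = DatasetDesign(
    name="Miletic_7T", tr_s=3.0, n_runs=3, total_trials=342, stop_fraction=0.25,
    n_staircases=2, ssd_min_ms=0, ssd_max_ms=900, ssd_start_ms=200,
)

DATASET_DESIGNS: dict[str, DatasetDesign] = {
    d.name: d for d in (ARON_3T, POLDRACK_3T, DEHOLLANDER_7T, ISHERWOOD_7T, MILETIC_7T)
}


def get_design(name: str) -> DatasetDesign:
    """Look up a shipped dataset design by name (case-sensitive)."""
    try:
        return DATASET_DESIGNS[name]
    except KeyError:
        raise KeyError(
            f"unknown design {name!r}; shipped designs: {sorted(DATASET_DESIGNS)}"
        ) from None
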