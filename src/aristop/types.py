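"""Core in-memory containers shared by the simulator and the analysis."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import HANDS, RunConfig


@dataclass
class TrialRecord:
    """One task trial.

    ``ssd`` is signed ms relative to the response target (negative = stop
    signal before the target) and is ``None`` on go trials. ``response_time``
    maps hand -> ms from trial onset, ``None`` where the hand did not lift.
    ``outcome`` is ``go_response``, ``successful_stop`` or ``failed_stop``
    (stop outcomes refer to the cued hand(s)).
    """

    index: int
    block: int
    trial_type: str
    ssd: float | None
    response_time: dict[str, float | None]
    outcome: str
    feedback: str
    #: generator ground truth (injected dip window, true burst times); kept
    #: out of the analysis path and used only by recovery tests.
    ground_truth: dict[str, Any] = field(default_factory=dict, repr=False)

    @property
    def is_stop(self) -> bool:
        return self.trial_type != "go"

    def stop_time(self, target_time: float) -> float | None:
        """Absolute stop-signal time (ms from trial onset), None on go."""
        if self.ssd is None:
            return None
        return target_time + self.ssd

    def responded(self, hand: str) -> bool:
        return self.response_time.get(hand) is not None


@dataclass
class EMGTrace:
    """One channel's sampled signal for one trial."""

    channel: str
    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0  # trial onset, ms
    event_times: dict[str, float] = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.sampling_rate * 1000.0

    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate * 1000.0


@dataclass
class StaircaseState:
    """Current signed SSD per stop-trial type plus full update history."""

    ssd: dict[str, float]
    step: float
    history: list[tuple[int, str, str, float]] = field(default_factory=list)
    # (trial index, stop type, outcome, new ssd)


@dataclass
class Session:
    """One simulated participant: behavioral record plus reproducible EMG.

    EMG is regenerated on demand from per-trial seeds (``emg_seeds``) so a
    full-cohort dataset never needs to hold every trace in memory; the same
    seed always yields the same trace.
    """

    participant: str
    config: RunConfig
    seed: int
    mvc: float
    trials: list[TrialRecord]
    staircase: StaircaseState
    emg_seeds: list[int]

    def trials_df(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "index": t.index,
                "block": t.block,
                "trial_type": t.trial_type,
                "ssd": np.nan if t.ssd is None else t.ssd,
                **{f"rt_{h}": (np.nan if t.response_time[h] is None
                               else t.response_time[h]) for h in HANDS},
                "outcome": t.outcome,
                "feedback": t.feedback,
            })
        return pd.DataFrame(rows)

    def emg_for_trial(self, index: int,
                      channels: tuple[str, ...] | None = None):
        from .task_sim import synth_emg_trial
        rng = np.random.default_rng(self.emg_seeds[index])
        return synth_emg_trial(self.trials[index], self.config.emg, self.mvc,
                               rng, self.config.session, channels=channels)


@dataclass
class EpochMatrix:
    """Participants x time array of condition-mean, stop-locked,
    preprocessed EMG for one channel and condition."""

    values: np.ndarray          # shape (n_participants, n_samples)
    times: np.ndarray           # ms relative to the lock point
    lock: str                   # "stop_signal" or "mean_ssd"
    condition: str
    channel: str
    participants: list[str] = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class EMGEvent:
    """Burst timing for one trial x hand, relative to the stop signal
    (mean SSD on go trials)."""

    trial_index: int
    hand: str
    onset: float | None          # ms
    peak_time: float | None      # ms
    peak_amplitude: float | None
    partial: bool = False
    cancel_time: float | None = None


@dataclass
class PointwiseTestResult:
    """Per-time-point paired test across the epoch."""

    times: np.ndarray     # ms relative to the lock point
    t_values: np.ndarray
    p_values: np.ndarray  # NaN where the test is undefined (zero variance)
    fdr_mask: np.ndarray  # bool, BH-FDR at q
    df: int
    q: float

    @property
    def rejection_fraction(self) -> float:
        valid = ~np.isnan(self.p_values)
        if not valid.any():
            return 0.0
        return float(self.fdr_mask[valid].mean())


@dataclass
class SuppressionInterval:
    """Longest contiguous epoch interval with > min_prop significant points."""

    onset: float          # ms relative to the stop signal
    offset: float
    n_points: int
    prop_significant: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset
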