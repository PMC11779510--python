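"""Trial EMG preprocessing: rectify -> z-score -> moving average -> epoch.

The pipeline order is fixed. Each trial's signal is rectified (absolute
value), z-scored over the whole trial (sample SD, n-1), smoothed with a
moving average (12 samples = 2.4 ms at 5 kHz, window-start aligned), and a
600 ms epoch is cut around the lock point: the trial's own stop-signal time
on stop trials, the participant's mean stop-signal time of the comparison
stop type on go trials. Condition means across trials give one row per
participant for the pointwise statistics.

Conventions: sample indices are 0-based, intervals half-open; times are ms
from trial onset; epoch time axes are ms relative to the lock point.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PreprocConfig
from .errors import DegenerateInputError
from .types import EMGTrace, EpochMatrix, Session

logger = logging.getLogger(__name__)

__all__ = [
    "rectify", "zscore_trial", "moving_smooth", "baseline_amplitude",
    "extract_epoch", "preprocess_trial", "condition_mean",
    "block_baseline_rms", "condition_epochs", "epoch_time_axis",
]


def rectify(trace: np.ndarray) -> np.ndarray:
    """Full-wave rectification (elementwise absolute value); idempotent."""
    return np.abs(np.asarray(trace, dtype=float))


def zscore_trial(trace: np.ndarray, scope_slice: slice | None = None) -> np.ndarray:
    """Standardize a trial to mean 0, sample SD 1 (ddof=1).

    ``scope_slice`` restricts the samples used to estimate mean/SD (e.g. a
    baseline window); the transform is applied to the whole trace.
    """
    x = np.asarray(trace, dtype=float)
    ref = x if scope_slice is None else x[scope_slice]
    if ref.size < 2:
        raise DegenerateInputError("z-scoring needs >= 2 samples in scope")
    sd = ref.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("cannot z-score a zero-variance trace")
    return (x - ref.mean()) / sd


def moving_smooth(trace: np.ndarray, window: int) -> np.ndarray:
    """Moving average over ``window`` samples, aligned to the window start:
    output[i] = mean(trace[i : i + window]); length shrinks by window - 1."""
    x = np.asarray(trace, dtype=float)
    if window < 1:
        raise DegenerateInputError("window must be >= 1")
    if x.size < window:
        raise DegenerateInputError(
            f"trace of {x.size} samples shorter than window {window}")
    c = np.concatenate([[0.0], np.cumsum(x)])
    return (c[window:] - c[:-window]) / window


def baseline_amplitude(trace: np.ndarray, stop_time_ms: float,
                       sampling_rate: float,
                       window_ms: float = 500.0) -> float:
    """Mean amplitude over the ``window_ms`` preceding the stop signal
    (half-open: [stop - window, stop))."""
    x = np.asarray(trace, dtype=float)
    stop = int(round(stop_time_ms * sampling_rate / 1000.0))
    w = int(round(window_ms * sampling_rate / 1000.0))
    if stop - w < 0 or stop > x.size:
        raise DegenerateInputError(
            f"insufficient signal for a {window_ms} ms pre-stop baseline")
    return float(x[stop - w:stop].mean())


def extract_epoch(trace: np.ndarray, lock_time_ms: float,
                  sampling_rate: float, config: PreprocConfig) -> np.ndarray:
    """Cut [lock - epoch_pre, lock + epoch_post) from a trace.

    Index arithmetic is on the trace's own sampling grid; the caller passes
    the smoothed trace (window-start alignment keeps sample i of the
    smoothed trace at the time of raw sample i).
    """
    x = np.asarray(trace, dtype=float)
    lock = int(round(lock_time_ms * sampling_rate / 1000.0))
    pre = int(round(config.epoch_pre * sampling_rate / 1000.0))
    post = int(round(config.epoch_post * sampling_rate / 1000.0))
    start, stop = lock - pre, lock + post
    if start < 0 or stop > x.size:
        raise DegenerateInputError(
            f"epoch [{start}, {stop}) out of bounds for {x.size} samples")
    return x[start:stop]


def epoch_time_axis(config: PreprocConfig, sampling_rate: float) -> np.ndarray:
    """Per-sample times in ms relative to the lock point."""
    pre = int(round(config.epoch_pre * sampling_rate / 1000.0))
    n = config.epoch_samples(sampling_rate)
    return (np.arange(n) - pre) / sampling_rate * 1000.0


def preprocess_trial(trace: EMGTrace, lock_time_ms: float,
                     config: PreprocConfig) -> np.ndarray:
    """Full per-trial pipeline in the fixed order
    rectify -> z-score -> moving smooth -> epoch extraction."""
    fs = trace.sampling_rate
    x = rectify(trace.samples)
    if config.zscore_scope == "baseline":
        stop = int(round(lock_time_ms * fs / 1000.0))
        w = int(round(config.baseline_window * fs / 1000.0))
        if stop - w < 0:
            raise DegenerateInputError("baseline z-score scope out of bounds")
        x = zscore_trial(x, scope_slice=slice(stop - w, stop))
    else:
        x = zscore_trial(x)
    x = moving_smooth(x, config.smooth_window)
    return extract_epoch(x, lock_time_ms, fs, config)


def condition_mean(epochs_per_participant: list[list[np.ndarray]],
                   times: np.ndarray, condition: str, channel: str,
                   lock: str = "stop_signal",
                   participants: list[str] | None = None) -> EpochMatrix:
    """Samplewise mean across trials within participant, one row each.
    Participants with zero usable epochs are excluded (logged)."""
    rows, kept = [], []
    names = participants or [f"p{i}" for i in range(len(epochs_per_participant))]
    for name, epochs in zip(names, epochs_per_participant):
        if not epochs:
            logger.warning("condition_mean: participant %s has no epochs in "
                           "condition %s; excluded", name, condition)
            continue
        rows.append(np.mean(np.vstack(epochs), axis=0))
        kept.append(name)
    values = np.vstack(rows) if rows else np.empty((0, times.size))
    return EpochMatrix(values=values, times=np.asarray(times), lock=lock,
                       condition=condition, channel=channel,
                       participants=kept)


# ---------------------------------------------------------------------------
# Session-level helpers

def _mean_stop_signal_time(session: Session, stop_type: str) -> float:
    df = session.trials_df()
    ssds = df.loc[df["trial_type"] == stop_type, "ssd"]
    if ssds.empty:
        raise DegenerateInputError(f"no {stop_type} trials in session")
    return session.config.session.target_time + float(ssds.mean())


def condition_epochs(session: Session, channel: str, condition: str,
                     comparison_stop_type: str,
                     config: PreprocConfig) -> list[np.ndarray]:
    """Preprocessed epochs for one condition of one session.

    ``condition`` is ``"go"``, ``"successful_stop"`` or ``"failed_stop"``;
    stop trials are those of ``comparison_stop_type`` and are locked to their
    own stop signal, go trials to the session's mean stop-signal time of the
    comparison type. Out-of-bounds epochs are dropped with a logged warning.
    """
    target = session.config.session.target_time
    if condition == "go":
        trials = [t for t in session.trials if t.trial_type == "go"]
        lock = _mean_stop_signal_time(session, comparison_stop_type)
        locks = [lock] * len(trials)
    else:
        trials = [t for t in session.trials
                  if t.trial_type == comparison_stop_type
                  and t.outcome == condition]
        locks = [t.stop_time(target) for t in trials]
    epochs = []
    for trial, lock in zip(trials, locks):
        trace = session.emg_for_trial(trial.index, channels=(channel,))[channel]
        try:
            epochs.append(preprocess_trial(trace, lock, config))
        except DegenerateInputError as err:
            logger.warning("trial %d dropped (%s)", trial.index, err)
    return epochs


def block_baseline_rms(session: Session, channel: str,
                       window_ms: float = 500.0) -> pd.Series:
    """Fatigue check: RMS of the raw channel over each stop trial's pre-stop
    baseline window, averaged within block. Go trials carry no stop signal
    and are skipped; blocks without usable trials get NaN."""
    target = session.config.session.target_time
    fs = session.config.session.sampling_rate
    per_block: dict[int, list[float]] = {}
    for trial in session.trials:
        stop = trial.stop_time(target)
        if stop is None:
            continue
        trace = session.emg_for_trial(trial.index, channels=(channel,))[channel]
        x = np.asarray(trace.samples, dtype=float)
        hi = int(round(stop * fs / 1000.0))
        lo = hi - int(round(window_ms * fs / 1000.0))
        if lo < 0 or hi > x.size:
            logger.warning("trial %d skipped in block RMS (baseline out of "
                           "bounds)", trial.index)
            continue
        rms = float(np.sqrt(np.mean(x[lo:hi] ** 2)))
        per_block.setdefault(trial.block, []).append(rms)
    n_blocks = session.config.session.n_blocks
    return pd.Series({b: (float(np.mean(per_block[b])) if b in per_block
                          else np.nan) for b in range(n_blocks)},
                     name=f"baseline_rms_{channel}")
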