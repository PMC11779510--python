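"""FDI burst events: onset (2-SD rule), peak, partial responses and cancel
times on successful stop trials.

Onset follows the within-trial threshold rule: the first sample of the
rectified trace strictly above mean + 2 x sample SD, both computed over the
full trial (including the burst, which biases the threshold upward on
burst-heavy trials — a documented property of the rule).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CUED_HANDS, HANDS
from .errors import UsageError
from .preprocess import moving_smooth, rectify
from .types import EMGEvent, Session, TrialRecord

logger = logging.getLogger(__name__)

__all__ = ["detect_onset", "detect_peak", "classify_partial", "detect_events"]


def detect_onset(rectified: np.ndarray, min_run: int = 1) -> int | None:
    """Index of the first sample strictly above mean + 2 x SD (sample SD) of
    the whole trace; ``None`` if the threshold is never crossed.

    ``min_run`` > 1 requires the crossing to be sustained for that many
    consecutive samples (the onset is the start of the first such run),
    which suppresses isolated noise exceedances when scanning whole trials.
    """
    x = np.asarray(rectified, dtype=float)
    if x.size < 2 or x.std(ddof=1) == 0.0:
        logger.warning("onset detection on a degenerate trace; no onset")
        return None
    above = x > (x.mean() + 2.0 * x.std(ddof=1))
    if min_run <= 1:
        idx = np.flatnonzero(above)
        return int(idx[0]) if idx.size else None
    run = np.convolve(above.astype(int), np.ones(min_run, dtype=int),
                      mode="valid")
    idx = np.flatnonzero(run == min_run)
    return int(idx[0]) if idx.size else None


def detect_peak(rectified: np.ndarray, onset: int) -> tuple[int, float]:
    """Maximum of the rectified trace at or after ``onset``; ties go to the
    earliest sample."""
    x = np.asarray(rectified, dtype=float)
    rel = int(np.argmax(x[onset:]))  # argmax returns the first maximum
    return onset + rel, float(x[onset + rel])


def classify_partial(trial: TrialRecord, hand: str,
                     event: EMGEvent) -> EMGEvent:
    """Flag a partial response: a burst onset on a successful stop trial
    without a button release; its peak time is the cancel time."""
    if not (trial.is_stop and hand in CUED_HANDS[trial.trial_type]
            and trial.outcome == "successful_stop"):
        raise UsageError("partial classification applies to the cued hand "
                         "of successful stop trials only")
    partial = event.onset is not None and not trial.responded(hand)
    event.partial = partial
    event.cancel_time = event.peak_time if partial else None
    return event


def detect_events(session: Session, smooth_window: int = 12,
                  min_burst_ms: float = 10.0) -> pd.DataFrame:
    """One row per trial x hand with FDI burst onset/peak (ms relative to the
    stop signal; to the session's mean SSD over stop trials on go trials),
    plus partial/cancel columns for cued hands of successful stops.

    Detection runs on the moving-average-smoothed rectified trace and
    requires the 2-SD crossing to be sustained (for ``min_burst_ms`` or twice
    the smoother's span, whichever is longer) so that isolated noise
    exceedances on burst-free trials are not read as bursts.
    """
    scfg = session.config.session
    fs = scfg.sampling_rate
    min_run = max(1, int(round(min_burst_ms * fs / 1000.0)),
                  2 * smooth_window)
    df = session.trials_df()
    mean_ssd = float(df.loc[df["trial_type"] != "go", "ssd"].mean())
    go_lock = scfg.target_time + mean_ssd

    rows = []
    for trial in session.trials:
        lock = trial.stop_time(scfg.target_time)
        if lock is None:
            lock = go_lock
        for hand in HANDS:
            trace = session.emg_for_trial(
                trial.index, channels=(f"{hand}_FDI",))[f"{hand}_FDI"]
            x = moving_smooth(rectify(trace.samples), smooth_window)
            onset_idx = detect_onset(x, min_run=min_run)
            event = EMGEvent(trial_index=trial.index, hand=hand,
                             onset=None, peak_time=None, peak_amplitude=None)
            if onset_idx is not None:
                peak_idx, peak_amp = detect_peak(x, onset_idx)
                event.onset = onset_idx / fs * 1000.0 - lock
                event.peak_time = peak_idx / fs * 1000.0 - lock
                event.peak_amplitude = peak_amp
            if (trial.is_stop and hand in CUED_HANDS[trial.trial_type]
                    and trial.outcome == "successful_stop"):
                event = classify_partial(trial, hand, event)
            rows.append({
                "trial_index": trial.index,
                "trial_type": trial.trial_type,
                "outcome": trial.outcome,
                "hand": hand,
                "onset_ms": np.nan if event.onset is None else event.onset,
                "peak_ms": (np.nan if event.peak_time is None
                            else event.peak_time),
                "peak_amplitude": (np.nan if event.peak_amplitude is None
                                   else event.peak_amplitude),
                "partial": event.partial,
                "cancel_time_ms": (np.nan if event.cancel_time is None
                                   else event.cancel_time),
            })
    return pd.DataFrame(rows)
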