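"""Behavioral metrics: signed response times, lift and stop accuracies,
SSRT by the integration method with go-omission replacement, and the
stopping-interference effect.

Response times are "signed" ms relative to the anticipated response target
(negative = early lift). SSRT is estimated per stop-trial type from that
type's own p(respond | stop signal) and mean stop-signal time.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .config import CONTINUING_HAND, CUED_HANDS, HANDS, STOP_TYPES
from .errors import UndefinedInputError, UsageError

__all__ = [
    "signed_rt", "lift_accuracy", "stop_accuracy", "ssrt_integration",
    "interference_effect", "feedback_color", "summarize_session",
    "summarize_cohort",
]


def signed_rt(response_time: float | None, target_time: float) -> float | None:
    """Response time relative to the target; ``None`` propagates (an absent
    response is absent, never zero)."""
    if response_time is None or (isinstance(response_time, float)
                                 and math.isnan(response_time)):
        return None
    return response_time - target_time


def lift_accuracy(signed_rts, window: float = 100.0) -> float:
    """Fraction of trials responded within ``window`` ms of the target
    (inclusive bounds); omissions (NaN) count as inaccurate."""
    rts = np.asarray(signed_rts, dtype=float)
    if rts.size == 0:
        raise UndefinedInputError("lift_accuracy of an empty selection")
    with np.errstate(invalid="ignore"):
        hits = np.abs(rts) <= window
    return float(np.where(np.isnan(rts), False, hits).mean())


def stop_accuracy(trials_df: pd.DataFrame, stop_type: str) -> float:
    """Proportion of the given stop type's trials with the cued hand(s)
    successfully withheld."""
    sel = trials_df[trials_df["trial_type"] == stop_type]
    if len(sel) == 0:
        raise UndefinedInputError(f"no trials of type {stop_type!r}")
    return float((sel["outcome"] == "successful_stop").mean())


def ssrt_integration(go_rts, p_respond: float, n_go_omissions: int,
                     stop_signal_time: float) -> float:
    """Stop-signal reaction time by the integration method.

    Go omissions are replaced with copies of the maximum observed go RT; the
    augmented distribution is sorted and its value at rank
    ``ceil(p_respond * N)`` (1-based, N including replacements) is taken; SSRT
    is that value minus the mean stop-signal time. All times are ms from
    trial onset. Failed-stop RTs must not be included in ``go_rts``.
    """
    rts = np.sort(np.asarray(go_rts, dtype=float))
    rts = rts[~np.isnan(rts)]
    if rts.size == 0:
        raise UndefinedInputError("ssrt_integration requires go RTs")
    if not 0.0 <= p_respond <= 1.0:
        raise UsageError(f"p_respond must be in [0, 1], got {p_respond}")
    if p_respond == 0.0:
        raise UsageError("SSRT is undefined at p_respond = 0")
    if n_go_omissions:
        rts = np.concatenate([rts, np.full(n_go_omissions, rts[-1])])
        rts.sort()
    n = rts.size
    rank = math.ceil(p_respond * n)  # 1-based; ties at the lower rank
    nth_rt = rts[rank - 1]
    ssrt = float(nth_rt - stop_signal_time)
    if ssrt <= 0.0:
        warnings.warn(f"nonpositive SSRT ({ssrt:.1f} ms): stop-signal time "
                      "is at or beyond the p-quantile go RT", stacklevel=2)
    return ssrt


def interference_effect(go_signed_rts, continuing_signed_rts) -> float:
    """Stopping-interference effect for one hand: mean continuing-hand RT on
    selective stop trials minus mean go RT (both signed, same hand)."""
    go = np.asarray(go_signed_rts, dtype=float)
    cont = np.asarray(continuing_signed_rts, dtype=float)
    go, cont = go[~np.isnan(go)], cont[~np.isnan(cont)]
    if go.size == 0 or cont.size == 0:
        raise UndefinedInputError("interference_effect of an empty selection")
    return float(cont.mean() - go.mean())


def feedback_color(trial_type: str, response_time: dict[str, float | None],
                   target_time: float) -> str:
    """Trial feedback: green within 50 ms of the target (or a fully correct
    stop), yellow within 50-100 ms, red otherwise (any response on a cued
    stop hand, a lift outside 100 ms, or an omission)."""
    def graded(hands: tuple[str, ...]) -> str:
        rts = [signed_rt(response_time.get(h), target_time) for h in hands]
        if any(rt is None for rt in rts):
            return "red"
        worst = max(abs(rt) for rt in rts)
        if worst <= 50.0:
            return "green"
        if worst <= 100.0:
            return "yellow"
        return "red"

    if trial_type == "go":
        return graded(HANDS)
    cued = CUED_HANDS[trial_type]
    if any(response_time.get(h) is not None for h in cued):
        return "red"
    if trial_type == "stop_both":
        return "green"
    return graded((CONTINUING_HAND[trial_type],))


# ---------------------------------------------------------------------------
# Session / cohort summaries

def _signed(series: pd.Series, target: float) -> np.ndarray:
    return series.to_numpy(dtype=float) - target


def summarize_session(trials_df: pd.DataFrame, target_time: float,
                      accuracy_window: float = 100.0) -> dict[str, float]:
    """Per-participant behavioral summary (the per-row quantities of the
    cohort behavior table): mean signed go RT and lift accuracy per hand,
    and per stop type the stop accuracy, mean SSD, SSRT, failed-stop RT and
    (for selective types) the interference effect of the continuing hand."""
    out: dict[str, float] = {}
    go = trials_df[trials_df["trial_type"] == "go"]
    for hand in HANDS:
        srt = _signed(go[f"rt_{hand}"], target_time)
        out[f"go_rt_{hand}"] = float(np.nanmean(srt))
        out[f"go_lift_accuracy_{hand}"] = lift_accuracy(srt, accuracy_window)

    for stop_type in STOP_TYPES:
        sel = trials_df[trials_df["trial_type"] == stop_type]
        if len(sel) == 0:
            continue
        acc = stop_accuracy(trials_df, stop_type)
        out[f"stop_accuracy_{stop_type}"] = acc
        out[f"mean_ssd_{stop_type}"] = float(sel["ssd"].mean())
        stop_signal_time = target_time + out[f"mean_ssd_{stop_type}"]

        cued = CUED_HANDS[stop_type]
        # go finishing-time distribution of the stopping response: the cued
        # hand's RTs for selective stops; the first lift (per-trial minimum
        # over hands) for stop-both, since any lift counts as a failed stop
        per_hand = np.column_stack(
            [go[f"rt_{h}"].to_numpy(dtype=float) for h in cued])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            go_rts = np.nanmin(per_hand, axis=1)
        n_omit = int(np.isnan(go_rts).sum())
        go_rts = go_rts[~np.isnan(go_rts)]
        p_respond = 1.0 - acc
        if p_respond > 0.0 and go_rts.size:
            out[f"ssrt_{stop_type}"] = ssrt_integration(
                go_rts, p_respond, n_omit, stop_signal_time)

        failed = sel[sel["outcome"] == "failed_stop"]
        if len(failed):
            frts = np.concatenate(
                [_signed(failed[f"rt_{h}"], target_time) for h in cued])
            out[f"failed_stop_rt_{stop_type}"] = float(np.nanmean(frts))
            out[f"failed_stop_lift_accuracy_{stop_type}"] = lift_accuracy(
                frts[~np.isnan(frts)], accuracy_window)

        if stop_type in CONTINUING_HAND:
            hand = CONTINUING_HAND[stop_type]
            cont = _signed(sel[f"rt_{hand}"], target_time)
            cont = cont[~np.isnan(cont)]
            go_hand = _signed(go[f"rt_{hand}"], target_time)
            go_hand = go_hand[~np.isnan(go_hand)]
            if cont.size and go_hand.size:
                out[f"interference_{hand}"] = interference_effect(go_hand, cont)
                out[f"continuing_rt_{stop_type}"] = float(cont.mean())
                out[f"continuing_lift_accuracy_{stop_type}"] = lift_accuracy(
                    cont, accuracy_window)
    return out


def summarize_cohort(sessions, target_time: float | None = None) -> pd.DataFrame:
    """One summary row per participant; cohort means are column means
    (within-participant first, then across participants)."""
    rows = []
    for s in sessions:
        target = (target_time if target_time is not None
                  else s.config.session.target_time)
        row = {"participant": s.participant}
        row.update(summarize_session(s.trials_df(), target))
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant")
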