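"""Synthetic bimanual anticipatory response inhibition (ARI) sessions.

The simulator produces, per participant, a randomized trial schedule with
exact per-type counts, trial outcomes from an independent-race model under
per-stop-type 1-up/1-down SSD staircases, and phenomenological four-channel
surface EMG (left/right FDI and ADM): band-limited Gaussian carrier noise
multiplied by deterministic amplitude envelopes. Every injected effect (the
post-stop ADM suppression dip, response-coupled ADM increase, FDI bursts,
partial bursts on successful stops) is recorded as per-trial ground truth so
downstream recovery can be checked against metadata rather than re-derived.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import signal as sp_signal

from .behavior import feedback_color
from .config import (CHANNELS, CUED_HANDS, HANDS, STOP_TYPES,
                     EMGGenParams, RaceModelParams, RunConfig, SessionConfig)
from .errors import ConfigurationError, UsageError
from .types import EMGTrace, Session, StaircaseState, TrialRecord

__all__ = [
    "make_trial_schedule", "staircase_update", "simulate_trial",
    "simulate_mvc", "synth_emg_trial", "simulate_session", "simulate_cohort",
]

_FWHM_TO_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ~2.3548


def make_trial_schedule(config: SessionConfig,
                        rng: np.random.Generator) -> list[str]:
    """Uniformly permuted trial-type sequence with exact global counts.

    Counts are enforced over the whole session (192 go is not divisible by
    9 blocks), and the permutation is sliced into blocks downstream.
    """
    counts = config.trial_counts()
    schedule = [t for t, c in counts.items() for _ in range(c)]
    return [schedule[i] for i in rng.permutation(len(schedule))]


def staircase_update(state: StaircaseState, stop_type: str, outcome: str,
                     trial_index: int = -1) -> StaircaseState:
    """1-up/1-down SSD update for one stop-trial type.

    A failed stop moves the SSD one step more negative (the stop signal
    comes earlier, more time to stop); a successful stop moves it one step
    toward the target. Other stop types are untouched.
    """
    if stop_type not in STOP_TYPES:
        raise UsageError(f"not a stop trial type: {stop_type!r}")
    if outcome == "failed_stop":
        delta = -state.step
    elif outcome == "successful_stop":
        delta = state.step
    else:
        raise UsageError(f"staircase updates require a stop outcome, "
                         f"got {outcome!r}")
    new_ssd = dict(state.ssd)
    new_ssd[stop_type] += delta
    history = list(state.history)
    history.append((trial_index, stop_type, outcome, new_ssd[stop_type]))
    return StaircaseState(ssd=new_ssd, step=state.step, history=history)


def simulate_trial(trial_type: str, ssd: float | None,
                   race: RaceModelParams, rng: np.random.Generator,
                   config: SessionConfig, index: int = 0,
                   block: int = 0) -> TrialRecord:
    """Draw one trial from the independent-race model.

    Per hand the planned response time is Normal(go_rt_mean, go_rt_sd). On a
    stop cue, one stop latency Normal(ssrt_mean, ssrt_sd) races each cued
    hand's planned response: the hand responds (failed stop for that hand)
    iff planned RT < stop-signal time + stop latency. On selective trials the
    continuing hand is delayed by Normal(interference_delay_mean,
    interference_delay_sd). Go-trial hands omit with ``omission_rate``.
    """
    if (ssd is None) != (trial_type == "go"):
        raise UsageError("ssd must be given exactly on stop trials")

    planned = {h: rng.normal(race.go_rt_mean[h], race.go_rt_sd) for h in HANDS}
    response: dict[str, float | None] = {h: None for h in HANDS}

    if trial_type == "go":
        for h in HANDS:
            if rng.random() >= race.omission_rate:
                response[h] = planned[h]
        outcome = "go_response"
    else:
        stop_time = config.target_time + ssd
        ssrt = rng.normal(race.ssrt_mean, race.ssrt_sd)
        triggered = rng.random() >= race.trigger_failure_rate
        cued = CUED_HANDS[trial_type]
        any_cued_responded = False
        for h in cued:
            if (not triggered) or planned[h] < stop_time + ssrt:
                response[h] = planned[h]
                any_cued_responded = True
        if trial_type in ("stop_left", "stop_right"):
            other = "right" if trial_type == "stop_left" else "left"
            delay = rng.normal(race.interference_delay_mean,
                               race.interference_delay_sd)
            response[other] = planned[other] + delay
        outcome = "failed_stop" if any_cued_responded else "successful_stop"

    feedback = feedback_color(trial_type, response, config.target_time)
    return TrialRecord(index=index, block=block, trial_type=trial_type,
                       ssd=ssd, response_time=response, outcome=outcome,
                       feedback=feedback)


# ---------------------------------------------------------------------------
# EMG synthesis

@lru_cache(maxsize=32)
def _bandpass_sos(order: int, lo: float, hi: float, fs: float) -> np.ndarray:
    return sp_signal.butter(order, (lo, hi), btype="bandpass", fs=fs,
                            output="sos")


def band_limited_noise(n: int, sampling_rate: float, params: EMGGenParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``params.noise_band``
    with a Butterworth filter applied forward-backward (zero phase)."""
    lo, hi = params.noise_band
    if not 0.0 < lo < hi < sampling_rate / 2.0:
        raise ConfigurationError(
            f"noise_band {params.noise_band} invalid at {sampling_rate} Hz")
    sos = _bandpass_sos(params.filter_order, lo, hi, sampling_rate)
    raw = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = raw.std()
    if sd == 0.0:
        return raw
    return raw / sd


def simulate_mvc(params: EMGGenParams, rng: np.random.Generator,
                 sampling_rate: float = 5000.0) -> float:
    """Maximum voluntary contraction reference: the mean of the per-trace
    maxima of four simulated 1 s maximal contractions."""
    n = int(round(sampling_rate))
    maxima = [np.abs(band_limited_noise(n, sampling_rate, params, rng)
                     * params.mvc_sd).max() for _ in range(4)]
    return float(np.mean(maxima))


def _gauss(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def synth_emg_trial(trial: TrialRecord, params: EMGGenParams, mvc: float,
                    rng: np.random.Generator, config: SessionConfig,
                    channels: tuple[str, ...] | None = None,
                    ) -> dict[str, EMGTrace]:
    """Four-channel EMG for one trial (subset selectable via ``channels``).

    Each channel is independent unit-variance band-limited noise times an
    amplitude envelope. ADM envelopes sit at the tonic level (rectified mean
    = tonic_fraction_mvc x MVC), are multiplied by ``1 - dip_depth`` over the
    injected dip window on stop trials, and by a Gaussian
    ``coupled_increase_gain`` bump around the same hand's FDI burst onset
    when that hand responds. FDI envelopes are quiescent except for a
    Gaussian response burst (or a smaller aborted burst on some successful
    stop trials). Channel noise streams are spawned per channel in a fixed
    order, so a subset request yields bit-identical traces.
    """
    if mvc <= 0:
        raise ConfigurationError("mvc must be positive")
    wanted = CHANNELS if channels is None else tuple(channels)
    fs = config.sampling_rate
    n = int(round(config.trial_duration * fs / 1000.0))
    t = np.arange(n) / fs * 1000.0  # ms from trial onset

    sigma_tonic = (params.noise_sd if params.noise_sd is not None
                   else params.tonic_fraction_mvc * mvc / math.sqrt(2.0 / math.pi))
    burst_amp = (params.burst_amplitude if params.burst_amplitude is not None
                 else 0.6 * mvc)
    rest_sd = (params.fdi_rest_sd if params.fdi_rest_sd is not None
               else 0.02 * mvc)
    burst_sd = params.burst_width / _FWHM_TO_SD

    stop_time = trial.stop_time(config.target_time)
    event_times = {"target": config.target_time}
    if stop_time is not None:
        event_times["stop_signal"] = stop_time
    for h in HANDS:
        if trial.responded(h):
            event_times[f"response_{h}"] = trial.response_time[h]

    child_rngs = dict(zip(CHANNELS, rng.spawn(len(CHANNELS))))
    traces: dict[str, EMGTrace] = {}

    for hand in HANDS:
        responded = trial.responded(hand)
        burst_center = (trial.response_time[hand] + params.burst_center_offset
                        if responded else None)
        onset_true = (burst_center - params.burst_width / 2.0
                      if responded else None)

        fdi_name = f"{hand}_FDI"
        if fdi_name in wanted:
            crng = child_rngs[fdi_name]
            env = np.full(n, rest_sd)
            if responded:
                env = env + burst_amp * _gauss(t, burst_center, burst_sd)
            elif (trial.is_stop and hand in CUED_HANDS[trial.trial_type]
                  and trial.ground_truth.get(f"partial_{hand}",
                                             crng.random() < params.partial_burst_rate)):
                center = stop_time + params.partial_peak_latency
                env = env + 0.4 * burst_amp * _gauss(t, center, burst_sd / 1.5)
            traces[fdi_name] = EMGTrace(
                channel=fdi_name,
                samples=env * band_limited_noise(n, fs, params, crng),
                sampling_rate=fs, event_times=dict(event_times))

        adm_name = f"{hand}_ADM"
        if adm_name in wanted:
            crng = child_rngs[adm_name]
            env = np.full(n, sigma_tonic)
            if trial.is_stop and params.dip_depth > 0.0:
                lo = stop_time + params.dip_latency
                hi = lo + params.dip_duration
                env = env * np.where((t >= lo) & (t <= hi),
                                     1.0 - params.dip_depth, 1.0)
            if responded and params.coupled_increase_gain > 1.0:
                gain = 1.0 + (params.coupled_increase_gain - 1.0) * _gauss(
                    t, onset_true, params.coupled_width)
                env = env * gain
            traces[adm_name] = EMGTrace(
                channel=adm_name,
                samples=env * band_limited_noise(n, fs, params, crng),
                sampling_rate=fs, event_times=dict(event_times))

    return traces


# ---------------------------------------------------------------------------
# Sessions and cohorts

def _trial_ground_truth(trial: TrialRecord, params: EMGGenParams,
                        config: SessionConfig,
                        rng: np.random.Generator) -> dict:
    """Record the generator's injected effects as per-trial metadata."""
    gt: dict = {}
    stop_time = trial.stop_time(config.target_time)
    if trial.is_stop:
        if params.dip_depth > 0.0:
            lo = stop_time + params.dip_latency
            gt["dip_window"] = (lo, lo + params.dip_duration)
        else:
            gt["dip_window"] = None
    for hand in HANDS:
        if trial.responded(hand):
            center = trial.response_time[hand] + params.burst_center_offset
            gt[f"burst_center_{hand}"] = center
            gt[f"onset_true_{hand}"] = center - params.burst_width / 2.0
        elif trial.is_stop and hand in CUED_HANDS[trial.trial_type]:
            gt[f"partial_{hand}"] = bool(rng.random() < params.partial_burst_rate)
            if gt[f"partial_{hand}"]:
                gt[f"partial_peak_{hand}"] = stop_time + params.partial_peak_latency
    return gt


def simulate_session(participant: str, config: RunConfig,
                     seed: int) -> Session:
    """One full session: schedule -> staircased race-model trials -> EMG
    seeds. EMG itself is regenerated lazily from per-trial seeds."""
    scfg = config.session
    n_trials = scfg.n_trials
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 + n_trials)
    rng = np.random.default_rng(children[0])
    mvc = simulate_mvc(config.emg, np.random.default_rng(children[1]),
                       scfg.sampling_rate)
    emg_seeds = [int(c.generate_state(1)[0]) for c in children[2:]]

    schedule = make_trial_schedule(scfg, rng)
    staircase = StaircaseState(ssd=scfg.initial_ssd(), step=scfg.staircase_step)
    trials: list[TrialRecord] = []
    for i, trial_type in enumerate(schedule):
        ssd = None if trial_type == "go" else staircase.ssd[trial_type]
        trial = simulate_trial(trial_type, ssd, config.race, rng, scfg,
                               index=i, block=i // scfg.trials_per_block)
        trial.ground_truth = _trial_ground_truth(trial, config.emg, scfg, rng)
        if trial.is_stop:
            staircase = staircase_update(staircase, trial_type,
                                         trial.outcome, trial_index=i)
        trials.append(trial)

    return Session(participant=participant, config=config, seed=seed,
                   mvc=mvc, trials=trials, staircase=staircase,
                   emg_seeds=emg_seeds)


def simulate_cohort(n_participants: int, config: RunConfig,
                    seed: int) -> list[Session]:
    """Independent sessions for ``n_participants``, with per-participant
    seeds derived from the master seed (recorded on each Session)."""
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    ss = np.random.SeedSequence(seed)
    sessions = []
    for i, child in enumerate(ss.spawn(n_participants)):
        p_seed = int(child.generate_state(1)[0])
        sessions.append(simulate_session(f"sub-{i + 1:02d}", config, p_seed))
    return sessions
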