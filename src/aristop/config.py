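"""Configuration objects for the task simulator, EMG generator, preprocessing
and the pointwise inhibition analysis.

Defaults encode the study conditions the package models: a bimanual
anticipatory response inhibition (ARI) task with a response target at 800 ms
into a 1 s filling bar, 9 blocks x 32 trials (192 go / 32 stop-both /
32 stop-left / 32 stop-right), per-stop-type 1-up/1-down 50 ms SSD
staircases starting at -200 ms (stop-both) and -250 ms (selective), surface
EMG sampled at 5,000 Hz, a 12-sample (2.4 ms) moving-average smoother, a
600 ms stop-locked epoch (100 ms pre, 500 ms post = 3,000 samples) and
Benjamini-Hochberg FDR at q = 0.05 with a >90% interval qualification rule.

SSD convention: stop-signal delays are signed milliseconds relative to the
response target; negative means the stop signal appears before the target,
and the absolute stop-signal time is ``target_time + ssd``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

from .errors import ConfigurationError

HANDS = ("left", "right")
TRIAL_TYPES = ("go", "stop_both", "stop_left", "stop_right")
STOP_TYPES = ("stop_both", "stop_left", "stop_right")
CHANNELS = ("left_FDI", "right_FDI", "left_ADM", "right_ADM")

#: hand cued to stop on each stop-trial type
CUED_HANDS = {
    "stop_both": ("left", "right"),
    "stop_left": ("left",),
    "stop_right": ("right",),
}
#: hand that must keep responding on selective stop trials
CONTINUING_HAND = {"stop_left": "right", "stop_right": "left"}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class SessionConfig:
    """Task structure and recording geometry for one session."""

    n_blocks: int = 9
    trials_per_block: int = 32
    go_fraction: float = 2.0 / 3.0
    target_time: float = 800.0       # ms from trial onset
    bar_fill_duration: float = 1000.0  # ms
    trial_duration: float = 2000.0   # ms of EMG recorded per trial
    ssd_init_both: float = -200.0    # ms, signed, relative to target
    ssd_init_selective: float = -250.0
    staircase_step: float = 50.0     # ms
    sampling_rate: float = 5000.0    # Hz
    epoch_pre: float = 100.0         # ms before the lock point
    epoch_post: float = 500.0        # ms after the lock point
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        _require(self.n_blocks >= 1 and self.trials_per_block >= 1,
                 "block structure must be positive")
        _require(0.0 < self.go_fraction < 1.0, "go_fraction must be in (0, 1)")
        _require(self.sampling_rate > 0, "sampling_rate must be positive")
        _require(self.staircase_step > 0, "staircase_step must be positive")
        _require(self.target_time <= self.bar_fill_duration,
                 "response target must lie within the bar-fill interval")
        _require(self.trial_duration >= self.bar_fill_duration,
                 "trial recording must cover the bar fill")
        _require(self.epoch_pre >= 0 and self.epoch_post > 0,
                 "epoch bounds must be nonnegative / positive")
        # counts must be exactly realisable
        self.trial_counts()

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def trial_counts(self) -> dict[str, int]:
        """Exact per-type trial counts; raises if the fractions do not yield
        integers (counts are enforced globally, not per block)."""
        total = self.n_trials
        n_go_f = total * self.go_fraction
        n_go = round(n_go_f)
        _require(abs(n_go_f - n_go) < 1e-9,
                 f"go_fraction x total trials = {n_go_f} is not an integer")
        n_stop = total - n_go
        _require(n_stop % len(STOP_TYPES) == 0,
                 f"{n_stop} stop trials do not split evenly over "
                 f"{len(STOP_TYPES)} stop types")
        per = n_stop // len(STOP_TYPES)
        return {"go": n_go, **{t: per for t in STOP_TYPES}}

    def initial_ssd(self) -> dict[str, float]:
        return {
            "stop_both": self.ssd_init_both,
            "stop_left": self.ssd_init_selective,
            "stop_right": self.ssd_init_selective,
        }


@dataclass(frozen=True)
class RaceModelParams:
    """Independent-race generative model of go and stop finishing times.

    Per hand the planned response time is Normal(go_rt_mean, go_rt_sd) in ms
    from trial onset. On a stop cue a stop latency Normal(ssrt_mean, ssrt_sd)
    races the planned response: the hand responds iff its planned RT beats
    stop-signal time + stop latency. On selective trials the continuing
    hand's response is delayed by Normal(interference_delay_mean,
    interference_delay_sd) (the stopping-interference effect). Trigger
    failures (stop process never starting) default to 0.
    """

    go_rt_mean: dict[str, float] = field(
        default_factory=lambda: {"left": 815.0, "right": 812.0})
    go_rt_sd: float = 60.0
    ssrt_mean: float = 250.0
    ssrt_sd: float = 25.0
    omission_rate: float = 0.01
    interference_delay_mean: float = 95.0
    interference_delay_sd: float = 40.0
    trigger_failure_rate: float = 0.0

    def __post_init__(self) -> None:
        _require(set(self.go_rt_mean) == set(HANDS),
                 "go_rt_mean must give a mean per hand")
        _require(self.go_rt_sd >= 0 and self.ssrt_sd >= 0
                 and self.interference_delay_sd >= 0, "sd values must be >= 0")
        _require(0.0 <= self.omission_rate < 1.0,
                 "omission_rate must be in [0, 1)")
        _require(0.0 <= self.trigger_failure_rate < 1.0,
                 "trigger_failure_rate must be in [0, 1)")
        _require(self.ssrt_mean >= 0, "ssrt_mean must be >= 0")


@dataclass(frozen=True)
class EMGGenParams:
    """Phenomenological EMG generator: band-limited Gaussian carrier noise
    shaped by multiplicative amplitude envelopes.

    ADM channels carry tonic activity whose rectified mean is
    ``tonic_fraction_mvc x MVC``; on stop trials the envelope is multiplied
    by ``1 - dip_depth`` over ``[stop + dip_latency, stop + dip_latency +
    dip_duration]`` (the injected global-inhibition dip), and by
    ``coupled_increase_gain`` in a Gaussian window around the same hand's
    FDI burst onset whenever that hand responds. FDI channels are quiescent
    except for a Gaussian-envelope response burst; successful-stop trials
    carry a smaller aborted ("partial") burst with probability
    ``partial_burst_rate``.
    """

    tonic_fraction_mvc: float = 0.10
    noise_sd: float | None = None       # carrier sd; None -> derived from MVC
    noise_band: tuple[float, float] = (50.0, 450.0)  # Hz
    filter_order: int = 4               # Butterworth, applied forward-backward
    burst_amplitude: float | None = None  # peak envelope sd; None -> 0.6 x MVC
    burst_width: float = 100.0          # FWHM of the burst envelope, ms
    burst_center_offset: float = -50.0  # burst center relative to button lift, ms
    fdi_rest_sd: float | None = None    # resting FDI sd; None -> 0.02 x MVC
    dip_latency: float = 150.0          # ms after the stop signal
    dip_duration: float = 50.0          # ms
    dip_depth: float = 0.5              # multiplicative depth in [0, 1]
    coupled_increase_gain: float = 1.2  # >= 1
    coupled_width: float = 30.0         # Gaussian sd of the coupled bump, ms
    partial_burst_rate: float = 0.15
    partial_peak_latency: float = 140.0  # ms after the stop signal
    mvc_sd: float = 1.0                 # carrier sd of maximal contractions

    def __post_init__(self) -> None:
        _require(0.0 <= self.dip_depth <= 1.0, "dip_depth must be in [0, 1]")
        _require(self.coupled_increase_gain >= 1.0,
                 "coupled_increase_gain must be >= 1")
        _require(0.0 <= self.partial_burst_rate <= 1.0,
                 "partial_burst_rate must be in [0, 1]")
        _require(0.0 < self.tonic_fraction_mvc, "tonic fraction must be > 0")
        lo, hi = self.noise_band
        _require(0.0 < lo < hi, "noise_band must be an increasing Hz pair")
        _require(self.burst_width > 0 and self.coupled_width > 0,
                 "envelope widths must be positive")

    def validate_against(self, config: SessionConfig) -> None:
        _require(self.noise_band[1] < config.sampling_rate / 2.0,
                 "noise_band must lie below the Nyquist frequency")


@dataclass(frozen=True)
class PreprocConfig:
    """Preprocessing applied, in fixed order, to each trial's EMG:
    rectify -> z-score -> 12-sample moving average -> stop-locked epoch."""

    smooth_window: int = 12          # samples
    epoch_pre: float = 100.0         # ms
    epoch_post: float = 500.0        # ms
    baseline_window: float = 500.0   # ms preceding the stop signal
    zscore_scope: str = "whole_trial"  # or "baseline"

    def __post_init__(self) -> None:
        _require(self.smooth_window >= 1, "smooth_window must be >= 1")
        _require(self.zscore_scope in ("whole_trial", "baseline"),
                 "zscore_scope must be 'whole_trial' or 'baseline'")
        _require(self.epoch_pre >= 0 and self.epoch_post > 0,
                 "epoch bounds must be nonnegative / positive")

    def epoch_samples(self, sampling_rate: float) -> int:
        return int(round((self.epoch_pre + self.epoch_post)
                         * sampling_rate / 1000.0))


@dataclass(frozen=True)
class AnalysisConfig:
    """Pointwise-test settings: two-sided paired t per time point, BH-FDR
    at q within each comparison, longest interval with >90% significant."""

    q: float = 0.05
    min_prop: float = 0.9
    sided: str = "two-sided"

    def __post_init__(self) -> None:
        _require(0.0 < self.q < 1.0, "q must be in (0, 1)")
        _require(0.0 <= self.min_prop < 1.0, "min_prop must be in [0, 1)")
        _require(self.sided in ("two-sided", "less", "greater"),
                 "sided must be 'two-sided', 'less' or 'greater'")


@dataclass(frozen=True)
class RunConfig:
    """Bundle of every stage's configuration, serialisable to/from JSON."""

    session: SessionConfig = field(default_factory=SessionConfig)
    race: RaceModelParams = field(default_factory=RaceModelParams)
    emg: EMGGenParams = field(default_factory=EMGGenParams)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    _SECTIONS = {
        "session": SessionConfig,
        "race": RaceModelParams,
        "emg": EMGGenParams,
        "preproc": PreprocConfig,
        "analysis": AnalysisConfig,
    }

    def __post_init__(self) -> None:
        self.emg.validate_against(self.session)

    def to_dict(self) -> dict[str, Any]:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in self._SECTIONS}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            section = dict(data.get(name, {}))
            fields = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(section) - fields
            if bad:
                raise ConfigurationError(
                    f"unknown keys in config section '{name}': {sorted(bad)}")
            for key in ("go_rt_mean",):
                if key in section and isinstance(section[key], dict):
                    section[key] = {k: float(v) for k, v in section[key].items()}
            for key in ("noise_band",):
                if key in section:
                    section[key] = tuple(section[key])
            kwargs[name] = section_cls(**section)
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration (provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
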