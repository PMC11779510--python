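# Methods

This note documents the models, defaults and numerical choices behind
`aristop`, and what the synthetic-data validation does and does not show.

## Task model

A session has 9 blocks × 32 trials with exact global counts of 192 go, 32
stop-both, 32 stop-left and 32 stop-right trials. Counts are enforced over
the whole session, not per block (192 go does not divide into 9 blocks); the
schedule is a uniformly random permutation sliced into blocks. The response
target sits at 800 ms into a 1 s bar fill; each trial's EMG covers 2 s.

Stop-signal delays (SSDs) are signed ms relative to the target: the absolute
stop time is `target + ssd`, and more negative SSDs mean more time to stop.
Staircases start at −200 ms (stop-both) and −250 ms (selective), move 50 ms
more negative after a failed stop and 50 ms toward the target after a
successful stop, independently per stop type, and are unbounded — clamping
the walk was rejected because a boundary at the staircase's equilibrium
biases stop accuracy away from the 1-up/1-down target of 50%. Trials whose
stop signal falls too early for a given window (epoch or 500 ms baseline)
are dropped by the consuming stage with a logged reason instead.

## Race model

Trial outcomes follow an independent race with Gaussian finishing times:

| parameter | default | meaning |
|---|---|---|
| `go_rt_mean` | 815 / 812 ms (left/right) | planned lift time from trial onset |
| `go_rt_sd` | 60 ms | within-participant RT spread |
| `ssrt_mean`, `ssrt_sd` | 250 ms, 25 ms | stop-process latency |
| `omission_rate` | 0.01 | go-trial omissions per hand |
| `interference_delay_mean/sd` | 95 ms, 40 ms | continuing-hand delay on selective stops |
| `trigger_failure_rate` | 0 | stop process never starting |

A cued hand responds (failed stop) iff its planned RT beats
`stop time + stop latency`; one stop latency is drawn per trial. On
selective trials the continuing hand is delayed by the interference draw.
The defaults were chosen once so that the staircase equilibrium
(`median RT − ssrt_mean − target ≈ −235 ms`), lift accuracy (~89%) and the
interference effect (95 ms) sit in the range typical of healthy young adults
on this task; they are a plausible generating process, not a claim about any
particular dataset's true process. Hands race independently, so for
stop-both trials the behaviorally relevant go finishing time is the *first*
lift; SSRT integration for stop-both therefore uses the per-trial minimum RT
across hands, while selective types use the cued hand's RTs. Feedback
windows are inclusive (|RT| ≤ 50 ms green, ≤ 100 ms yellow, else red; any
response on a cued stop hand is red).

SSRT integration takes the rank `ceil(p_respond × N)` (1-based, ties to the
lower rank) of the ascending go distribution after appending one copy of the
maximum observed go RT per go omission. The maximum observed RT (rather than
a trial deadline) is used for replacement; `p_respond = 0` raises, and a
nonpositive SSRT is returned as-is with a warning.

## EMG generator

EMG is phenomenological: unit-variance Gaussian noise band-limited to
50–450 Hz (4th-order Butterworth, forward–backward) multiplied by a
deterministic amplitude envelope. No motor-unit biophysics is modeled.

- **MVC**: mean of the per-trace maxima of four 1 s maximal contractions
  (carrier sd 1.0 signal unit).
- **Tonic ADM**: carrier sd `0.1 × MVC / √(2/π)`, so the rectified mean sits
  at 10% of MVC.
- **FDI bursts**: Gaussian envelope, FWHM 100 ms, peak sd 0.6 × MVC,
  centered 50 ms before the button lift (bursts lead the mechanical
  response); resting FDI sd 0.02 × MVC. Successful-stop hands carry an
  aborted burst (0.4 × amplitude, narrower) with probability 0.15, peaking
  140 ms post-stop — the generator's cancel time.
- **Suppression dip**: on stop trials the ADM envelope is multiplied by
  `1 − dip_depth` (default 0.5) over `[stop + 150, stop + 200]` ms, with
  rectangular edges. The window and depth are recorded per trial as ground
  truth.
- **Response-coupled increase**: when a hand responds, its ADM envelope is
  multiplied by a Gaussian gain bump (peak 1.2, sd 30 ms) centered at the
  FDI burst onset, emulating the coupling between response initiation and
  tonic activity.

Per-trial noise is drawn from per-channel generators spawned in a fixed
order from per-trial seeds, so any channel subset is bit-identical to the
full set and a session can regenerate its EMG lazily from the recorded
seeds. A dataset is fully determined by (config, master seed).

## Preprocessing

The per-trial order is fixed and guarded by tests: rectify (absolute value)
→ z-score → 12-sample moving average → epoch extraction. "Trial-by-trial
z-scoring" standardizes over the entire trial's samples with the sample SD
(n − 1); a baseline-window scope is available as a config switch. The
smoother is a moving average of the already-rectified signal, aligned to the
window start (output length shrinks by w − 1), applied before epoching so
every epoch keeps exactly `(pre + post) × rate` samples — 3,000 at the
defaults (100 ms pre, 500 ms post, 5 kHz). Stop trials are locked to their
own stop signal; go trials to the participant's mean stop-signal time of the
comparison stop type, computed per pairing. Indices are 0-based with
half-open intervals; times are ms from trial onset, epoch axes ms relative
to the lock point.

## Burst events

Onset is the first sample of the rectified trace strictly above
`mean + 2 × SD` (sample SD, whole trial — which biases the threshold upward
on burst-heavy trials; documented, and matched by the brute-force oracle in
the tests). Because any stationary noise trace eventually exceeds a 2-SD
threshold at isolated samples, the session-level event scan additionally
requires the crossing to be *sustained*: detection runs on the 12-sample
smoothed rectified trace and the excursion must last at least
`max(10 ms, 2 × smoother span)`. Without this gate, every burst-free trial
would eventually be flagged and partial-response counts would be
meaningless; with it, a null generator (no partial bursts) produces zero
partial detections while true partial bursts are found reliably. The peak is
the maximum at/after onset, ties to the earliest sample.

## Statistics

Pointwise tests are two-sided paired t tests across participants'
condition-mean traces (participants, not trials, are the paired units;
df = n − 1). Exactly equal conditions give t = 0, p = 1; a constant nonzero
difference leaves p undefined (excluded from FDR, logged). BH-FDR at
q = 0.05 is applied within each comparison over its p-values (statsmodels'
step-up behind the module's interface; an independent brute-force oracle in
the tests). The suppression interval is the longest contiguous run with
strictly more than 90% significant points, ties to the earliest onset,
evaluated with exact integer arithmetic and validated against an exhaustive
O(n²) scan. The three-way failed-stop contrast is run as the three pairwise
comparisons, each with its own FDR.

Power uses the exact noncentral-t distribution: for paired d and n, the
noncentrality is `d·√n` with df n − 1. At n = 18, d = 0.93, α = 0.05
two-sided this gives 0.960; note that a power figure *averaged over two
effectors whose effect sizes average to d* is necessarily below the power
*at* d (Jensen's inequality), so averaged published figures can sit slightly
lower than the single-d value.

## Validation scales and what they show

Recovery experiments run the full default geometry (18 participants × 288
trials, 5 kHz): an injected dip of depth 0.5 is recovered with ≥ 80% overlap
and median onset error within ±15 ms over 20 seeds. The onset lands a few ms
early because the smoother and the carrier's autocorrelation blur the
rectangular dip edges. False-positive control uses a reduced-scale
configuration (1 kHz, 72 trials, 8 participants, 200 seeds) with the dip
*and* the coupled gain disabled — with the coupled gain on, go and
failed-stop trials genuinely differ (failed-stop lifts are earlier), so it
is not a null; this is a property of the task, not of the detector.

Passing these tests shows the pipeline recovers multiplicative amplitude
dips embedded in band-limited Gaussian carriers at realistic SNR and does
not hallucinate them under exchangeable conditions. Real surface EMG differs
in ways the generator does not emulate — nonstationary noise, movement
artifacts, electrode drift, motor-unit synchronization, non-Gaussian
amplitude distributions and participant-specific burst shapes — so ground
truth recovery here bounds methodological, not physiological, validity.

## Known limitations

- The generator's dip is rectangular and multiplicative; graded or additive
  suppression would blur recovered onsets further.
- Independent hands overstate bimanual RT variability relative to the
  strongly coupled lifts of real participants; only the stop-both SSRT
  reading (first lift) depends on this.
- The omnibus ANOVA machinery reported alongside such analyses
  (sphericity corrections etc.) is deliberately out of scope; standard
  statistics packages cover it.
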