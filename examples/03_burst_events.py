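"""FDI burst events and partial responses.

Simulates one session and tabulates burst onset and peak times (relative to
the stop signal; to the mean SSD on go trials) per trial type, plus the
number of partial responses — bursts on successful stop trials that were
aborted before the button release, whose peak is the "cancel time".
"""

from aristop import simulate_session
from aristop.events import detect_events
from aristop.pipeline import reduced_scale_config

config = reduced_scale_config(dip_depth=0.5, coupled_increase_gain=1.2)
session = simulate_session("sub-01", config, seed=3)
events = detect_events(session)

print("mean FDI burst timing (ms relative to stop signal / mean SSD):")
grouped = events.groupby(["trial_type", "outcome"])
for (trial_type, outcome), grp in grouped:
    detected = grp.dropna(subset=["onset_ms"])
    if detected.empty:
        continue
    print(f"  {trial_type:11s} {outcome:15s} onset {detected['onset_ms'].mean():7.1f}"
          f"  peak {detected['peak_ms'].mean():7.1f}  (n={len(detected)})")

partials = events[events["partial"]]
print(f"partial responses: {len(partials)} "
      f"(mean cancel time {partials['cancel_time_ms'].mean():.0f} ms)"
      if len(partials) else "partial responses: 0")
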