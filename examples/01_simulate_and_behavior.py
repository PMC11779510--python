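"""Simulate a small cohort and compute the behavioral summary table.

Builds six synthetic participants at reduced scale (1 kHz EMG, 72 trials)
and prints the cohort means of the standard stop-task metrics: signed go RT,
stop accuracy per stop type, SSRT by the integration method, and the
stopping-interference effect. Stop accuracies should sit near 50% (the
1-up/1-down staircase's target) and SSRT near the generative 250 ms stop
latency.
"""

from aristop import simulate_cohort
from aristop.behavior import summarize_cohort
from aristop.pipeline import reduced_scale_config

config = reduced_scale_config(dip_depth=0.5, coupled_increase_gain=1.2)
cohort = simulate_cohort(6, config, seed=42)
table = summarize_cohort(cohort)

print("cohort means (6 participants, 72 trials each):")
for col in ("go_rt_left", "go_rt_right",
            "stop_accuracy_stop_both", "stop_accuracy_stop_left",
            "stop_accuracy_stop_right",
            "ssrt_stop_both", "ssrt_stop_left", "ssrt_stop_right",
            "mean_ssd_stop_both", "interference_left", "interference_right"):
    print(f"  {col:28s} {table[col].mean():8.1f}")
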