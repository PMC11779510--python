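"""Paired-t power for the go vs failed-stop amplitude comparison.

Prints the power of a two-sided paired t test (noncentral-t exact) across
sample sizes at the benchmark effect size d = 0.93, the kind of sensitivity
statement used to plan tonic-EMG suppression studies.
"""

from aristop import paired_t_power

d = 0.93
print(f"two-sided paired-t power at d = {d}, alpha = 0.05:")
for n in (8, 12, 18, 24, 30):
    print(f"  n = {n:2d}: power = {paired_t_power(n, d):.3f}")

print("\nminimum n for power >= 0.95:",
      next(n for n in range(2, 100) if paired_t_power(n, d) >= 0.95))
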