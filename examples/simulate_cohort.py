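"""Simulate a small labeled EEG cohort and export it as EDF + ground truth.

Builds three subjects (one per diagnostic group) with planted microstate
structure, writes them to ./scratch/sim_cohort/ as EDF files with JSON
sidecars, and prints per-subject spectral summaries.  The printed
alpha/delta power ratio should be highest for the healthy control and
visibly reduced for the AD subject (alpha attenuation + delta bursts).
"""

import numpy as np
from scipy.signal import welch

from mscascade.synthetic import CohortSpec, simulate_cohort, write_cohort

spec = CohortSpec(n_per_class={"AD": 1, "FTD": 1, "HC": 1}, duration_s=60.0, seed=0)
cohort = simulate_cohort(spec)
write_cohort(cohort, "scratch/sim_cohort")

print(f"{'subject':<10} {'group':<5} {'samples':>8} {'alpha/delta power':>18}")
for rec, truth in cohort:
    f, p = welch(rec.data, fs=rec.rate, nperseg=1024)
    alpha = p[:, (f >= 8) & (f <= 13)].sum()
    delta = p[:, (f >= 0.5) & (f <= 4)].sum()
    print(f"{rec.subject_id:<10} {rec.group:<5} {rec.n_samples:>8} {alpha / delta:>18.2f}")

n_states = len(np.unique(cohort[0][1].state_sequence))
print(f"\nground truth: {n_states} microstate classes; "
      f"mean segment {cohort[0][1].segment_durations_ms.mean():.0f} ms "
      "(planted range 60-120 ms)")
print("wrote EDF + sidecars to ./scratch/sim_cohort/")
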