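"""Quantify the association between whitening-front and crack-tip propagation.

In whole rat tibia tests the crack line is visible, so its tip can be
annotated manually (five repetitions against observer variability).  The
whitening front runs a constant few hundred micrometres ahead of the
crack tip; Pearson's r quantifies how tightly the two propagate in sync.
"""

import numpy as np

from whitefront import front_crack_correlation, rat_tibia_scenario, synth_video

params = rat_tibia_scenario(seed=1)
_, truth = synth_video(params)

# emulate five repetitions of manual annotation with ~5 px click noise
rng = np.random.default_rng(1)
active = truth.da_crack_mm > 0
reps = [
    truth.da_crack_mm[active] + rng.normal(0, 5 * params.mm_per_pixel, active.sum())
    for _ in range(5)
]
crack_mean = np.mean(reps, axis=0)

report = front_crack_correlation(truth.da_true_mm[active], crack_mean)
print(f"frames with visible crack: {report.n}")
print(f"Pearson r = {report.r:.3f}   (p = {report.p:.2e})")
print(f"front-crack lag: {report.lag_mean_mm * 1000:.0f} um mean, "
      f"{report.lag_sd_mm * 1000:.0f} um sd   (programmed {truth.lag_mm * 1000:.0f} um)")
print("\nA high r with a constant lag means the whitening front propagates in")
print("sync with the crack tip and can stand in for it as the effective crack")
print("length in specimens where the crack itself is invisible.")
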