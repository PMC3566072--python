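"""Generate a synthetic bend-test video, track the whitening front, build the R-curve.

The scenario emulates a miniature human cortical-bone SE(B) specimen
(B = W = 0.9 mm, a0 = 0.3 mm, 6.15 mm span, E = 12 GPa) filmed at 60 fps
while loaded at 0.01 mm/s.  The pipeline registers each frame to the
first, segments the whitening zone in the difference image, converts the
front position into crack extension Δa, and evaluates J(Δa) and
K_eff(Δa) from the synchronised load-displacement record.
"""

import numpy as np

from whitefront import (
    ScenarioParams,
    TrackConfig,
    build_rcurve,
    modulus_from_record,
    sync_frames,
    synth_video,
    track,
)

params = ScenarioParams(seed=0)
frames, truth = synth_video(params)
synced = sync_frames(frames, truth.mech)
trajectory = track(
    frames,
    synced,
    params.notch_tip_px,
    params.calibration,
    TrackConfig(roi=params.roi(), reg_window=params.reg_window()),
)

force = np.array([s.force_N for s in synced if s.synced])
disp = np.array([s.disp_mm for s in synced if s.synced])
E, fit = modulus_from_record(force, disp, params.geometry)
curve = build_rcurve(trajectory, params.geometry, E, m=fit.m)

print(f"flexural modulus from the linear slope: E = {E:.0f} MPa (truth {params.E_MPa:.0f})")
print(f"segmentation threshold (Otsu, final difference frame): {trajectory.threshold_used:.3f}")
print(f"resistance curve: {len(curve)} points up to peak load\n")
print("   da_mm    a/W    J_kJm2   Keff_MPa_sqrt_m")
for pt in curve.points[::10]:
    print(f"   {pt.da_mm:5.2f}  {pt.a_mm / params.geometry.W:5.3f}  {pt.J:8.4f}   {pt.K_eff:7.3f}")

err_px = (
    np.nan_to_num(trajectory.da_raw_mm) - np.where(np.isfinite(truth.front_px[:, 0]), truth.da_true_mm, 0.0)
) / params.mm_per_pixel
print(f"\nfront-tracking RMS error vs ground truth: {np.sqrt(np.mean(err_px**2)):.2f} px")
print("J rises with crack extension Δa: the damage zone resists growth —")
print("the rising R-curve behaviour the method is designed to measure.")
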