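# Methods

## Measurement model

The package treats a three-point-bend fracture test of a miniature SE(B)
specimen as two synchronised data streams: a grayscale video of the
specimen face and the tester's force/time/displacement record.  Because
bending and recording start together, frame *X* of an *f*-fps capture
occurred at *X*/*f* seconds; force and displacement are interpolated at
the frame times over the shared acquisition index.  (Interpolating in
time rather than matching on force keeps the mapping single-valued after
peak load, where force is non-monotonic.)

The crack itself is assumed invisible; the observable is the whitening
zone — micro-crack damage ahead of the crack tip that raises local
reflectivity.  Its upper boundary (the *whitening front*) is used as the
effective crack tip.  The validity of that substitution is an empirical
claim: in specimens where both are visible, front and crack tip
propagate in sync with a constant offset of a few hundred micrometres
(the `correlate` module quantifies exactly this on annotated series).

## Front tracking

Each retained frame is registered to the whitening-free first frame by
single-step DFT-upsampled cross-correlation (rigid translation only;
sub-pixel to 1/upsample px, default 1/100).  The difference image is
formed in reference coordinates — the current frame is warped back by
the estimated shift (bilinear) and the reference subtracted — so the
notch-tip pixel stays fixed; negative differences are clipped (whitening
is an intensity increase) and unresolved borders zeroed.  For rigid
shifts this is equivalent to resampling the reference forward.

Segmentation thresholds the difference image and applies a morphological
join operator with a 2-px-diameter disc.  The default operator is
*closing*: the intent is to join neighbouring whitening patches by
removing small dark islands (for instance the dark crack line inside the
bright zone), which is what closing does; opening is available by
config.  Morphology is evaluated with an explicit background pad so the
result equals the operation on the infinite plane — naive border
handling hallucinates mask pixels at the ROI edge under closing.

The front is localised on the largest 4-connected component of the mask
("the whitening region"; isolated supra-threshold noise pixels must not
hijack a top-most-pixel definition), after discarding components below a
small minimum area (5 px).  Within that region, the top (minimum) row's
left-most and right-most pixels are the top-left/top-right extrema; the
front is whichever lies farther from the notch tip (ties resolve
top-left).

Crack extension Δa defaults to the **vertical projection**
`(tip_row − front_row)·mm/px`: Δa enters the SE(B) geometry function as
a through-width crack length, and a straight-line distance would couple
the lateral extent of the zone's top row into *a(i)*.  The Euclidean
distance between front pixel and notch tip — the more literal reading of
"distance between the whitening front and the initial notch tip" — is
available via `displacement_mode="euclidean"`.

The raw per-frame series is monotonicised with a running maximum:
whitening is accumulated damage, so transient dropouts (a frame where
the zone dims below threshold) must not move the effective crack tip
backwards.

### Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `stride` | 15 | analyse 1 of every 15 captured frames (4 Hz at 60 fps) |
| `upsample_factor` | 100 | registration resolution, 0.01 px |
| `threshold` | `"otsu"` | one global threshold from the *final* frame's difference image (largest whitening extent, cleanest bimodal histogram), applied to all frames for consistency; a fixed value can be supplied |
| `element_diameter_px` | 2 | structuring-disc diameter for the join operator |
| `join_operator` | `closing` | see above |
| `min_area_px` | 5 | discard segmentation specks below this area |
| `smooth_sigma` | (0.7, 1.4) px | Gaussian smoothing of the difference image before thresholding; anisotropic on purpose — the front advances along rows, so smoothing more along columns pools evidence across the front's width (matched filtering) without blurring the advancing edge |
| `roi` | config | rectangular region around the notch; segmentation is confined to it |
| `reg_window` | optional | sub-rectangle used for shift estimation, placed away from the growing whitening so scene change does not bias registration |
| `gamma`, `window_percentiles` | off | per-frame windowing re-normalises each frame by its own statistics; once the whitening grows, that drifts and leaks gain ghosts into the differences — preprocessing is therefore display/QC oriented and off in the default pipeline |

## Fracture mechanics

With the synchronised record `(F_i, d_i)` and crack length
`a_i = a0 + Δa_i` (monotonicised Δa):

* `K_i = F_i·S/(B·W^{3/2})·f(a_i/W)`, with the ASTM E1820 SE(B)
  geometry polynomial
  `f(x) = 3√x·[1.99 − x(1−x)(2.15 − 3.93x + 2.7x²)] / [2(1+2x)(1−x)^{3/2}]`.
* `J_el,i = K_i²(1−ν²)/E` (plane-strain conversion, ν = 0.33 for bone).
* `J_pl,i = η·A_pl,i/(B·b0)`, `b0 = W − a0`, η = 1.9 (basic SE(B)
  procedure; configurable).  `A_pl,i` is the trapezoidal area under
  F vs plastic displacement `d_pl = d − F/m` up to sample *i*, floored
  at 0; *m* is the least-squares slope of the linear part of the record
  (default window: rising-branch samples between 10% and 50% of peak
  force; r² < 0.99 warns).
* `K_eff,i = sqrt(J_i·E/(1−ν²))`.

Units are N and mm throughout, giving moduli in MPa, J in N/mm ≡ kJ/m²,
and K in N·mm^−1.5, converted to MPa·√m by the exact factor √(10⁻³).

The R-curve emits one point per synced frame with Δa > 0 or F > 0,
truncates points with `a_i ≥ W` (front at the top surface), and by
default terminates at peak load: failure coincides with the front
reaching the top surface, and on the softening branch `a_i` is pinned at
the ligament while `J_el ∝ F²` merely decays — no longer a resistance
measurement.  `stop_at_peak=False` keeps the full record.

Validity screening beyond `a_i < W` (J_max / Δa_max qualification,
unloading-compliance crack estimates) is out of scope.  Note that the
SE(B) `f(a/W)` grows without bound as a/W → 1, so late points of a
near-breakthrough test carry very large J values; interpret them
accordingly.

## Notched-beam modulus correction (FE)

The apparent flexural modulus of a notched beam,
`E_f = S³m/(4B(W−a0)³)` (three-point-bend relation evaluated with the
notched in-plane width), *overestimates* the material modulus: the notch
perturbs the stress field only locally, so the measured stiffness drops
far less than the `(W−a0)³` section scaling assumes.

A linear-elastic plane-stress model quantifies this: a structured mesh of
fully integrated 4-node bilinear quadrilaterals (2×2 Gauss), ~0.075 mm
elements in a band around midspan and ~0.2 mm elsewhere (≈10³ elements
at the default geometry), with the notch realised as a zero-width slot
by node duplication (sharp-crack limit; the saw-cut width is not
modelled).  Contact is replaced by the simplest constraints that leave
the kinematics right: supports are *single pinned corner nodes* (a
roller must leave the section free to rotate — pinning a patch of nodes
was tried and stiffened a slender beam by ~10%), and the load is a
prescribed-displacement patch of ±0.075 mm (a rigid flat punch;
convergent, unlike a point displacement whose local compliance diverges
logarithmically under refinement).  The apparent stiffness is the total
vertical reaction per unit prescribed displacement.

Solving for a0 = 0, 0.075, 0.15, 0.3 mm gives strictly decreasing
stiffnesses and strongly increasing apparent moduli (11.2 → 26.9 GPa at
12 GPa input).  The correction model fits
`g(a0) = E_f_app(0)/E_f_app(a0)` with `1 + c1·a0 + c2·a0²` (anchored
g(0) = 1, monotone non-increasing, R² ≈ 0.9996); `correct_modulus`
multiplies a measured notched value by g(a0).

Two deliberate scope points:

* The correction removes the **notch** bias only.  At the stubby default
  geometry (S/W ≈ 6.8) the plane-stress solution contains ~7% shear
  deflection, so even the un-notched apparent modulus sits below the FE
  input modulus.  That shear is equally present in the physical
  un-notched measurement, so the corrected value is the modulus *an
  un-notched bend test would have measured* — which is precisely the
  quantity the flexural formula defines.  Closed-loop recovery is
  therefore asserted against the un-notched apparent modulus (within 1%
  at every fitted a0), and agreement with Euler–Bernoulli beam theory is
  asserted in the slender limit (S/W = 20, within 3%), where the formula's
  own assumptions hold.
* Absolute stiffness at the stubby geometry converges slowly (~1% per
  mesh halving: point-support log term plus the crack-tip singularity);
  the notched/un-notched stiffness *ratio* that the correction consumes
  converges below 1% per halving at the finest level, and that is the
  convergence property the tests assert.

## Front-vs-crack correlation

Manual crack annotations are ingested as a CSV (frame, repetition,
start/end pixels); repetitions aggregate to per-frame mean and standard
deviation of Δa_crack (standard deviation over ≥2 repetitions captures
intra-observer variability).  The association with the front series is
Pearson's r with the exact t-transform p-value (n−2 dof), computed
against the repetition mean; zero-variance series are flagged rather
than propagating NaNs silently.  The front-minus-crack lag mean and sd
estimate the process-zone length and its stability.

## Synthetic scenarios: what they emulate, and what they do not

`synth_video` renders: a speckled specimen band (Gaussian-filtered noise
texture, sd 0.08, on a 0.05 background) with PSF-like smooth edges
(σ = 0.7 px), a dark notch slot, a whitening halo nucleating at the
notch tip and growing along a monotone schedule (linear from frame 5 to
breakthrough at frame 70 by default), an optional 1-px dark crack line
lagging the front by a constant 0.35 mm (drawn once from 0.30–0.40 mm in
the rat preset), iid Gaussian frame jitter (sd 0.3 px), and sensor noise
(sd 0.025 against halo amplitude 0.25: contrast/noise 10).  The
mechanics record ramps displacement at 0.01 mm/s with force exactly
linear at the notched-beam flexural slope until the breakthrough frame,
then decays exponentially (τ = 0.15 s) — stable softening, no
instability fracture.

Two design choices matter for interpretation:

* **Self-measured truth.**  The halo is rendered from the
  pixel-quantised schedule with steep analytic edges (σ = 0.35 px)
  positioned so that thresholding the noise-free layer at amplitude/2
  yields exactly the intended pixel support; the emitted ground-truth
  front is then *measured from that support with the same localiser the
  pipeline uses*.  "Render then measure" is exact by construction, and
  recovery tests measure tracking fidelity, not rendering bookkeeping.
* **Shift-covariant rendering.**  All scene components are analytic
  functions sampled at jitter-shifted coordinates (texture via cubic
  interpolation of a fixed field), so sub-pixel jitter moves the scene
  without interpolation-dependent intensity loss.  Crisp pixel-mask
  rendering was tried first; its bilinear attenuation at edges is an
  artefact of the renderer, not of imaging physics.

What passing tests therefore show: the pipeline recovers a known front
trajectory to sub-pixel RMS under realistic jitter and noise, and the
J/K_eff computation reproduces a forward-computed reference exactly when
the front is recovered exactly.  What they do not show: robustness to
illumination drift, out-of-plane motion, specimen rotation, partially
reversible whitening, multiple damage zones, or real bone texture —
real-data behaviour must be validated on real videos.

## Numerical choices and degenerate inputs

* Intensities are floating [0, 1]; 8/16-bit inputs divide by their code
  range; colour converts by BT.709 luminance.
* Pixel calibration uses the Euclidean distance between the support
  points (the in-plane distance a span calibration measures).
* Zero-variance images refuse registration ("no texture"); coincident
  support points refuse calibration; constant-intensity frames window to
  zeros with a warning; an empty whitening mask is a valid "no front
  yet" result; frames past the end of the mechanics record are flagged
  unsynced and excluded from the R-curve.
* Equidistant front extrema tie-break to the top-left pixel; Otsu on a
  flat final difference disables segmentation with a warning rather than
  thresholding noise.
* `A_pl` floors at 0; `a_i ≥ W` truncation uses a 1e-9 tolerance against
  float round-off in `a0 + Δa`.
* The FE solve treats a singular reduced system (insufficient
  constraints) as an error; element areas are validated positive at mesh
  construction.

## Known limitations

* Rigid-translation registration only; rotation or deformation of the
  field of view is not compensated (the paper's method shares this
  limit).
* The whitening front is a surface observable; through-thickness damage
  is inferred, not measured (tomography shows the correspondence but
  also its partial reversibility under unloading).
* η and f(a/W) are the standard SE(B) values; very short cracks or
  non-standard span ratios would need their own calibration.
* The FE correction is 2-D plane stress with an idealised sharp slot; a
  finite-width saw cut and 3-D effects are not modelled.
* J values near a/W → 1 are formula-dominated and should not be read as
  material properties.
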