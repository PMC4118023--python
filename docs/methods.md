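# Methods

## Overview

`emdflow` asks what a retinotopic array of correlation-type elementary
motion detectors (EMDs) — the canonical model of insect local motion
computation — represents about the three-dimensional structure of the
environment during translatory self-motion. The package couples three
components:

1. a **panoramic scene simulator** with exact ground-truth depth,
2. a **model of the fly visual motion pathway** (photoreceptor
   nonlinearity, peripheral band-pass, opponent Reichardt detectors,
   motion-energy combination), and
3. a **depth-from-parallax estimator** (Lucas–Kanade flow, geometric
   projection, triangulation, calibrated correction) plus the
   correlation analyses that relate the motion-energy profile to scene
   features.

The central quantity is the **contrast-weighted nearness** map: the
pointwise product of local RMS contrast and nearness (reciprocal
distance, cm⁻¹). During straight translation at roughly constant speed,
the motion-energy profile of the EMD array closely tracks this map —
the array highlights the contrast borders of *nearby* objects.

## Scene simulation

Scenes are built from textured vertical cylinders on a textured ground
plane inside a distant backdrop sphere (default 100 m). The camera sits
0.5 m above ground and translates along a 1 m straight track in 100
steps of 10 mm (1 m/s ⇒ 10 ms per step); saccade-like turns rotate the
camera in place with a raised-cosine yaw-velocity profile (default 180°
in 70 ms; smooth, zero-velocity endpoints). Depth-equalized control
scenes project the panorama of the track center onto a sphere of radius
1 m or 5 m: texture is preserved from the center viewpoint while every
direction shares one distance.

Surface textures are periodic 1/f-shaped noise: flat below an outer
correlation scale (cylinders 5 cm, ground 15 cm, backdrop 3°) and
scale-free down to the grid resolution, standardized to a target RMS
contrast (0.35 objects, 0.30 ground, 0.25 backdrop) around a mean of
1.0 (linear brightness, arbitrary units). The 1/f spectrum matters: the
pathway's temporal band-pass weights the finer, faster-moving
components, so the spectrum shapes the effective temporal-frequency
content and hence the measured response delay.

The **standard fixture** is a fixed arrangement of eight cylinders at
0.85–3.7 m from the track center (the nearest/largest, a 0.25 m-radius
trunk 1.9 m to the side, is the "dominant object"); ground-truth
nearness spans about two orders of magnitude, as in a cluttered forest.
The arrangement is a study condition and does not vary with the seed;
the seed controls the texture noise realizations. Rendering uses
analytic ray–cylinder/plane/sphere intersections (verified against a
brute-force ray marcher) and returns co-registered brightness and
central-ray depth (cm).

## Optics and periphery

Receptors form an equirectangular lattice: 1.25° spacing, elevation
−58°…+47° (85 rows × 288 columns). The angular sensitivity is Gaussian,
`F(φ) = exp(−2.77 φ²/Δρ²)` with acceptance angle Δρ = 1.64° as full
width at half maximum, truncated at 2Δρ and renormalized to a weighted
mean (so a uniform scene maps to a uniform response). The renderer
supersamples at spacing/9 (the 9×9 ordered-grid anti-aliasing
convention); azimuthal offsets are foreshortened by cos(elevation), so
the kernel separates per row. 100 Hz pose-locked sequences are
upsampled tenfold to 1 kHz with monotone piecewise-cubic Hermite
interpolation (shape-preserving: passes through every sample, no
overshoots); N frames become (N−1)·10 + 1.

Photoreceptors apply the Naka–Rushton transform `U = Iᵅ/(Iᵅ + I₀ᵅ)`
with α = 0.7 and I₀ equal to the mean brightness of the current frame
(a crude global adaptation; it changes slowly along a track). The first
optic ganglion is a serial first-order low-pass (τ_L = 8 ms) and
high-pass (τ_H = 20 ms). Filters are discretized with the exact
exponential solution for piecewise-linear input (pole `exp(−dt/τ)`;
unconditionally stable; analog magnitude response reproduced to <0.1 %
at 1 kHz) and initialized at steady state on the first frame, so the
high-pass output starts at zero.

## EMD arrays and motion energy

Each EMD multiplies the low-pass-delayed signal (τ_lp = 40 ms) of one
receptor with the undelayed signal of its direct neighbor and subtracts
the mirror-symmetric subunit: `r = LP[s₁]·s₂ − s₁·LP[s₂]`. Horizontal
arrays pair azimuthal neighbors and wrap around the panorama (288
detector columns); vertical arrays pair elevation neighbors (84
detector rows). A drifting sinusoid of amplitude ΔU, wavelength λ and
temporal frequency f (toward increasing index) produces the mean
response `ΔU²·(ωτ/(1+ω²τ²))·sin(2πΔφ/λ)`, ω = 2πf — maximal at
f = 1/(2πτ) ≈ 3.98 Hz; this closed form (re-derived symbolically in the
tests via the convolution integral) is the oracle for the simulated
arrays (agreement ≤ 2 %). Motion energy is the pointwise Euclidean norm
of the horizontal/vertical pair on their overlap grid (84 × 288;
horizontal output registered to the left receptor, vertical to the
upper); it is identical whether the signed responses are full-wave
rectified first or not.

## Depth from motion parallax

High-resolution equirectangular frames (927 × 251) are rendered with
3×3 ordered-grid supersampling — band-limited image formation, as a
physical camera would provide; single-ray sampling would alias the 1/f
texture and bias the gradient-based flow estimate low. The stack is
normalized to [0, 1], pre-smoothed with Gaussians (spatial σ = 0.2 px;
temporal σ = 1.5 frames over 5 original frames) and differentiated
centrally; per-pixel flow solves the 5×5-window least-squares system,
with pixels rejected when the smaller structure-tensor eigenvalue falls
below 0.0039 (the threshold is only meaningful under the stated [0, 1]
normalization).

Measured flow is projected onto the geometrically correct
pure-translation direction (the tangent-plane component of −heading;
magnitude factor sin θ, zero at the flow-field singularities FOE/FOC),
and depth follows by small-angle triangulation, `D = b·sinθ/Δφ` with
baseline b = 1 cm per frame pair. Non-positive projections and depths
beyond twice the backdrop distance are invalid (data, not errors). The
systematic quadratic error of such estimators is inverted by
`Dc = −p₂/(2p₁) + sqrt((p₂/(2p₁))² + D/p₁)` with defaults
p₁ = 2.778·10⁻³ cm⁻¹, p₂ = 0.456; `fit_depth_correction` re-calibrates
(least squares of measured vs true depth on a known-depth rendered
movie) when the defaults do not suit the estimator at hand. Finalizing
applies an invalid-aware 3×3 median (pixels with <3 valid neighbors
drop out), a 10×10 ordered-grid Gaussian-acceptance aggregation to the
receptor lattice, and the reciprocal to nearness.

On the standard fixture the estimated nearness correlates with ground
truth at r ≈ 0.92 over valid receptors, and the dominant object's depth
is recovered within ~6 %.

## Feature maps and correlation analyses

Local RMS contrast is the standard deviation over the 3×3 receptor
neighborhood divided by its mean (azimuth-wrapped, vertically
truncated), computed on the receptor-resolution brightness frame before
the Naka–Rushton stage; contrast-weighted nearness is the elementwise
product with the nearness map, inheriting its validity mask.

Correlations are squared Pearson coefficients over valid pixels,
by default on log-transformed maps (the energy/feature relation is
roughly linear on double-logarithmic axes); values are floored at
10⁻³ × their own valid median before the log. Zero-variance inputs
yield an invalid (NaN) result rather than an exception. The pathway's
temporal filters delay the energy profile; `estimate_latency` finds the
lag maximizing mean pixelwise R² between energy(t) and features(t−lag)
over late intersaccadic frames, and all analyses compensate 22 ms by
default. Masks exclude (or exclusively keep) pixels within a
great-circle radius of the FOE/FOC; spatial pooling convolves maps with
a k×k uniform kernel (odd multiples of the lattice spacing,
azimuth-wrapped, invalid-aware), and the pooling analysis reports both
pooled-vs-pooled ("reliability") and pooled-vs-unpooled
("localizability") R² curves.

## Problem sizes and numerical choices

The default study renders 100 supersampled frames (805 × 2592) per
condition, yielding 991 one-millisecond frames at 85 × 288 receptor
resolution; the latency search spans lags 0–60 ms sampling every fifth
frame of the second half of the translation (transients settled).
These sizes keep a full condition run at roughly one to two minutes on
a single CPU while leaving the quantitative results stable across
seeds (the measured latency is 23 ms for every seed tested).
Determinism: all randomness flows from one integer seed through
`numpy` SeedSequences; identical seeds give bit-identical frame stacks.

## What the synthetic scenes do and do not capture

The generator reproduces the geometry of cluttered environments
(order-of-magnitude nearness range, vertical objects over a ground
plane, distant backdrop), saccade/intersaccade gaze dynamics, and
natural-image-like 1/f surface statistics with controlled contrast. It
does **not** reproduce bright skies or back-lit canopies (all surfaces
share one mean brightness), occlusion-rich foliage, specularities, or
brightness changes over time. One measurable consequence: in these
scenes, nearer surfaces systematically subtend coarser angular texture
and therefore survive the acceptance-angle blur with more contrast, so
motion energy and contrast-weighted nearness share an
elevation-profile correlation that persists even during pure rotation
(R² ≈ 0.3, unchanged when the feature map is rotated in azimuth —
i.e. it carries no azimuth-specific depth information; removing row
means leaves R² ≈ 0.08). Real outdoor imagery, whose strongest
contrasts sit in the distant background, does not show this shared
structure, and rotation correlations measured on it collapse toward
zero. Passing tests on the synthetic fixtures therefore demonstrate
the depth-dependent, azimuth-specific part of the result — the
full-depth vs depth-equalized contrast and the latency, pooling and
recovery properties — but the absolute rotation correlation level is
fixture-statistics-dependent.

## Known limitations

- The quadratic depth correction defaults calibrate a particular
  flow-estimation stack; with this package's estimator the correction
  is near-neutral around 2 m but distorts depths far from that range
  (nearness *correlations* are insensitive to this monotone warp).
- The latency estimate reads a broad optimum (the R²-vs-lag curve
  varies by <2 % across 0–60 ms); its location is stable across seeds
  on the standard fixture but depends on scene texture statistics.
- Saccade dynamics are a raised-cosine idealization, not recorded
  blowfly kinematics; 180° amplitude is beyond the naturalistic range.
- Horizontal EMD baselines are lattice neighbors; no correction is made
  for the shrinking great-circle separation at high elevations.
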