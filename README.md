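# emdflow

Model analysis of how the insect visual motion pathway represents the
depth structure of cluttered environments during translatory
self-motion.

Flying insects extract spatial information from **motion parallax**:
during straight (intersaccadic) flight, nearby objects sweep across the
retina faster than distant ones. The local motion measurements behind
this are well described by **correlation-type elementary motion
detectors** (EMDs) — but EMD responses confound velocity with pattern
properties such as contrast, which has long been considered a defect of
the mechanism. This package implements the analysis showing it is a
feature: the **motion-energy profile** of a retinotopic EMD array — the
map of `absEMD(x,y) = sqrt(vEMD² + hEMD²)` — represents the
**contrast-weighted nearness** of the environment,

    CwN(x, y) = c(x, y) · N(x, y),

where `c` is the local RMS contrast (3×3 neighborhood std/mean) and
`N = 1/D` the nearness (reciprocal distance, cm⁻¹). In other words, the
EMD array highlights the contrast borders of *nearby* objects.

The package provides:

- a **panoramic scene simulator** (textured cylinders + ground +
  backdrop; 1/f surface textures; exact ground-truth depth maps;
  straight tracks, saccade-like turns, and depth-equalized sphere
  controls),
- the **motion pathway model**: Gaussian acceptance-angle sampling to an
  85 × 288 receptor lattice (1.25° spacing, Δρ = 1.64°), Naka–Rushton
  photoreceptors (α = 0.7, per-frame I₀), band-pass lamina filtering
  (τ_L = 8 ms, τ_H = 20 ms), opponent EMD arrays (τ_lp = 40 ms), motion
  energy,
- **depth from motion parallax**: Lucas–Kanade flow, projection onto
  the translational flow geometry, triangulation, quadratic error
  correction (p₁ = 2.778·10⁻³, p₂ = 0.456), nearness maps at receptor
  resolution,
- **analyses**: pixelwise log-domain R², filter-latency estimation,
  FOE/FOC masking, square uniform pooling (reliability vs
  localizability), correlation time courses, and condition comparisons
  (full-depth vs depth-equalized vs rotation).

See `docs/methods.md` for the model details and numerical choices.

## Worked example

```python
import numpy as np
import emdflow as ef
from emdflow.analysis import pixel_correlation
from emdflow.pipeline import pathway_latency

# simulate the standard cluttered scene and run the motion pathway
run = ef.run_condition(seed=0, condition="full_depth")

# motion energy vs contrast-weighted nearness at the track center,
# compensating the 22 ms filter delay of the pathway
r2 = pixel_correlation(run["energy"][500], run["cwn"][500 - 22]).r2
print(f"R^2 at track center: {r2:.3f}")

# response latency of the pathway (lag maximizing the mean R^2)
print(f"pathway latency: {pathway_latency(run):.0f} ms")
```

prints

```
R^2 at track center: 0.840
pathway latency: 23 ms
```

The R² of ~0.84 says that, frame by frame, the spatial pattern of
motion energy is largely explained by where nearby, high-contrast
structure sits in the visual field; the 23 ms lag is the cumulative
group delay of the pathway's temporal filters. Running the same
analysis on a depth-equalized control (`condition="de_1m"`, identical
texture but all depth structure removed) drops the center R² to ~0.23 —
the difference is the depth information carried by motion parallax.

The command-line workbench exposes the same pipeline
(`emdflow simulate | run-model | depth-map | features | analyze |
reproduce`); every output TIFF carries a JSON sidecar with the exact
configuration and seed that produced it.

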