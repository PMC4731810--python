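# nestcamo

Quantify the camouflage of ground-nesting bird clutches — eggs, or the
incubating adult — through the eyes of their predators, and test whether
better camouflage predicts nest survival.

Ground-nesting birds such as plovers, coursers and nightjars rely on
background matching to protect their clutches from visually hunting
predators. Judging that match with human eyes is misleading: the relevant
predators range from dichromatic mammals to tetrachromatic, UV-sensitive
birds. `nestcamo` implements the full measurement chain for calibrated
multispectral photography of nests:

1. **Calibration** (`nestcamo.calibration`) — raw 16-bit camera counts are
   linearized with a monotone power-law response fitted on Spectralon
   reflectance standards, normalized against a 40% grey standard, and
   rescaled to survive pixel saturation (an image whose brightest pixel is
   120% reflectance is stored scaled by 1/1.2 and restored in floating
   point). UV-pass and visible-pass exposures are registered with a
   scale-plus-translation transform, giving a five-channel reflectance
   stack (visible R/G/B + UV R/B).
2. **Predator vision** (`nestcamo.vision`) — receptor quantum catches
   Q = ∫R(λ)S(λ)I(λ)dλ are predicted per pixel from the camera channels by
   degree-2 polynomial regressions fitted on a reflectance spectral
   library, for a dichromat (ferret), a trichromat (human) and a
   tetrachromat with a double cone (peafowl).
3. **Background-match metrics** (`nestcamo.metrics`, `nestcamo.colour`) —
   per visual system: mean luminance and contrast (mean and SD of
   √luminance); `luminance_diff`, the L1 distance between 32-level
   luminance histograms of target and surround; `pattern_diff`, the L1
   distance between granularity spectra from FFT bandpass filters at 17
   scales (2 px to 512 px in √2 steps); and colour match in
   just-noticeable differences (JNDs) under the receptor-noise model, with
   Weber fractions derived from cone ratios (ferret 1:14, human
   1:5.49:10.99, peafowl 1:1.9:2.2:2.1; noise 0.05 for the most abundant
   cone), after clustering each region into dominant colours with a
   0.05-JND local / 1-JND global rule.
4. **Survival analysis** (`nestcamo.survival`) — Kaplan–Meier curves with
   Greenwood 95% bands under median splits, fixed-effects Cox
   proportional hazards of predation on any metric, and pooled group
   summaries.
5. **Synthetic data** (`nestcamo.simulate`) — calibrated scenes with
   controllable luminance/pattern/contrast/colour mismatch and nest-fate
   tables whose predation hazard depends on mismatch, so the whole chain
   is testable without photographs.

## Worked example

Render a synthetic nest scene whose target's texture is 3× coarser than
its background, and measure its camouflage as a ferret would see it:

```python
import nestcamo as nc
from nestcamo.vision import builtin_visual_system

image, regions, truth = nc.generate_scene(
    nc.SceneSpec(size=128, pattern_scale=3.0, seed=7))
mapper = nc.fit_default_mapper(builtin_visual_system("ferret"), seed=0)
rec = nc.run_nest(image, regions, {"ferret": mapper}, nest_id="demo")[0]
```

This prints, via the record's fields:

```
mean luminance  target 0.570  background 0.562
contrast        target 0.072  background 0.075
luminance_diff  0.244
pattern_diff    0.174
best JND match  0.010   mean JND match 0.010
```

The target matches its background in mean luminance, contrast and colour
(best JND ≈ 0: indistinguishable), but the deliberate pattern mismatch
shows up in `pattern_diff` (a perfectly matched control scene scores
≈ 0.05 here). Feeding such metrics into the survival stage recovers a
planted camouflage–survival effect:

```python
res = nc.pattern_recovery_replicate(seed=1, n_nests=150)
# beta 0.973  se 0.152  z 6.42  events 53/150
```

i.e. a simulated study of 150 nests whose log-hazard rises by 1 per SD of
pattern mismatch yields β̂ = 0.97 ± 0.15 (Z = 6.4) — the Cox model, fed
pipeline-computed `pattern_diff`, detects that poorly pattern-matched
nests are depredated sooner.

A `nestcamo` console script exposes the stages as subcommands
(`calibrate`, `simulate-scene`, `simulate-study`, `metrics`, `survive`);
see `nestcamo --help`.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions and known limitations in detail.
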