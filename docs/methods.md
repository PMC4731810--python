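# Methods

This note documents the models behind `nestcamo`, the parameters that
matter, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Image calibration

**Linearization.** Camera counts are non-linear in scene radiance. Each of
the five channels (visible R/G/B, UV R/B) gets a monotone
power-law-plus-offset curve, `linear = a·(count/65535)^g + c` with
`a, g > 0`, fitted by least squares (`scipy.optimize.curve_fit`) to the
(reflectance, mean count) pairs of at least four photographed reflectance
standards. The per-channel R² is reported against the standards'
reflectances; on counts simulated from a power-law sensor the fit is exact
(R² ≥ 0.999). The power-law form is a modelling choice — it matches
typical sensor tone curves and is invertible-free (the model maps counts
forward to linear response, so no numerical inversion is needed).

**Grey-standard normalization.** Per channel, pixels are scaled so the
mean linearized response over the grey-standard region equals the
standard's known reflectance (default 0.40). Reflectance is therefore a
fraction of a perfect diffuse reflector and may exceed 1 for specular or
sunlit surfaces.

**Saturation rule.** For 16-bit storage, if the global maximum reflectance
M exceeds 1 all values are divided by M and `saturation_scale = 1/M` is
recorded; reconstruction divides the stored values back out in floating
point. Values above 1 are *retained*, not clipped: the rule exists to
eliminate saturation, and round-trip error is bounded by half a 16-bit
quantization step.

**UV/visible registration.** The transform is restricted to uniform scale
about the image centre plus translation — the geometry a tripod-mounted
refocus induces; rotation is excluded. Scale is grid-searched (default
0.95–1.05, 21 steps); per candidate scale the translation comes from
phase correlation between the visible green and UV blue channels
(`skimage.registration.phase_cross_correlation`, 0.1 px upsampling), and
the candidate with the highest normalized cross-correlation wins. A
correlation below a configurable floor raises rather than silently
returning a bad transform. Known synthetic shifts are recovered to
±0.5 px and scales to one grid step.

**Scale matching.** Images photographed at different distances are
brought to a common px/mm by bilinear interpolation (order-1, no
anti-aliasing so constants are preserved exactly).

## Predator vision mapping

Receptor quantum catch of a surface is
`Q = ∫R(λ)S(λ)I(λ)dλ / ∫S(λ)I(λ)dλ` (trapezoidal rule on the shared
wavelength grid, 320–680 nm at 4 nm by default), normalized so a perfect
reflector gives Q = 1. The default illuminant is equal-energy; measured
illuminants can be supplied as curves.

Because camera channels are not predator receptors, receptor catches are
*predicted* from the five camera catches by per-receptor polynomial
regressions (degree 2 with pairwise interactions and intercept;
`sklearn.PolynomialFeatures` + `LinearRegression`) fitted on a
reflectance spectral library. Calibrated reflectance channels serve
directly as camera quantum catches when mapping images. This works
because natural reflectance spectra are smooth and effectively
low-dimensional, so five broad channels carry nearly all the information
a receptor integral needs; on the synthetic library the training R² per
receptor exceeds 0.998 for all built-in systems. Negative predicted
catches (extrapolation at very dark pixels) are clamped at 1e-6 because
the colour model takes log ratios.

Built-in visual systems (synthetic Gaussian sensitivities; measured
curves may be loaded from CSV):

| system  | receptors (short→long) | cone ratio | luminance channel |
|---------|------------------------|------------|-------------------|
| ferret  | S, L                   | 1 : 14     | L cone            |
| human   | S, M, L                | 1 : 5.49 : 10.99 | (L + M)/2   |
| peafowl | U, S, M, L (+ double)  | 1 : 1.9 : 2.2 : 2.1 | double cone |

The peafowl double cone is an achromatic-only channel: it gets its own
fitted mapping and defines luminance but takes no part in colour
distances.

## Achromatic metrics

Mean luminance and contrast are the mean and population SD of
square-root-transformed luminance over a masked region (the square root
normalizes the typically right-skewed luminance distribution). The
transform applies *only* to these two statistics, not to histograms or
pattern spectra.

`luminance_diff` bins untransformed luminance into 32 equal levels over
0–100% reflectance (values above 100% go to the top bin), normalizes
counts to proportions — target and surround differ in area, and
proportions compare appearance rather than area — and sums absolute
bin differences. Range [0, 2]; an L1 metric.

`pattern_diff` compares granularity spectra. The region's bounding box is
cropped; pixels outside the mask are replaced by the region mean (no
windowing — mean-padding avoids spurious edge energy); an annular FFT
bandpass at each of 17 scales (2 px to 512 px, consecutive scales in
ratio √2, band k keeping spatial periods in [scale_k, scale_{k+1}))
filters the crop; the energy at a scale is the SD of the filtered values
over the mask. Scales coarser than the crop report zero energy so all
spectra share 17 scales. `pattern_diff` is the L1 distance between two
such spectra: sensitive to marking size, spacing and contrast, blind to
phase — it tests background matching, not template matching. Scale
values are computed as 2^(1+k/2) so even-index scales are exact binary
floats and integer-period signals land in the intended band.

## Colour metrics

Colour distances use the receptor-noise-limited model: for catches
`a, b`, contrasts `Δf_i = ln(a_i/b_i)` enter the standard quadratic form
(for a dichromat `|Δf₁ − Δf₂|/√(ω₁² + ω₂²)`; tri- and tetrachromatic
forms are the corresponding quadratic expressions, implemented for any
n ≥ 2). Weber fractions come from cone ratios by the noise-pooling rule
`ω_i = 0.05·√(η_max/η_i)` — 0.05 for the most abundant cone class, larger
for rarer ones. The log-ratio form makes distances invariant to a common
illumination scaling and a true metric on log-catch space.

Each region is reduced to dominant colours in two stages: (1) local
region growing (4-connectivity, row-major scan) joins a pixel to the
growing cluster if it is within 0.05 JND of the neighbouring pixel it was
reached from — adjacent-pixel comparison is the default because it is
what lets smooth shading gradients clump into one colour; comparison to
the cluster's running mean is available via `local_compare="mean"` —
then (2) global linking, largest cluster first, absorbs any remaining
cluster whose mean is within 1 JND, chaining until stable. Recording
stops at 99% cumulative coverage or 32 colours. Cluster means are
geometric (log-space) means, consistent with the log-ratio metric; ties
in coverage break by discovery order.

Colour match of a target against its surround: `best_jnd` is the distance
from the most abundant target colour to the nearest background colour;
`mean_jnd` is the coverage-weighted mean distance to all background
colours (weights renormalized over the colours found). best ≤ mean by
construction.

## Survival analysis

Nests contribute observation time from discovery to predation (the
event), hatching, or censoring; hatching is treated as censoring for the
predation hazard. Kaplan–Meier curves (per median-split group) come from
`lifelines`, with Greenwood variance `V̂ = Σ d/(n(n−d))` accumulated from
the event table and a log-transformed 95% band `exp(ln Ŝ ± 1.96√V̂)`
clipped to [0, 1]. The Cox model is fixed-effects
(`lifelines.CoxPHFitter`: Efron tie handling, Newton–Raphson), with
covariates standardized internally and species available as strata.
Random-effect (frailty) models are deliberately out of scope; the
fixed-effects estimator preserves the association test and is verifiable
against a directly enumerated partial likelihood (the test suite checks
agreement to 1e-6 on small samples without ties). Interaction analyses
(e.g. egg contrast × background contrast) are offered as a fixed-effects
logistic regression labelled explicitly as an approximation without
random effects.

Pooled group summaries combine per-species (n, mean, sd) rows by
sample-size weighting: pooled mean `Σnᵢmᵢ/Σnᵢ` and pooled variance
`[Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²]/(N−1)`, equal to the statistics of the
concatenated raw samples.

## Synthetic data

The generator reproduces the *statistical structure* the analysis
assumes, not photographs.

**Spectra.** Reflectance spectra are low-order random Fourier series
(default 4 harmonics, amplitude SD 0.22/k³, base level uniform on
0.2–0.6) clipped to (0.01, 0.99). The steep amplitude decay models the
low effective dimensionality of natural reflectance spectra — the
property that makes camera-to-receptor mapping accurate in the first
place. Adjacent-wavelength correlation across a library exceeds 0.9.

**Scenes.** Backgrounds are isotropic 1/f^β Gaussian textures
(default β = 1) band-limited to spatial periods 4–32 px, modulating a
5-channel base reflectance multiplicatively (amplitude 0.25). The target
is a centred ellipse (default semi-axes size/4.5 × size/6) with its own
texture *filtered from the same white-noise field*, so with all mismatch
knobs off the target texture equals the background's exactly. Knobs:
`pattern_scale` multiplies the target's period band (texture coarseness);
`contrast_scale` its amplitude; `delta_luminance` scales its base
reflectance; `delta_colour_jnd` applies opposite log offsets to UV vs
visible channels calibrated so a ferret-ratio dichromat sees exactly the
requested JND. A 2-px guard ring separates target and background masks.
Not emulated: directional illumination and shadows, object boundaries and
occlusion, anisotropic textures, specularity, sensor noise — so passing
tests demonstrate correctness of the measurement chain, not field
performance on real photographs.

**Fates.** Predation times are exponential with hazard
`λ·exp(β·z)` where z is the standardized mismatch (defaults λ = 0.015/day,
β = 1, incubation 28 days, giving roughly a one-third predation rate).
Censoring is independent per nest with one of the field's non-predation
fates (desertion 0.20, unknown fate 0.09, trampling 0.025, season end
0.02), at a uniform time within incubation; survivors hatch at day 28.
The constant baseline hazard is chosen for analytic tractability, and the
Cox estimator does not depend on it.

**End-to-end check.** `pattern_recovery_replicate` generates scenes
across a pattern-mismatch gradient (target texture scale 1–4×,
log-uniform), runs the full cone-catch + granularity pipeline at 64×64 px
(a deliberate small problem size; metric values are resolution-dependent
but the survival association is not), draws fates with β = 1 per SD of
`pattern_diff`, and fits the Cox model. Across seeded replicates at
n = 150 the planted effect is detected (Z > 1.96) in well over 80% of
runs.

## Numerical conventions and degenerate inputs

- Masks: nonzero pixels are members; target ∩ background must be empty;
  exclusions are removed from both before any metric.
- Empty masks, regions under 4×4 px (pattern), fewer than 2 pixels
  (contrast), non-positive catches (JND), zero events (Cox) all raise
  informative errors rather than returning NaN.
- All generators take integer seeds and are bit-reproducible.
- Histogram bin index is `min(floor(32·v), 31)`; median-split ties go to
  the "low" group; cluster-coverage ties break by discovery order.

## Known limitations

- The polynomial vision mapping is only as good as the spectral library
  it is trained on; extrapolation outside the library's gamut is clamped
  but not flagged.
- The global colour-linking stage is greedy (largest first); a different
  merge order can change cluster boundaries for colours near exactly
  1 JND apart.
- Fixed-effects Cox ignores among-species and spatial clustering of
  hazards; stratification by species mitigates but does not model it.
- The scene generator's textures are Gaussian and isotropic; real nest
  substrates have oriented structure (grass, twigs) whose granularity
  spectra are richer.
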