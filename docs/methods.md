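# Methods

## The measurement this package models

A microtubule is a hollow cylinder of outer radius 12.5 nm. Immunolabeling
places fluorophores not on the tube itself but on an affinity stack —
primary plus secondary IgG antibodies contribute a linkage error of
17.5 nm, DNA-modified secondary antibodies add the oligonucleotide length
— so the dye occupies a cylindrically symmetric shell around the tube. In
a 2D super-resolution image the projection of that shell produces the
characteristic double-peaked transverse profile, and the separation of the
two sidewall peaks (the *peak-to-peak distance*) is the standard readout
for both labeling geometry and, after gel expansion, the molecular
expansion factor.

Two labeling orders behave differently under expansion by a linear factor
*e*:

- **pre-expansion labeling** — dyes are anchored into the gel before
  swelling, so all radial distances (tube radius *and* label shell) scale
  with *e*; the linkage error is magnified;
- **post-expansion labeling** — antibodies bind after swelling, so only
  the structure scales; on the biological scale the linkage error shrinks
  to 17.5 nm / *e*.

## Forward model

For a radial dye density ρ(r), the transverse profile is the line-of-sight
projection

    P(x) = ∫ ρ(√(x² + u²)) du ,

which for a volume-uniform annulus [r₁, r₂] reduces to
√(r₂² − x²) − √(max(r₁,|x|)² − x²) — the same function used as the
"cylinder" cross-section fit model. The projection is convolved with a
Gaussian of width σ_loc (localization precision, held fixed on the image
scale because it is a property of the imaging, not of the specimen) and
normalized to unit area.

The peak-to-peak distance is then extracted exactly as on measured data: a
bi-Gaussian y = h₁G(x−c₁;w₁) + h₂G(x−c₂;w₂) + b is fitted by nonlinear
least squares and the distance is |c₂ − c₁|. Two properties of this
readout matter and are deliberate:

1. **Local seeding.** The fit is seeded at the two highest local maxima of
   the (2 nm smoothed) profile with widths taken from the local curvature
   at each maximum, and then optimized locally (trust-region reflective,
   with one polishing restart). The fit landscape genuinely contains two
   optima — a "peak-locked" solution whose centers sit on the sidewall
   maxima and a "broad-lobe" solution whose wider Gaussians also absorb
   the interior plateau. Locally seeded fits track the peak-locked
   solution when the sidewalls are sharp relative to the structure (large
   expansions) and relax into the broad solution when blur and structure
   size are comparable (unexpanded samples). This size-dependent readout
   is not an artifact to be engineered away: it is how practitioner fits
   behave, and it is what makes the unexpanded prediction (32.4 nm) *not*
   simply 1/e times the expanded one.
2. **Matched window.** The fitted window spans the fluorophore shell plus
   blur tails plus a 20 nm margin (`profile_half_width`). Fitting over a
   much wider window biases the distance low, because the empty tails
   force the baseline toward zero and the Gaussians toward covering the
   interior. Measured profiles should therefore be fitted over the same
   window the model uses; `extract_profiles` takes the half-width as a
   parameter for exactly this reason.

For noisy measured profiles the bi-Gaussian additionally has a soft
symmetry-breaking mode (one lobe sharpens on one sidewall, the other
broadens inward), which biases the distance low by several percent.
`fit_profile(..., symmetric=True)` constrains the two components to mirror
images (equal h and w, centers c₀ ± d/2); on an ideal symmetric profile it
coincides with the free fit, on noisy data it removes the soft mode. The
pooled-segment analyses in this package use the symmetric variant.

### Geometry catalogue

`data/geometries.yaml` describes each labeling protocol as a fluorophore
shell: `label_inner`/`label_outer` bound the shell as radial offsets
beyond the tube surface, `ring_weight` of the dye sits in a thin
(`ring_thickness` = 1 nm) ring at the outer edge and the rest is uniform
over the shell, and `sigma_loc` = 3 nm blurs the projection. The numbers
are calibrated: the exact radial dye distributions of the published
simulations this model reproduces are not stated in the available text, so
the catalogue pins the free parameters against the published simulated
peak-to-peak values and keeps them fixed thereafter. The calibrated
geometry is physically coherent:

| preset | shell | reading |
|---|---|---|
| `igg_pre` | ring at 11.9 nm beyond the surface (93% ring weight) | digestion-compacted IgG stack, dye layer at ~24.4 nm radius |
| `igg_post` | ring at 17.5 nm, `expands_linker: false` | intact post-expansion stack at the full linkage error |
| `dna42_dsdna` | ring at 11.9 + 38·0.34 nm | gel-extended double strand; the dye sits 4 bases in from the strand end |
| `dna42_ssdna` | ring at 11.9 + 9.1 nm | coiled single strand; worm-like-chain rms end-to-end of the 12.9 nm contour with persistence length 5 nm |
| `dna42_relaxed` | uniform shell 11.1–24.0 nm | unexpanded DNA antibody: orientationally disordered linker, hemisphere-averaged radial offsets |

`pre_post_mix` is a superposition: the pre-label profile is added to the
post-label profile with weight 0.1 (signal dilution of the pre-expansion
dye by roughly the square of the expansion factor, i.e. its 2D projection
density drops ~10-fold at 3.2x) and the sum renormalized.

Reference outputs of the calibrated catalogue (all within 2% of the
published simulated values they were pinned to): unexpanded IgG 32.4 nm;
unexpanded 42-base DNA antibody 41.5 nm; 3.2x dsDNA 226.0 nm; 3.2x coiled
ssDNA 201.6 nm; 3.2x pre+post superposition 80.3 nm; measured 137.1 nm and
133.8 nm invert to 3.1x and 3.0x.

### Inversion

`infer_expansion_factor` solves predict_p2p(g, e) = measured by Brent's
method on [1, 10] (tolerance 1e-9). Monotonicity of predict_p2p in *e* is
grid-checked for every shipped preset, which guarantees a unique root. The
predicted-profile axis uses a fixed point count (4001) rather than a fixed
step so the objective varies smoothly with *e*; a step-quantized window
would make it micro-discontinuous and limit the round-trip identity
(infer ∘ predict = id), which holds to ~1e-9 in *e*. Results are reported
at one decimal, plus full precision.

## Image pipeline

Tracing follows the classic recipe for fiber-like structures in rendered
localization images: Gaussian blur (bridging labeling gaps; for hollow
filaments the blur should exceed about half the expected sidewall distance
so the two walls merge into one ridge), thresholding (Otsu by default, Li
or a fixed value selectable), Lee skeletonization to one-pixel width,
splitting at branch pixels (pixels with more than two skeleton neighbors
are discarded, so every path has internal degree ≤ 2 and no pixel belongs
to two paths), a minimum-length filter, and a degree-3 parametric
smoothing spline with s = smoothing · n · pixel_size² (≈ one pixel rms
residual at smoothing = 1). Traversal starts at endpoints; loops are
opened at their lexicographically smallest pixel; everything is
deterministic.

The skeleton of a blurred *hollow* filament wanders toward whichever
sidewall is locally brighter, and the averaged profile inherits that
jitter as extra sidewall width. `refine_centerline` therefore resamples
the original image perpendicular to the trace, estimates the local
symmetry center by mirror correlation over 200 nm arc chunks (precision
set by the sidewall width, not the shell radius, unlike an intensity
centroid), median-filters and smooths the correction over 300 nm, and
refits the spline (two iterations). On synthetic data this brings the
centerline within ~1–2 nm rms of the generating curve.

Profiles are extracted every `step` nm of arc length by bilinear
interpolation along the perpendicular, averaged, and optionally
end-trimmed (`trim`) because skeleton erosion and spline end effects
distort the first few hundred nm of each trace. Per-segment peak-to-peak
values aggregate as the unweighted sample mean ± sd (n−1) across segments;
each segment counts once regardless of length, matching how such
statistics are usually quoted. For 3D stacks, `xz_projection` extracts the
same perpendicular profiles plane by plane; each plane's averaged profile
becomes one row of a side-view image in which a hollow filament appears as
an annulus.

## Synthetic data

The generator emulates rendered dSTORM images of immunolabeled (expanded)
microtubules: smooth random filaments (cubic splines along jittered
chords, bounded curvature, enforced pairwise separation), localizations
Poisson-distributed along the arc with radial offsets drawn from the
geometry's fluorophore shell at a uniform azimuth, isotropic Gaussian
localization noise, and uniform background. A single integer seed makes
every fixture bit-reproducible. Default scale: 20 × 20 µm field, 150
localizations/µm, 0.5 background/µm² — small enough that unit tests run in
seconds.

It does **not** simulate raw camera frames, blinking kinetics, repeated
localizations of one fluorophore, drift, or gel distortion fields. Passing
tests therefore demonstrate that the analysis is unbiased for the assumed
point statistics, not that it is robust to every artifact of real data.

### Closure experiment

`validation.closure_experiment` ties the two halves of the package
together: generate a sample at expansion *e*, analyze it blind with the
full pipeline, and compare with predict_p2p. Conditions (chosen once):
three filaments in an 8 × 8 µm field, 1500 localizations/µm (the grouped-
localization density regime of well-labeled dSTORM microtubules), 0.3/µm²
background, 2 nm render pixels; tracing blur 1.1× the expected distance,
profile window from `profile_half_width`, segment profiles pooled
(weighted by contributing lines, as when one averaged cross-section is
reported for several segments) and fitted symmetrically. Recovery is
within ~2% of prediction at e ∈ {1, 2, 3.2, 4} (worst case over several
seeds ~5%); the suite asserts 5%.

## Numerical choices and degenerate inputs

- Cross-section models are evaluated exactly as written; the cylinder
  model's bore condition uses |x − c| so the shape is translation
  invariant. Invalid radii (r₁ ≥ r₂) raise.
- Fits report components in canonical order (c₁ < c₂ < c₃); ties in peak
  detection break leftmost-first. Width or radius collapse raises a
  `FitError` rather than returning a degenerate optimum.
- The cylinder-family fit landscapes are rugged near the shell edges
  (square-root kinks); those fits should be seeded within ~5–10% of the
  expected parameters, as their documented workflow has always required.
- Rendering: counts mode conserves the localization count exactly;
  coordinates follow the x → columns, y → rows convention with pixel
  centers at (i + 0.5) · pixel_size. Pixel sizes are always explicit —
  TIFF resolution tags are honored when present but never guessed.
- Blur with σ = 0 is the identity; empty masks skeletonize to empty;
  blank images trace to an empty list; an empty localization table
  refuses to render.

## Known limitations

- The fluorophore-shell parameters are calibrated against published
  simulation outputs, not measured dye distributions; other gel
  chemistries or antibody stacks need recalibration.
- The two-regime behavior of the bi-Gaussian readout means predicted
  distances near the regime transition (e ≈ 2–3 for the IgG geometry) are
  more sensitive to profile broadening than elsewhere; the closure
  experiment quantifies this.
- Tracing assumes sparse, well-separated filaments; crossings are cut at
  junctions rather than resolved, and labeling gaps are not bridged
  beyond the tracing blur.
- The expansion model is a single linear scale factor; anisotropic gel
  distortion is out of scope.
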