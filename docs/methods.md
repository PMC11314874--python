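# Methods

## The model

The package works on the LIP (Logarithmic Image Processing) tone scale.
A grey-level image acquired in transmission is identified with the
semi-transparent obstacle that produced it; the tone `f(x) ∈ [0, M[` of a
pixel is an attenuation, equivalent to a transmittance
`T_f(x) = 1 − f(x)/M` — the probability that a particle of the source
passes the obstacle at `x`. The scale is inverted relative to display
intensity: tone 0 is white (transparency), tones near `M` are black. `M`
is an open bound (total opacity, never attained); the largest storable
intensity is `M − 1`. Stored files use `I = (M−1) − f`; conversion
happens only at the I/O boundary (`to_tone` / `from_tone`).

Superposition of obstacles multiplies transmittances, giving

    f ⊕ g = f + g − f·g/M          (addition)
    λ ⊗ f = M − M·(1 − f/M)^λ      (scalar multiplication)

`⊕` models a change of exposure (adding a uniform filter darkens), `⊗` a
change of thickness (λ>1 darkens, 0<λ<1 brightens). Extended to tones in
`]−∞, M[`, these laws form a real vector space; the opposite
`⊖f = −f/(1 − f/M)` satisfies `f ⊕ ⊖f = 0` and negative tones act as
light intensifiers (transmittance > 1). All internal arithmetic is
double-precision on tones; negative tones are unbounded below, so no
integer representation is attempted before export.

## Full Dynamic Range Expansion

Write `f(a) = sup f`, `f(b) = inf f`, `DR(f) = f(a) − f(b)`.

**Subtractive route.** `DR(f ⊖ C) = DR(f)/(1 − C/M)` grows with `C`, so
`DR = M−1` is achieved at the closed form `C0 = M·(1 − DR(f)/(M−1))`.
Since `f ⊖ C` is affine in `f`, the result (translated so its minimum is
0) is exactly the classical linear stretch of `[f(b), f(a)]` onto
`[0, M−1]`; the tests assert agreement to 1e-9.

**Multiplicative route.** For `λ < 0`, `DR(λ ⊗ f) =
M·[(1−f(a)/M)^λ − (1−f(b)/M)^λ]` is continuous and strictly increasing
as λ decreases, from 0 toward ∞, so the equation

    (1 − f(a)/M)^λ0 − (1 − f(b)/M)^λ0 = 1 − 1/M

has a unique negative root. It is solved by integer descent
λ = −1, −2, −3, … until the left side first
exceeds `1 − 1/M` (hard cap at −1000, beyond which the expansion is
declared infeasible — this happens only when `f(a) ≤ 0`, i.e. an image
already brighter than the source everywhere, for which `DR(λ⊗f)` stays
bounded), then bisection of the unit bracket to interval width 1e-6
(default `tol`) or 200 halvings. The display image is
`λ0 ⊗ f − λ0 ⊗ f(a)` with *arithmetic* subtraction of the constant —
the only reading under which the span is exactly `[0, M−1]`.

**Orientation.** Because `λ0 < 0`, the map above is strictly decreasing
in tone: applied literally it swaps bright and dark. The default
`orientation="order_preserving"` reflects the result as `(M−1) − g`,
mapping `f(b) ↦ 0` and `f(a) ↦ M−1` while spanning the same range;
`orientation="literal"` keeps the unreflected formula for reproducing
the raw algebra. Achieved-range tolerance is 0.5 grey level on the
continuous (pre-quantization) image.

**Colour.** One shared `λ0` is solved on the Global Dynamic Range (joint
max minus joint min over R, G, B); all channels are multiplied by it and
translated by the single constant `λ0 ⊗ (joint max)`. A per-channel
solve would change hue; the shared LIP-affine map preserves the
per-pixel ordering of channels (verified in tests).

## σ-maximization

σ is read as the population standard deviation of the pixel grey-level
distribution — computable from a 1-grey-level-bin histogram — not the
standard deviation of histogram *counts*, which a constant image would
maximize and which therefore cannot be an enhancement objective.

- Subtractive family `f ⊖ C`: affine in `f` with slope `1/(1−C/M)`
  strictly increasing in `C`, so σ increases monotonically and the
  in-scale constraint (min enhanced tone ≥ 0, i.e. `C ≤ f(b)`) always
  binds: `C0 = f(b)` in closed form. The brute-force grid search is kept
  only as a test oracle. Inputs with negative tones are rejected (the
  family is defined for `C ∈ [0, M[`).
- Scalar family `λ ⊗ f`, `λ ∈ (0, lam_max]` (default 5): closure of the
  LIP laws keeps tones in `[0, M[` automatically, so the search is
  unconstrained on the interval. A coarse grid (step 0.01) locates the
  basin; golden-section refines the bracketing ±1-step interval to
  width 1e-3; ties break to the smallest λ (first grid maximum).
  `constraint_active` flags a boundary hit at `lam_max`.

The recovery check exploits the group property `λ⊗(μ⊗f) = (λμ)⊗f`: the
σ-maximal member of a full-range ramp's ⊗-orbit is built (argmax_μ
σ(μ⊗ramp) ≈ 1.644 — a plain ramp is *not* σ-maximal in its own orbit),
darkened by the thickness factor 1/0.28, and the search recovers
λ ≈ 0.280 up to search tolerance. The recovery runs on continuous tones:
8-bit quantization of so dark a fixture saturates tones near `M` and
genuinely shifts the optimum.

## LIP interpolation of slice stacks

The segment `[f,g](λ) = λ⊗f ⊕ (1−λ)⊗g`, λ ∈ [0,1], has exact endpoints
(λ=1 ↦ f) and produces tones between the parents' pixelwise extrema
(both laws are monotone). The stack resampler inserts `k` intermediates
between each consecutive pair; the ladder is oriented so the image
nearest the leading slice `f` carries the largest weight on `f`
(λ = k/(k+1), …, 1/(k+1)), making the densified stack spatially
monotone. Counts follow `n + (n−1)·k` — 12 slices with k=4 give 56 —
and the spacing metadata is divided by `k+1`; physical metadata never
enters the math, and non-cubic results only log a warning.

## Synthetic data

The generators emulate the package's acquisition scenarios and are
deterministic in their seed:

- `ramp_chart` — full-scale linear ramp (tones 0…M−1), the chart used to
  inspect tone profiles and their opposites.
- `low_light` — a well-exposed base darkened in the tone domain by
  `λ⊗f` (λ>1, thicker obstacle ≈ shorter exposure; default λ=2) or
  `f ⊕ C` (uniform filter); the ground-truth parameter is returned for
  recovery tests.
- `colour_scene` — sums of random Gaussian blobs per channel with tones
  confined to [40, 220] by default: smooth, limited-range, realistic
  input for range expansion.
- `slice_stack` — 12 slices, 16×16, in-plane resolution 0.2 vs spacing
  1.0 (the 5× anisotropy typical of tomographic stacks), dark tone range
  [120, 240].

What these fixtures do not emulate: sensor noise, optics (blur, vignetting),
saturation/clipping in the raw data, and natural-image statistics. Passing
tests therefore certify the algebra and the enhancement contracts, not
perceptual quality on real photographs.

## Numerical choices

- Quantization at export: round-half-to-even, silent clipping to
  `[0, M−1]` with the clip count recorded on the result and logged.
- The randomized algebra suites draw tones uniformly from [−240, 240]
  (per-operand transmittance ≥ 1/16) and scalars from [−1, 1]. This is a
  conditioning bound, not an algebraic one: compound tones close to `M`
  have transmittances ~1e-5, and raising those to negative powers
  produces magnitudes ~1e7 where a 1e-9 *absolute* contract exceeds what
  double precision can represent. Within the stated ensemble the
  measured residuals are ≤ ~1.5e-10; outside it the identities still
  hold to relative precision.
- Dichotomy: tol 1e-6 on the interval, cap 200 iterations, bracket cap
  −1000; the λ0 reported is the final interval midpoint.
- Degenerate inputs: constant images raise `DegenerateImageError`
  everywhere an expansion or search is undefined (CLI exit code 3);
  images already spanning ≥ M−1 are still processed (the multiplicative
  map is nonlinear, so a negative λ0 exists regardless).
- Golden-section is seeded from the coarse-grid maximum, so a multimodal
  σ profile resolves to the basin containing the global grid optimum.

## Known limitations

- σ profiles are not proven unimodal; the grid step (0.01) bounds how
  narrow a basin the search can see.
- 16-bit RGB PNG is not writable (backend limitation); TIFF covers it.
- The multiplicative FDRE saturates bright regions of very dark scenes
  by design (it expands bright tones more); no local/adaptive variant is
  provided.
- Enhancement amplifies noise along with signal; denoising is out of
  scope.
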