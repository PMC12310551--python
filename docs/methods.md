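# Methods

## Scope and model

`fieldray` models the restriction of one eye's visual field (VF) by the
anatomy of the head carrying it, under three assumptions:

1. **Pure self-occlusion.** The only optics considered is whether a
   straight ray from the eye centre escapes the head mesh. Eyelashes,
   pupil size, squint, eye movements and spectral effects are out of
   scope; the eye is a point just proud of the socket surface.
2. **Binary scene.** The head is perfectly non-reflective and the
   environment is a constant-radiance source. Under these conditions a
   physically based render from the eye is exactly the binary visibility
   function, so the package computes visibility by deterministic
   watertight ray casting — one primary ray per pixel centre, no
   anti-aliasing (the scene is binary; accuracy is governed by sensor
   resolution alone).
3. **Linear shape space.** Heads come from a blendshape model: generic
   mesh plus morph targets of identical topology, vertices varying
   linearly in the coefficients `c_i` (coefficients are unrestricted in
   the synthesis; random sampling draws them uniformly from (−1, 1)).

## Geometry conventions

- Coordinates are millimetres. The eye pose carries three orthonormal
  axes: `forward` (gaze, θ = 0), `temporal` (horizontally away from the
  nose, φ = 0) and `up` (φ = 90°), with φ counted counter-clockwise as
  seen looking outward along the gaze axis — φ = 0 temporal, 90 superior,
  180 nasal, 270 inferior. `EyePose.from_anchor` builds the frame for a
  right eye (`temporal = up × forward`); pass `right_eye=False` to flip
  the chirality for a left eye.
- The sensor rig is the unique minimal set of five 90°-FOV cube faces
  covering the frontal hemisphere: forward, up, down, temporal, nasal.
  Ray origins are lifted `eps_offset = 1e-4 mm` along `forward` so rays
  do not re-hit the socket surface at their origin.
- Ray/triangle intersection uses the shear + 2D-edge-function watertight
  formulation. Edge and vertex grazes count as hits; a ray crossing the
  shared edge of two triangles evaluates the same edge function in both,
  so it cannot slip through a seam (an earlier three-dot-product
  implementation demonstrably did, on rays aligned with fixture seams).
  The brute-force and BVH (median split, leaf size 4) paths execute the
  identical per-triangle test, so their results are bitwise equal; this
  equality is asserted in the tests rather than assumed.

## Boundary extraction

Boundary pixels are taken from **both** sides of the occlusion edge
(open pixels with an occluded 4-neighbour, and occluded pixels with an
open 4-neighbour), with the neighbourhood resolved across shared cube
faces by continuing the pixel grid one step past each edge and looking
the direction up on the containing face. The two-sided convention makes
the boundary estimate unbiased to first order in the pixel size; a
one-sided convention biases θ low by about half a pixel, which is what a
spherical-cap fixture measures.

Each boundary pixel contributes its (θ, φ); θ > 90° is discarded (the VF
is the frontal hemisphere) and per-bin means give θ(φ) on `n_bins`
equally spaced azimuth bins (36,000 at full scale; 360 in fast runs).
Empty bins are filled by circular linear interpolation between the
nearest non-empty bins; if no boundary pixel exists at all, the field is
declared fully open (θ ≡ 90°). Multiple disjoint boundary crossings at
one azimuth are averaged together — faithful to the per-bin averaging
definition, but blurring for non-star-convex fields.

**Degenerate boundaries.** When the true boundary runs through the
forward pole (e.g. an occluding plane containing the eye), the azimuth of
a near-pole boundary pixel is ill-conditioned and per-bin averaging
misassigns it; θ(φ) is then unreliable. For this reason the package also
integrates the projected solid angle **directly from the occlusion
maps** (`projected_solid_angle_from_maps`): each open pixel with θ ≤ 90°
contributes `cos θ · dA / r³`. On star-convex fields the two routes agree
(cross-checked in the tests); on degenerate ones only the map route is
trustworthy, and it is the one the half-space fixture is verified with.

## Projected solid angle

`Ω = Σ_k (π/n_bins) sin²θ_k` is the exact integral of `cos θ sin θ` over
`θ ∈ [0, θ_k]` per bin. Ω ∈ [0, π] sr; the headline scalar
`100·(π−Ω)/π` is the percent decrease relative to an unobstructed
hemisphere. The cosine weight models aperture foreshortening: light
arriving obliquely to the gaze axis contributes less to corneal/retinal
flux.

## Synthetic head generator

The generator stands in for an external scanned identity space so the
whole pipeline is testable without licensed data. It emulates the
features that matter for the right eye's field: a convex cranium
(icosphere, radius 100 mm) carrying a nose wedge on the nasal side, a
brow ridge above the right eye and a cheek bulge below it, each a radial
cosine-falloff bump (smooth and strictly local, so each morph dents the
boundary in a limited azimuth range, qualitatively like single-parameter
morphs of a scanned face model). Feature ranges default to nose 6–20 mm,
brow 3–12 mm, cheek 2–10 mm: the generic head carries the mid-range
protrusion, the +1 target the high end, so coefficients in [−1, 1] sweep
the stated range. Morph target `i` displaces feature `i mod 3`; beyond
three targets, centres are jittered reproducibly from the spec seed. The
eye anchor sits 1 mm proud of the feature-free socket surface, so the
ray-origin lift logic is exercised and the bare cranium horizon already
restricts the field (the generic synthetic head loses ≈ 3.6% of the
hemispheric projected solid angle at res 128).

What the generator does **not** emulate: anatomical statistics of real
faces (absolute solid-angle numbers are not comparable to scanned-head
values), concavities such as deep sockets, asymmetry, and correlated
multi-feature morphs. Tests passing on it show the pipeline's geometry,
binning and optimization are correct — not that real-head variability is
reproduced; the scanned-model checks exist separately for that and
require the external model.

## Template fit

The loss is `L = 0.75·Σ_φ Σ_j (pred − rendered)² + 0.25·(anchor terms)`,
predictions by the sign-split linear model, **unclipped** inside the
loss: clipping to [0, 90]° would break the quadratic structure, so it is
applied only when predictions are reported. Weights must sum to 1;
0.75/0.25 favours prediction accuracy over staying near the rendered
templates.

Gradient descent is full-batch with the analytic gradient
`2 w_p Aᵀ(AX − Y) + 2 w_a (X − X_rend)`, initialized at the rendered
templates. "Stopped decreasing" is made precise as patience-based early
stopping on the validation loss (first `n_validation` heads of the seeded
sample reserved; default patience 10 epochs, max 10⁵), returning the
best-validation iterate. A non-finite loss raises with advice to lower
the learning rate. The default `lr = 5e-8` matches the stability bound of
the full-scale problem (10,000 heads, 100 parameters, where the Hessian's
largest eigenvalue is of order 10⁷); small test instances use a
proportionally larger rate or converge impractically slowly.

Because bins decouple and every bin shares the design matrix, the exact
minimizer solves `(w_p AᵀA + w_a I) X = w_p AᵀY + w_a X_rend` once for
all bins (`closed_form_templates`); with `w_anchor > 0` the system is
positive definite, and a singular system (possible only with no anchor
and uncovered coefficient signs) is reported, never silently
regularized. The iterative and closed-form routes agree to ~1e-15
relative loss on test instances.

`TemplateBoundaryPredictor` wraps prediction + optimization as a
scikit-learn estimator (`fit(X, y)` on coefficient rows and rendered
boundaries; `optimize` ∈ {'gd', 'exact', None}).

## Numerical choices and problem sizes

- Default full-scale parameters: 1024² sensors, 36,000 bins, 10,000
  random heads — the scale intended for scanned-head models.
- The test suite and `scripts/acceptance.py` run at desk scale: sensor
  resolution 128–512, 360 bins, 30–50 random heads, chosen so the whole
  battery completes in well under a minute after JIT warm-up while
  keeping fixture errors an order of magnitude inside their tolerances
  (cap-fixture Ω errors ≈ 0.02% at res 256 against the closed form
  π sin²θ₀).
- Determinism: all sampling uses named NumPy PCG64 generators seeded from
  the experiment seed; experiment outputs embed seed, resolution and bin
  count. Per-face boundary renders are cached keyed by a content hash of
  mesh + rig + binning.
- Ties in ray casting (exact edge grazes) count as occluded:
  determinism over optimism.

## Known limitations

- θ(φ) is a single-valued function: non-star-convex fields (islands,
  overhangs) are blurred by per-bin averaging; no smoothing or splining
  is applied.
- The linear model cannot capture interactions between parameters (sharp
  boundary corners arising from feature combinations), which is visible
  in the tails of the prediction-error distribution.
- Only symmetric treatment of one (right) eye is provided; a left eye is
  a chirality flip of the pose frame.
- OBJ support is deliberately minimal (v/f records, fan triangulation) —
  sufficient for morphable-model meshes, not a general importer.
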