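# fieldray

Simulation and linear prediction of human **visual-field (VF) boundaries**
from parametric head anatomy.

The directions from which light can reach an eye are limited not just by
optics but by the head that carries it: the nose, brow and cheeks occlude
part of the frontal hemisphere. For light-exposure research (melanopsin-
mediated, "non-visual" effects of light) this matters, because wearable
light loggers measure corneal-plane irradiance and ignore the individual
visual field entirely. `fieldray` quantifies that anatomical restriction:
it synthesises head shapes from a morphable (blendshape) model, ray-casts
binary visibility from the right eye, extracts the VF boundary, integrates
projected solid angles, and fits a linear model that predicts the boundary
directly from shape coefficients.

## The model

**Head synthesis.** A morphable model is a generic mesh `M_g` plus morph
targets `M_i` of identical topology; a new head is

```
M(c) = M_g + Σ_i c_i (M_i − M_g),        c_i ∈ [−1, 1]
```

**Visibility.** Five 90°-FOV, eye-centred square cameras (forward, up,
down, temporal, nasal — the faces of a cube) cover the frontal hemisphere.
For a perfectly non-reflective head in a constant-radiance environment the
rendered radiance image equals the binary visibility function, so one
watertight ray cast per pixel centre reproduces a physically based render
of that scene exactly, without Monte Carlo noise.

**Boundary.** Directions are written in eye polar coordinates: `θ` from
the forward ray, `φ` counter-clockwise from the temporal direction (up at
90°). Pixels on the open/occluded edge contribute `(θ, φ)` pairs; the
360° azimuth range is split into `n_bins` bins (36,000 at full scale) and
`θ` is averaged per bin, giving the boundary function `θ(φ)`. Its
cosine-weighted (projected) solid angle is

```
Ω = Σ_k (π / n_bins) · sin²θ_k   ∈ [0, π] sr,
```

equal to π sr for an unobstructed hemisphere; `100·(π−Ω)/π` is the percent
decrease the field suffers relative to that hemisphere.

**Linear prediction.** With `θ_g` the generic boundary and `θ_{±i}` the
boundaries with coefficient `i` at ±1, a novel head is predicted by

```
θ(c) = θ_g + Σ_i |c_i| · (θ_{sign(c_i), i} − θ_g)
```

(or the symmetric variant using only `θ_{+i}`). The template set is then
refined by full-batch gradient descent on the weighted quadratic loss
`0.75·(prediction error)² + 0.25·(anchor-to-rendered)²` with validation-
based early stopping; because the loss is convex quadratic and azimuth
bins decouple, a closed-form per-bin solve provides an exact oracle for
the iterative fit. The optimizer is also packaged as a scikit-learn
estimator, `TemplateBoundaryPredictor` (`fit`/`predict`/`get_params`).

## Worked example

```python
import numpy as np
import fieldray as fr
from fieldray.experiments import ExperimentConfig, eye_rig, trace_boundary

model = fr.make_synthetic_model(fr.SyntheticHeadSpec(n_ids=3, seed=7))
cfg = ExperimentConfig(res=128, n_bins=360)
rig = eye_rig(model, cfg)

generic = trace_boundary(fr.blend_face(model, np.zeros(3)), rig, cfg.n_bins)
omega = fr.projected_solid_angle(generic)
print(f"omega = {omega:.4f} sr, decrease = {fr.percent_decrease(omega):.2f} %")

big_nose = trace_boundary(fr.blend_face(model, [1.0, 0.0, 0.0]), rig, cfg.n_bins)
print(f"nose at +1: decrease = "
      f"{fr.percent_decrease(fr.projected_solid_angle(big_nose)):.2f} %")
```

prints

```
omega = 3.0300 sr, decrease = 3.55 %
nose at +1: decrease = 5.20 %
```

i.e. the synthetic head's anatomy already costs ~3.6% of the hemispheric
projected solid angle, and lengthening the nose morph to its +1 extreme
deepens the loss to ~5.2%, by denting the boundary on the nasal side only.

The same pipeline is scriptable from a shell:

```bash
fieldray synth-head --out head/
fieldray boundary --manifest head/manifest.yaml --res 256 --bins 360 --out b.csv
fieldray solid-angle b.csv
fieldray templates --manifest head/manifest.yaml --res 128 --bins 360 --out tpl/
fieldray variability --manifest head/manifest.yaml --n-faces 50 --res 128 --bins 360 --seed 1 --out var/
```

## Layout

- `fieldray.mesh`, `fieldray.morphable` — OBJ I/O, blendshape synthesis
- `fieldray.synthetic` — procedural morphable head + analytic occluders
- `fieldray.camera`, `fieldray.raycast` — eye rig, watertight ray casting
- `fieldray.boundary` — θ(φ) extraction, projected solid angle
- `fieldray.templates`, `fieldray.optimize` — linear prediction, template fit
- `fieldray.experiments`, `fieldray.cli` — study drivers and the `fieldray` CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
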