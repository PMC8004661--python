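# Methods

## Model and assumptions

The object is modelled as a spheroid (ellipsoid of revolution) with
semi-axes `A ≥ B`, observed by an orthographic camera: at typical
working distances (~1 m) perspective across a single object is
negligible, and the orthographic silhouette of a spheroid is always an
ellipse with one principal axis equal to one of the spheroid's two
equal axes.  The model type — sphere, oblate (unique axis shortest) or
prolate (unique axis longest) — is supplied by configuration, never
auto-detected.  Segmentation is assumed done: background pixels are
pure black and a pixel is foreground iff any RGB channel is non-zero.

Coordinates: `x` = column rightwards, `y` = row downwards, `z` towards
the camera, right-handed.  A surface point is visible iff `z > 0`.
"Rotating downwards" means rotations with positive `rx` in this frame;
under `R_x(+φ)` the elevation angle of an oblate object's unique axis
decreases by φ, which makes the minor-axis sequence `{b_i}` increase
exactly while θ > 0 — the basis of the sign-disambiguation rule.

Between consecutive views the object undergoes a single 3-D rotation
whose axis lies (to good approximation) in the image plane: rollers
force the dominant component about `x`, shape irregularities add a
small `ry`, and `rz` is negligible and fixed to zero.  Translation is
removed by working in silhouette-centred coordinates per view.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `stride` | 4 | px | subsampling of the moment sums; 16× cheaper, error negligible at fruit scale (see limitations) |
| `factor` | 4 | – | block-average downsample of the matching images |
| `sigma` | 1.25 | reduced px | Gaussian width of the high-pass (`downsampled − blur`); reflect padding, kernel truncated at 4σ |
| `shrink` | 0.85 | – | border-ellipse factor for relevant points; points nearer the limb may rotate out of view within `β_max` |
| `percentile` | 97 | – | nearest-rank threshold on the candidate `|high-pass|` values; strict inequality keeps ~3% (50–100 points at fruit scale) |
| `beta_max` | 35 | deg | upper bound of `rx`, set by the mechanical transport |
| `alpha` | 10 | deg | half-range of `ry` |
| `gamma` | 1 | deg | grid step; refinement operates at γ/2 and below |

## Numerical choices

* **Eigenvector convention.**  The covariance eigenvectors fix only a
  line; `v1` is sign-fixed to `v1x ≥ 0` (tie: `v1y ≥ 0`) and
  `v2 = rot90(v1)`, making the pose matrix reproducible.
* **Elevation clamping.**  `cos θ = √((b²−B²)/(A²−B²))` is evaluated
  with the ratio clamped to [0, 1]; noise routinely pushes measured
  axes slightly outside `[B, A]`.  A clamp that moves the ratio by more
  than 0.05 is logged.
* **Endpoint signing.**  The first/last view's elevation sign uses the
  single available neighbour pair of `{b_i}`; interior extrema choose
  the candidate (±|θ|) closest to the mean of the already-signed
  neighbours, iterating until stable; a perfectly flat sequence carries
  no information and defaults to the positive branch.
* **Prolate sign rule.**  The monotonicity rule is derived for oblate
  objects.  For a prolate object tumbling end-over-end (unique axis
  projecting along the ellipse major direction) the same derivation
  gives the *opposite* monotonicity: writing the unique-axis direction
  as `(0, cos θ, sin θ)` and applying `R_x(+φ)` yields θ → θ + φ,
  whereas the oblate form `(0, sin θ, cos θ)` yields θ → θ − φ.  The
  pipeline therefore flips the direction flag before sign assignment
  for prolate models.
* **Lifting.**  The per-pixel height is the larger root of the surface
  quadratic in `z`; a negative discriminant marks a pixel outside the
  model silhouette.  The quadric scales linearly, so lifting at reduced
  resolution with the scaled geometry equals the full-resolution lift
  divided by the factor — tracking therefore lifts at full resolution
  directly and reports full-resolution positions.
* **Target sampling.**  Rotated points sample the target working image
  at the nearest pixel (no interpolation), keeping the per-node cost at
  one 3×3 × 3×N product plus a gather; at reduced resolution the
  rounding error is far below the texture scale.  Points rotated to
  `z < 0` (hidden) or outside the target image are skipped; a node
  where no point survives is marked invalid in the error map.
* **Tie-breaking.**  The coarse-grid argmin resolves ties
  first-in-row-major (rx, then ry), and the naive reference
  implementation reproduces this exactly — the two paths use the same
  elementary float operations and agree bit for bit.  On the half-step
  5×5 subgrid, exact ε ties are common (sub-pixel displacements round
  to identical target pixels), and among tied minima the node closest
  to the window centre wins so plateaus do not cancel refinement.
* **Refinement.**  The subgrid reuses the 9 coarse nodes it overlaps
  and evaluates only the 16 new half-step nodes.  Two independent 1-D
  parabolas through the minimum and its ±γ/2 neighbours give the final
  vector; vertex offsets are clamped to ±γ/2, a non-convex triple
  leaves the node unchanged, and a minimum on the window boundary skips
  refinement on that axis with a warning.  The reported ε at an
  off-node vector is the fitted parabola value, flagged as
  interpolated.

## The synthetic generator

`spinfit.synthetic` renders exactly the input the pipeline consumes:
orthographic, pre-segmented views of one textured spheroid on a black
background, with ground-truth per-transition rotation vectors.  Its
defaults mirror typical inspection data — object diameters of a few
hundred pixels, 10–16 views, rotations of 10–30° per transition
dominated by `rx`, optional Gaussian "slip" jitter on the rotation
vector and additive per-view noise.  The texture is a seeded sum of 64
random 3-D cosine waves evaluated on the body-frame direction sphere,
band-limited to surface wavelengths of 15–45 px at the equator:
features a few reduced-resolution pixels wide survive the 4× downsample
(white noise would alias away, and a textureless surface is
unmatchable by construction — both failure modes are demonstrable by
turning the contrast knob).  A fixed seed reproduces frames byte for
byte.

What the generator does *not* emulate: shading and specular highlights
(intensity is attached to the surface point, so a rotated point keeps
its brightness exactly), non-spheroidal shape error, stems and
segmentation artefacts, motion blur, and JPEG compression.  Passing
tests on this substrate therefore validate the geometry and the
estimator under the model's own assumptions; they do not bound the
additional error real produce introduces through shape mismatch and
photometric effects.

Experiment sizes used by the validation suite: 50 random ellipses for
the moment fits; five elevations of a 120×70 px oblate spheroid; 100
random lifting instances against a 10⁻⁴-resolution root scan; 10
rendered pairs for the exact reference comparison; 20 sphere/oblate
instances (rx ∈ [10°, 30°], ry ∈ [−5°, 5°]) for rotation recovery; a
15-view constant-speed sequence; and a 21-view full revolution for
closure.  Oblate recovery instances embed the evaluated transition in a
longer sequence whose elevation sweep passes an edge-on view, because
`B = min(b_i)` is only observable there — a bare 2-view oblate sequence
cannot constrain the shape (real systems always pool the full 13–16
view sequence).  Their initial elevations are drawn from [35°, 55°] so
no transition straddles θ = 0, which a 2-view window cannot
disambiguate.

## Known limitations

* **Stride error at small silhouettes.**  The stride-4 moment trick is
  negligible at fruit scale (≤ ~0.4% axis change for semi-axes
  ≥ 125 px) but reaches 1–2.5% for semi-axes near 20 px, where the
  strided lattice is only ~10 cells across; the error is stochastic
  lattice-phase noise, not a correctable bias.
* **Accumulated drift.**  Per-transition errors are a few tenths of a
  degree but are correlated along a sequence (one texture, similar
  poses), so a 20-transition revolution accumulates ~1° of rotation
  error, i.e. ~2–3.5 px of closure error at a 150 px radius — matching
  is limited by texture asymmetry near the limb ring under
  nearest-neighbour sampling.
* **`ry` is the weak axis**: rotations about `y` displace points in
  proportion to their height spread, and oblate pose errors feed it
  directly; expect 2–3× the `rx` error.
* The elevation-sign rule assumes the projected equator stays roughly
  aligned between views (true on roller transport); a near-vertical
  major axis for oblate objects would invalidate the monotonicity
  argument.
* No `rz` search, no perspective model, no multi-object scenes, and no
  defence against textureless surfaces — the estimator needs skin
  texture to match.
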