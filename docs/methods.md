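# Methods

`shapecomplete` builds a statistical shape model (SSM) of the radius from
corresponded surface meshes, augments it with an isotropic Gaussian-process
kernel, and predicts the distal 12% of a bone from its proximal 88%.  This
note records the model, the algorithms, the numerical choices, and what the
synthetic test bed does and does not establish.

## The shape model

Shapes are triangulated surfaces with a shared topology of `n` vertices,
flattened to vectors `x ∈ R^{3n}` (coordinates in mm).  The SSM is the
linear-Gaussian point-distribution model

    x = x̄ + U diag(√λ) c,      c ~ N(0, I_K),

with `x̄` the Procrustes mean, `U` the orthonormal eigenbasis of the sample
covariance (divisor `n_train − 1`, computed by SVD of the centred data
matrix), and eigenvalues `λ_1 ≥ … ≥ λ_K` in mm².  Components with
`λ_k < 10⁻¹² λ_1` are discarded, so `K = n_train − 1` exactly on
generic-position data.  Alignment is **rigid-only** generalized Procrustes
(no scaling step): absolute bone size is clinically meaningful — length
error is one of the evaluated degrees of freedom — so size must stay in
the model.

The model is built twice: correspondence → GPA → PCA against a decimated
starting reference, then all steps repeated with the first-pass mean as the
reference, which removes the arbitrary-reference bias.  Meshes that already
share the current reference topology are corresponded by construction and
enter the second pass unchanged.

## Correspondence

Dense correspondence is established by multiscale nonrigid ICP: each
schedule step builds a low-rank Gaussian-process deformation prior on the
reference (isotropic kernel `scale·exp(−r²/σ²)`, leading eigenfunctions via
Nyström approximation on farthest-point-sampled landmark vertices) and
alternates closest-point assignment with ridge GP regression of the
displacement field.  Defaults: three steps with σ = (100, 60, 30) mm,
scale 10, 50/100/200 basis functions, 20 iterations per step, observation
noise 1 mm; kernel bandwidth strictly decreases so early steps capture
global bending and later steps local distal shape.

Two details matter in practice:

* **Symmetric matching.**  Closest-point assignment from the deformed
  reference alone cannot see longitudinal stretch — every reference vertex
  finds a nearby point on a longer target's shaft and the stretch collapses
  onto the end caps.  Target vertices therefore also pull their nearest
  deformed-reference vertex, and both directions carry a 3×median outlier
  guard with a 1 mm floor (the floor keeps genuinely deformed regions when
  most of the surface already coincides).
* **Anatomical landmarks.**  A near-cylindrical shaft leaves axial position
  and rotation almost unobservable to any surface-distance matcher.  When
  landmark positions are available (the generator provides the radial-head
  centre, ridge midpoint and sigmoid-notch point exactly; clinical use
  would take the same three points picked for the anatomical frame), they
  are pinned in the regression with weight 10.  Rigid pre-alignment is
  capped at 10° of rotation — canonical-frame inputs are already
  rotationally aligned, and larger ICP rotations on a tube are spurious
  axial spins.

## Completion

The completion model adds the isotropic kernel `k(x,x′) =
scale·exp(−‖x−x′‖²/σ²)·I₃` (no factor 2 in the denominator) to the SSM
covariance, evaluated at the reference vertices, low-rank via Nyström with
the combined basis re-orthonormalised.  Prediction is GP posterior
regression: with `Q` the √λ-scaled basis restricted to observed coordinate
rows and `y` the centred observations,

    α = (QᵀQ + noise·I)⁻¹ Qᵀ y,    x̂ = x̄ + Q_full α.

`noise` is used directly as the ridge magnitude (a variance-like quantity),
matching the tuning grid noise ∈ {5, 10, 15, 20}, σ ∈ {50 … 300} mm,
scale ∈ {5, 10, 15}; the hyperparameters' units are not stated more
precisely than this anywhere upstream, and the grid is what defines them
operationally.

Correspondence between a proximal input and the model is iterated
closest-point model fitting, not a single assignment pass: the posterior
solve alternates with re-assignment from the current predicted proximal
surface, annealing the ridge from 50 down to the target value.  Components
of the fitting procedure that proved necessary, and why:

* **Cut-consistency constraint.**  The input is known to be the proximal
  `f = 0.88` of a bone, so the predicted bone's Y-extent must place the
  input rim at fraction `f`; this enters as one weighted row constraining
  the Y coordinate of the currently most distal vertex.  Without it the
  bone's length is weakly identified (stretch slides tangentially along the
  shaft surface).
* **Boundary handling, twice, averaged.**  Most distal information lives in
  the last few millimetres before the cut, where closest-point targets are
  biased by the open rim.  Predicted vertices overhanging the input's cut
  plane and footpoints on boundary faces are excluded; the remaining bias
  has opposite sign under two legitimate treatments of the cut — keeping
  the reference's fixed proximal vertex set versus re-cutting the observed
  set from the current prediction — so both refinements are run and their
  coefficient vectors averaged.
* **Multi-start over distal components.**  Model components whose variance
  concentrates distally (> 40% of their squared mass outside the observed
  rows) are weakly observed and can trap the fit in a wrong basin.  The fit
  is restarted at ±2σ perturbations of the two largest such components and
  the candidate with the smallest combined forward-residual +
  input-coverage distance wins.
* **Pose is frozen during fitting.**  In-fit rigid updates follow the
  tangential sliding of closest-point matching and corrupt the distal
  extrapolation; the pose comes from a capped rigid ICP pre-alignment (or
  identity for canonical inputs) chosen by proximal fit quality, and the
  prediction is returned in the input's original pose.

The hyperparameter grid search completes every validation bone for all 72
triples.  Rigid alignment and correspondence refinement run once per
(σ, scale) pair at the median ridge value; each noise level then gets its
own final posterior solve from the refined correspondence.  The argmin is
by mean point-to-surface error of the full predicted mesh against the
reference, ties broken by smaller noise, then σ, then scale.

## Evaluation metrics

* **Accuracy**: mean one-sided point-to-surface distance (predicted vertex
  → reference surface), in mm; a symmetric variant exists but is not the
  default.
* **Hausdorff**: symmetric maximum of vertex-to-surface distances.
* **Compactness**: cumulative eigenvalue fraction per component count.
* **Generalization**: projection RMSE (root mean squared per-vertex
  residual) of a held-out corresponded shape against models built on the
  first `n` shapes of one seed-shuffled order.
* **Specificity**: model samples (standard-normal coefficients, seeded)
  scored by accuracy against their nearest test shape and the Hausdorff
  distance to it; a `reconstruct` mode projects the test shapes instead,
  since the description of this metric admits both readings.
* **Completion self-consistency** is reported as the mean distal RMS
  surface distance over a 10-case set of model-drawn shapes — the same
  aggregation used for completion accuracy elsewhere (per-case values
  scatter with the draw because strongly distal-weighted draws are
  intrinsically harder to infer from proximal data).

Closest-point queries are exact: a KD-tree stage proposes the
centroid-nearest triangles and a certification bound
(`d(q, tri) ≥ d(q, centroid) − r_tri`) triggers an exhaustive fallback
where needed.  Iterative registration loops use the uncertified stage-1
answer (`exact=False`), which coincides with the exact one near the
surface; all reported metrics use the exact path.

## Clinical 6-DOF decomposition

The predicted and reference distal segments (faces fully within the distal
fraction; 0.12 primary, 0.5 for the half-bone comparison mode) are rigidly
registered — centroid/principal-axis initialisation over the four proper
sign combinations *plus the identity orientation* (near-identical segments
can swap principal-axis order), then ICP refinement as a deterministic
surrogate for interactive alignment.  The transform is re-expressed about
the reference distal segment's **surface** centroid (area-weighted; a
volume centroid is undefined for open cut segments) and decomposed with
intrinsic X→Z→Y Euler angles: radial inclination φx, volar tilt φz, axial
rotation φy, then dorsal shift Δx, lengthening Δy, radial shift Δz from the
origin displacement.  Signs: +X dorsal, +Y distal (too-long prediction ⇒
positive lengthening), +Z toward the sigmoid notch.  The 3D angle
(axis-angle magnitude) and 3D distance are convention-free.  Near-gimbal
configurations (|φz| → 90°) are flagged but still decomposed.

## The synthetic test bed

No suitable public dataset of segmented radii exists, so all quantitative
claims are made against a generator with known ground truth.  The template
is a closed tube-like surface spanning exactly the bone length on +Y, with
a radial-head bulge at the proximal end, an interosseous-crest ridge along
the shaft, and a distal end flared across Z carrying a radial-styloid bump
(+X) and a shallow sigmoid-notch concavity (+Z).  The crest anchors axial
rotation for registration, and the styloid/notch pair breaks the two-fold
symmetry of the distal end — without them, distal rigid registration is
ambiguous up to a 180° flip, an ambiguity the real bone does not have.

Populations are `template + Σ_k c_k·sd_k·mode_k + ε` with standard-normal
latents and i.i.d. Gaussian vertex noise.  Built-in modes (unit RMS
displacement fields, scaled by their sd in mm): lengthening (8),
bowing (3), distal volar tilt (2), distal radial inclination (2), distal
width (2), head radius (1.5).  The distal modes are linearised rotations or
scalings of the part beyond the 88% cut, feathered over 5% of bone length,
so 6-DOF ground truth is available in closed form.  The default vertex
noise of 0.3 mm reflects segmentation error at roughly half a CT slice
thickness.  Default problem sizes — 100 shapes at 2000 vertices with a
1500-vertex decimated reference — keep a complete build-tune-evaluate cycle
in the ten-minute range on a single CPU while leaving the mesh fine enough
that discretisation error (≈ vertex spacing²·curvature ≈ 0.05 mm) sits well
below the effects being measured.

What the generator does **not** emulate: real cortical geometry, the
anatomical correlation between proximal and distal shape (here the distal
modes are independent of the proximal bone by construction, which makes
distal prediction strictly harder than in vivo), segmentation artefacts
beyond white noise, and intensity data.  Passing tests therefore establish
the correctness and internal consistency of the machinery, not clinical
accuracy figures; those require patient CT data.

## Known limitations

* Registration recovers material correspondence only where geometry (or a
  landmark) determines it; on the synthetic shaft the landmark-interpolated
  stretch deviates from the generator's linear stretch by a few mm, which
  deflates the registered model's variance relative to a topology-identical
  build (≈ 40% at the default schedule).  This affects how much variance a
  registered model captures, not the validity of the completion machinery.
* Binary STL is float32 by format definition; at bone-scale coordinates its
  round-trip error is ~10⁻⁵ mm.  PLY/OBJ/ASCII-STL round-trip below
  10⁻⁶ mm.
* Completion error on draws whose distal components exceed ±2σ can reach
  ~1 mm: the proximal surface simply carries little information about
  them.  The posterior covariance (returned with every completion) makes
  this uncertainty explicit.
* The registration schedule and the completion solver's iteration counts
  are configurable; the defaults documented here are the ones used by every
  reported number.
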