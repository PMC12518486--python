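# shapecomplete

Statistical shape modelling and Gaussian-process shape completion for the
distal radius.

When a malunited distal radius needs corrective osteotomy, 3D planning
normally uses the mirrored healthy contralateral bone as the reconstruction
template — but in a meaningful fraction of patients no healthy contralateral
radius exists.  `shapecomplete` implements the alternative: learn a
statistical shape model (SSM) from healthy radii, extend it into a shape
completion model with an isotropic Gaussian-process kernel, and predict the
distal 12% of a bone from its proximal 88%.  It is written for researchers
in computational anatomy and surgical planning who want a fully scripted,
reproducible version of that pipeline, plus the evaluation battery that
goes with it (accuracy, compactness, generalization, specificity, Hausdorff
heatmaps, and the clinical 6-DOF error decomposition).

## The model

Corresponded bone surfaces `x ∈ R^{3n}` (vertices in mm) are aligned by
rigid-only generalized Procrustes analysis and decomposed by PCA:

    x = x̄ + U diag(√λ) c,   c ~ N(0, I_K)

For completion the covariance is augmented with an isotropic Gaussian
kernel `k(x, x′) = scale · exp(−‖x−x′‖² / σ²) · I₃` over the reference
surface, and the missing distal part is inferred by GP posterior
regression from the observed proximal vertices:

    α = (QᵀQ + noise·I)⁻¹ Qᵀ y,    x̂ = x̄ + Q_full α

with `Q` the √λ-scaled basis restricted to the observed coordinates.  The
hyperparameters (noise, σ, scale) are tuned by exhaustive search over the
72-point grid noise ∈ {5,10,15,20} × σ ∈ {50,…,300} × scale ∈ {5,10,15}.
Since clinical CT segmentations are not publicly deposited, the package
ships a synthetic radius generator (known shape modes, landmarks and
correspondence) against which every stage is validated.

## Worked example

```python
import numpy as np
from shapecomplete import (KernelParams, ShapeCompletionModel, accuracy,
                           default_modes, generate_population, make_template)
from shapecomplete.completion import _proximal_submesh

# a synthetic population standing in for segmented healthy radii
template, landmarks, lm_idx = make_template(n_vertices=2000)
population = generate_population(template, default_modes(template),
                                 n_shapes=80, noise_sd_mm=0.3, seed=1,
                                 landmark_indices=lm_idx)

model = ShapeCompletionModel.from_population(population)
results = model.fit(KernelParams(noise=20, sigma=100, scale=5), seed=1)
print(results.summary())

# predict a full bone from its proximal 88%
bone = results.sample(seed=7)
proximal, _ = _proximal_submesh(bone, 0.88)
predicted = results.complete(proximal)
print(f"accuracy: {accuracy(predicted.mesh, bone):.3f} mm")
print(f"6-DOF:    {results.clinical_error(predicted.mesh, bone).as_dict()}")
```

prints (numbers from this exact script):

```
Shape completion model
==========================================================
Training shapes:            80
Model vertices:             1982
Retained components:        79
Components for 95% var:     6
Kernel (noise, sigma, scale):(20, 100, 5)
----------------------------------------------------------
  PC   eigenvalue (mm^2)   cum. variance
   1          26353.7162          50.77%
   2           8211.5399          66.58%
   3           6461.2901          79.03%
   4           5234.9098          89.11%
   5           2964.6713          94.83%
   6           2191.5039          99.05%
   7              8.2883          99.06%
   8              8.2199          99.08%
   9              8.1651          99.09%
  10              8.0721          99.11%
 ...  (69 more components)
==========================================================

accuracy: 0.176 mm
6-DOF:    {'phi_x_deg': -1.70, 'phi_z_deg': -2.19, 'phi_y_deg': 4.24,
           'delta_x_mm': 0.67, 'delta_y_mm': 0.09, 'delta_z_mm': -0.09,
           'angle_3d_deg': 5.04, 'dist_3d_mm': 0.69, 'gimbal_degenerate': False}
```

The summary shows the six generative modes carrying ~99% of the variance
(components 7–79 are segmentation noise at ~8 mm² each), and the
completion reconstructs a model-drawn bone to 0.18 mm mean surface
distance.  The 6-DOF table shows the residual orientation error of the
predicted distal articular segment — a few degrees, dominated by the
axial rotation that the proximal shaft constrains only weakly.

The same pipeline is available from the shell:

```bash
shapecomplete synth --n-shapes 100 --seed 1 --out-dir data/
shapecomplete run-all --config docs/example-config.yaml
```

with subcommands `synth / align / correspond / build / grid-search /
complete / evaluate / clinical / run-all` (exit codes: 0 ok, 2 validation
error, 1 compute error).

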