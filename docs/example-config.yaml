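# Full-pipeline configuration for `shapecomplete run-all --config <file>`.
# Every value shown is the default; only `seed` is mandatory.
seed: 1
out_dir: out
# data_dir: path/to/meshes     # PLY/STL/OBJ in the canonical frame
#                              # (optional landmarks.csv: shape,name,x,y,z);
#                              # omit to generate the synthetic population:
synth:
  n_shapes: 100
  n_vertices: 2000
  noise_sd_mm: 0.3
split: [8, 1, 1]
fraction: 0.88                 # proximal fraction observed by completion
clinical_fraction: 0.12        # distal fraction registered for 6-DOF errors
reference_vertices: 1500       # decimated reference carrying model topology
schedule:                      # nonrigid registration steps
  sigma: [100.0, 60.0, 30.0]
  scale: [10.0, 10.0, 10.0]
  n_basis: [50, 100, 200]
  n_iter: [20, 20, 20]
  noise: [1.0, 1.0, 1.0]
grid:                          # completion hyperparameter search
  noise: [5, 10, 15, 20]
  sigma: [50, 100, 150, 200, 250, 300]
  scale: [5, 10, 15]
n_basis: 200                   # kernel eigenpairs added to the SSM
n_specificity_samples: 10
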