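# rp2gauge

Gauge-equivariant convolutional layers for diffusion MRI on the real
projective plane, with a residual network that upsamples the angular
resolution of a six-direction single-shell acquisition.

## The problem

A single-shell diffusion MRI (dMRI) signal is a function of the gradient
direction g on the unit sphere, and it is antipodally symmetric: the tensor
model predicts

    S_k = S0 · exp(−b gₖᵀ D gₖ),

so S(g) = S(−g) and the true domain is the set of unoriented lines through
the origin — the real projective plane ℝP², a non-orientable manifold.
Standard CNNs assume a flat, orientable grid and cannot be applied directly.

`rp2gauge` models ℝP² as the top half of an icosahedron: ten triangular
faces whose boundary seam is glued to itself by the antipodal map.  A
hexagonal grid is obtained by subdividing each face `r` times; five square
charts cover the grid and are stored side by side in a `(2^r+2) × 5(2^r+2)`
rectangle (6 × 30 at the default r = 2).  Where charts meet, their hexagonal
frames differ by an element of the dihedral group D6 — six rotations and,
because the manifold is non-orientable, six reflections.  Convolutions become
exactly equivariant to these frame changes by

* expanding each 7-weight hexagonal filter into its 12 rotated/reflected
  copies (the lifting layer), and each 7 × 12-weight filter of deeper layers
  into a 12 × 12 block structure (regular group convolution), satisfying the
  kernel constraint `K(g⁻¹v) = ρ(g⁻¹) K(v) ρ(g)`;
* padding chart borders from the neighbouring chart or the antipodal partner
  while permuting the 12-slot orientation axis by the gauge transition
  (left strip ← R·θᵢ, bottom/right ← S_{θ₂}·θᵢ).

On top of the layers the package provides the q-space projection (inverse
distance weighting on folded angles), a log-linear diffusion tensor fitter
with FA/V1 metrics, a synthetic crossing-bundle phantom generator, and two
residual denoising architectures (a plain 3D-conv baseline and the 3D-conv →
gauge-equivariant model), trained to predict the fully-sampled tensor-model
signal from six directions.  All layers and the training loop run on numpy
via a small built-in reverse-mode autodiff engine.

## Worked example

```python
import numpy as np
from rp2gauge import (build_atlas, make_phantom, PhantomConfig, ModelConfig,
                      TrainConfig, make_training_pairs, train, evaluate)
from rp2gauge.pipeline import GaugeModel

atlas = build_atlas(refinement=2)
print(atlas.flat_layout, atlas.n_vertices, atlas.n_uncovered_corners)
# (6, 30) 81 11   — five 5x5 charts padded to 6x6, stacked to 6x30;
#                   81 grid points, 11 cone-point corners in no chart

phantom = make_phantom(PhantomConfig(shape=(16, 16, 16), snr=30.0), seed=7)
cfg = ModelConfig(channels_per_direction=2, gauge_layers=3,
                  final_zero_init=True, seed=0)
data = make_training_pairs(phantom, cfg, atlas=atlas)
model = GaugeModel(cfg, atlas)
train(model, data, TrainConfig(learning_rate=1e-3, epochs=250, steps=250,
                               voxel_subsample=512, seed=0))
report = evaluate(model, phantom, data)
print(report.mad_fa_model, report.mad_fa_baseline)
# 0.0923 0.0949  — masked mean absolute FA error of the trained model vs.
#                  the plain six-direction tensor fit: projecting onto the
#                  icosahedral grid and applying the learned residual
#                  correction beats fitting the six noisy directions directly
```

The same workflow is available from the shell:

```bash
rp2gauge make-grid -r 2 -o atlas.h5
rp2gauge simulate -c phantom.yaml --seed 7 -o data/
rp2gauge train --arch gauge -c config.yaml --data data/ -o model.h5
rp2gauge predict --model model.h5 --data data/ -o pred.h5
rp2gauge evaluate --model model.h5 --data data/ --report metrics.json
```

## Layout

```
src/rp2gauge/
  d6.py          exact D6 algebra and orientation-slot permutations
  atlas.py       half-icosahedron grid, charts, gauge transitions, padding tables
  padding.py     scalar/regular feature maps and gauge-aware padding
  gauge_conv.py  kernel expansion, lifting/regular convolutions, pooling
  qspace.py      gradient schemes, folded angles, IDW projection
  dti.py         tensor signal model, fitting, FA/V1 metrics, phantoms
  autodiff.py    minimal reverse-mode autodiff on numpy arrays
  nn.py          trainable layers, Adam, plateau scheduler
  pipeline.py    residual architectures, training loop, evaluation
  cli.py         command-line interface
```
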