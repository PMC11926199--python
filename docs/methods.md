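# Methods

## Domain model

The single-shell dMRI signal at a voxel is treated as a function on ℝP²,
realized as the upper half of an icosahedron (the five pole faces and the
five adjacent middle-band faces) with the boundary seam glued antipodally:
the lower-ring corner l_k coincides with the upper-ring corner u_{k+3} after
negation.  Refinement r subdivides every face r times and projects the new
vertices to the unit sphere, giving 5·4^r + 1 distinct grid points.  Each
antipodal class is keyed by the lexicographically larger of ±(rounded
coordinates); the stored representative is the upper-hemisphere point, with
points on the equator resolved by the first-nonzero-coordinate-positive rule.

Chart k is the rhombus pole–u_k–l_k–u_{k+1} carrying a (2^r+1)² pixel grid:
rows run from the pole towards u_k, columns towards u_{k+1}; the diagonal
a+b = 2^r is the shared mesh edge u_k–u_{k+1}.  On the underlying triangular
mesh each pixel's six neighbours are the steps
{(0,±1), (±1,0), (1,−1), (−1,1)}; embedded in a square 3×3 stencil the two
remaining corners (−1,−1) and (1,1) are masked to zero.  The 11 original
icosahedron corners are cone points (five mesh neighbours instead of six):
they belong to no chart, carry no value, and are fixed at zero everywhere —
zero is invariant under every gauge action, so masking preserves
equivariance.  When a corner value is wanted for display it can be copied
from the nearest interior pixel, and corners are excluded from all losses
and metrics.

## Gauge transitions and padding

Gauge transitions between overlapping charts are *derived*, not hand-coded:
at a shared grid point the six neighbour vertices are matched between the two
charts' frames, and the unique D6 element relating the two direction
labelings is the transition.  The derivation reproduces the three expected
special cases exactly — left strip ← R (60° counter-clockwise), top row ←
R⁻¹, bottom strip and right column ← S_{θ₂} (the reflection that swaps the
chart axes, picked up when crossing the antipodal seam) — and passes the
pairwise cocycle condition g_ij g_ji = 1 on every overlap.  (At refinement 2
no non-corner point lies in three charts, so no non-trivial triple cocycle
exists.)

Padding is a precomputed gather: every duplicated or strip pixel copies from
the unique "owner" position of its grid point — the position whose full hex
neighbourhood is valid under convolution — permuting the 12-slot orientation
axis by the transition (value[h] ← owner[g·h]).  The gather is exact,
idempotent, differentiable (its adjoint is a scatter-add), and is re-applied
after every convolution, which refreshes the top row and right column of
each chart as well as the strips.

## Equivariant layers

With act_g the action of g on ring directions, the layers are the discrete
group correlations

    lifting:  y(x, g) = Σ_c Σ_v I_c(x + g·v) Ψ_c(v)              (7 weights)
    regular:  y(x, g) = Σ_c Σ_h Σ_v ζ_c(x + g·v, h) Ψ_c(v, g⁻¹h) (7×12 weights)

whose expanded kernels satisfy K(g⁻¹v) = ρ(g⁻¹)K(v)ρ(g) for the regular
permutation representation ρ, verified numerically to 1e-12.  Bias is per
output channel, shared across orientation slots (a slot-dependent bias would
break equivariance); the nonlinearity is pointwise ReLU applied after the
bias.  Group batch norm computes per-channel statistics jointly over batch,
orientation and space, which commutes with orientation permutations;
orientation pooling defaults to the mean (linear, hence compatible with the
residual structure; max is available for inference-side use).  Global
five-fold rotation of the icosahedron about the pole is a cyclic chart
relabeling, and a four-layer block commutes with it to float32 precision —
the padding tables are chart-periodic because every owner position is forced
(left chart columns own the pole-edge points, bottom rows own the seam
points), with no arbitrary tie-break.

Vectorized layers contract shifted views of the padded array with the
expanded weight copies via BLAS; unit tests compare them against independent
brute-force loops over pixels, the 12 group elements and the 7 stencil
offsets (agreement ≤ 1e-10).

## q-space projection

Per-direction values are interpolated to the grid vertices with inverse
distance weighting on the folded angular distance arccos|v·g| with power 2
over *all* input directions; a vertex closer than 1e-9 rad to an input
direction takes that sample exactly.  Folding makes the projection invariant
under flipping the sign of any gradient direction, which is equivalent to
averaging antipodal samples.  With only six inputs a nearest-neighbour
cutoff would make the interpolant discontinuous in the directions; using all
directions keeps it continuous.  The exponent and the exactness guard are
the only free choices and are exposed as parameters.

## Tensor model and metrics

Tensors are fitted by ordinary least squares on ln(S/S0) with the standard
six-column quadratic-form design matrix and known S0 (S0 is held fixed
throughout, matching the residual architectures, which never upsample it).
A rank-deficient design raises; nonpositive signal values are clamped with a
warning.  FA uses the standard normalized eigenvalue-dispersion formula; V1
is the leading eigenvector with the first-nonzero-component-positive sign
convention, and angular errors always fold the sign:
Δθ = arccos|v₁·v₂| in degrees.  Evaluation restricts Δθ to voxels with
ground-truth FA > 0.2 *and* Westin linear coefficient (λ₁−λ₂)/λ₁ > 0.1: for
isotropic or planar tensors (e.g. a balanced fibre crossing) the leading
eigenvector is degenerate and its direction carries no information.

## Synthetic phantom

The generator emulates a single-shell b = 1000 s/mm² acquisition on a 16³
patch: 90 unit directions whose first six are the icosahedral six-direction
DTI scheme (an optimal six-direction set, mimicking the incremental ordering
of real protocols) followed by a golden-ratio hemisphere spiral; two
orthogonal straight bundles with eigenvalues (1.7, 0.3, 0.3) µm²/ms crossing
at the patch centre (crossing voxels average the two compartments, giving a
planar tensor with reduced FA); an isotropic background at 0.8 µm²/ms; a
CSF-like sphere at 3.0 µm²/ms excluded from the evaluation mask; synthetic
T1/T2 contrasts derived from the tissue labels; and Rician noise (Gaussian
quadratures, magnitude signal) at SNR 30 relative to S0 = 1000.  The same
seed yields bit-identical volumes.  The phantom exercises high-FA, low-FA,
crossing and CSF regimes, but it does not emulate real anatomy, spatially
varying S0, susceptibility distortion, motion, or spatially correlated
noise — passing tests demonstrate correctness of the machinery and the
denoising direction of the method, not clinical performance.

## Architectures and training

Both networks are residual.  The baseline stacks 3×3×3 convolutions
(246 filters, seven layers by default) over the nine input channels (T1,
T2, S0, six direction volumes, each z-scored over the training set) and adds
the six input attenuation volumes to its six output channels.  The gauge
model runs three 3D-conv layers of 6·C channels, splits them into six
direction groups of C channels (direction-major grouping: direction d owns
channels [dC, (d+1)C)), projects each channel's six values per voxel onto
the grid vertices with the per-subject IDW matrix, moves the 16³ voxels to
the batch axis, applies a lifting layer and regular layers with group batch
norm and ReLU, collapses the orientation axis by mean pooling, and adds the
projected input X_flat.  The final gauge layer maps to one channel (the
reference layer counts leave the collapse to a single flat map unstated;
folding it into the last layer keeps the block depth as configured).  The
3D-conv trunk uses an identity-style initialization (each direction group
passes its direction's channel through the kernel centre on top of a
down-scaled random init) so the projection carries real signal from the
first step; with `final_zero_init` the last layer starts at zero and the
untrained network is exactly the residual identity.

Labels: the tensor model is fitted to all 90 (noisy) directions and
evaluated at the grid vertices (Y_flat, in attenuation units S/S0); the
training target is Y_flat − X_flat for the gauge model and the fitted-model
signal along the six input directions for the baseline.  Optimization is
Adam with MSE loss, batch size one patch, learning rate halved on plateaus.
Training may subsample a random set of voxels per step (plain stochastic
subsampling of the per-voxel loss), which bounds memory and time on a single
CPU.  Divergence (non-finite loss) aborts with a diagnostic; fixed seeds
give bit-identical loss histories.

### Study sizes

The desk-scale studies in the tests use a scaled-down gauge model
(C = 2 channels per direction, three gauge layers) on a single 16³ phantom
patch, 512-voxel subsampling, and learning rate 1e-3: a 50-step smoke run
on a noiseless phantom (default initialization; training MSE falls by well
over half) and a 250-step denoising run on a Rician-noise phantom
(`final_zero_init=True`, so training starts from the identity and descends
from there).  In the denoising run the trained model's masked FA error is
below that of fitting the six noisy directions directly; the untrained
identity projection is already competitive because interpolating six
directions onto 75 vertices smooths the noise, and training improves on it.
Inference uses the batch-norm running statistics accumulated during
training.

## Known limitations

* Chart-level parallelism and kernel-expansion caching are simple; the
  gauge layers are an order of magnitude more expensive than plain
  convolutions of the same width, as expected from the 12- and 144-fold
  filter copies.
* Equator grid points are assigned to antipodal representatives by a fixed
  half-plane rule; any consistent rule works, but serialized atlases are
  only interchangeable between builds using the same rule.
* The refinement level is parameterized (default 2, matching 5×5 charts);
  the cone-point masking cost grows relative to the number of grid points
  as refinement decreases, so r = 1 is usable but noticeably lossier.
* Only single-shell acquisitions are projected; multi-shell data must be
  projected shell by shell.
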