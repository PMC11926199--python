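"""Residual denoising architectures, training loop and evaluation.

Two patch-based residual networks predict the fully-sampled tensor-model
signal from a six-direction acquisition plus structural contrasts:

* **base** — a stack of plain 3D convolutions whose output (six direction
  volumes) is added to the six input direction volumes.
* **gauge** — three 3D convolution layers producing ``6 x C`` channels
  (``C`` feature channels per input gradient direction), projected per voxel
  onto the icosahedral grid with inverse-distance weighting, followed by a
  block of gauge-equivariant layers (one lifting + regular convolutions with
  group batch norm and ReLU, orientation pooling at the end) whose scalar
  output is added to the projected input ``X_flat``.

Training targets follow the residual construction: the tensor model is fitted
to the fully-sampled signal and evaluated on the grid vertices (``Y_flat``),
the label being ``Y_flat - X_flat`` (for the base model, the model signal
along the six input directions).  Signals enter the projection path in
attenuation units (S/S0); the convolution trunk additionally receives
z-scored inputs (zero mean, unit variance per channel over the training set).

Voxels are moved to the batch axis for the gauge block; training may sample a
random voxel subset per step, which is ordinary stochastic gradient
subsampling of the per-voxel loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .atlas import AtlasGrid, build_atlas
from .autodiff import Tensor, einsum2, tensor
from .dti import fit_tensor, mad_metric, metrics_of, simulate_signal
from .padding import scalar_from_vertex_values
from .qspace import GradientScheme, interpolation_weights

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingSample",
    "TrainingSet",
    "GaugeModel",
    "BaseModel",
    "build_model",
    "make_training_pairs",
    "train",
    "evaluate",
    "EvalReport",
]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults are the full-size networks (246-filter base stack; 6 x 64
    channel trunk with a 64-channel gauge block); small studies override the
    widths.
    """

    architecture: str = "gauge"            # "gauge" | "base"
    patch_size: int = 16
    refinement: int = 2
    conv3d_layers: int = 3
    channels_per_direction: int = 64       # gauge trunk: 6*C channels
    gauge_layers: int = 4                  # lifting + (gauge_layers-1) regular
    base_layers: int = 7
    base_channels: int = 246
    pooling: str = "mean"
    n_input_directions: int = 6
    n_structural: int = 3                  # T1, T2, S0 input channels
    final_zero_init: bool = False          # exact residual identity at init
    seed: int = 0

    def validate(self) -> None:
        if self.architecture not in ("gauge", "base"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.gauge_layers < 2:
            raise ValueError("gauge block needs a lifting and a final layer")
        if self.base_layers < 2 or self.conv3d_layers < 1:
            raise ValueError("invalid layer counts")


@dataclass
class TrainConfig:
    """Optimization settings (Adam, MSE loss, plateau-halved learning rate)."""

    learning_rate: float = 1e-4
    plateau_factor: float = 0.5
    plateau_patience: int = 2
    epochs: int = 20
    batch_size: int = 1
    steps: int | None = None               # optional cap on total steps
    voxel_subsample: int | None = None     # gauge: voxels per step
    seed: int = 0


@dataclass
class TrainingSample:
    """One 16^3 patch with its projection operator and labels."""

    inputs: np.ndarray          # [9, D, H, W] z-scored network inputs
    attenuation_in: np.ndarray  # [n_in, D, H, W] raw S_i / S0
    widw: np.ndarray            # [n_signal_vertices, n_in] IDW matrix
    x_flat: np.ndarray          # [n_vox, Hf, Wf]
    target_flat: np.ndarray     # [n_vox, Hf, Wf]  (Y_flat - X_flat)
    target_dirs: np.ndarray     # [n_in, D, H, W] model signal at input dirs


@dataclass
class TrainingSet:
    samples: list[TrainingSample]
    atlas: AtlasGrid
    norm_mean: np.ndarray
    norm_std: np.ndarray
    loss_weight: np.ndarray     # [Hf, Wf] live-pixel mask


# ---------------------------------------------------------------------------
# models

class GaugeModel:
    """3D-conv trunk + gauge-equivariant block with residual output."""

    def __init__(self, cfg: ModelConfig, atlas: AtlasGrid | None = None):
        cfg.validate()
        self.cfg = cfg
        self.atlas = atlas if atlas is not None else build_atlas(cfg.refinement)
        rng = np.random.default_rng(cfg.seed)
        nd, c = cfg.n_input_directions, cfg.channels_per_direction
        cin = cfg.n_structural + cfg.n_input_directions
        widths = [cin] + [nd * c] * cfg.conv3d_layers
        # identity-style init: direction group d carries the S_d channel from
        # the first step, so the projection sees real signal immediately
        first = np.repeat(cfg.n_structural + np.arange(nd), c)
        ident = np.arange(nd * c)
        self.trunk = [nn.Conv3d(widths[i], widths[i + 1], rng,
                                passthrough=(first if i == 0 else ident))
                      for i in range(cfg.conv3d_layers)]
        self.lift = nn.GaugeLift(self.atlas, c, c, rng, activation="identity")
        self.bns = [nn.GroupBatchNorm(c)]
        self.regs = []
        for i in range(cfg.gauge_layers - 2):
            self.regs.append(nn.GaugeRegular(self.atlas, c, c, rng,
                                             activation="identity"))
            self.bns.append(nn.GroupBatchNorm(c))
        # final layer collapses to one channel; ``final_zero_init`` makes the
        # untrained network the exact residual identity
        self.final = nn.GaugeRegular(self.atlas, c, 1, rng,
                                     activation="identity",
                                     zero_init=cfg.final_zero_init)

    def params(self) -> list[Tensor]:
        ps = []
        for layer in [*self.trunk, self.lift, *self.regs, self.final, *self.bns]:
            ps.extend(layer.params())
        return ps

    def forward(self, sample: TrainingSample, voxel_idx: np.ndarray | None = None,
                train: bool = True) -> Tensor:
        """Predict ``Y_flat`` as ``[n_sel_vox, Hf, Wf]`` (batch of one patch)."""
        from .autodiff import relu

        cfg = self.cfg
        nd, c = cfg.n_input_directions, cfg.channels_per_direction
        x = tensor(sample.inputs[None])                  # [1, 9, D, H, W]
        for layer in self.trunk:
            x = layer(x)
        D, Hv, Wv = sample.inputs.shape[1:]
        nvox = D * Hv * Wv
        # direction-major channel grouping: direction d owns channels
        # [d*c, (d+1)*c)
        feat = x.reshape(nd, c, nvox)                    # batch of one
        verts = einsum2("dcv,sd->cvs", feat, sample.widw)
        flatmaps = nn.vertex_scatter_op(self.atlas, verts)  # [c, nvox, Hf, Wf]
        z = flatmaps.transpose((1, 0, 2, 3))             # [nvox, c, Hf, Wf]
        x_flat = sample.x_flat
        if voxel_idx is not None:
            z = z.transpose((1, 2, 3, 0))
            from .autodiff import take_last
            z = take_last(z, voxel_idx).transpose((3, 0, 1, 2))
            x_flat = x_flat[voxel_idx]
        z = self.lift(z)
        z = relu(self.bns[0](z, train=train))
        for reg, bn in zip(self.regs, self.bns[1:]):
            z = relu(bn(reg(z), train=train))
        z = self.final(z)
        res = nn.orientation_pool_op(z, self.cfg.pooling)  # [nvox, 1, Hf, Wf]
        res = res.reshape(res.shape[0], *res.shape[2:])
        return res + tensor(x_flat)


class BaseModel:
    """Plain 3D-convolution residual stack over the six input directions."""

    def __init__(self, cfg: ModelConfig, atlas: AtlasGrid | None = None):
        cfg.validate()
        self.cfg = cfg
        self.atlas = atlas   # unused; kept for a uniform interface
        rng = np.random.default_rng(cfg.seed)
        cin = cfg.n_structural + cfg.n_input_directions
        widths = [cin] + [cfg.base_channels] * (cfg.base_layers - 1)
        self.layers = [nn.Conv3d(widths[i], widths[i + 1], rng)
                       for i in range(cfg.base_layers - 1)]
        self.layers.append(nn.Conv3d(widths[-1], cfg.n_input_directions, rng,
                                     activation="identity", zero_init=True))

    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, sample: TrainingSample, voxel_idx=None,
                train: bool = True) -> Tensor:
        x = tensor(sample.inputs[None])
        for layer in self.layers:
            x = layer(x)
        return x.reshape(x.shape[1:]) + tensor(sample.attenuation_in)


def build_model(cfg: ModelConfig, atlas: AtlasGrid | None = None):
    """Instantiate the configured architecture."""
    cfg.validate()
    if cfg.architecture == "gauge":
        return GaugeModel(cfg, atlas)
    return BaseModel(cfg, atlas)


# ---------------------------------------------------------------------------
# data assembly

def make_training_pairs(phantom, cfg: ModelConfig,
                        atlas: AtlasGrid | None = None,
                        n_in: int | None = None) -> TrainingSet:
    """Build normalized training samples and residual labels from a phantom.

    ``X_flat`` projects the first ``n_in`` attenuations onto the grid;
    ``Y_flat`` evaluates the tensor fitted to *all* directions at the grid
    vertices.  The base-model label is the fitted-model signal along the
    input directions themselves.
    """
    cfg.validate()
    n_in = n_in or cfg.n_input_directions
    if len(phantom.scheme) < n_in:
        raise ValueError(
            f"phantom has {len(phantom.scheme)} directions, need {n_in}")
    atlas = atlas if atlas is not None else build_atlas(cfg.refinement)

    scheme_in = phantom.scheme.subset(n_in)
    shape = phantom.signal.shape[:3]
    nvox = int(np.prod(shape))

    att = phantom.signal / phantom.s0
    att_in = np.moveaxis(att[..., :n_in], -1, 0)          # [n_in, D, H, W]
    s0_vol = np.full(shape, 1.0)

    # fully-sampled tensor fit -> label signal
    tensors = fit_tensor(phantom.signal, phantom.scheme, phantom.s0)
    verts = atlas.vertices[atlas.signal_vertex_ids]
    bval = float(phantom.scheme.bvalues[0])
    vert_scheme = GradientScheme(verts, np.full(len(verts), bval))
    y_vert = simulate_signal(tensors, vert_scheme, 1.0)   # attenuation
    y_flat = scalar_from_vertex_values(atlas, y_vert.reshape(nvox, -1)).values

    widw = interpolation_weights(atlas, scheme_in)
    x_vert = att[..., :n_in].reshape(nvox, n_in) @ widw.T
    x_flat = scalar_from_vertex_values(atlas, x_vert).values

    target_dirs = np.moveaxis(simulate_signal(tensors, scheme_in, 1.0), -1, 0)

    channels = np.stack([phantom.t1, phantom.t2, s0_vol, *att_in])
    mean = channels.reshape(channels.shape[0], -1).mean(axis=1)
    std = channels.reshape(channels.shape[0], -1).std(axis=1)
    std = np.where(std < 1e-12, 1.0, std)
    inputs = (channels - mean[:, None, None, None]) / std[:, None, None, None]

    f32 = np.float32
    sample = TrainingSample(
        inputs=inputs.astype(f32), attenuation_in=att_in.astype(f32),
        widw=widw.astype(f32), x_flat=x_flat.astype(f32),
        target_flat=(y_flat - x_flat).astype(f32),
        target_dirs=target_dirs.astype(f32))
    live = (~atlas.zero_mask).reshape(atlas.flat_layout).astype(float)
    return TrainingSet(samples=[sample], atlas=atlas,
                       norm_mean=mean, norm_std=std, loss_weight=live)


# ---------------------------------------------------------------------------
# training and evaluation

def train(model, data: TrainingSet, cfg: TrainConfig):
    """Optimize the model with Adam / MSE; returns the loss history.

    The learning rate is halved when the epoch loss plateaus.  Diverging
    training (NaN loss) aborts with a diagnostic.
    """
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                 patience=cfg.plateau_patience)
    rng = np.random.default_rng(cfg.seed)
    history: list[float] = []
    total_steps = 0
    is_gauge = isinstance(model, GaugeModel)
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for sample in data.samples:
            if cfg.steps is not None and total_steps >= cfg.steps:
                break
            vox_idx = None
            target = sample.target_flat + sample.x_flat if is_gauge \
                else sample.target_dirs
            weight = None
            if is_gauge:
                nvox = sample.x_flat.shape[0]
                if cfg.voxel_subsample and cfg.voxel_subsample < nvox:
                    vox_idx = rng.choice(nvox, cfg.voxel_subsample,
                                         replace=False)
                    target = target[vox_idx]
                weight = np.broadcast_to(data.loss_weight, target.shape)
            opt.zero_grad()
            pred = model.forward(sample, voxel_idx=vox_idx, train=True)
            loss = nn.mse_loss(pred, target, weight)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at step {total_steps}: loss={value}")
            loss.backward()
            opt.step()
            history.append(value)
            epoch_losses.append(value)
            total_steps += 1
        if not epoch_losses:
            break
        sched.step(float(np.mean(epoch_losses)))
    return history


def save_model(model, path) -> None:
    """Write a self-describing checkpoint (architecture config, atlas
    refinement, parameters, batch-norm running statistics)."""
    import h5py

    with h5py.File(path, "w") as f:
        for k, v in vars(model.cfg).items():
            f.attrs[k] = v
        for i, p in enumerate(model.params()):
            f.create_dataset(f"param_{i}", data=p.data)
        if isinstance(model, GaugeModel):
            for i, bn in enumerate(model.bns):
                f.create_dataset(f"bn_{i}_mean", data=bn.running_mean)
                f.create_dataset(f"bn_{i}_var", data=bn.running_var)


def load_model(path, atlas: AtlasGrid | None = None):
    """Rebuild a model from a checkpoint written by :func:`save_model`."""
    import h5py

    with h5py.File(path, "r") as f:
        fields = {k: f.attrs[k] for k in f.attrs}
        for k, v in list(fields.items()):
            if isinstance(v, np.generic):
                fields[k] = v.item()
        fields["architecture"] = str(fields["architecture"])
        fields["pooling"] = str(fields["pooling"])
        cfg = ModelConfig(**fields)
        model = build_model(cfg, atlas)
        for i, p in enumerate(model.params()):
            data = f[f"param_{i}"][...]
            if data.shape != p.data.shape:
                raise ValueError("checkpoint incompatible with architecture")
            p.data = data.astype(p.data.dtype)
        if isinstance(model, GaugeModel):
            for i, bn in enumerate(model.bns):
                bn.running_mean = f[f"bn_{i}_mean"][...]
                bn.running_var = f[f"bn_{i}_var"][...]
    return model


@dataclass
class EvalReport:
    """Masked mean-absolute-difference metrics against the ground truth."""

    mad_fa_model: float
    mad_theta_model: float
    mad_fa_baseline: float
    mad_theta_baseline: float
    n_voxels: int


def _metrics_from_signal(signal, scheme, s0):
    return metrics_of(fit_tensor(signal, scheme, s0))


def evaluate(model, phantom, data: TrainingSet,
             mask: np.ndarray | None = None,
             prediction: np.ndarray | None = None,
             fa_threshold: float = 0.2) -> EvalReport:
    """Reconstruct a dense single-shell volume from the model output, fit
    tensors, and report MAD of FA and of the V1 angle on the mask.

    The ground truth is the tensor fit of the fully-sampled signal (the same
    construction used for the training labels); the no-network baseline fits
    the raw six-direction signal directly.  The angular metric is restricted
    to voxels whose ground-truth FA exceeds ``fa_threshold`` and whose
    Westin linear coefficient (lambda1 - lambda2) / lambda1 exceeds 0.1: for
    isotropic or planar tensors the leading eigenvector is degenerate and its
    angle carries no information.
    """
    mask = phantom.mask if mask is None else np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    sample = data.samples[0]
    atlas = data.atlas
    shape = phantom.signal.shape[:3]
    nvox = int(np.prod(shape))
    bval = float(phantom.scheme.bvalues[0])

    truth = _metrics_from_signal(phantom.signal, phantom.scheme, phantom.s0)
    truth_fa, truth_v1 = truth.fa, truth.v1

    n_in = model.cfg.n_input_directions
    scheme_in = phantom.scheme.subset(n_in)
    base = _metrics_from_signal(phantom.signal[..., :n_in], scheme_in,
                                phantom.s0)
    base_fa, base_v1 = base.fa, base.v1

    if isinstance(model, GaugeModel):
        if prediction is None:
            prediction = model.forward(sample, train=False).data
        flat = prediction.reshape(nvox, -1)
        owners = atlas.vertex_owner_flat[atlas.signal_vertex_ids]
        vert_vals = flat[:, owners] * phantom.s0
        verts = atlas.vertices[atlas.signal_vertex_ids]
        vert_scheme = GradientScheme(verts, np.full(len(verts), bval))
        pred = _metrics_from_signal(vert_vals.reshape(*shape, -1),
                                    vert_scheme, phantom.s0)
    else:
        if prediction is None:
            prediction = model.forward(sample, train=False).data
        pred_signal = np.moveaxis(prediction, 0, -1) * phantom.s0
        pred = _metrics_from_signal(pred_signal, scheme_in, phantom.s0)
    pred_fa, pred_v1 = pred.fa, pred.v1

    ev = truth.eigenvalues
    linear = np.divide(ev[..., 0] - ev[..., 1], ev[..., 0],
                       out=np.zeros(ev.shape[:-1]), where=ev[..., 0] > 0)
    theta_mask = mask & (truth_fa > fa_threshold) & (linear > 0.1)
    if not theta_mask.any():
        theta_mask = mask
    return EvalReport(
        mad_fa_model=mad_metric(truth_fa, pred_fa, mask),
        mad_theta_model=mad_metric(truth_v1, pred_v1, theta_mask, angular=True),
        mad_fa_baseline=mad_metric(truth_fa, base_fa, mask),
        mad_theta_baseline=mad_metric(truth_v1, base_v1, theta_mask,
                                      angular=True),
        n_voxels=int(mask.sum()),
    )
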