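"""Diffusion tensor signal model, fitting, metrics and synthetic phantoms.

The single-shell diffusion signal is modelled as

    S_k = S0 * exp(-b g_k^T D g_k)

with ``D`` the per-voxel symmetric diffusion tensor (mm^2/s), ``g_k`` unit
gradient directions and ``b`` the diffusion weighting (s/mm^2).  Tensors are
fitted by ordinary least squares on ``ln(S/S0)`` with the standard 6-column
quadratic-form design matrix and known ``S0``; with a full-rank design and at
least six directions the noiseless fit is exact.

Derived metrics: fractional anisotropy

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||

and the principal eigenvector V1 (defined up to sign; angular errors are
computed with the antipodal fold).

The phantom generator builds a small volume with two crossing fibre bundles,
an isotropic background and a CSF-like compartment excluded from the
evaluation mask, with Rician (or Gaussian) noise at a configurable SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .qspace import GradientScheme

__all__ = [
    "simulate_signal",
    "design_matrix",
    "fit_tensor",
    "DTIMetrics",
    "metrics_of",
    "delta_theta",
    "mad_metric",
    "PhantomConfig",
    "PhantomVolume",
    "make_phantom",
    "make_scheme",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


def simulate_signal(D: np.ndarray, scheme: GradientScheme,
                    S0: float | np.ndarray = 1.0) -> np.ndarray:
    """Evaluate the tensor model: ``D [..., 3, 3] -> values [..., n_dirs]``."""
    g = scheme.directions
    quad = np.einsum("kd,...de,ke->...k", g, np.asarray(D, dtype=float), g)
    return np.asarray(S0)[..., None] * np.exp(-scheme.bvalues * quad) \
        if np.ndim(S0) else S0 * np.exp(-scheme.bvalues * quad)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """``[n_dirs, 6]`` matrix B with ``ln(S/S0) = -B d`` for
    ``d = (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``."""
    g = scheme.directions
    b = scheme.bvalues[:, None]
    return b * np.stack([
        g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
        2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
    ], axis=1)


def _tensors_from_components(d: np.ndarray) -> np.ndarray:
    D = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    D[..., 0, 0] = d[..., 0]
    D[..., 1, 1] = d[..., 1]
    D[..., 2, 2] = d[..., 2]
    D[..., 0, 1] = D[..., 1, 0] = d[..., 3]
    D[..., 0, 2] = D[..., 2, 0] = d[..., 4]
    D[..., 1, 2] = D[..., 2, 1] = d[..., 5]
    return D


def fit_tensor(values: np.ndarray, scheme: GradientScheme,
               S0: float | np.ndarray = 1.0) -> np.ndarray:
    """Log-linear least-squares tensor fit: ``values [..., n_dirs] -> D``.

    Raises on a rank-deficient design (fewer than six independent
    directions); nonpositive signal values are clamped with a warning.
    """
    B = design_matrix(scheme)
    if len(scheme) < 6 or np.linalg.matrix_rank(B) < 6:
        raise np.linalg.LinAlgError(
            "tensor fit requires >= 6 directions with a rank-6 design matrix")
    vals = np.asarray(values, dtype=float)
    floor = 1e-10 * float(np.max(np.atleast_1d(S0)))
    if np.any(vals <= 0):
        warnings.warn("nonpositive signal values clamped before log transform")
        vals = np.maximum(vals, floor)
    y = -np.log(vals / np.asarray(S0)[..., None] if np.ndim(S0) else vals / S0)
    d, *_ = np.linalg.lstsq(B, y.reshape(-1, y.shape[-1]).T, rcond=None)
    return _tensors_from_components(d.T.reshape(y.shape[:-1] + (6,)))


@dataclass
class DTIMetrics:
    """Eigen-decomposition summary of a tensor field."""

    eigenvalues: np.ndarray   # [..., 3] sorted descending
    fa: np.ndarray            # [...]
    v1: np.ndarray            # [..., 3] unit, sign-normalized
    v1_stable: np.ndarray     # [...] bool: leading eigenvalue separated


def metrics_of(D: np.ndarray) -> DTIMetrics:
    """Eigenvalues (descending), FA, and principal eigenvector of ``D``.

    V1 is sign-normalized so its first nonzero component is positive; when
    the two leading eigenvalues coincide V1 is flagged unstable (any vector
    of the leading subspace is equally valid).
    """
    D = np.asarray(D, dtype=float)
    w, v = np.linalg.eigh(D)                       # ascending
    w = w[..., ::-1]
    v1 = v[..., :, ::-1][..., :, 0]
    mean = w.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(w - mean, axis=-1)
    den = np.linalg.norm(w, axis=-1)
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num),
                                  where=den > 0)
    # sign convention: first component with magnitude above tolerance > 0
    first = np.argmax(np.abs(v1) > 1e-12, axis=-1)
    lead = np.take_along_axis(v1, first[..., None], axis=-1)[..., 0]
    v1 = v1 * np.where(lead < 0, -1.0, 1.0)[..., None]
    stable = (w[..., 0] - w[..., 1]) > 1e-12 * np.maximum(np.abs(w[..., 0]), 1)
    return DTIMetrics(eigenvalues=w, fa=np.clip(fa, 0.0, 1.0), v1=v1,
                      v1_stable=stable)


def delta_theta(v1a: np.ndarray, v1b: np.ndarray) -> np.ndarray:
    """Angle in degrees between principal directions, folded to [0, 90]
    (eigenvector signs are arbitrary)."""
    a = np.asarray(v1a, dtype=float)
    b = np.asarray(v1b, dtype=float)
    for name, x in (("v1a", a), ("v1b", b)):
        if np.any(np.abs(np.linalg.norm(x, axis=-1) - 1.0) > 1e-6):
            raise ValueError(f"{name} must be unit vectors")
    dot = np.abs(np.sum(a * b, axis=-1))
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


def mad_metric(truth: np.ndarray, pred: np.ndarray, mask: np.ndarray,
               angular: bool = False) -> float:
    """Mean absolute difference over masked voxels; with ``angular`` the
    difference is the folded angle (degrees) between unit-vector fields."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty evaluation mask")
    if angular:
        diff = delta_theta(np.asarray(truth)[mask], np.asarray(pred)[mask])
    else:
        if np.asarray(truth).shape != np.asarray(pred).shape:
            raise ValueError("shape mismatch")
        diff = np.abs(np.asarray(truth)[mask] - np.asarray(pred)[mask])
    return float(diff.mean())


# ---------------------------------------------------------------------------
# gradient schemes and phantoms

def make_scheme(n_directions: int = 90, bvalue: float = 1000.0) -> GradientScheme:
    """Single-shell scheme whose first six directions are the icosahedral
    six-direction DTI scheme; further directions follow a golden-ratio spiral
    on the hemisphere (an incremental, approximately uniform ordering)."""
    if n_directions < 1:
        raise ValueError("need at least one direction")
    ico = np.array([
        [0, 1, _GOLDEN], [0, -1, _GOLDEN], [1, _GOLDEN, 0],
        [-1, _GOLDEN, 0], [_GOLDEN, 0, 1], [_GOLDEN, 0, -1],
    ], dtype=float)
    ico /= np.linalg.norm(ico, axis=1, keepdims=True)
    dirs = [d for d in ico[:n_directions]]
    m = n_directions - len(dirs)
    for i in range(m):
        z = 1.0 - (i + 0.5) / m
        lon = 2.0 * np.pi * i / _GOLDEN
        r = np.sqrt(max(0.0, 1.0 - z * z))
        dirs.append(np.array([r * np.cos(lon), r * np.sin(lon), z]))
    return GradientScheme(np.array(dirs), np.full(n_directions, bvalue))


@dataclass
class PhantomConfig:
    """Study conditions of the synthetic crossing-bundle phantom.

    Defaults emulate a single-shell b = 1000 s/mm^2 acquisition with 90
    directions on a 16^3 patch: two orthogonal straight bundles with white
    matter-like eigenvalues (1.7, 0.3, 0.3) um^2/ms, an isotropic grey
    matter-like background (0.8 um^2/ms) and a CSF-like corner sphere
    (3.0 um^2/ms) excluded from the evaluation mask.  Noise is Rician at
    SNR 30 relative to S0.
    """

    shape: tuple[int, int, int] = (16, 16, 16)
    n_directions: int = 90
    bvalue: float = 1000.0
    s0: float = 1000.0
    lambda_parallel: float = 1.7e-3
    lambda_perp: float = 0.3e-3
    background_adc: float = 0.8e-3
    csf_adc: float = 3.0e-3
    bundle_halfwidth: float = 2.5
    snr: float = 30.0
    noise: str = "rician"            # "rician" | "gaussian" | "none"

    def validate(self) -> None:
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("phantom shape must be 3D with sides >= 4")
        if self.noise not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise != "none" and self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class PhantomVolume:
    """Synthetic 4D acquisition with ground truth."""

    signal: np.ndarray          # [x, y, z, n_dirs] noisy
    clean_signal: np.ndarray    # [x, y, z, n_dirs] exact tensor model
    scheme: GradientScheme
    tensors: np.ndarray         # [x, y, z, 3, 3] ground truth
    s0: float
    mask: np.ndarray            # [x, y, z] CSF-excluding evaluation mask
    t1: np.ndarray              # synthetic structural contrast
    t2: np.ndarray
    config: PhantomConfig = field(repr=False, default=None)


def _bundle_tensor(direction: np.ndarray, lpar: float, lperp: float) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    return lperp * np.eye(3) + (lpar - lperp) * np.outer(d, d)


def make_phantom(config: PhantomConfig | None = None,
                 seed: int = 0) -> PhantomVolume:
    """Deterministic synthetic volume: two crossing bundles + background.

    Bundle 1 runs along x, bundle 2 along y; where the slabs cross the two
    tensor compartments are averaged (a classic partial-volume crossing with
    reduced FA).  The same seed always yields bit-identical volumes.
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    nx, ny, nz = config.shape
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    cx = (nx - 1) / 2.0

    in_b1 = (np.abs(Y - cy) <= config.bundle_halfwidth) & \
            (np.abs(Z - cz) <= config.bundle_halfwidth)
    in_b2 = (np.abs(X - cx) <= config.bundle_halfwidth) & \
            (np.abs(Z - cz) <= config.bundle_halfwidth)
    csf = ((X - 1.5) ** 2 + (Y - 1.5) ** 2 + (Z - 1.5) ** 2) <= 2.5 ** 2

    T1 = _bundle_tensor(np.array([1.0, 0.0, 0.0]),
                        config.lambda_parallel, config.lambda_perp)
    T2 = _bundle_tensor(np.array([0.0, 1.0, 0.0]),
                        config.lambda_parallel, config.lambda_perp)
    tensors = np.empty((nx, ny, nz, 3, 3))
    tensors[...] = config.background_adc * np.eye(3)
    tensors[in_b1] = T1
    tensors[in_b2] = T2
    tensors[in_b1 & in_b2] = 0.5 * (T1 + T2)
    tensors[csf] = config.csf_adc * np.eye(3)

    scheme = make_scheme(config.n_directions, config.bvalue)
    clean = simulate_signal(tensors, scheme, config.s0)

    if config.noise == "none":
        signal = clean.copy()
    else:
        sigma = config.s0 / config.snr
        if config.noise == "gaussian":
            signal = clean + rng.normal(0.0, sigma, clean.shape)
        else:  # Rician: magnitude of complex signal with Gaussian quadratures
            re = clean + rng.normal(0.0, sigma, clean.shape)
            im = rng.normal(0.0, sigma, clean.shape)
            signal = np.hypot(re, im)

    # synthetic structural contrasts: tissue-dependent levels + mild noise
    tissue = np.zeros((nx, ny, nz))
    tissue[in_b1 | in_b2] = 1.0
    tissue[csf] = 2.0
    t1 = np.choose(tissue.astype(int), [0.6, 1.0, 0.2]) \
        + 0.02 * rng.standard_normal((nx, ny, nz))
    t2 = np.choose(tissue.astype(int), [0.7, 0.5, 1.0]) \
        + 0.02 * rng.standard_normal((nx, ny, nz))

    return PhantomVolume(signal=signal, clean_signal=clean, scheme=scheme,
                         tensors=tensors, s0=config.s0, mask=~csf,
                         t1=t1, t2=t2, config=config)
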