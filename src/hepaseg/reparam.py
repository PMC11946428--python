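"""Structural re-parameterization.

During training a re-parameterizable unit evaluates several parallel linear
branches (a 3x3x3 convolution, a 1x1x1 convolution and an identity, each
followed by batch normalization).  Because every branch is linear, the whole
sum collapses algebraically into a single convolution for inference:
normalization folds into the kernel and bias, small kernels zero-pad to the
target size, and the identity becomes a centered delta kernel.  The deployed
network is therefore exactly (up to float round-off) equivalent to the
trained one while carrying fewer parameters.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BranchWeights", "NormStats", "fuse_norm", "identity_branch",
           "merge_branches", "convert_to_deploy", "equivalence_report"]


@dataclass
class NormStats:
    """Inference-time normalization statistics of one branch."""

    mean: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5


@dataclass
class BranchWeights:
    """A dense convolution branch: kernel, bias, optional trailing norm."""

    kernel: np.ndarray          # (Cout, Cin, kx, ky, kz)
    bias: np.ndarray | None = None
    norm: NormStats | None = None

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float64)
        if self.kernel.ndim != 5:
            raise ValueError("kernel must have shape (Cout, Cin, kx, ky, kz)")
        if any(k % 2 == 0 for k in self.kernel.shape[2:]):
            raise ValueError("kernel spatial sizes must be odd")
        if self.bias is None:
            self.bias = np.zeros(self.kernel.shape[0])
        self.bias = np.asarray(self.bias, dtype=np.float64)

    @property
    def out_channels(self):
        return self.kernel.shape[0]

    @property
    def in_channels(self):
        return self.kernel.shape[1]


def fuse_norm(branch: BranchWeights) -> BranchWeights:
    """Fold the trailing normalization into the kernel and bias.

    With per-channel statistics (mu, sigma^2) and affine (gamma, beta),
    y = gamma * (conv(x) + b - mu) / sqrt(sigma^2 + eps) + beta, so the
    fused kernel is k * gamma/sqrt(sigma^2+eps) and the fused bias is
    (b - mu) * gamma/sqrt(sigma^2+eps) + beta.
    """
    if branch.norm is None:
        raise ValueError("branch carries no normalization statistics")
    st = branch.norm
    denom = np.asarray(st.var, dtype=np.float64) + st.eps
    if np.any(denom <= 0):
        raise ValueError("variance + epsilon must be positive")
    scale = np.asarray(st.gamma, dtype=np.float64) / np.sqrt(denom)
    kernel = branch.kernel * scale[:, None, None, None, None]
    bias = (branch.bias - np.asarray(st.mean)) * scale + np.asarray(st.beta)
    return BranchWeights(kernel=kernel, bias=bias, norm=None)


def identity_branch(channels: int, norm: NormStats | None = None) -> BranchWeights:
    """The identity map as a 1x1x1 delta kernel (in == out channels only)."""
    kernel = np.eye(channels)[:, :, None, None, None]
    return BranchWeights(kernel=kernel, bias=np.zeros(channels), norm=norm)


def merge_branches(branches: list, target_size: int = 3) -> BranchWeights:
    """Sum parallel norm-free branches into one kernel of ``target_size``.

    Smaller kernels are zero-padded centrally, so convolution with the merged
    kernel equals the sum of the branch convolutions exactly.
    """
    if not branches:
        raise ValueError("no branches to merge")
    if target_size % 2 == 0:
        raise ValueError("target kernel size must be odd")
    co, ci = branches[0].out_channels, branches[0].in_channels
    for b in branches:
        if b.norm is not None:
            raise ValueError("merge requires norm-free branches; fuse first")
        if (b.out_channels, b.in_channels) != (co, ci):
            raise ValueError("branches have incompatible channel counts")
        if any(k > target_size for k in b.kernel.shape[2:]):
            raise ValueError("branch kernel exceeds the merge target size")
    kernel = np.zeros((co, ci, target_size, target_size, target_size))
    bias = np.zeros(co)
    for b in branches:
        kx, ky, kz = b.kernel.shape[2:]
        ox, oy, oz = ((target_size - k) // 2 for k in (kx, ky, kz))
        kernel[:, :, ox:ox + kx, oy:oy + ky, oz:oz + kz] += b.kernel
        bias += b.bias
    return BranchWeights(kernel=kernel, bias=bias, norm=None)


def convert_to_deploy(model):
    """Collapse every re-parameterizable unit of ``model`` in place.

    Converting an already-deployed model warns and is a no-op; conversion is
    idempotent.
    """
    units = [m for m in model.modules() if hasattr(m, "reparameterize")]
    if units and all(getattr(m, "deployed", False) for m in units):
        warnings.warn("model is already in deploy form", stacklevel=2)
        return model
    for m in units:
        if not getattr(m, "deployed", False):
            m.reparameterize()
    if hasattr(model, "config"):
        model.config.deploy = True
    model.eval()
    return model


def equivalence_report(train_model, deploy_model, shape=(1, 1, 32, 32, 16),
                      n_probes: int = 10, seed: int = 0) -> dict:
    """Max-abs output deviation between training-form (eval) and deployed
    networks over seeded random probes."""
    from .nn import Tensor, no_grad

    rng = np.random.default_rng(seed)
    train_model.eval()
    deploy_model.eval()
    worst = 0.0
    for _ in range(n_probes):
        x = rng.standard_normal(shape).astype(np.float32)
        with no_grad():
            a = train_model(Tensor(x))
            b = deploy_model(Tensor(x))
        a = a[-1] if isinstance(a, (list, tuple)) else a
        b = b[-1] if isinstance(b, (list, tuple)) else b
        worst = max(worst, float(np.abs(a.data - b.data).max()))
    return {"n_probes": n_probes, "shape": list(shape), "max_abs_dev": worst}
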