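"""Ghost-convolution encoder and nHSIC feature-diversity regularization.

A Ghost layer produces a few "intrinsic" maps by a true convolution and the
remaining channels by cheap depthwise transforms of them.  The backbone stacks
one stem convolution and four bottlenecks (four Ghost layers each) with stage
outputs at 1/2, 1/4, 1/8 and 1/8 of the input size.  Because cheap transforms
alone cannot guarantee heterogeneous intrinsic maps, training can add a
normalized HSIC penalty between intrinsic channels (a regularized form of the
Hilbert-Schmidt independence criterion); centered kernel alignment (CKA) over
the same channels visualizes the resulting redundancy structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

DEFAULT_EPSILON = 1e-5


# ---------------------------------------------------------------------------
# Ghost layers and the encoder
# ---------------------------------------------------------------------------


@dataclass
class GhostLayerSpec:
    """One Ghost convolution: intrinsic_m true maps, expanded ratio_s-fold."""

    in_channels: int
    intrinsic_m: int
    ratio_s: int = 2
    primary_kernel: int = 1
    cheap_kernel: int = 3
    stride: int = 1

    def __post_init__(self):
        for name in ("in_channels", "intrinsic_m", "ratio_s"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.primary_kernel % 2 == 0 or self.cheap_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")

    @property
    def out_channels(self) -> int:
        return self.intrinsic_m * self.ratio_s


class GhostLayer(nn.Module):
    """y = concat(I, Phi_1(I), ..., Phi_{s-1}(I)) with I = conv(x) + b.

    The identity transform counts as one of the ratio_s expansions, so the
    intrinsic maps are preserved verbatim in the output.  The most recent
    intrinsic maps are kept on ``last_intrinsic`` for the nHSIC regularizer
    (still attached to the autodiff graph).
    """

    def __init__(self, spec: GhostLayerSpec, rng=None):
        super().__init__()
        self.spec = spec
        k = spec.primary_kernel
        self.primary = nn.Conv2d(
            spec.in_channels, spec.intrinsic_m, k, stride=spec.stride, padding=k // 2, rng=rng
        )
        self.cheap = nn.Sequential(
            *[
                nn.DepthwiseConv2d(spec.intrinsic_m, spec.cheap_kernel, padding=spec.cheap_kernel // 2, rng=rng)
                for _ in range(spec.ratio_s - 1)
            ]
        )
        self.last_intrinsic: Tensor | None = None

    def forward(self, x: Tensor) -> Tensor:
        intrinsic = self.primary(x)
        self.last_intrinsic = intrinsic
        if self.spec.ratio_s == 1:
            return intrinsic
        parts = [intrinsic]
        for layer in self.cheap.layers:
            parts.append(layer(intrinsic))
        return ad.concat(parts, axis=1)


def ghost_layer(x: Tensor | np.ndarray, spec: GhostLayerSpec, rng=None) -> Tensor:
    """Functional form of a freshly initialized Ghost layer (mainly for tests)."""
    layer = GhostLayer(spec, rng=rng)
    x = x if isinstance(x, Tensor) else Tensor(x)
    return layer(x)


class GhostBlock(nn.Module):
    """Ghost layer followed by BatchNorm and ReLU."""

    def __init__(self, spec: GhostLayerSpec, rng=None):
        super().__init__()
        self.ghost = GhostLayer(spec, rng=rng)
        self.bn = nn.BatchNorm2d(spec.out_channels)
        self.act = nn.ReLU()

    def forward(self, x):
        return self.act(self.bn(self.ghost(x)))


@dataclass
class BackboneConfig:
    """Stem width and the four bottlenecks of the encoder.

    ``stage_channels`` are the bottleneck output widths; strides are fixed at
    (1, 2, 2, 1) after a stride-2 stem, yielding stage resolutions 1/2, 1/4,
    1/8 and 1/8 of the input.  Each bottleneck stacks ``layers_per_bottleneck``
    Ghost layers (four, matching the reference design).
    """

    stem_channels: int = 16
    stage_channels: tuple = (16, 24, 40, 80)
    ratio_s: int = 2
    cheap_kernel: int = 3
    layers_per_bottleneck: int = 4

    STRIDES = (1, 2, 2, 1)

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("exactly four bottlenecks are required")
        for c in (self.stem_channels, *self.stage_channels):
            if c % self.ratio_s != 0:
                raise ValueError("channel widths must be divisible by ratio_s")


class Bottleneck(nn.Module):
    """Four Ghost blocks; the first carries the stage stride (3x3 primary)."""

    def __init__(self, in_channels: int, out_channels: int, stride: int, cfg: BackboneConfig, rng=None):
        super().__init__()
        blocks = []
        c = in_channels
        for i in range(cfg.layers_per_bottleneck):
            spec = GhostLayerSpec(
                in_channels=c,
                intrinsic_m=out_channels // cfg.ratio_s,
                ratio_s=cfg.ratio_s,
                primary_kernel=3 if (i == 0 and stride == 2) else 1,
                cheap_kernel=cfg.cheap_kernel,
                stride=stride if i == 0 else 1,
            )
            blocks.append(GhostBlock(spec, rng=rng))
            c = out_channels
        self.blocks = nn.Sequential(*blocks)

    def forward(self, x):
        return self.blocks(x)

    @property
    def first_ghost(self) -> GhostLayer:
        return self.blocks.layers[0].ghost


class HGhostBackbone(nn.Module):
    """Stem + four Ghost bottlenecks; returns (F1, F2, F3, F4).

    Stage spatial sizes are 1/2, 1/4, 1/8 and 1/8 of the input.  The intrinsic
    maps of the first Ghost layer of each bottleneck are exposed through
    :meth:`monitored_intrinsics` for the nHSIC regularizer and CKA analysis.
    """

    def __init__(self, cfg: BackboneConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or BackboneConfig()
        self.cfg = cfg
        self.stem = nn.Sequential(
            nn.Conv2d(3, cfg.stem_channels, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(cfg.stem_channels),
            nn.ReLU(),
        )
        c = cfg.stem_channels
        stages = []
        for out_c, stride in zip(cfg.stage_channels, cfg.STRIDES):
            stages.append(Bottleneck(c, out_c, stride, cfg, rng=rng))
            c = out_c
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self._stages = stages

    def forward(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 8")
        feats = []
        out = self.stem(x)
        for stage in self._stages:
            out = stage(out)
            feats.append(out)
        return tuple(feats)

    def monitored_intrinsics(self) -> list[Tensor]:
        """Intrinsic maps of the first Ghost layer of each bottleneck."""
        out = []
        for stage in self._stages:
            t = stage.first_ghost.last_intrinsic
            if t is not None:
                out.append(t)
        return out


# ---------------------------------------------------------------------------
# HSIC / nHSIC / CKA
# ---------------------------------------------------------------------------


def _centering(m: int) -> np.ndarray:
    return np.eye(m) - np.ones((m, m)) / m


def hsic_empirical(Kx: np.ndarray, Ky: np.ndarray) -> float:
    """Empirical HSIC: (m-1)^{-2} tr(Kx H Ky H) for m x m kernel matrices."""
    Kx, Ky = np.asarray(Kx, dtype=np.float64), np.asarray(Ky, dtype=np.float64)
    m = Kx.shape[0]
    if Kx.shape != (m, m) or Ky.shape != (m, m):
        raise ValueError("kernel matrices must be square and equally sized")
    if m < 2:
        raise ValueError("HSIC needs at least two samples")
    H = _centering(m)
    return float(np.trace(Kx @ H @ Ky @ H) / (m - 1) ** 2)


def _regularized_kernel(I: Tensor, eps: float) -> Tensor:
    """K-tilde = Kbar (Kbar + eps*s*I)^{-1} for the linear kernel of I (s x p)."""
    s = I.shape[0]
    H = Tensor(_centering(s).astype(np.float64))
    K = ad.matmul(I, ad.transpose(I, (1, 0)))
    Kbar = ad.matmul(ad.matmul(H, K), H)
    M = Kbar + Tensor((eps * s * np.eye(s)).astype(np.float64))
    # Kbar and M share an eigenbasis, so solve(M, Kbar) is the symmetric K-tilde
    return ad.solve(M, Kbar)


def nhsic(Ii, Ij, eps: float = DEFAULT_EPSILON) -> Tensor:
    """Normalized HSIC tr(K~_i K~_j) between two representations (s x p).

    Linear kernels, centered, regularized by eps*s on the diagonal; the value
    lies in [0, s].  Symmetric in its arguments; zero when either input is
    constant across samples.  Differentiable when given Tensors.
    """
    Ii = Ii if isinstance(Ii, Tensor) else Tensor(np.asarray(Ii, dtype=np.float64))
    Ij = Ij if isinstance(Ij, Tensor) else Tensor(np.asarray(Ij, dtype=np.float64))
    if Ii.shape[0] != Ij.shape[0]:
        raise ValueError("representations must share the sample count")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if not (np.isfinite(Ii.data).all() and np.isfinite(Ij.data).all()):
        raise ValueError("non-finite representation input")
    Ki = _regularized_kernel(Ii, eps)
    Kj = _regularized_kernel(Ij, eps)
    return (Ki * ad.transpose(Kj, (1, 0))).sum()


def l_nhsic(intrinsics: list, alpha: float | None = None, eps: float = DEFAULT_EPSILON) -> Tensor:
    """nHSIC diversity penalty over all unordered pairs of representations.

    ``alpha`` defaults to 1/#pairs so the penalty is a pairwise average and the
    loss weight lambda controls the total contribution.
    """
    if len(intrinsics) < 2:
        warnings.warn("l_nhsic needs at least two representations; returning 0", stacklevel=2)
        return Tensor(np.zeros(()))
    n = len(intrinsics)
    npairs = n * (n - 1) // 2
    if alpha is None:
        alpha = 1.0 / npairs
    tensors = [
        I if isinstance(I, Tensor) else Tensor(np.asarray(I, dtype=np.float64)) for I in intrinsics
    ]
    kts = [_regularized_kernel(I, eps) for I in tensors]
    total = None
    for i in range(n):
        for j in range(i + 1, n):
            term = (kts[i] * ad.transpose(kts[j], (1, 0))).sum()
            total = term if total is None else total + term
    return total * alpha


def l_nhsic_channels(
    intrinsic: Tensor,
    eps: float = DEFAULT_EPSILON,
    pool_hw: int = 8,
    max_channels: int = 50,
    alpha: float | None = None,
) -> Tensor:
    """Channelwise nHSIC penalty for one layer's intrinsic maps (N, m, H, W).

    Each of the first ``max_channels`` intrinsic channels, spatially
    average-pooled to ``pool_hw`` squared, is one scalar representation
    evaluated on the N*pool_hw^2 (sample, position) pairs; the penalty
    averages nHSIC over all channel pairs.  Scalar representations give
    rank-one kernels, so K-tilde has the closed form

        K~_i = c_i c_i^T / (|c_i|^2 + eps*s),   c_i = centered channel,

    and tr(K~_i K~_j) = <c_i, c_j>^2 / ((|c_i|^2+eps*s)(|c_j|^2+eps*s)) — a
    regularized squared cosine, i.e. exactly the CKA-style redundancy the
    penalty is meant to suppress.  (Treating whole pooled maps as
    p-dimensional features over the batch would be degenerate at small batch
    sizes: every centered kernel becomes the same near-identity projector and
    the penalty carries no gradient.)  Equivalent to the generic
    :func:`nhsic` applied to (s, 1) channel matrices; vectorized here.
    """
    N, m = intrinsic.shape[0], intrinsic.shape[1]
    if N < 2:
        raise ValueError("nHSIC needs a batch of at least 2 samples")
    m = min(m, max_channels)
    if m < 2:
        warnings.warn("fewer than two intrinsic channels; penalty is 0", stacklevel=2)
        return Tensor(np.zeros(()))
    x = intrinsic[:, :m]
    oh = min(pool_hw, x.shape[2])
    ow = min(pool_hw, x.shape[3])
    x = ad.box_resize(x, oh, ow)
    s = N * oh * ow
    V = ad.reshape(ad.transpose(x, (1, 0, 2, 3)), (m, s))  # (m, s) channel rows
    Vc = V - ad.tmean(V, axis=1, keepdims=True)
    G = ad.matmul(Vc, ad.transpose(Vc, (1, 0)))  # (m, m) centered Gram
    eye = Tensor(np.eye(m, dtype=np.float32))
    denom = (G * eye).sum(axis=1) + eps * s  # |c_i|^2 + eps*s per channel
    dinv = 1.0 / denom
    scale = ad.reshape(dinv, (m, 1)) * ad.reshape(dinv, (1, m))
    pair = (G * G) * scale  # tr(K~_i K~_j) for every pair
    offdiag_sum = ((1.0 - eye) * pair).sum() * 0.5
    npairs = m * (m - 1) // 2
    if alpha is None:
        alpha = 1.0 / npairs
    return offdiag_sum * alpha


def cka_matrix(channels: np.ndarray) -> np.ndarray:
    """Linear CKA similarity among channel representations.

    ``channels`` is (n_channels, n_features); returns a symmetric (n, n)
    matrix with unit diagonal.  Zero-variance channels are defined to have
    similarity 0 against every other channel.
    """
    X = np.asarray(channels, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two channel representations")
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    # linear CKA between 1-D representations reduces to squared correlation
    G = Xc @ Xc.T
    denom = np.outer(norms, norms)
    with np.errstate(divide="ignore", invalid="ignore"):
        cka = np.where(denom > 0, (G / np.where(denom > 0, denom, 1.0)) ** 2, 0.0)
    np.fill_diagonal(cka, 1.0)
    return cka


def mean_offdiagonal_cka(channels: np.ndarray) -> float:
    """Mean off-diagonal CKA — the redundancy statistic monitored in training."""
    cka = cka_matrix(channels)
    n = cka.shape[0]
    return float((cka.sum() - np.trace(cka)) / (n * (n - 1)))


def cka_heatmap(channels: np.ndarray, path) -> np.ndarray:
    """Render the CKA similarity matrix of channel representations to a PNG."""
    cka = cka_matrix(channels)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(figsize=(5, 4))
    im = axis.imshow(cka, vmin=0.0, vmax=1.0, cmap="magma")
    axis.set_xlabel("intrinsic channel")
    axis.set_ylabel("intrinsic channel")
    fig.colorbar(im, ax=axis, label="linear CKA")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return cka
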