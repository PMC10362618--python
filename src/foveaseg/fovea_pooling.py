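"""Fovea Pooling: importance-aware attention and adaptive-radius aggregation.

The operator mimics the retinal fovea: a pointwise spatial attention module
(collect + distribute branches) scores every position of a feature map with an
importance value Z in [0, 1]; each position is then pooled with a radius that
shrinks as importance grows,

    r_k = floor(exp(sigma * (1 - Z_k))),   sigma = ln(s * w),

so maximally important positions keep full resolution (r=1) while unimportant
ones aggregate a wide neighbourhood (r up to floor(s*w), the pooling boundary
fraction s of the map width w).  Pooling is stride-1 over square windows of
side (2r - 1) with reflect padding, so the output keeps the input size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass
class PoolingBoundary:
    """Normalized radius cap: s = e^sigma / w for a stage of spatial size w."""

    s: float

    def __post_init__(self):
        if not 0 < self.s <= 1:
            raise ValueError(f"pooling boundary s must be in (0, 1], got {self.s}")

    def sigma(self, w: int) -> float:
        return boundary_to_sigma(self.s, w)


@dataclass
class PoolingMethod:
    """Window aggregation rule: average, lp, mixed (max/mean) or identity."""

    kind: str = "mixed"
    p: float = 2.0
    mix: float = 0.5

    def __post_init__(self):
        if self.kind not in ("average", "lp", "mixed", "identity"):
            raise ValueError(f"unknown pooling method {self.kind!r}")
        if self.p < 1:
            raise ValueError("lp exponent must be >= 1")
        if not 0 <= self.mix <= 1:
            raise ValueError("mix weight must lie in [0, 1]")


def boundary_to_sigma(s: float, w: int) -> float:
    """Invert the boundary normalization s = e^sigma / w, i.e. sigma = ln(s*w)."""
    if s <= 0:
        raise ValueError("boundary s must be positive")
    if w < 1:
        raise ValueError("stage size w must be >= 1")
    return float(np.log(s * w))


def radius_cap(sigma: float) -> int:
    """Largest radius the law can produce: floor(e^sigma), guarded for exact powers."""
    return max(1, int(np.floor(np.exp(sigma) + 1e-9)))


def radius_map(Z: np.ndarray, sigma: float) -> np.ndarray:
    """Per-position pooling radius r = floor(exp(sigma*(1-Z))), clamped to >= 1.

    Monotone non-increasing in Z: important positions pool over small windows.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.min() < 0 or Z.max() > 1:
        warnings.warn("importance map outside [0, 1]; clamping", stacklevel=2)
        Z = np.clip(Z, 0.0, 1.0)
    # 1e-9 guard so exact powers (e.g. exp(ln 8)) are not floored one short
    r = np.floor(np.exp(sigma * (1.0 - Z)) + 1e-9).astype(np.int64)
    return np.maximum(r, 1)


@lru_cache(maxsize=32)
def _attention_index(h: int, w: int) -> np.ndarray:
    """Channel index map for the over-complete attention embedding.

    The embedding at position [k, l] holds one channel per relative offset on
    a (2h-1) x (2w-1) grid; source position [s, t] is read from channel
    (h-1-k+s, w-1-l+t) (0-based).  Returns an (h*w, h*w) int array indexed
    [target_flat, source_flat].
    """
    k, l = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    s, t = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rows = (h - 1) - k.reshape(-1, 1) + s.reshape(1, -1)
    cols = (w - 1) - l.reshape(-1, 1) + t.reshape(1, -1)
    return (rows * (2 * w - 1) + cols).astype(np.intp)


def attention_from_embedding(embedding: Tensor, h: int, w: int) -> Tensor:
    """Assemble the pointwise attention A[k,l][s,t] from an embedding tensor.

    ``embedding`` is (N, (2h-1)*(2w-1), h, w); the result is (N, h, w, h, w).
    """
    n_ch = (2 * h - 1) * (2 * w - 1)
    if embedding.shape[1] != n_ch:
        raise ValueError(
            f"embedding must have {(2*h-1)*(2*w-1)} channels for a {h}x{w} map, "
            f"got {embedding.shape[1]}"
        )
    L = h * w
    flat = ad.reshape(embedding, (embedding.shape[0], n_ch, L))
    att = ad.psa_gather(flat, _attention_index(h, w))  # (N, L, L)
    return ad.reshape(att, (embedding.shape[0], h, w, h, w))


class ImportanceAware(nn.Module):
    """Collect/distribute pointwise attention producing an importance map.

    Works at a fixed resolution (h, w); inputs at other sizes must be resized
    by the caller.  Each branch maps the reduced feature to an over-complete
    (2h-1)(2w-1)-channel embedding through a 1x1 bottleneck of ``branch_width``
    channels.
    """

    def __init__(self, in_channels: int, h: int, w: int, branch_width: int = 32, rng=None):
        super().__init__()
        self.h, self.w = h, w
        n_ch = (2 * h - 1) * (2 * w - 1)
        self.collect = nn.Sequential(
            nn.Conv2d(in_channels, branch_width, 1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(branch_width, n_ch, 1, rng=rng),
        )
        self.distribute = nn.Sequential(
            nn.Conv2d(in_channels, branch_width, 1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(branch_width, n_ch, 1, rng=rng),
        )

    def collect_distribute_attention(self, feature: Tensor) -> tuple[Tensor, Tensor]:
        """Return the two (N, h, w, h, w) pointwise attention tensors."""
        if feature.shape[2] != self.h or feature.shape[3] != self.w:
            raise ValueError(
                f"feature is {feature.shape[2]}x{feature.shape[3]} but this module "
                f"works at {self.h}x{self.w}; downsample before calling"
            )
        a_c = attention_from_embedding(self.collect(feature), self.h, self.w)
        a_d = attention_from_embedding(self.distribute(feature), self.h, self.w)
        return a_c, a_d

    def forward(self, feature: Tensor) -> Tensor:
        a_c, a_d = self.collect_distribute_attention(feature)
        return importance_map(a_c, a_d, feature)


def importance_map(attn_c: Tensor, attn_d: Tensor, feature: Tensor) -> Tensor:
    """Aggregate collect+distribute attention into a normalized importance map.

    z_i = (1/N) sum_j a^c_{i,j} x_j + (1/N) sum_j a^d_{i,j} x_j gives a vector
    per position; it is reduced to a scalar by the channel mean and min-max
    normalized into [0, 1] per sample.  A constant raw map (degenerate case)
    returns Z identically 1 so the subsequent pooling degrades to the identity.
    Returns (N, 1, H, W).
    """
    n, c, h, w = feature.shape
    L = h * w
    a = ad.reshape(attn_c, (n, L, L)) + ad.reshape(attn_d, (n, L, L))
    xf = ad.transpose(ad.reshape(feature, (n, c, L)), (0, 2, 1))  # (N, L, C)
    z = ad.matmul(a, xf) * (1.0 / L)  # (N, L, C) aggregated features
    raw = ad.tmean(z, axis=2)  # channel-mean scalar importance, (N, L)
    if not np.all(np.isfinite(raw.data)):
        raise FloatingPointError("non-finite importance aggregate")
    lo = ad.tmin(raw, axis=1, keepdims=True)
    hi = ad.tmax(raw, axis=1, keepdims=True)
    span = hi - lo
    degenerate = (span.data < 1e-12).astype(raw.data.dtype)  # (N, 1)
    zn = (raw - lo) / (span + 1e-30)
    Z = zn * Tensor(1.0 - degenerate) + Tensor(degenerate)
    return ad.reshape(Z, (n, 1, h, w))


def adaptive_pool(
    feature: Tensor | np.ndarray,
    radii: np.ndarray,
    method: PoolingMethod | str = "average",
    max_radius: int | None = None,
) -> Tensor:
    """Stride-1 pooling of an NCHW tensor with a per-position radius map.

    ``radii`` may be (H, W) or (N, H, W).  ``max_radius``, when given, is the
    floor(e^sigma) contract from the radius law; larger radii are rejected.
    """
    if isinstance(method, str):
        method = PoolingMethod(kind=method)
    radii = np.asarray(radii)
    if max_radius is not None and radii.max() > max_radius:
        raise ValueError(
            f"radius map contains r={radii.max()} above the boundary cap {max_radius}"
        )
    x = feature if isinstance(feature, Tensor) else Tensor(feature)
    return ad.adaptive_pool(x, radii, method=method.kind, p=method.p, mix=method.mix)


class FoveaPooling(nn.Module):
    """One Fovea Pooling skip module for an encoder stage.

    Pipeline: 1x1 prior convolution to C/4 channels -> importance at a capped
    working resolution (bilinear resampling in/out) -> radius map from the
    stage's pooling boundary -> adaptive-radius pooling -> 1x1 restore
    convolution back to C channels.  Output spatial size equals input.

    The floor in the radius law is piecewise constant, so by default no
    gradient reaches the importance branch (the pooling path follows the
    mean-window gradient exactly).  ``importance_grad=True`` multiplies the
    pooled output by a straight-through factor (identically 1 in the forward
    pass) so the importance branch still receives a training signal.
    """

    def __init__(
        self,
        channels: int,
        stage_size: int,
        boundary: PoolingBoundary | float,
        method: PoolingMethod | None = None,
        attention_max_hw: int = 32,
        branch_width: int = 32,
        importance_grad: bool = False,
        rng=None,
    ):
        super().__init__()
        if channels % 4 != 0:
            raise ValueError("stage channels must be divisible by 4 for the C/4 prior conv")
        self.boundary = boundary if isinstance(boundary, PoolingBoundary) else PoolingBoundary(boundary)
        self.method = method or PoolingMethod()
        self.stage_size = stage_size
        self.sigma = self.boundary.sigma(stage_size)
        self.max_radius = radius_cap(self.sigma)
        self.importance_grad = importance_grad
        wk = min(attention_max_hw, stage_size)
        self.work_hw = wk
        c4 = channels // 4
        self.prior = nn.Conv2d(channels, c4, 1, rng=rng)
        self.importance = ImportanceAware(c4, wk, wk, branch_width=branch_width, rng=rng)
        self.restore = nn.Conv2d(c4, channels, 1, rng=rng)

    def importance_full(self, x: Tensor) -> Tensor:
        """Importance map of the reduced feature, upsampled to x's spatial size."""
        xr = self.prior(x)
        h, w = xr.shape[2], xr.shape[3]
        xs = ad.bilinear_resize(xr, self.work_hw, self.work_hw)
        Z = self.importance(xs)
        Z = ad.bilinear_resize(Z, h, w)  # convex interpolation keeps [0, 1]
        return Z, xr

    def forward(self, x: Tensor) -> Tensor:
        Z, xr = self.importance_full(x)
        radii = radius_map(Z.data[:, 0], self.sigma)  # (N, H, W), detached
        pooled = adaptive_pool(xr, radii, self.method, max_radius=self.max_radius)
        if self.importance_grad and self.method.kind != "identity":
            r_cont = ad.exp(Z * (-self.sigma) + self.sigma)  # exp(sigma*(1-Z))
            ste = r_cont / r_cont.detach()  # == 1 in the forward pass
            pooled = pooled * ste
        return self.restore(pooled)
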