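"""Fovea-UNet assembly: Ghost encoder, Fovea Pooling skips, U-Net decoder.

The encoder produces four stage features at 1/2, 1/4, 1/8 and 1/8 of the
input.  Each stage feature passes through a Fovea Pooling module before
fusion; F4 (the bottleneck) is concatenated with FP(F3) at the shared 1/8
resolution, then the decoder upsamples twice (fusing FP(F2) and FP(F1)) and
once more to full resolution, ending in a 1x1 sigmoid head.  Setting the
pooling method to ``identity`` builds plain identity skip connections with no
Fovea Pooling parameters at all — the ablation baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .fovea_pooling import FoveaPooling, PoolingBoundary, PoolingMethod
from .hghost import BackboneConfig, HGhostBackbone


@dataclass
class NetworkConfig:
    """Architecture of the full segmentation network.

    Defaults reproduce the reference model at 1024x1024 input; the widths can
    be reduced uniformly for desk-scale experiments (see ``scaled``).
    """

    input_size: int = 1024
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    fp_method: str = "mixed"
    fp_boundaries: tuple = (1 / 8, 1 / 16, 1 / 8, 1 / 8)
    fp_attention_max_hw: int = 32
    # per-stage width of the attention-branch bottleneck; chosen together with
    # the decoder ladder so the default model matches the reference footprint
    fp_branch_width: int | tuple = (92, 92, 92, 91)
    fp_lp_p: float = 2.0
    fp_mix: float = 0.5
    fp_importance_grad: bool = False
    decoder_channels: tuple = (376, 200, 104, 40)
    n_classes: int = 1

    def __post_init__(self):
        if isinstance(self.backbone, dict):
            self.backbone = BackboneConfig(**self.backbone)
        self.fp_boundaries = tuple(self.fp_boundaries)
        self.decoder_channels = tuple(self.decoder_channels)
        if isinstance(self.fp_branch_width, (list, tuple)):
            self.fp_branch_width = tuple(self.fp_branch_width)
        if len(self.fp_boundaries) != 4:
            raise ValueError("exactly four pooling boundaries are required")
        if len(self.decoder_channels) != 4:
            raise ValueError("decoder ladder must have four widths")
        if self.input_size % 8:
            raise ValueError("input size must be divisible by 8")

    @property
    def stage_sizes(self) -> tuple:
        s = self.input_size
        return (s // 2, s // 4, s // 8, s // 8)

    def pooling_method(self) -> PoolingMethod:
        return PoolingMethod(kind=self.fp_method, p=self.fp_lp_p, mix=self.fp_mix)

    @staticmethod
    def scaled(input_size: int = 96) -> "NetworkConfig":
        """Width-reduced configuration for CPU-scale training experiments."""
        return NetworkConfig(
            input_size=input_size,
            backbone=BackboneConfig(stem_channels=8, stage_channels=(8, 12, 16, 24)),
            fp_attention_max_hw=12,
            fp_branch_width=16,
            decoder_channels=(48, 32, 24, 16),
        )


class DecoderBlock(nn.Module):
    """Optional 2x bilinear upsample, concatenate skip, two 3x3 conv+BN+ReLU."""

    def __init__(self, in_channels: int, out_channels: int, upsample: bool, rng=None):
        super().__init__()
        self.upsample = upsample
        self.conv = nn.Sequential(
            nn.Conv2d(in_channels, out_channels, 3, padding=1, rng=rng),
            nn.BatchNorm2d(out_channels),
            nn.ReLU(),
            nn.Conv2d(out_channels, out_channels, 3, padding=1, rng=rng),
            nn.BatchNorm2d(out_channels),
            nn.ReLU(),
        )

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        if self.upsample:
            x = ad.bilinear_resize(x, x.shape[2] * 2, x.shape[3] * 2)
        if skip is not None:
            x = ad.concat([x, skip], axis=1)
        return self.conv(x)


class FoveaUNet(nn.Module):
    """End-to-end segmentation network mapping an RGB tile to a probability map."""

    def __init__(self, cfg: NetworkConfig | None = None, rng=None):
        super().__init__()
        cfg = cfg or NetworkConfig()
        self.cfg = cfg
        self.backbone = HGhostBackbone(cfg.backbone, rng=rng)
        ch = cfg.backbone.stage_channels
        method = cfg.pooling_method()
        self.use_fp = cfg.fp_method != "identity"
        if self.use_fp:
            widths = cfg.fp_branch_width
            if isinstance(widths, int):
                widths = (widths,) * 4
            fps = []
            for c, size, s, bw in zip(ch, cfg.stage_sizes, cfg.fp_boundaries, widths):
                fps.append(
                    FoveaPooling(
                        channels=c,
                        stage_size=size,
                        boundary=PoolingBoundary(s),
                        method=method,
                        attention_max_hw=cfg.fp_attention_max_hw,
                        branch_width=bw,
                        importance_grad=cfg.fp_importance_grad,
                        rng=rng,
                    )
                )
            self.fp1, self.fp2, self.fp3, self.fp4 = fps
            self._fps = fps
        else:
            self._fps = []
        d = cfg.decoder_channels
        # F4 and F3 share the 1/8 resolution: first block fuses without upsampling
        self.dec3 = DecoderBlock(ch[3] + ch[2], d[0], upsample=False, rng=rng)
        self.dec2 = DecoderBlock(d[0] + ch[1], d[1], upsample=True, rng=rng)
        self.dec1 = DecoderBlock(d[1] + ch[0], d[2], upsample=True, rng=rng)
        self.dec0 = DecoderBlock(d[2], d[3], upsample=True, rng=rng)
        self.head = nn.Conv2d(d[3], cfg.n_classes, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 8")
        f1, f2, f3, f4 = self.backbone(x)
        if self.use_fp:
            f1, f2, f3, f4 = (fp(f) for fp, f in zip(self._fps, (f1, f2, f3, f4)))
        out = self.dec3(f4, f3)
        out = self.dec2(out, f2)
        out = self.dec1(out, f1)
        out = self.dec0(out)
        return ad.sigmoid(self.head(out))

    def predict_mask(self, x: Tensor, threshold: float = 0.5) -> np.ndarray:
        with ad.no_grad():
            prob = self.forward(x)
        return (prob.data >= threshold).astype(np.uint8)

    def monitored_intrinsics(self):
        return self.backbone.monitored_intrinsics()


def build_fovea_unet(cfg: NetworkConfig | None = None, rng=None) -> FoveaUNet:
    return FoveaUNet(cfg, rng=rng)


@dataclass
class ParamReport:
    total: int
    megabytes: float
    breakdown: dict

    def as_table(self) -> str:
        lines = [f"{'module':<14}{'params':>12}{'MB':>10}"]
        for name, count in self.breakdown.items():
            lines.append(f"{name:<14}{count:>12}{4 * count / 2**20:>10.2f}")
        lines.append(f"{'total':<14}{self.total:>12}{self.megabytes:>10.2f}")
        return "\n".join(lines)


def param_report(model: nn.Module) -> ParamReport:
    """Trainable parameter count and 4-bytes-per-parameter footprint in MB."""
    breakdown: dict[str, int] = {}
    for name, p in model.named_parameters():
        top = name.split(".", 1)[0]
        breakdown[top] = breakdown.get(top, 0) + p.size
    total = sum(breakdown.values())
    return ParamReport(total=total, megabytes=4 * total / 2**20, breakdown=breakdown)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def _config_dict(cfg: NetworkConfig) -> dict:
    d = asdict(cfg)
    return d


def save_checkpoint(model: FoveaUNet, path) -> None:
    """Single-file checkpoint: weights + architecture config."""
    path = Path(path)
    state = model.state_dict()
    meta = json.dumps(_config_dict(model.cfg))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> FoveaUNet:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        cfg = NetworkConfig(
            input_size=meta["input_size"],
            backbone=BackboneConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in meta["backbone"].items()}),
            fp_method=meta["fp_method"],
            fp_boundaries=tuple(meta["fp_boundaries"]),
            fp_attention_max_hw=meta["fp_attention_max_hw"],
            fp_branch_width=tuple(meta["fp_branch_width"])
            if isinstance(meta["fp_branch_width"], list)
            else meta["fp_branch_width"],
            fp_lp_p=meta["fp_lp_p"],
            fp_mix=meta["fp_mix"],
            fp_importance_grad=meta["fp_importance_grad"],
            decoder_channels=tuple(meta["decoder_channels"]),
            n_classes=meta["n_classes"],
        )
        model = FoveaUNet(cfg)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
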