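"""Neural building blocks: ghost block, ghost coordinate attention (GCA),
GGC block and residual GGC (RGGC) block.

The ghost block replaces a dense convolution by a cheap two-stage recipe:
a 1x1 pointwise convolution produces ``out_channels / ratio`` *intrinsic*
feature maps, and a depthwise convolution of those intrinsic maps produces
the remaining *cheap* maps; the two sets are concatenated (intrinsic first).

Ghost coordinate attention factorises channel attention into two 1D
encodings: features are mean-pooled along width (giving a C x H x 1
descriptor) and along height (C x 1 x W), processed jointly by a shared
ghost block, split, and mapped by two separate ghost blocks + sigmoid into
directional attention maps in (0, 1).

A GGC block runs a ghost expansion and a GCA branch in parallel on the same
input and fuses them multiplicatively; an RGGC block wraps GGC-expand /
ghost-reduce in a residual unit whose stride-2 variant performs the
encoder's downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor, as_tensor


class ConfigurationError(ValueError):
    """An invalid block hyper-parameter combination."""


class AssemblyError(RuntimeError):
    """Branches of a composite block disagree on tensor layout."""


class DegenerateInputError(ValueError):
    """Input too small for the requested operation."""


class AttentionPair(NamedTuple):
    """Directional attention maps: ``a_h`` (N,C,H,1) and ``a_w`` (N,C,1,W)."""
    a_h: Tensor
    a_w: Tensor


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class GhostConfig:
    out_channels: int
    ratio: int = 2
    dw_kernel: int = 3
    use_norm_act: bool = True

    def __post_init__(self):
        if self.out_channels < 1 or self.ratio < 2:
            raise ConfigurationError("out_channels >= 1 and ratio >= 2 required")
        if self.out_channels % self.ratio:
            raise ConfigurationError(
                f"out_channels ({self.out_channels}) must be divisible by "
                f"ratio ({self.ratio})")
        if self.dw_kernel % 2 == 0:
            raise ConfigurationError("dw_kernel must be odd")


@dataclass
class GCAConfig:
    in_channels: int
    out_channels: int
    reduction: int = 16
    min_mid: int = 8

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1 or self.reduction < 1:
            raise ConfigurationError("channels and reduction must be positive")

    @property
    def mid_channels(self) -> int:
        mid = max(self.min_mid, self.in_channels // self.reduction, 2)
        return mid + (mid % 2)  # ghost blocks need an even width at ratio 2


@dataclass
class RGGCConfig:
    in_channels: int
    mid_channels: int
    out_channels: int
    stride: int = 1

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ConfigurationError("stride must be 1 or 2")
        if self.mid_channels < self.out_channels:
            raise ConfigurationError("mid_channels must be >= out_channels")
        if self.mid_channels % 2 or self.out_channels % 2:
            raise ConfigurationError("mid/out channels must be even (ghost ratio 2)")


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class GhostBlock(nn.Module):
    """Pointwise "intrinsic" convolution + depthwise "cheap" expansion,
    concatenated intrinsic-first along channels.

    ``act`` overrides whether the ReLU is applied after each normalisation
    (the residual-reduction ghost block uses norm without activation).
    """

    def __init__(self, in_channels: int, cfg: GhostConfig, stride: int = 1,
                 act: bool | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ConfigurationError("stride must be 1 or 2")
        self.cfg = cfg
        self.in_channels = in_channels
        self.stride = stride
        intrinsic = cfg.out_channels // cfg.ratio
        cheap = cfg.out_channels - intrinsic
        self.intrinsic_channels = intrinsic
        use_norm = cfg.use_norm_act
        self.use_act = cfg.use_norm_act if act is None else (act and use_norm)
        self.primary = nn.Conv2d(in_channels, intrinsic, 1, stride=stride,
                                 bias=not use_norm)
        self.cheap = nn.Conv2d(intrinsic, cheap, cfg.dw_kernel, padding=cfg.dw_kernel // 2,
                               groups=intrinsic, bias=not use_norm)
        self.norm1 = nn.BatchNorm2d(intrinsic) if use_norm else None
        self.norm2 = nn.BatchNorm2d(cheap) if use_norm else None

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.primary(x)
        if self.norm1 is not None:
            y1 = self.norm1(y1)
        if self.use_act:
            y1 = y1.relu()
        y2 = self.cheap(y1)
        if self.norm2 is not None:
            y2 = self.norm2(y2)
        if self.use_act:
            y2 = y2.relu()
        return nn.concat([y1, y2], axis=1)


class GCA(nn.Module):
    """Ghost coordinate attention.

    Width- and height-pooled descriptors are concatenated along the pooled
    axis, passed through a shared ghost block (with norm + ReLU), split back,
    and mapped by two separate ghost blocks (no norm) + sigmoid into the
    directional attention pair.

    The ghost blocks here use a 1x1 cheap operation (``dw_kernel=1``): the
    attention transform must act per position along the pooled axis so that
    permuting input rows permutes ``a_h`` identically — a wider depthwise
    kernel would smear positional information across coordinates.
    """

    def __init__(self, cfg: GCAConfig):
        super().__init__()
        self.cfg = cfg
        mid = cfg.mid_channels
        self.shared = GhostBlock(cfg.in_channels,
                                 GhostConfig(mid, dw_kernel=1,
                                             use_norm_act=True))
        self.attend_h = GhostBlock(mid, GhostConfig(cfg.out_channels,
                                                    dw_kernel=1,
                                                    use_norm_act=False))
        self.attend_w = GhostBlock(mid, GhostConfig(cfg.out_channels,
                                                    dw_kernel=1,
                                                    use_norm_act=False))

    @staticmethod
    def pool(x: Tensor) -> tuple[Tensor, Tensor]:
        """Directional mean pooling: ``z_h`` (N,C,H,1) over width and
        ``z_w`` (N,C,1,W) over height."""
        x = as_tensor(x)
        return (x.mean(axis=3, keepdims=True),
                x.mean(axis=2, keepdims=True))

    def forward(self, x: Tensor) -> AttentionPair:
        x = as_tensor(x)
        if x.shape[1] != self.cfg.in_channels:
            raise AssemblyError(
                f"GCA expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        N, C, H, W = x.shape
        if H + W < 2:
            raise DegenerateInputError("need H + W >= 2 for coordinate pooling")
        z_h, z_w_row = self.pool(x)                              # (N,C,H,1), (N,C,1,W)
        z_w = z_w_row.transpose((0, 1, 3, 2))                    # (N,C,W,1)
        z = nn.concat([z_h, z_w], axis=2)                        # (N,C,H+W,1)
        z = self.shared(z)
        part_h = z[:, :, :H, :]
        part_w = z[:, :, H:, :]
        a_h = self.attend_h(part_h).sigmoid()                    # (N,out,H,1)
        a_w = self.attend_w(part_w).sigmoid().transpose((0, 1, 3, 2))  # (N,out,1,W)
        return AttentionPair(a_h, a_w)


class GGCBlock(nn.Module):
    """Parallel ghost-expansion and GCA branches fused multiplicatively."""

    def __init__(self, in_channels: int, mid_channels: int,
                 gca_reduction: int = 16):
        super().__init__()
        self.ghost = GhostBlock(in_channels, GhostConfig(mid_channels))
        self.gca = GCA(GCAConfig(in_channels, mid_channels,
                                 reduction=gca_reduction))

    def forward(self, x: Tensor) -> Tensor:
        expanded = self.ghost(x)
        a_h, a_w = self.gca(x)
        if expanded.shape[1] != a_h.shape[1]:
            raise AssemblyError("ghost and attention branches disagree on width")
        return expanded * a_h * a_w


class RGGCBlock(nn.Module):
    """Residual unit: GGC expand -> (stride-2 depthwise conv) -> ghost reduce,
    plus an identity or depthwise+pointwise projection shortcut."""

    def __init__(self, cfg: RGGCConfig, gca_reduction: int = 16):
        super().__init__()
        self.cfg = cfg
        cin, mid, cout, s = (cfg.in_channels, cfg.mid_channels,
                             cfg.out_channels, cfg.stride)
        self.ggc = GGCBlock(cin, mid, gca_reduction)
        if s == 2:
            self.down = nn.Sequential(
                nn.Conv2d(mid, mid, 3, stride=2, padding=1, groups=mid,
                          bias=False),
                nn.BatchNorm2d(mid))
        else:
            self.down = nn.Identity()
        self.reduce = GhostBlock(mid, GhostConfig(cout), act=False)
        if s == 1 and cin == cout:
            self.shortcut = nn.Identity()
        else:
            self.shortcut = nn.Sequential(
                nn.Conv2d(cin, cin, 3, stride=s, padding=1, groups=cin,
                          bias=False),
                nn.BatchNorm2d(cin),
                nn.Conv2d(cin, cout, 1, bias=False),
                nn.BatchNorm2d(cout))

    def forward(self, x: Tensor) -> Tensor:
        main = self.reduce(self.down(self.ggc(x)))
        return main + self.shortcut(x)
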