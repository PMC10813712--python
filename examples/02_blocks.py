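"""Exercise the building blocks: ghost block, ghost coordinate attention,
and the residual GGC unit.

Prints the channel/shape contracts and the parameter saving of a ghost
block over the dense 3x3 convolution it replaces.
"""

import numpy as np

from rggcunet import nn
from rggcunet.blocks import (GCA, GCAConfig, GGCBlock, GhostBlock,
                             GhostConfig, RGGCBlock, RGGCConfig)
from rggcunet.nn.tensor import Tensor

nn.manual_seed(0)
x = Tensor(np.random.default_rng(0).normal(size=(1, 16, 32, 32)).astype(np.float32))

ghost = GhostBlock(16, GhostConfig(32))
y = ghost(x)
print(f"ghost block: 16ch -> {y.shape[1]}ch "
      f"({ghost.intrinsic_channels} intrinsic pointwise + "
      f"{y.shape[1] - ghost.intrinsic_channels} cheap depthwise)")

dense = nn.Conv2d(16, 32, 3, padding=1, bias=False)
n_ghost = sum(p.size for p in ghost.parameters())
n_dense = sum(p.size for p in dense.parameters())
print(f"parameters: ghost {n_ghost} vs dense 3x3 {n_dense} "
      f"({100 * n_ghost / n_dense:.0f}%)")

gca = GCA(GCAConfig(16, 32))
a_h, a_w = gca(x)
print(f"GCA attention maps: a_h {a_h.shape} (per-row), a_w {a_w.shape} "
      f"(per-column), all values in ({a_h.data.min():.3f}, "
      f"{a_h.data.max():.3f}) strictly inside (0,1)")

rggc = RGGCBlock(RGGCConfig(16, 32, 24, stride=2))
print(f"stride-2 RGGC: {x.shape} -> {rggc(x).shape} (downsampled residual unit)")
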