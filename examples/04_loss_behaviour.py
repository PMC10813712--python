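"""Why the class-wise Dice loss (CDL) instead of plain Dice.

On a lesion-free patch the foreground Dice ratio collapses: with no true
foreground, any false-positive prediction drives it to its floor at once,
so the plain Dice loss is stuck near 1 regardless of *how many* false
positives there are — a flat, uninformative penalty with an
epsilon-sized gradient.  The CDL instead scores the *background* overlap
on negative patches, so the penalty (and its gradient) grows smoothly
with the false-positive area.
"""

import numpy as np

from rggcunet.losses import class_wise_dice_loss, soft_dice

empty = np.zeros((32, 32))

def fp_sheet(n_pixels):
    p = np.zeros((32, 32))
    p.ravel()[:n_pixels] = 0.9
    return p

print("negative patch (no lesion), prediction with k false-positive pixels:")
print(f"{'k':>6} {'plain Dice loss':>16} {'CDL':>8}")
for k in (0, 16, 256, 1024):
    plain = 1 - soft_dice(fp_sheet(k), empty).item()
    cdl = class_wise_dice_loss(fp_sheet(k), empty).item()
    print(f"{k:6d} {plain:16.4f} {cdl:8.4f}")
print("-> plain Dice jumps to ~1 for any k>0 (flat penalty, no gradient");
print("   signal), CDL grows with the false-positive area.\n")

target = np.zeros((32, 32))
target[10:20, 10:20] = 1.0
print("positive patch:")
print(f"  CDL, perfect prediction : "
      f"{class_wise_dice_loss(target, target).item():.4f}")
print(f"  CDL, all-background     : "
      f"{class_wise_dice_loss(np.zeros_like(target), target).item():.4f}  "
      "<- missed lesion costs the full foreground term")
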