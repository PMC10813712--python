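"""Train a small network on synthetic patches and evaluate it.

Uses a narrow configuration (the full reference network is far larger) for
a quick CPU demonstration: 200 epochs on 16 small synthetic patches with a
held-out validation set (augmentation disabled for speed).  Expect the
training loss to fall below ~0.15 and the validation DSC to climb past 0.5
within about three minutes; a properly converged model needs the full
protocol (thousands of epochs at 128x128).
"""

from rggcunet.config import DataConfig, OptimizerConfig, RunConfig
from rggcunet.data import SynthConfig
from rggcunet.model import ModelConfig
from rggcunet.train import run_training

cfg = RunConfig(
    model=ModelConfig(stage_widths=(8, 16, 24, 32, 48), mid_expansion=2.0),
    data=DataConfig(synth=SynthConfig(patch_size=64, cell_radius=(8.0, 14.0)),
                    n_train=16, n_val=8, negative_fraction=0.25,
                    augment=False),
    optimizer=OptimizerConfig(beta1=0.9),
    epochs=200, batch_size=4, seed=0, val_every=20,
    output_dir="example_output/tiny_run")

model, history = run_training(cfg)
print("\nepoch  train_loss  val_dsc")
for row in history:
    if "val_dsc" in row:
        print(f"{row['epoch']:5d}  {row['train_loss']:10.4f}  "
              f"{row['val_dsc']:7.4f}")
print(f"\nbest checkpoint and metrics written to {cfg.output_dir}/")
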