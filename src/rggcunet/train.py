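"""Training, inference and evaluation loops.

``run_training`` optimises the class-wise Dice loss (with deep supervision)
using Adam, tracks the validation DSC, and keeps the best checkpoint next
to the fully resolved config.  Everything is seeded: data generation,
parameter initialisation, shuffling and augmentation all derive from
``RunConfig.seed``, so a run is reproducible from its config file alone.
"""

from __future__ import annotations

import csv
import logging
import time
from pathlib import Path

import numpy as np

from . import data as D
from . import nn
from .config import RunConfig, config_hash, save_run_config
from .losses import total_loss
from .metrics import confusion_counts, compute_metrics, evaluate_pairs, write_report
from .model import ModelConfig, NetworkOutput, RGGCUNet, build_model
from .nn.tensor import Tensor

log = logging.getLogger("rggcunet")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: RGGCUNet, path: str | Path,
                    cfg: RunConfig | None = None) -> None:
    """Serialise weights to ``path`` (.npz); the generating config is
    written as YAML next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    if cfg is not None:
        save_run_config(cfg, path.with_suffix(".yaml"))


def load_checkpoint(path: str | Path,
                    model_cfg: ModelConfig | None = None) -> RGGCUNet:
    path = Path(path)
    if model_cfg is None:
        from .config import load_run_config
        model_cfg = load_run_config(path.with_suffix(".yaml")).model
    model = build_model(model_cfg)
    with np.load(path) as npz:
        model.load_state_dict(dict(npz))
    return model


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _to_batch(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack (image, mask) pairs into (N,3,H,W), (N,H,W), (N,) arrays."""
    imgs = np.stack([np.transpose(img, (2, 0, 1)) for img, _ in samples])
    msks = np.stack([msk for _, msk in samples]).astype(np.float32)
    y_p = (msks.reshape(len(samples), -1).any(axis=1)).astype(np.float32)
    return imgs.astype(np.float32), msks, y_p


def _load_patch_set(manifest: str, patch_size: int, stride: int):
    pairs = D.read_manifest(manifest)
    out = []
    for img_path, msk_path in pairs:
        img = D.load_image(img_path)
        msk = D.load_mask(msk_path)
        if img.shape[:2] != msk.shape:
            log.error("size mismatch for %s vs %s; skipping", img_path, msk_path)
            continue
        if img.shape[0] == patch_size and img.shape[1] == patch_size:
            out.append((img, msk))
        else:
            for ip, mp, _off in D.dense_crop(img, msk, patch_size, stride):
                out.append((ip, mp))
    return out


def prepare_datasets(cfg: RunConfig):
    """Training/validation patch lists from manifests or the synthetic
    generator (train seeds and val seeds come from disjoint ranges)."""
    ps = cfg.data.synth.patch_size
    if cfg.data.train_manifest:
        train = _load_patch_set(cfg.data.train_manifest, ps,
                                cfg.data.crop_stride_train)
        val = (_load_patch_set(cfg.data.val_manifest, ps,
                               cfg.data.crop_stride_eval)
               if cfg.data.val_manifest else [])
    else:
        train = D.generate_dataset(cfg.data.synth, cfg.data.n_train,
                                   base_seed=cfg.seed * 100_000,
                                   negative_fraction=cfg.data.negative_fraction)
        val = D.generate_dataset(cfg.data.synth, cfg.data.n_val,
                                 base_seed=cfg.seed * 100_000 + 50_000,
                                 negative_fraction=cfg.data.negative_fraction)
    return train, val


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def validation_dsc(model: RGGCUNet, val_set) -> float:
    """Micro-averaged DSC of argmax predictions over a patch set."""
    if not val_set:
        return float("nan")
    model.eval()
    pooled = None
    for img, msk in val_set:
        x = np.transpose(img, (2, 0, 1))[None].astype(np.float32)
        prob = model(x).main.data[0]
        pred = prob.argmax(axis=0).astype(np.uint8)
        c = confusion_counts(pred, msk.astype(np.uint8))
        pooled = c if pooled is None else pooled + c
    model.train()
    return compute_metrics(pooled)["dsc"]


def run_training(cfg: RunConfig) -> tuple[RGGCUNet, list[dict]]:
    """Train a model under ``cfg``; returns (model, per-epoch history).

    Writes ``config.yaml``, ``history.csv``, a text log and the best
    checkpoint (by validation DSC; falls back to final weights when there
    is no validation set) into ``cfg.output_dir``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    save_run_config(cfg, out / "config.yaml")
    log.info("run config hash %s | numpy %s scipy %s", config_hash(cfg),
             np.__version__, _scipy_version())
    log.info("seed %d", cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    model = build_model(cfg.model, seed=cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.optimizer.lr,
                  beta1=cfg.optimizer.beta1, beta2=cfg.optimizer.beta2,
                  weight_decay=cfg.optimizer.weight_decay)
    train_set, val_set = prepare_datasets(cfg)
    if not train_set:
        raise ValueError("empty training set")

    history: list[dict] = []
    best_dsc, step = -1.0, 0
    ckpt = out / "best.npz"
    n = len(train_set)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_losses = []
        t0 = time.time()
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            samples = []
            for j in idx:
                img, msk = train_set[j]
                if cfg.data.augment:
                    img, msk = D.augment(img, msk,
                                         seed=int(rng.integers(2 ** 31)))
                samples.append((img, msk))
            x, masks, y_p = _to_batch(samples)
            output = model(x)
            loss = total_loss(output, masks, y_p, cfg.loss)
            if not np.isfinite(loss.item()):
                dump = out / f"nonfinite_batch_step{step}.npz"
                np.savez(dump, images=x, masks=masks, y_p=y_p)
                raise FloatingPointError(
                    f"non-finite loss at step {step}; offending batch "
                    f"dumped to {dump}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                break
        row = {"epoch": epoch, "step": step,
               "train_loss": float(np.mean(epoch_losses)),
               "seconds": round(time.time() - t0, 2)}
        if val_set and epoch % cfg.val_every == 0:
            row["val_dsc"] = validation_dsc(model, val_set)
            if row["val_dsc"] >= best_dsc:
                best_dsc = row["val_dsc"]
                save_checkpoint(model, ckpt, cfg)
        history.append(row)
        log.info("epoch %d: loss %.4f%s", epoch, row["train_loss"],
                 f" val_dsc {row['val_dsc']:.4f}" if "val_dsc" in row else "")
        if cfg.max_steps is not None and step >= cfg.max_steps:
            break
    if not ckpt.exists():
        save_checkpoint(model, ckpt, cfg)
    _write_history(history, out / "history.csv")
    return model, history


def _write_history(history: list[dict], path: Path) -> None:
    if not history:
        return
    fields = sorted({k for row in history for k in row})
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        w.writerows(history)


def _setup_logging(out: Path) -> None:
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            h.close()
            log.removeHandler(h)
    fh = logging.FileHandler(out / f"train_{int(time.time())}.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)


def _scipy_version() -> str:
    import scipy
    return scipy.__version__


# ---------------------------------------------------------------------------
# inference / evaluation
# ---------------------------------------------------------------------------

def predict_image(model: RGGCUNet, image: np.ndarray, patch_size: int = 128,
                  stride: int = 128) -> np.ndarray:
    """Class-probability map (C, H, W) for an arbitrary-size RGB image.

    Images at least ``patch_size`` wide/tall are densely cropped, predicted
    patchwise and stitched (overlaps averaged); smaller images are
    reflect-padded to a multiple of 16, predicted whole, and cropped back.
    """
    model.eval()
    H, W = image.shape[:2]
    if H < patch_size or W < patch_size:
        padded, (h0, w0) = D.pad_to_multiple(image, 16)
        x = np.transpose(padded, (2, 0, 1))[None].astype(np.float32)
        return model(x).main.data[0][:, :h0, :w0]
    padded, (h0, w0) = D.pad_to_multiple(image, 16)
    preds = []
    for ip, _m, off in D.dense_crop(padded, None, patch_size, stride):
        x = np.transpose(ip, (2, 0, 1))[None].astype(np.float32)
        preds.append((model(x).main.data[0], off))
    prob = D.stitch(preds, padded.shape[:2])
    return prob[:, :h0, :w0]


def run_evaluation(model: RGGCUNet, manifest: str | Path,
                   out_csv: str | Path | None = None,
                   patch_size: int = 128, stride: int = 128) -> dict:
    """Patchwise inference + stitching over a manifest; per-image and
    aggregate DSC/Jaccard/precision/recall, optionally written as CSV."""
    pairs = D.read_manifest(manifest)
    preds, trues, names = [], [], []
    for img_path, msk_path in pairs:
        img = D.load_image(img_path)
        msk = D.load_mask(msk_path)
        if img.shape[:2] != msk.shape:
            log.error("size mismatch for %s; skipping", img_path)
            continue
        prob = predict_image(model, img, patch_size, stride)
        preds.append(prob.argmax(axis=0).astype(np.uint8))
        trues.append(msk)
        names.append(Path(img_path).name)
    report = evaluate_pairs(zip(preds, trues), names=names)
    if out_csv is not None:
        write_report(report, out_csv)
    return report
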