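"""Training, inference and dataset evaluation orchestration.

Training follows a two-phase schedule: Adam with β = (0.9, 0.999) at
learning rate 0.003 up to the switch epoch (150 by default), then 0.0001.
Each image receives one randomly drawn augmentation per epoch, mini-batches
are reshuffled every epoch, a 9:1 train/validation split monitors progress,
and weights are checkpointed every ``checkpoint_every`` epochs plus whenever
the validation loss improves.  Everything is reproducible from the config
seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import dataio, evalmetrics
from .nn import Adam
from .network import ModelConfig, VesselSegmenter, build_model
from .objective import LossConfig, total_loss
from .sample import FundusSample

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "lr_at",
    "train",
    "predict",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
    "dice_score",
]


@dataclass
class TrainConfig:
    lr_initial: float = 0.003
    lr_after: float = 0.0001
    lr_switch_epoch: int = 150
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 150
    batch_size: int = 0          # 0: auto (8 at <=128 px, 2 otherwise)
    checkpoint_every: int = 20
    seed: int = 0
    split_ratio: float = 0.9
    augment: bool = True
    equalize: bool = True
    stop_at_train_dice: float | None = None

    def validate(self) -> "TrainConfig":
        if self.lr_initial <= 0 or self.lr_after <= 0:
            raise ValueError("learning rates must be > 0")
        if self.checkpoint_every < 1:
            raise ValueError("checkpoint_every must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        return self


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)
    best_checkpoint: str | None = None


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Phased learning rate: ``lr_initial`` through the switch epoch, then
    ``lr_after``."""
    if epoch < 1:
        raise ValueError(f"epochs are 1-based, got {epoch}")
    return config.lr_initial if epoch <= config.lr_switch_epoch \
        else config.lr_after


def dice_score(pred: np.ndarray, target: np.ndarray) -> float:
    """Hard Dice overlap of two binary masks (1.0 when both are empty)."""
    pred = np.asarray(pred).astype(bool)
    target = np.asarray(target).astype(bool)
    denom = pred.sum() + target.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(pred & target) / denom


# ---------------------------------------------------------------------------
# checkpoints: npz of weights + embedded JSON config snapshot
# ---------------------------------------------------------------------------

def save_checkpoint(model: VesselSegmenter, path,
                    extra: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"model": model.config.to_dict(), "extra": extra or {}}
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)
    return path


def load_checkpoint(path) -> tuple[VesselSegmenter, dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k[len("state/"):]: data[k] for k in data.files
                 if k.startswith("state/")}
    model = build_model(ModelConfig.from_dict(meta["model"]))
    try:
        model.load_state_dict(state)
    except (KeyError, ValueError) as exc:
        raise ValueError(
            f"checkpoint {path} does not match the configured model: {exc}"
        ) from None
    return model, meta.get("extra", {})


# ---------------------------------------------------------------------------
# preprocessing shared by train / predict
# ---------------------------------------------------------------------------

def _prepare_image(image: np.ndarray, use_equalize: bool) -> np.ndarray:
    x = dataio.normalize(image)
    if use_equalize:
        x = dataio.equalize(x)
    return np.ascontiguousarray(x.transpose(2, 0, 1)).astype(np.float32)


def _batch_arrays(samples: list[FundusSample], use_equalize: bool
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs = np.stack([_prepare_image(s.image, use_equalize) for s in samples])
    gs = np.stack([s.vessel_mask[None].astype(np.float32) for s in samples])
    fovs = np.stack([s.fov_mask for s in samples])
    return xs, gs, fovs


def _resolve_samples(dataset) -> list[FundusSample]:
    if isinstance(dataset, (str, Path)):
        samples = dataio.load_dataset(dataset)
    else:
        samples = list(dataset)
    if not samples:
        raise ValueError("empty dataset")
    return samples


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(dataset, config: TrainConfig,
          model_config: ModelConfig | None = None,
          loss_config: LossConfig | None = None,
          out_dir=None, verbose: bool = False
          ) -> tuple[VesselSegmenter, TrainHistory]:
    """Train a model on a dataset directory or a list of samples."""
    config.validate()
    loss_config = (loss_config or LossConfig()).validate()
    samples = _resolve_samples(dataset)
    by_id = {s.sample_id: s for s in samples}
    if len(samples) >= 2 and config.split_ratio < 1.0:
        train_ids, val_ids = dataio.split_train_val(
            list(by_id), config.split_ratio)
    else:
        # split_ratio >= 1 trains on everything (overfit experiments)
        train_ids, val_ids = sorted(by_id), []
    train_samples = [by_id[i] for i in train_ids]
    val_samples = [by_id[i] for i in val_ids]

    model_config = model_config or ModelConfig()
    d = model_config.to_dict()
    d["seed"] = config.seed
    model = build_model(d)

    side = max(samples[0].native_height, samples[0].native_width)
    batch_size = config.batch_size or (8 if side <= 128 else 2)

    optimizer = Adam(model.parameters(), lr=config.lr_initial,
                     betas=(config.beta1, config.beta2))
    history = TrainHistory()
    out_dir = Path(out_dir) if out_dir is not None else None
    best_val = np.inf

    for epoch in range(1, config.epochs + 1):
        optimizer.lr = lr_at(epoch, config)
        rng = np.random.default_rng([config.seed & 0x7FFFFFFF, epoch])
        order = rng.permutation(len(train_samples))
        model.train()
        epoch_loss = 0.0
        inter = 0
        denom = 0
        n_batches = 0
        for start in range(0, len(order), batch_size):
            batch = [train_samples[i] for i in order[start:start + batch_size]]
            if config.augment:
                batch = [dataio.augment_random(s, rng)[0] for s in batch]
            xs, gs, _ = _batch_arrays(batch, config.equalize)
            out = model.forward(xs)
            loss, _ = total_loss(out, gs, loss_config)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item()
            n_batches += 1
            main = out[0] if isinstance(out, list) else out
            pred = main.data >= 0.5
            inter += np.count_nonzero(pred & (gs >= 0.5))
            denom += int(pred.sum() + (gs >= 0.5).sum())
        train_dice = 2.0 * inter / denom if denom else 1.0
        train_loss = epoch_loss / max(n_batches, 1)

        val_loss, val_acc = np.nan, np.nan
        if val_samples:
            val_loss, val_acc = _validate(model, val_samples, config,
                                          loss_config)
        history.epochs.append(epoch)
        history.train_loss.append(train_loss)
        history.train_dice.append(train_dice)
        history.val_loss.append(float(val_loss))
        history.val_acc.append(float(val_acc))
        history.lr.append(optimizer.lr)
        if verbose:
            print(f"epoch {epoch:4d}  loss {train_loss:.4f}  "
                  f"dice {train_dice:.4f}  val_loss {val_loss:.4f}")

        if out_dir is not None:
            if epoch % config.checkpoint_every == 0 or epoch == config.epochs:
                p = save_checkpoint(model,
                                    out_dir / "checkpoints" / f"epoch_{epoch:04d}.npz",
                                    {"epoch": epoch})
                history.checkpoints.append(str(p))
            if val_samples and val_loss < best_val:
                best_val = val_loss
                p = save_checkpoint(model, out_dir / "checkpoints" / "best.npz",
                                    {"epoch": epoch, "val_loss": float(val_loss)})
                history.best_checkpoint = str(p)
        if (config.stop_at_train_dice is not None
                and train_dice >= config.stop_at_train_dice):
            break

    if out_dir is not None:
        _write_history(history, out_dir / "history.csv")
        if not history.checkpoints:
            p = save_checkpoint(model, out_dir / "checkpoints" / "final.npz",
                                {"epoch": history.epochs[-1]})
            history.checkpoints.append(str(p))
    return model, history


def _validate(model, val_samples, config, loss_config):
    model.eval()
    losses, accs = [], []
    for s in val_samples:
        xs, gs, fovs = _batch_arrays([s], config.equalize)
        probs = model.predict_proba(xs)
        loss, _ = total_loss(probs.astype(np.float64), gs.astype(np.float64),
                             loss_config)
        losses.append(float(loss))
        counts = evalmetrics.confusion(probs[0, 0], s.vessel_mask, s.fov_mask)
        accs.append(evalmetrics.metrics_from_confusion(counts).acc)
    model.train()
    return float(np.mean(losses)), float(np.mean(accs))


def _write_history(history: TrainHistory, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "train_dice", "val_loss",
                         "val_acc", "lr"])
        for row in zip(history.epochs, history.train_loss, history.train_dice,
                       history.val_loss, history.val_acc, history.lr):
            writer.writerow(row)


# ---------------------------------------------------------------------------
# inference and evaluation
# ---------------------------------------------------------------------------

def _infer_sample(model: VesselSegmenter, sample: FundusSample,
                  use_equalize: bool) -> np.ndarray:
    xs = _prepare_image(sample.image, use_equalize)[None]
    return model.predict_proba(xs)[0, 0]


def predict(checkpoint, image_paths, out_dir, threshold: float = 0.5,
            use_equalize: bool = True) -> list[dict]:
    """Run inference and write probability and binary-mask PNGs.

    Probability maps are stored as 16-bit PNGs, thresholded masks as 8-bit
    {0,255} PNGs, both at the image's native resolution.
    """
    model, _ = (checkpoint, {}) if isinstance(checkpoint, VesselSegmenter) \
        else load_checkpoint(checkpoint)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = []
    for path in image_paths:
        path = Path(path)
        image = dataio._to_unit_float(iio.imread(path))
        if image.ndim == 2:
            image = np.stack([image] * 3, axis=-1)
        sample = FundusSample(image=image[..., :3],
                              vessel_mask=np.zeros(image.shape[:2], np.uint8),
                              fov_mask=np.ones(image.shape[:2], np.uint8),
                              native_height=image.shape[0],
                              native_width=image.shape[1],
                              sample_id=path.stem)
        prob = _infer_sample(model, sample, use_equalize)
        prob_path = out / f"{path.stem}_prob.png"
        mask_path = out / f"{path.stem}_mask.png"
        iio.imwrite(prob_path,
                    np.round(prob * 65535).astype(np.uint16))
        iio.imwrite(mask_path,
                    ((prob >= threshold) * 255).astype(np.uint8))
        results.append({"id": path.stem, "prob": str(prob_path),
                        "mask": str(mask_path)})
    return results


def evaluate(checkpoint, dataset, out_dir=None, threshold: float = 0.5,
             use_equalize: bool = True) -> dict:
    """Evaluate a checkpoint (or model) against a labelled dataset.

    Returns the aggregated metrics summary (pooled + per-image mean ± std)
    and, when ``out_dir`` is given, writes the per-image CSV and JSON
    summary.
    """
    model, _ = (checkpoint, {}) if isinstance(checkpoint, VesselSegmenter) \
        else load_checkpoint(checkpoint)
    samples = _resolve_samples(dataset)
    per_image = []
    for s in samples:
        prob = _infer_sample(model, s, use_equalize)
        counts = evalmetrics.confusion(prob, s.vessel_mask, s.fov_mask,
                                       threshold)
        entry = {"id": s.sample_id, "counts": counts}
        vessel_frac = s.vessel_mask[s.fov_mask.astype(bool)].mean()
        if 0.0 < vessel_frac < 1.0:
            entry["auc"], _ = evalmetrics.roc_auc(prob, s.vessel_mask,
                                                  s.fov_mask)
        per_image.append(entry)
    summary = evalmetrics.aggregate_over_dataset(per_image)
    if out_dir is not None:
        evalmetrics.write_reports(summary, out_dir)
    return summary
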