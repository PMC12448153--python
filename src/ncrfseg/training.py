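"""Training recipe: normalisation, augmentation, loss, optimisation.

Per-patient z-scoring for T2w-like intensities and [0, 1] rescaling for
auxiliary channels; centre crop / horizontal flip / gamma augmentation;
cross-entropy loss with Adam, weight-decay regularisation and per-step
gradient clipping; checkpoint selection by validation mean foreground
Dice.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor
from .model import SegmentationModel


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    gradient_clip: float = 0.01
    clip_mode: str = "norm"            # "norm" (global L2) or "value"
    epochs: int = 200
    batch_size: int = 8
    seed: int = 0
    crop_size: int | None = None
    flip: bool = True
    gamma: bool = True
    gamma_range: tuple = (0.7, 1.5)
    log_path: str | None = None

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay, self.gradient_clip) < 0:
            raise ValueError("rates must be non-negative")
        if self.clip_mode not in ("norm", "value"):
            raise ValueError("clip_mode must be 'norm' or 'value'")


@dataclass
class NormalizedVolume:
    values: np.ndarray
    method: str
    stats: tuple


def normalize_zscore(volume: np.ndarray) -> NormalizedVolume:
    """Per-patient standardisation: (I - mu) / sigma over the whole volume."""
    volume = np.asarray(volume, dtype=np.float64)
    mu = float(volume.mean())
    sigma = float(volume.std())
    if sigma == 0:
        raise ValueError("constant volume: standard deviation is zero")
    return NormalizedVolume((volume - mu) / sigma, "zscore", (mu, sigma))


def normalize_minmax(volume: np.ndarray) -> NormalizedVolume:
    """Per-patient rescaling to [0, 1]."""
    volume = np.asarray(volume, dtype=np.float64)
    vmin, vmax = float(volume.min()), float(volume.max())
    if vmax == vmin:
        raise ValueError("constant volume: min equals max")
    return NormalizedVolume((volume - vmin) / (vmax - vmin), "minmax",
                            (vmin, vmax))


def augment(image: np.ndarray, mask: np.ndarray, config: TrainConfig,
            rng: np.random.Generator):
    """Centre crop, joint horizontal flip (p=0.5), gamma transform (image only).

    The gamma transform maps the slice's own [min, max] range through a
    power law, so it is monotone, leaves the range endpoints in place, and
    is the identity at exponent 1 even for standardised (negative-valued)
    intensities.  Mask labels are never interpolated.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if config.crop_size is not None:
        ch = cw = config.crop_size
        h, w = image.shape[-2:]
        if ch > h or cw > w:
            raise ValueError(f"crop {ch} exceeds image size ({h}, {w})")
        top, left = (h - ch) // 2, (w - cw) // 2
        image = image[..., top:top + ch, left:left + cw]
        mask = mask[..., top:top + ch, left:left + cw]
    if config.flip and rng.random() < 0.5:
        image = image[..., ::-1].copy()
        mask = mask[..., ::-1].copy()
    if config.gamma:
        exponent = rng.uniform(*config.gamma_range)
        lo, hi = image.min(), image.max()
        if hi > lo:
            image = lo + (hi - lo) * ((image - lo) / (hi - lo)) ** exponent
    return image, mask


def cross_entropy(logq: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood; logq (B, H, W, K), labels (B, H, W)."""
    k = logq.shape[-1]
    onehot = np.eye(k, dtype=logq.dtype)[labels]
    return (logq * onehot).sum() * (-1.0 / labels.size)


@dataclass
class TrainResult:
    model: SegmentationModel
    history: list = field(repr=False)
    best_epoch: int = -1
    best_val_dsc: float = float("nan")


def _patient_slices(patients, in_channels: int):
    """Normalise per patient and flatten to ((H, W) image, label) pairs."""
    pairs = []
    for p in patients:
        norm = normalize_zscore(p.volume).values
        for img, lab in zip(norm, p.mask):
            pairs.append((img, lab.astype(np.int64)))
    return pairs


def mean_foreground_dsc(model: SegmentationModel, patients) -> float:
    """Per-patient 3D Dice over foreground classes, averaged."""
    from .metrics import PatientMasks, dsc
    scores = []
    for p in patients:
        norm = normalize_zscore(p.volume).values
        pred = model.predict_volume(norm.astype(model.dtype))
        masks = PatientMasks(pred, p.mask, p.spacing)
        per_class = [dsc(masks, c) for c in range(1, model.config.n_classes)]
        scores.append(float(np.mean(per_class)))
    return float(np.mean(scores))


def train(model: SegmentationModel, dataset, config: TrainConfig) -> TrainResult:
    """Run the optimisation loop; the model ends holding the best-validation
    parameters (or the final ones if no validation split is given)."""
    if isinstance(dataset, dict):
        train_patients = dataset["train"]
        val_patients = dataset.get("val", [])
    else:
        train_patients, val_patients = list(dataset), []
    in_channels = model.config.backbone.in_channels
    pairs = _patient_slices(train_patients, in_channels)
    if not pairs:
        raise ValueError("empty training set")

    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    opt = nn.Adam(params, lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history = []
    best_state, best_dsc, best_epoch = None, -np.inf, -1

    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            images, labels = [], []
            for idx in batch_idx:
                img, lab = augment(*pairs[idx], config, rng)
                images.append(img)
                labels.append(lab)
            x = np.stack(images).astype(model.dtype)[..., None]
            if in_channels > 1:
                x = np.repeat(x, in_channels, axis=-1)
            x = Tensor(x)
            y = np.stack(labels)
            logq, _ = model.forward(x)
            loss = cross_entropy(logq, y)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            if config.gradient_clip > 0:
                if config.clip_mode == "norm":
                    nn.clip_grad_norm(params, config.gradient_clip)
                else:
                    for p in params:
                        if p.grad is not None:
                            p.grad = np.clip(p.grad, -config.gradient_clip,
                                             config.gradient_clip)
            opt.step()
            losses.append(value)

        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_patients:
            val_dsc = mean_foreground_dsc(model, val_patients)
            record["val_dsc"] = val_dsc
            if val_dsc > best_dsc:
                best_dsc, best_epoch = val_dsc, epoch
                best_state = model.state_dict()
        history.append(record)

    if best_state is not None:
        model.load_state_dict(best_state)
    if config.log_path:
        path = Path(config.log_path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as handle:
            fields = sorted({k for rec in history for k in rec})
            writer = csv.DictWriter(handle, fieldnames=fields)
            writer.writeheader()
            writer.writerows(history)
    return TrainResult(model, history, best_epoch,
                       best_dsc if np.isfinite(best_dsc) else float("nan"))
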