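"""Training schedule, loop, history logging, and the ablation harness.

The schedule follows the original recipe: Adam with He-initialized
weights, initial learning rate 1e-3 decayed by 0.98 per epoch and restored
to 1e-3 every 100 epochs (warm restarts), L2 weight decay 1e-4 added to
the loss, minibatches of 16 images with drop-last batching, per-epoch
shuffling, on-the-fly augmentation of each minibatch (never persisted),
per-epoch validation, and selection of the weights with the highest
validation mean Dice.  With 1902 training images this presents
118 * 16 * 200 = 377 600 (augmented) images to the network over 200 epochs.

`Segmenter` / `FitResult` wrap the same loop in a fit-then-inspect shape:
``Segmenter(spec, config).fit(train, valid, root)`` returns a result object
carrying the trained network, the learning curves and a ``summary()``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .augment import AugmentConfig, augment_minibatch_arrays
from .dataio import GrayImage, LabelMap, Manifest, read_image, read_label
from .errors import ContractError
from .losses import LOSS_VARIANTS, batch_loss_and_grad
from .metrics import MetricsReport, evaluate, mean_foreground_dice
from .model import NetSpec, Network, build_network, count_parameters, probs_to_labels
from .nn import F32, Adam
from .preprocess import PreprocessConfig, preprocess_pipeline, resize_label


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    lr_decay: float = 0.98  # per-epoch multiplicative decay
    restart_period: int = 100  # epochs between learning-rate restarts
    weight_decay: float = 1e-4  # L2 coefficient added to the loss
    minibatch: int = 16
    max_epochs: int = 200
    loss_variant: str = "igd"  # igd | gdl | ce
    augment: bool = True
    patience: int = 50  # early stop on stalled validation Dice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.lr_decay <= 0 or self.weight_decay < 0:
            raise ContractError("rates must be positive (weight decay non-negative)")
        if self.minibatch < 1 or self.restart_period < 1:
            raise ContractError("minibatch and restart period must be >= 1")
        self.max_epochs = max(1, self.max_epochs)  # at least one epoch always runs
        if self.loss_variant not in LOSS_VARIANTS:
            raise ContractError(f"unknown loss variant {self.loss_variant!r}")


@dataclass
class TrainHistory:
    """Per-epoch learning curves."""

    train_loss: list[float] = field(default_factory=list)
    train_dice: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    valid_dice: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_table(self) -> str:
        out = io.StringIO()
        out.write("epoch\tlr\ttrain_loss\ttrain_dice\tvalid_loss\tvalid_dice\n")
        for i in range(len(self)):
            out.write(
                f"{i + 1}\t{self.learning_rate[i]:.6g}\t{self.train_loss[i]:.6f}\t"
                f"{self.train_dice[i]:.6f}\t{self.valid_loss[i]:.6f}\t{self.valid_dice[i]:.6f}\n"
            )
        return out.getvalue()


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Decayed learning rate with warm restarts:
    lr = initial * decay^((epoch - 1) mod restart_period), epoch 1-based."""
    if epoch < 1:
        raise ContractError("epoch index is 1-based")
    return config.initial_lr * config.lr_decay ** ((epoch - 1) % config.restart_period)


def images_seen(n_train: int, minibatch: int, epochs: int) -> int:
    """Augmented images presented to the network under drop-last batching."""
    if n_train < 1 or minibatch < 1 or epochs < 1:
        raise ContractError("all counts must be >= 1")
    return (n_train // minibatch) * minibatch * epochs


def smooth_history(history: TrainHistory, window: int) -> TrainHistory:
    """Centered moving average with edge truncation; window 1 is identity."""
    if window < 1:
        raise ContractError("window must be >= 1")

    def smooth(series: list[float]) -> list[float]:
        n = len(series)
        h = window // 2
        arr = np.asarray(series, dtype=np.float64)
        return [float(arr[max(0, i - h) : min(n, i + h + 1)].mean()) for i in range(n)]

    return TrainHistory(
        train_loss=smooth(history.train_loss),
        train_dice=smooth(history.train_dice),
        valid_loss=smooth(history.valid_loss),
        valid_dice=smooth(history.valid_dice),
        learning_rate=smooth(history.learning_rate),
    )


# ---------------------------------------------------------------------------
# data loading


def load_split_arrays(
    manifest: Manifest,
    root: str | Path,
    rows: int,
    cols: int,
    preprocess: PreprocessConfig | None = None,
    label_encoding: str = "internal",
) -> tuple[np.ndarray, np.ndarray]:
    """Load and preprocess every record of a manifest into stacked arrays:
    unit-float images (N, rows, cols) and labels (N, rows, cols)."""
    if len(manifest) == 0:
        raise ContractError("empty manifest")
    pconf = preprocess or PreprocessConfig(target_rows=rows, target_cols=cols)
    if (pconf.target_rows, pconf.target_cols) != (rows, cols):
        pconf = replace(pconf, target_rows=rows, target_cols=cols)
    root = Path(root)
    images = np.empty((len(manifest), rows, cols), dtype=F32)
    labels = np.empty((len(manifest), rows, cols), dtype=np.int64)
    for i, rec in enumerate(manifest.records):
        img = preprocess_pipeline(read_image(root / rec.image), pconf)
        images[i] = img.pixels
        if rec.label is None:
            raise ContractError(f"record {rec.image} has no label; cannot train/evaluate")
        lab = resize_label(read_label(root / rec.label, label_encoding), rows, cols)
        labels[i] = lab.labels
    return images, labels


# ---------------------------------------------------------------------------
# the loop


def _forward_eval(net: Network, images: np.ndarray, batch: int) -> np.ndarray:
    """Deterministic inference over a stack, returning probabilities."""
    chunks = []
    for start in range(0, images.shape[0], batch):
        x = images[start : start + batch, :, :, None]
        chunks.append(net.forward(x, train=False))
    return np.concatenate(chunks, axis=0)


def train(
    net: Network,
    train_manifest: Manifest,
    valid_manifest: Manifest,
    config: TrainConfig,
    root: str | Path,
    augment_config: AugmentConfig | None = None,
    preprocess: PreprocessConfig | None = None,
    verbose: bool = False,
) -> tuple[Network, TrainHistory]:
    """Train ``net`` on the manifests and return it holding the weights of
    the epoch with the highest validation mean Dice, plus the full history.

    Fully reproducible for fixed (seed, config, manifests) on one device.
    Nothing is written to disk; augmented minibatches live only in memory.
    """
    if len(valid_manifest) == 0:
        raise ContractError("validation manifest must be non-empty")
    rows, cols = net.spec.rows, net.spec.cols
    x_train, y_train = load_split_arrays(train_manifest, root, rows, cols, preprocess)
    x_valid, y_valid = load_split_arrays(valid_manifest, root, rows, cols, preprocess)
    n = x_train.shape[0]
    if n < config.minibatch:
        raise ContractError(
            f"training set ({n}) smaller than one minibatch ({config.minibatch})"
        )
    aug = augment_config or AugmentConfig()
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(net.parameters(), weight_decay=config.weight_decay)

    history = TrainHistory()
    best_dice = -np.inf
    best_state: dict[str, np.ndarray] | None = None
    since_best = 0
    n_batches = n // config.minibatch

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_schedule(epoch, config)
        perm = rng.permutation(n)
        epoch_loss, epoch_dice = 0.0, 0.0
        for b in range(n_batches):
            idx = perm[b * config.minibatch : (b + 1) * config.minibatch]
            imgs, labs = x_train[idx], y_train[idx]
            if config.augment:
                imgs, labs, _ = augment_minibatch_arrays(imgs, labs, aug, rng)
            probs = net.forward(imgs[:, :, :, None], train=True, rng=rng)
            loss, dprobs = batch_loss_and_grad(probs, labs, config.loss_variant)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {b}: {loss}"
                )
            penalty = 0.5 * config.weight_decay * sum(
                float((p.value**2).sum()) for p in optimizer.params if p.decay
            )
            optimizer.zero_grad()
            net.backward(dprobs.astype(F32))
            optimizer.step(lr)
            epoch_loss += loss + penalty
            epoch_dice += mean_foreground_dice(probs_to_labels(probs), labs)
        val_probs = _forward_eval(net, x_valid, config.minibatch)
        val_loss, _ = batch_loss_and_grad(val_probs, y_valid, config.loss_variant)
        val_dice = mean_foreground_dice(probs_to_labels(val_probs), y_valid)

        history.train_loss.append(epoch_loss / n_batches)
        history.train_dice.append(epoch_dice / n_batches)
        history.valid_loss.append(float(val_loss))
        history.valid_dice.append(float(val_dice))
        history.learning_rate.append(lr)
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {lr:.2e}  train loss {history.train_loss[-1]:.4f} "
                f"dice {history.train_dice[-1]:.4f}  valid loss {val_loss:.4f} "
                f"dice {val_dice:.4f}"
            )

        if val_dice > best_dice:
            best_dice = val_dice
            best_state = net.copy_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    if best_state is not None:
        net.load_state_arrays(best_state)
    return net, history


def plot_history(history: TrainHistory, path: str | Path, smooth_window: int = 1) -> None:
    """Write Dice and loss learning curves (optionally moving-average
    smoothed) to an image file.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = smooth_history(history, smooth_window) if smooth_window > 1 else history
    epochs = np.arange(1, len(shown) + 1)
    fig, (ax_dice, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    ax_dice.plot(epochs, shown.train_dice, label="train (minibatch)")
    ax_dice.plot(epochs, shown.valid_dice, label="validation")
    ax_dice.set_xlabel("epoch")
    ax_dice.set_ylabel("mean Dice")
    ax_dice.legend()
    ax_loss.plot(epochs, shown.train_loss, label="train")
    ax_loss.plot(epochs, shown.valid_loss, label="validation")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("loss")
    ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# ablation harness (model x loss x augmentation comparison grid)


@dataclass
class AblationArm:
    model: str  # "proposed" | "unet"
    loss_variant: str  # "igd" | "gdl" | "ce"
    augment: bool

    @property
    def name(self) -> str:
        tag = "Proposed" if self.model == "proposed" else "U-Net"
        suffix = "+DA" if self.augment else ""
        return f"{tag}+{self.loss_variant.upper()}{suffix}"


def run_ablation(
    arms: Sequence[AblationArm],
    train_manifest: Manifest,
    valid_manifest: Manifest,
    test_manifest: Manifest,
    config: TrainConfig,
    root: str | Path,
    proposed_spec: NetSpec | None = None,
    unet_spec: NetSpec | None = None,
    augment_config: AugmentConfig | None = None,
) -> list[tuple[AblationArm, MetricsReport, MetricsReport]]:
    """Train every arm with the same seed and data, evaluate on the
    validation and test splits, and return per-arm metric reports."""
    if len(arms) == 0:
        raise ContractError("need at least one arm")
    proposed_spec = proposed_spec or NetSpec()
    unet_spec = unet_spec or dataclasses.replace(proposed_spec, block="double")
    rows_out = []
    for arm in arms:
        spec = proposed_spec if arm.model == "proposed" else unet_spec
        net = build_network(spec, seed=config.seed)
        arm_config = replace(config, loss_variant=arm.loss_variant, augment=arm.augment)
        net, _ = train(net, train_manifest, valid_manifest, arm_config, root, augment_config)
        reports = []
        for manifest in (valid_manifest, test_manifest):
            x, y = load_split_arrays(manifest, root, spec.rows, spec.cols)
            preds = probs_to_labels(_forward_eval(net, x, config.minibatch))
            reports.append(evaluate(list(preds), list(y)))
        rows_out.append((arm, reports[0], reports[1]))
    return rows_out


def ablation_table(rows: Sequence[tuple[AblationArm, MetricsReport, MetricsReport]]) -> str:
    lines = ["arm\tsplit\tclass\tdice\tiou"]
    for arm, valid_report, test_report in rows:
        for split, report in (("valid", valid_report), ("test", test_report)):
            for k, cm in sorted(report.per_class.items()):
                lines.append(f"{arm.name}\t{split}\t{k}\t{cm.dice_mean:.4f}\t{cm.iou_mean:.4f}")
            lines.append(f"{arm.name}\t{split}\tmean\t{report.mean_dice:.4f}\t{report.mean_iou:.4f}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# model/results facade


class Segmenter:
    """Fit-style wrapper: construct with the architecture and schedule,
    call :meth:`fit` with data manifests, inspect the returned result."""

    def __init__(
        self,
        spec: NetSpec | None = None,
        config: TrainConfig | None = None,
        augment_config: AugmentConfig | None = None,
        preprocess: PreprocessConfig | None = None,
    ):
        self.spec = spec or NetSpec()
        self.config = config or TrainConfig()
        self.augment_config = augment_config
        self.preprocess = preprocess

    def fit(
        self, train_manifest: Manifest, valid_manifest: Manifest, root: str | Path
    ) -> "FitResult":
        net = build_network(self.spec, seed=self.config.seed)
        net, history = train(
            net,
            train_manifest,
            valid_manifest,
            self.config,
            root,
            self.augment_config,
            self.preprocess,
        )
        return FitResult(net, history, self.config)


@dataclass
class FitResult:
    """A trained segmenter with its learning curves."""

    network: Network
    history: TrainHistory
    config: TrainConfig

    @property
    def best_epoch(self) -> int:
        return int(np.argmax(self.history.valid_dice)) + 1

    @property
    def best_valid_dice(self) -> float:
        return float(np.max(self.history.valid_dice))

    def predict(self, image: GrayImage) -> LabelMap:
        from .model import predict as _predict

        return _predict(self.network, image)

    def evaluate(self, manifest: Manifest, root: str | Path) -> MetricsReport:
        x, y = load_split_arrays(manifest, root, self.network.spec.rows, self.network.spec.cols)
        preds = probs_to_labels(_forward_eval(self.network, x, self.config.minibatch))
        return evaluate(list(preds), list(y))

    def summary(self) -> str:
        spec = self.network.spec
        lines = [
            "Segmentation fit summary",
            "========================",
            f"architecture        {spec.block} encoder-decoder, base {spec.base_width}, "
            f"{spec.levels} levels, input {spec.rows}x{spec.cols}, K={spec.n_classes}",
            f"parameters          {count_parameters(self.network):,}",
            f"loss                {self.config.loss_variant.upper()}"
            f"{' + augmentation' if self.config.augment else ''}",
            f"epochs run          {len(self.history)} (max {self.config.max_epochs})",
            f"best epoch          {self.best_epoch}",
            f"best valid Dice     {self.best_valid_dice:.4f}",
            f"final train loss    {self.history.train_loss[-1]:.4f}",
        ]
        return "\n".join(lines)
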