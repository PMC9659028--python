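"""Patch sampling, optimization schedule, and retraining strategies.

Training follows a plateau schedule: Adam at an initial learning rate
of 1e-4, categorical cross-entropy with L2 weight 1e-4, the learning
rate divided by 10 after 4 consecutive epochs without a strictly better
validation accuracy, early stopping after 20 such epochs, and at most
200 epochs; the checkpoint with the best validation accuracy is kept.
Each epoch draws a fresh random patch set (the full-scale default is
262,144 patches per epoch for training and validation individually)
with a 20/80 tumor/healthy mix.

Three retraining strategies against domain shift compose freely:
retrain from scratch on pooled data vs fine-tune the base model on
local data only; uniform patch sampling vs upweighting local slides;
and hard negative mining, which oversamples healthy patches from
mask-code-3 regions that an earlier model falsely flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from lymphmet.augment import AugmentParams, augment
from lymphmet.network.densenet import DenseNet, NetworkConfig, build_network
from lymphmet.network.layers import Param, softmax as _softmax
from lymphmet.synthetic import CODE_HARD_NEGATIVE, CODE_HEALTHY, CODE_TUMOR


@dataclass
class TrainConfig:
    l2_weight: float = 1e-4
    lr_init: float = 1e-4
    lr_drop_factor: float = 10.0
    lr_patience_epochs: int = 4
    early_stop_patience: int = 20
    max_epochs: int = 200
    patches_per_epoch: int = 262_144
    tumor_fraction: float = 0.20
    patch_px: int = 279
    batch_size: int = 32
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.lr_patience_epochs >= self.max_epochs or \
                self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience values must be < max_epochs")


@dataclass
class StrategyConfig:
    transfer_mode: str = "scratch_pooled"  # scratch_pooled | finetune_local
    sampling_mode: str = "uniform"  # uniform | local_upweighted
    local_upweight_factor: float = 1.0
    hnm_enabled: bool = False
    hnm_code_sampling_weight: float = 4.0  # weight of mask code 3 vs code 1

    def __post_init__(self) -> None:
        if self.transfer_mode not in ("scratch_pooled", "finetune_local"):
            raise ValueError(f"unknown transfer_mode {self.transfer_mode}")
        if self.sampling_mode not in ("uniform", "local_upweighted"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode}")
        if self.local_upweight_factor < 1.0:
            raise ValueError("local_upweight_factor must be >= 1")
        if self.hnm_code_sampling_weight < 0.0:
            raise ValueError("hnm_code_sampling_weight must be >= 0")


# --------------------------------------------------------------------------
# plateau schedule (pure function of the validation-accuracy sequence)
# --------------------------------------------------------------------------


class PlateauSchedule:
    """Learning-rate plateau drops and early stopping.

    "No improvement" means not strictly greater than the best value so
    far.  The drop-patience counter resets after each drop; the
    early-stop counter only resets on improvement.
    """

    def __init__(self, config: TrainConfig):
        self.config = config
        self.lr = config.lr_init
        self.best: float | None = None
        self.best_epoch: int | None = None
        self._bad_lr = 0
        self._bad_stop = 0

    def update(self, epoch: int, val_acc: float) -> tuple[float, bool, bool]:
        """Returns (lr for the next epoch, stop flag, improved flag)."""
        improved = self.best is None or val_acc > self.best
        if improved:
            self.best = val_acc
            self.best_epoch = epoch
            self._bad_lr = 0
            self._bad_stop = 0
        else:
            self._bad_lr += 1
            self._bad_stop += 1
            if self._bad_lr >= self.config.lr_patience_epochs:
                self.lr /= self.config.lr_drop_factor
                self._bad_lr = 0
        stop = (self._bad_stop >= self.config.early_stop_patience
                or epoch >= self.config.max_epochs)
        return self.lr, stop, improved


def run_schedule(val_accuracies: Sequence[float], config: TrainConfig
                 ) -> pd.DataFrame:
    """Replay the schedule over a validation-accuracy sequence."""
    sched = PlateauSchedule(config)
    rows = []
    lr_in = sched.lr
    for epoch, acc in enumerate(val_accuracies, start=1):
        lr_out, stop, improved = sched.update(epoch, acc)
        rows.append({"epoch": epoch, "lr": lr_in, "val_acc": acc,
                     "improved": improved, "next_lr": lr_out, "stop": stop})
        lr_in = lr_out
        if stop:
            break
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# epoch sampling
# --------------------------------------------------------------------------


@dataclass
class SlideSource:
    """One training slide: raster, label mask, and its provenance."""

    slide_id: str
    tissue: np.ndarray
    mask: np.ndarray  # uint8 codes 0/1/2/3
    local: bool = False  # belongs to the local (upweighted) datasets


def sample_epoch(
    sources: Sequence[SlideSource],
    config: TrainConfig,
    strategy: StrategyConfig,
    seed: int,
    n_patches: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one epoch of labelled patches.

    Patch labels follow a Bernoulli(tumor_fraction) draw; a slide is
    then chosen with probability proportional to its (weighted) count
    of candidate pixels of that class, and the patch is cut around a
    uniformly chosen candidate pixel.  Local upweighting multiplies
    every local slide-pixel's weight by the configured factor; hard
    negative mining multiplies code-3 (hard-negative) pixels' weight
    within the healthy class.
    """
    rng = np.random.default_rng(seed)
    n_patches = config.patches_per_epoch if n_patches is None else n_patches
    half = config.patch_px // 2
    upw = (strategy.local_upweight_factor
           if strategy.sampling_mode == "local_upweighted" else 1.0)
    w3 = strategy.hnm_code_sampling_weight if strategy.hnm_enabled else 1.0

    tumor_pools = []  # (source index, pixel indices, slide weight)
    healthy_pools = []  # (source index, idx1, idx3, slide weight)
    for si, src in enumerate(sources):
        if src.tissue.shape != src.mask.shape:
            raise ValueError(f"{src.slide_id}: mask not aligned to raster")
        interior = np.zeros(src.mask.shape, dtype=bool)
        if min(src.mask.shape) > 2 * half:
            interior[half:src.mask.shape[0] - half,
                     half:src.mask.shape[1] - half] = True
        sw = upw if src.local else 1.0
        t_idx = np.argwhere((src.mask == CODE_TUMOR) & interior)
        i1 = np.argwhere((src.mask == CODE_HEALTHY) & interior)
        i3 = np.argwhere((src.mask == CODE_HARD_NEGATIVE) & interior)
        if len(t_idx):
            tumor_pools.append((si, t_idx, sw * len(t_idx)))
        if len(i1) + len(i3):
            healthy_pools.append((si, i1, i3, sw * (len(i1) + w3 * len(i3))))

    if config.tumor_fraction > 0 and not tumor_pools:
        raise ValueError("no tumor pixels available but tumor_fraction > 0")
    if config.tumor_fraction < 1 and not healthy_pools:
        raise ValueError("no healthy pixels available")

    t_weights = np.array([p[2] for p in tumor_pools], dtype=np.float64)
    h_weights = np.array([p[3] for p in healthy_pools], dtype=np.float64)

    patches = np.empty((n_patches, config.patch_px, config.patch_px),
                       dtype=np.float32)
    labels = np.empty(n_patches, dtype=np.int64)
    for k in range(n_patches):
        is_tumor = rng.uniform() < config.tumor_fraction
        if is_tumor:
            si, idx, _ = tumor_pools[
                rng.choice(len(tumor_pools), p=t_weights / t_weights.sum())]
            row, col = idx[rng.integers(len(idx))]
        else:
            si, i1, i3, _ = healthy_pools[
                rng.choice(len(healthy_pools), p=h_weights / h_weights.sum())]
            p3 = (w3 * len(i3)) / (len(i1) + w3 * len(i3))
            idx = i3 if (len(i3) and rng.uniform() < p3) else i1
            row, col = idx[rng.integers(len(idx))]
        patch = sources[si].tissue[row - half: row - half + config.patch_px,
                                   col - half: col - half + config.patch_px]
        if config.augment:
            patch = augment(patch, AugmentParams.draw(rng))
        patches[k] = patch
        labels[k] = 1 if is_tumor else 0
    return patches, labels


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Param], lr: float, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.l2 = l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.l2 and p.decay:
                g = g + self.l2 * p.value
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _as_input(x: np.ndarray, in_channels: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[-1] == 1 and in_channels > 1:
        x = np.repeat(x, in_channels, axis=-1)
    return x


def _center_logits(logits: np.ndarray) -> np.ndarray:
    ci, cj = logits.shape[1] // 2, logits.shape[2] // 2
    return logits[:, ci, cj, :]


def train(
    network: DenseNet,
    train_data: Callable[[int], tuple[np.ndarray, np.ndarray]],
    val_data: Callable[[int], tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
) -> tuple[DenseNet, pd.DataFrame]:
    """Plateau-scheduled Adam training; returns the best-val checkpoint.

    ``train_data(epoch)`` / ``val_data(epoch)`` return that epoch's
    ``(patches, labels)``; supervision is the center position of each
    patch's output map (patch labels are defined by the center pixel).
    """
    sched = PlateauSchedule(config)
    opt = Adam(network.params(), lr=sched.lr, l2=config.l2_weight)
    history = []
    best_state = network.get_state()
    best_val = -np.inf
    for epoch in range(1, config.max_epochs + 1):
        x_train, y_train = train_data(epoch)
        x_val, y_val = val_data(epoch)
        if len(x_train) == 0 or len(x_val) == 0:
            raise ValueError("empty patch stream")
        x_train = _as_input(x_train, network.config.in_channels)
        x_val = _as_input(x_val, network.config.in_channels)

        opt.lr = sched.lr
        correct = 0
        for start in range(0, len(x_train), config.batch_size):
            xb = x_train[start:start + config.batch_size]
            yb = y_train[start:start + config.batch_size]
            logits = network.forward_logits(xb, train=True)
            center = _center_logits(logits)
            probs = _softmax(center)
            correct += int((probs.argmax(axis=-1) == yb).sum())
            dcenter = probs.copy()
            dcenter[np.arange(len(yb)), yb] -= 1.0
            dcenter /= len(yb)
            dlogits = np.zeros_like(logits)
            ci, cj = logits.shape[1] // 2, logits.shape[2] // 2
            dlogits[:, ci, cj, :] = dcenter
            network.zero_grads()
            network.backward(dlogits)
            opt.step()
        train_acc = correct / len(x_train)

        val_probs = _center_logits(network.forward(x_val))
        val_acc = float((val_probs.argmax(axis=-1) == y_val).mean())

        lr_next, stop, improved = sched.update(epoch, val_acc)
        if improved or epoch == 1:
            best_state = network.get_state()
            best_val = val_acc
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_acc": train_acc, "val_acc": val_acc})
        if stop:
            break
    network.set_state(best_state)
    return network, pd.DataFrame(history)


# --------------------------------------------------------------------------
# strategies
# --------------------------------------------------------------------------


def run_strategy(
    base_state: list[np.ndarray] | None,
    sources: Sequence[SlideSource],
    strategy: StrategyConfig,
    config: TrainConfig,
    network_config: NetworkConfig,
    val_sources: Sequence[SlideSource] | None = None,
    val_patches: int | None = None,
) -> tuple[DenseNet, pd.DataFrame]:
    """Dispatch one retraining strategy.

    ``scratch_pooled`` re-initializes and trains on all sources;
    ``finetune_local`` starts from the base checkpoint and trains on the
    local sources only.  Sampling mode and hard negative mining are
    composed into the epoch sampler.
    """
    if strategy.transfer_mode == "finetune_local":
        if base_state is None:
            raise ValueError("finetune_local requires a base checkpoint")
        network = build_network(network_config, seed=config.seed)
        network.set_state(base_state)
        train_sources = [s for s in sources if s.local]
        if not train_sources:
            raise ValueError("finetune_local requires local sources")
    else:
        network = build_network(network_config, seed=config.seed)
        train_sources = list(sources)
    v_sources = list(val_sources) if val_sources is not None else train_sources

    def train_data(epoch: int):
        return sample_epoch(train_sources, config, strategy,
                            seed=config.seed + 1000 * epoch)

    def val_data(epoch: int):
        # fixed per-epoch seed sequence keeps validation comparable
        return sample_epoch(v_sources, config, strategy,
                            seed=config.seed + 1000 * epoch + 1,
                            n_patches=val_patches)

    return train(network, train_data, val_data, config)
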