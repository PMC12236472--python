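"""Training loop: Adam with gradient clipping, λ scheduling, plateau decay.

The optimizer is an adaptive-moment method starting at learning rate 1e-4,
with global-norm gradient clipping at 1.0 and a halving of the learning
rate when the validation loss plateaus.  Per-task class weights default to
inverse class frequency measured on the training windows.  The checkpoint
with the lowest validation total loss is retained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ..labels import LabelMasks
from .augment import augment_batch
from .loss import LossWeights, lambda_schedule, total_loss, weighted_cross_entropy
from .model import ModelConfig, MultiModalNet


@dataclass
class TrainConfig:
    epochs: int = 30
    lr: float = 1e-4
    clip_norm: float = 1.0
    seed: int = 0
    val_fraction: float = 0.2
    augment: bool = True
    class_weighting: str = "inverse"  # "inverse" or "none"
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    weight_cap: float = 50.0


@dataclass
class Checkpoint:
    state: list[np.ndarray]
    model_config: dict
    log: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    class_weights: dict = field(default_factory=dict)

    def save(self, path) -> None:
        import json

        arrays = {f"p{i}": a for i, a in enumerate(self.state)}
        arrays.update({f"w_{k}": v for k, v in self.class_weights.items()})
        meta = {
            "model_config": self.model_config,
            "log": self.log,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "n_params": len(self.state),
            "weight_keys": list(self.class_weights),
        }
        np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            state = [z[f"p{i}"] for i in range(meta["n_params"])]
            weights = {k: z[f"w_{k}"] for k in meta["weight_keys"]}
        return cls(
            state=state,
            model_config=meta["model_config"],
            log=meta["log"],
            best_epoch=meta["best_epoch"],
            best_val_loss=meta["best_val_loss"],
            class_weights=weights,
        )

    def build_model(self) -> MultiModalNet:
        model = MultiModalNet(ModelConfig.from_dict(self.model_config))
        model.load_state_dict(self.state)
        return model


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


def clip_gradients(params, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm and norm > 0:
        s = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= s
    return norm


def inverse_class_weights(
    labels_list: list[np.ndarray], n_classes: int, cap: float = 50.0
) -> np.ndarray:
    """Inverse-frequency class weights, normalized to mean 1 and capped."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for lab in labels_list:
        counts += np.bincount(np.asarray(lab).reshape(-1), minlength=n_classes)
    freq = counts / max(counts.sum(), 1)
    w = np.where(freq > 0, 1.0 / np.maximum(freq, 1e-12), 0.0)
    present = w > 0
    if present.any():
        w[present] = w[present] / w[present].mean()
    return np.minimum(w, cap)


def _window_losses(model: MultiModalNet, density, af3, masks: LabelMasks, cw: dict):
    lb, lc, la = model.forward(density, af3)
    loss_b = weighted_cross_entropy(lb, masks.backbone, cw.get("backbone"))
    loss_c = weighted_cross_entropy(lc, masks.calpha, cw.get("calpha"))
    loss_a = weighted_cross_entropy(la, masks.amino, cw.get("amino"))
    return loss_b, loss_c, loss_a


def train(
    model: MultiModalNet, dataset: list[tuple], config: TrainConfig | None = None
) -> Checkpoint:
    """Train on a list of ``(density, encoding_or_None, LabelMasks)`` windows.

    The dataset is split into training and validation windows (at least one
    of each when possible); the returned checkpoint holds the parameters
    with the lowest validation total loss and a per-epoch log of λ values
    and losses.
    """
    cfg = config or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(dataset))
    n_val = int(round(cfg.val_fraction * len(dataset)))
    if len(dataset) >= 2:
        n_val = max(1, min(n_val, len(dataset) - 1))
        val_set = [dataset[i] for i in idx[:n_val]]
        train_set = [dataset[i] for i in idx[n_val:]]
    else:
        val_set = list(dataset)
        train_set = list(dataset)

    if cfg.class_weighting == "inverse":
        cw = {
            "backbone": inverse_class_weights(
                [m.backbone for _, _, m in train_set], 4, cfg.weight_cap
            ),
            "calpha": inverse_class_weights(
                [m.calpha for _, _, m in train_set], 4, cfg.weight_cap
            ),
            "amino": inverse_class_weights(
                [m.amino for _, _, m in train_set], 21, cfg.weight_cap
            ),
        }
    else:
        cw = {}

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    ckpt = Checkpoint(
        state=model.state_dict(),
        model_config=model.config.to_dict(),
        class_weights=cw,
    )
    stale = 0
    for epoch in range(cfg.epochs):
        lam = lambda_schedule(epoch)
        model.train_mode()
        order = rng.permutation(len(train_set))
        epoch_losses = np.zeros(4)
        for wi in order:
            density, af3, masks = train_set[wi]
            if cfg.augment:
                density, af3, masks = augment_batch(
                    density, af3, masks, rng_seed=rng
                )
            model.zero_grad()
            loss_b, loss_c, loss_a = _window_losses(model, density, af3, masks, cw)
            loss = total_loss(loss_b, loss_c, loss_a, lam)
            loss.backward()
            clip_gradients(params, cfg.clip_norm)
            opt.step()
            epoch_losses += [loss_b.item(), loss_c.item(), loss_a.item(), loss.item()]
        epoch_losses /= max(len(train_set), 1)

        model.eval_mode()
        val_total = 0.0
        for density, af3, masks in val_set:
            lb_, lc_, la_ = _window_losses(model, density, af3, masks, cw)
            val_total += total_loss(lb_, lc_, la_, lam).item()
        val_total /= len(val_set)

        ckpt.log.append(
            {
                "epoch": epoch,
                "lambda": list(lam.as_tuple()),
                "train_backbone": epoch_losses[0],
                "train_calpha": epoch_losses[1],
                "train_amino": epoch_losses[2],
                "train_total": epoch_losses[3],
                "val_total": val_total,
                "lr": opt.lr,
            }
        )
        if val_total < ckpt.best_val_loss:
            ckpt.best_val_loss = val_total
            ckpt.best_epoch = epoch
            ckpt.state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                stale = 0
    return ckpt
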