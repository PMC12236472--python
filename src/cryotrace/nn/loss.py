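"""Multi-task loss: per-task weighted cross-entropy and the λ combination.

The total loss is ``λ_b·L_backbone + λ_c·L_calpha + λ_a·L_amino`` with the
λ triple summing to 1.  Each task loss is a class-weighted cross-entropy
averaged over voxels:

    L = −(1/N) Σ_n w_{y_n} · log softmax(x_n)[y_n]

Training prioritizes backbone-atom learning early — λ starts at
(0.6, 0.3, 0.1) — and then shifts emphasis toward Cα and amino-acid
prediction, reaching (0.25, 0.4, 0.35) at epoch 25 via a linear ramp over
epochs 20–25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, add, scale

LAMBDA_START = (0.6, 0.3, 0.1)
LAMBDA_END = (0.25, 0.4, 0.35)
RAMP_EPOCHS = (20.0, 25.0)


@dataclass
class LossWeights:
    lambda_backbone: float
    lambda_calpha: float
    lambda_amino: float
    class_weights: dict = field(default_factory=dict)  # task name -> (K,) array

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.lambda_backbone, self.lambda_calpha, self.lambda_amino)

    def __post_init__(self):
        if abs(sum(self.as_tuple()) - 1.0) > 1e-6:
            raise ValueError(f"lambda weights must sum to 1, got {self.as_tuple()}")


def weighted_cross_entropy(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Class-weighted cross-entropy over voxels.

    ``logits``: (K, *spatial); ``labels``: integer array of the spatial
    shape with values in [0, K); ``class_weights``: optional (K,) weights
    (defaults to 1).  The mean is taken over voxels, not over total weight.
    """
    K = logits.shape[0]
    labels = np.asarray(labels)
    if labels.shape != logits.shape[1:]:
        raise ValueError(
            f"label shape {labels.shape} does not match logits {logits.shape[1:]}"
        )
    flat_labels = labels.reshape(-1).astype(np.int64)
    if flat_labels.size == 0:
        raise ValueError("empty label volume")
    if flat_labels.min() < 0 or flat_labels.max() >= K:
        raise ValueError(
            f"labels out of range [0, {K}): found {flat_labels.min()}..{flat_labels.max()}"
        )
    if class_weights is None:
        w = np.ones(K, dtype=np.float64)
    else:
        w = np.asarray(class_weights, dtype=np.float64)
        if w.shape != (K,):
            raise ValueError(f"class_weights must have shape ({K},)")
    x = logits.data.reshape(K, -1).astype(np.float64)
    x = x - x.max(axis=0, keepdims=True)
    logz = np.log(np.exp(x).sum(axis=0, keepdims=True))
    logp = x - logz
    n = flat_labels.size
    idx = np.arange(n)
    wn = w[flat_labels]
    loss_val = -(wn * logp[flat_labels, idx]).sum() / n

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            grad = p * wn[None, :]
            grad[flat_labels, idx] -= wn
            grad *= float(g) / n
            logits._accumulate(grad.reshape(logits.shape).astype(np.float32))

    return Tensor(np.float64(loss_val), parents=(logits,), backward=backward)


def total_loss(l_b: Tensor, l_c: Tensor, l_a: Tensor, weights: LossWeights) -> Tensor:
    """λ-weighted sum of the three task losses."""
    lb, lc, la = weights.as_tuple()
    if abs(lb + lc + la - 1.0) > 1e-6:
        raise ValueError("lambda weights must sum to 1")
    return add(add(scale(l_b, lb), scale(l_c, lc)), scale(l_a, la))


def lambda_schedule(epoch: float) -> LossWeights:
    """λ triple as a function of (possibly fractional) epoch.

    (0.6, 0.3, 0.1) through epoch 20, a linear ramp over epochs 20–25, and
    (0.25, 0.4, 0.35) from epoch 25 onward; always sums to 1.
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    e0, e1 = RAMP_EPOCHS
    if epoch <= e0:
        tri = LAMBDA_START
    elif epoch >= e1:
        tri = LAMBDA_END
    else:
        t = (epoch - e0) / (e1 - e0)
        tri = tuple(
            (1 - t) * a + t * b for a, b in zip(LAMBDA_START, LAMBDA_END)
        )
    # renormalize away float drift so the sum-to-1 invariant is exact
    s = sum(tri)
    return LossWeights(*(v / s for v in tri))
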