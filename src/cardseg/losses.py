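"""Overlap losses for class-imbalanced segmentation.

Stacks are ``(K, M)`` arrays: ``T`` a one-hot ground truth (each pixel
column sums to 1) and ``Y`` predicted probabilities.  The generalized Dice
loss

    L = 1 - 2 * (sum_k w_k sum_m Y_km T_km) / (sum_k w_k sum_m Y_km^2 + T_km^2),
    w_k = 1 / (sum_m T_km)^2

counters class imbalance by down-weighting large classes, but its weight is
infinite whenever class k has no ground-truth pixels — which happens
routinely on apex slices where the RV vanishes.  The improved variant keeps
every weight finite and stabilizes the ratio:

    L = 1 - 2 * (sum_k w_k sum_m Y_km T_km + eps) / (sum_k w_k sum_m (Y_km^2 + T_km^2) + eps)

with w_k = 1 / sum_m T_km for present classes and, for absent classes,
w_k = 1 / (sum_m Y_km + eps), i.e. the weight is determined by the
predicted mass.  Pixel-wise cross-entropy is provided as the comparison
arm.  Exact analytic gradients with respect to Y (including the dependence
of the absent-class weights on Y) back the training loop and are verified
against finite differences in the tests.
"""

from __future__ import annotations

import numpy as np

from .dataio import LabelMap
from .errors import ContractError, UndefinedLossError

DEFAULT_EPS = 1e-8
CE_FLOOR = 1e-12


def one_hot_encode(label: LabelMap | np.ndarray, n_classes: int = 4) -> np.ndarray:
    """Label map (values in {1..K}) -> one-hot stack of shape (K, M)."""
    arr = label.labels if isinstance(label, LabelMap) else np.asarray(label)
    flat = arr.reshape(-1)
    if flat.size == 0:
        raise ContractError("empty label map")
    if flat.min() < 1 or flat.max() > n_classes:
        raise ContractError(f"label values must lie in 1..{n_classes}")
    t = np.zeros((n_classes, flat.size), dtype=np.float64)
    t[flat - 1, np.arange(flat.size)] = 1.0
    return t


def _check_stacks(y: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y, t = np.asarray(y, dtype=np.float64), np.asarray(t, dtype=np.float64)
    if y.shape != t.shape or y.ndim != 2:
        raise ContractError(f"Y and T must be matching (K, M) stacks, got {y.shape} vs {t.shape}")
    return y, t


def gdl_weights(t: np.ndarray) -> np.ndarray:
    """Baseline class weights w_k = 1/(sum_m T_km)^2.

    Absent classes get +infinity — the documented failure mode that
    motivates the improved weighting.
    """
    t = np.asarray(t, dtype=np.float64)
    sums = t.sum(axis=1)
    with np.errstate(divide="ignore"):
        return 1.0 / sums**2


def generalized_dice_loss(y: np.ndarray, t: np.ndarray) -> float:
    """Baseline generalized Dice loss; undefined when a class is absent."""
    y, t = _check_stacks(y, t)
    w = gdl_weights(t)
    if not np.isfinite(w).all():
        raise UndefinedLossError(
            "ground truth has an absent class: baseline weights are infinite "
            "(use improved_generalized_dice_loss)"
        )
    num = (w * (y * t).sum(axis=1)).sum()
    den = (w * (y**2 + t**2).sum(axis=1)).sum()
    return float(1.0 - 2.0 * num / den)


def igd_weights(y: np.ndarray, t: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Improved weights: 1/sum(T) for present classes, 1/(sum(Y)+eps) for
    absent ones.  Always finite."""
    y, t = _check_stacks(y, t)
    t_sums = t.sum(axis=1)
    y_sums = y.sum(axis=1)
    return np.where(t_sums > 0, 1.0 / np.where(t_sums > 0, t_sums, 1.0), 1.0 / (y_sums + eps))


def improved_generalized_dice_loss(y: np.ndarray, t: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """The absent-class-robust loss; finite for every valid (Y, T)."""
    y, t = _check_stacks(y, t)
    w = igd_weights(y, t, eps)
    num = (w * (y * t).sum(axis=1)).sum() + eps
    den = (w * (y**2 + t**2).sum(axis=1)).sum() + eps
    return float(1.0 - 2.0 * num / den)


def improved_gdl_gradient(y: np.ndarray, t: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Exact dLoss/dY for the improved loss, including the dependence of the
    absent-class weights on the predicted mass."""
    y, t = _check_stacks(y, t)
    t_sums = t.sum(axis=1)
    absent = t_sums == 0
    w = igd_weights(y, t, eps)
    a = (y * t).sum(axis=1)  # per-class overlap
    b = (y**2 + t**2).sum(axis=1)  # per-class denominator mass
    s = (w * a).sum() + eps
    q = (w * b).sum() + eps
    # dS, dQ per element; dw_k/dY_km = -w_k^2 on absent classes only
    dw = np.where(absent, -(w**2), 0.0)[:, None]
    ds = w[:, None] * t + dw * a[:, None]  # a_k = 0 for absent k, kept for clarity
    dq = 2.0 * w[:, None] * y + dw * b[:, None]
    return (-2.0 * (q * ds - s * dq) / q**2).astype(np.float64)


def gdl_gradient(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """dLoss/dY for the baseline loss (weights depend on T only)."""
    y, t = _check_stacks(y, t)
    w = gdl_weights(t)
    if not np.isfinite(w).all():
        raise UndefinedLossError("baseline gradient undefined with absent classes")
    s = (w * (y * t).sum(axis=1)).sum()
    q = (w * (y**2 + t**2).sum(axis=1)).sum()
    ds = w[:, None] * t
    dq = 2.0 * w[:, None] * y
    return -2.0 * (q * ds - s * dq) / q**2


def cross_entropy_loss(y: np.ndarray, t: np.ndarray, floor: float = CE_FLOOR) -> float:
    """Mean over pixels of -sum_k T_km log(Y_km + floor)."""
    y, t = _check_stacks(y, t)
    return float(-(t * np.log(y + floor)).sum() / y.shape[1])


def cross_entropy_gradient(y: np.ndarray, t: np.ndarray, floor: float = CE_FLOOR) -> np.ndarray:
    y, t = _check_stacks(y, t)
    return -t / (y + floor) / y.shape[1]


# ---------------------------------------------------------------------------
# minibatch interface used by the training loop

LOSS_VARIANTS = ("gdl", "igd", "ce")


def batch_loss_and_grad(
    probs: np.ndarray,
    labels: np.ndarray,
    variant: str = "igd",
    eps: float = DEFAULT_EPS,
) -> tuple[float, np.ndarray]:
    """Mean per-item loss and dLoss/dprobs for a batch.

    ``probs`` is (N, H, W, K) SoftMax output, ``labels`` (N, H, W) in
    {1..K}.  The loss is computed per minibatch item on its (K, M) stacks
    and averaged, so the scale is independent of batch size.
    """
    if variant not in LOSS_VARIANTS:
        raise ContractError(f"unknown loss variant {variant!r}")
    n, h, w, k = probs.shape
    if labels.shape != (n, h, w):
        raise ContractError("probability and label batch shapes do not match")
    total = 0.0
    grads = np.empty_like(probs, dtype=np.float64)
    for i in range(n):
        y = probs[i].reshape(-1, k).T  # (K, M)
        t = one_hot_encode(labels[i], k)
        if variant == "igd":
            total += improved_generalized_dice_loss(y, t, eps)
            g = improved_gdl_gradient(y, t, eps)
        elif variant == "gdl":
            total += generalized_dice_loss(y, t)
            g = gdl_gradient(y, t)
        else:
            total += cross_entropy_loss(y, t)
            g = cross_entropy_gradient(y, t)
        grads[i] = g.T.reshape(h, w, k)
    grads /= n
    return total / n, grads
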