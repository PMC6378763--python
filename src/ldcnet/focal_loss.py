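"""Binary cross-entropy and focal loss.

The focal loss rescales the cross-entropy of each sample by
``alpha_t * (1 - p_t)**gamma``: the modulating factor ``(1 - p_t)**gamma``
drives the contribution of easily classified samples (p_t near 1) towards
zero, and the class weight ``alpha_t`` (alpha for positives, 1 - alpha for
negatives) balances the two classes.  With gamma = 0 and alpha = 1 the focal
loss reduces exactly to the cross-entropy.

``p`` is always the model's probability for the positive (nodule) class;
ground truth uses y in {-1, +1} here, while the rest of the pipeline uses
{0, 1} labels and maps them at this module's boundary.  Losses are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: probability clamp keeping log() finite
EPS = 1e-7

__all__ = [
    "FocalParams",
    "Prediction",
    "cross_entropy",
    "pt",
    "alpha_t",
    "focal",
    "batch_loss",
    "batch_loss_and_grad",
    "EPS",
]


@dataclass(frozen=True)
class FocalParams:
    """Focusing parameter gamma >= 0 and class weight alpha in [0, 1]."""

    gamma: float = 2.5
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class Prediction:
    """A model probability for the positive class and the signed ground truth."""

    p: float
    y: int

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if self.y not in (-1, 1):
            raise ValueError("y must be -1 or +1")


def _clamp(p):
    return np.clip(p, EPS, 1.0 - EPS)


def pt(pred: Prediction) -> float:
    """Probability assigned to the true class: p if y=+1 else 1-p."""
    return pred.p if pred.y == 1 else 1.0 - pred.p


def alpha_t(pred: Prediction, params: FocalParams) -> float:
    """Class weight for this sample: alpha if y=+1 else 1-alpha."""
    return params.alpha if pred.y == 1 else 1.0 - params.alpha


def cross_entropy(pred: Prediction) -> float:
    """Binary cross-entropy -log p_t, natural log, probability clamped."""
    return float(-np.log(_clamp(pt(pred))))


def focal(pred: Prediction, params: FocalParams) -> float:
    """Focal loss -alpha_t * (1 - p_t)**gamma * log(p_t)."""
    p_t = _clamp(pt(pred))
    return float(-alpha_t(pred, params) * (1.0 - p_t) ** params.gamma * np.log(p_t))


def batch_loss(
    preds: list[Prediction],
    params: FocalParams | None = None,
    kind: str = "focal",
) -> float:
    """Arithmetic mean of per-sample losses over a non-empty batch."""
    if not preds:
        raise ValueError("empty batch")
    if kind == "cross_entropy":
        return float(np.mean([cross_entropy(pr) for pr in preds]))
    if kind == "focal":
        params = params if params is not None else FocalParams()
        return float(np.mean([focal(pr, params) for pr in preds]))
    raise ValueError(f"unknown loss kind {kind!r}")


def batch_loss_and_grad(
    p: np.ndarray,
    labels01: np.ndarray,
    params: FocalParams | None = None,
    kind: str = "focal",
) -> tuple[float, np.ndarray]:
    """Vectorised mean loss and its gradient with respect to ``p``.

    ``labels01`` uses pipeline {0,1} labels; they are mapped to the signed
    convention internally.  Where ``p`` hits the clamp the gradient is zero.
    Returns ``(mean_loss, d mean_loss / d p)`` with the 1/n factor included.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(labels01).astype(bool)  # True = positive class
    if p.size == 0:
        raise ValueError("empty batch")
    pc = _clamp(p)
    p_t = np.where(y, pc, 1.0 - pc)
    log_pt = np.log(p_t)
    if kind == "cross_entropy":
        gamma, a_t = 0.0, np.ones_like(pc)
    elif kind == "focal":
        params = params if params is not None else FocalParams()
        gamma = params.gamma
        a_t = np.where(y, params.alpha, 1.0 - params.alpha)
    else:
        raise ValueError(f"unknown loss kind {kind!r}")

    one_minus = 1.0 - p_t
    loss = -a_t * one_minus**gamma * log_pt
    # dL/dp_t = a_t * (gamma * (1-p_t)^(gamma-1) * log p_t - (1-p_t)^gamma / p_t)
    if gamma == 0.0:
        dl_dpt = -a_t / p_t
    else:
        dl_dpt = a_t * (
            gamma * one_minus ** (gamma - 1.0) * log_pt - one_minus**gamma / p_t
        )
    dpt_dp = np.where(y, 1.0, -1.0)
    grad = dl_dpt * dpt_dp
    grad = np.where((p > EPS) & (p < 1.0 - EPS), grad, 0.0)
    return float(loss.mean()), grad / p.size
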