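"""Segmentation training losses: binary cross-entropy, Dice, and propagation.

The combined objective is L = alpha * L_bce + beta * L_dice + gamma * L_prop,
where the propagation term penalizes predicted masks that miss regions implied
by neighbouring slices' segmentations (fractured bodies often have locally
destroyed or occluded margins that neighbours can vouch for).

All losses are pure functions of flattened pixel arrays; no autodiff.  The
Dice and propagation terms are written against predicted *labels* x_g in
[0, 1]; passing soft probabilities yields the soft variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BCE_EPS = 1e-7
DICE_SMOOTH = 1e-6


@dataclass(frozen=True)
class LossWeights:
    """Balancing coefficients (alpha, beta, gamma) for BCE/Dice/propagation."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one loss weight must be positive")


def _flat(a) -> np.ndarray:
    return np.asarray(a, dtype=float).ravel()


def bce_loss(y_g, x_p) -> float:
    """Mean binary cross-entropy -(1/N) sum[y log x_p + (1-y) log(1-x_p)].

    Probabilities are clipped to [eps, 1-eps] with eps = 1e-7 to stay finite.
    """
    y, p = _flat(y_g), _flat(x_p)
    if y.shape != p.shape:
        raise ValueError("length mismatch between labels and probabilities")
    if y.size == 0:
        raise ValueError("empty inputs")
    p = np.clip(p, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_loss(y_g, x_g) -> float:
    """Dice loss 1 - 2*sum(x_g*y_g) / (sum(x_g) + sum(y_g)), smoothed.

    A smoothing constant (1e-6) in numerator and denominator keeps the loss
    defined (zero) when both masks are empty.
    """
    y, x = _flat(y_g), _flat(x_g)
    if y.shape != x.shape:
        raise ValueError("length mismatch")
    num = 2.0 * float(np.sum(x * y)) + DICE_SMOOTH
    den = float(np.sum(x) + np.sum(y)) + DICE_SMOOTH
    return float(1.0 - num / den)


def propagation_loss(p_g, x_g) -> float:
    """Fraction of propagation-label pixels the prediction misses.

    sum(p_g - x_g * p_g) / sum(p_g); defined as 0 when the propagation label
    is empty (nothing to propagate).
    """
    p, x = _flat(p_g), _flat(x_g)
    if p.shape != x.shape:
        raise ValueError("length mismatch")
    total = float(np.sum(p))
    if total == 0.0:
        return 0.0
    return float(np.sum(p - x * p) / total)


def combined_loss(y_g, x_p, x_g, p_g, weights: LossWeights = LossWeights()) -> float:
    """Weighted sum alpha*BCE + beta*Dice + gamma*propagation."""
    return float(
        weights.alpha * bce_loss(y_g, x_p)
        + weights.beta * dice_loss(y_g, x_g)
        + weights.gamma * propagation_loss(p_g, x_g)
    )
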