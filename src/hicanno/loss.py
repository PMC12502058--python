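"""Adaptive hierarchical focal loss.

The classifier is trained with a focal loss at each level of the taxonomy,

    FL(p) = -(1 - p_true)^gamma * log(p_true),

averaged over the cells in a batch, and the two levels are combined as a
convex combination

    L_total = alpha * FL_base + (1 - alpha) * FL_sub.

The weight alpha is not fixed: after every training step it is pulled,
with momentum beta, toward the share of the total loss contributed by the
base level,

    alpha_{t+1} = beta * alpha_t + (1 - beta) * FL_base / (FL_base + FL_sub),

so the harder level automatically receives more weight on the next step.
Defaults: gamma = 2.0 (the standard focal-loss focusing value), beta = 0.9,
alpha_0 = 0.5 (equal initial emphasis; also the update's fixed point when
the two losses are balanced).

Cells whose subtype label is the sentinel (terminal-leaf bases, unlabeled
subtypes) are excluded from FL_sub; if a batch contains no subtype-labeled
cells, FL_sub = 0 for the combination and alpha is left unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import ValidationError
from .hierarchy import NO_SUBTYPE, CellTypeHierarchy

P_EPS = 1e-12  # clamp floor for p_true before the log


@dataclass
class LossState:
    """Mutable training-time state of the adaptive weighting."""

    alpha: float = 0.5
    beta: float = 0.9
    gamma: float = 2.0
    last_fl_base: float = 0.0
    last_fl_sub: float = 0.0
    step: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValidationError("beta must be in [0, 1]")
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")


def focal_loss(probs: np.ndarray, true_class: int | np.ndarray, gamma: float) -> float:
    """Mean focal loss of one or more probability vectors.

    ``probs`` is a simplex vector (K,) or batch (N, K); ``true_class`` a
    single index or an (N,) index vector.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == 1:
        probs = probs[None, :]
        true_class = np.asarray([true_class])
    else:
        true_class = np.asarray(true_class)
    n, k = probs.shape
    if np.any(true_class < 0) or np.any(true_class >= k):
        raise ValidationError(
            f"class index out of range [0, {k}): {true_class}"
        )
    p_true = np.clip(probs[np.arange(n), true_class], P_EPS, 1.0)
    return float(np.mean(-((1.0 - p_true) ** gamma) * np.log(p_true)))


def total_loss(fl_base: float, fl_sub: float, alpha: float) -> float:
    """Convex combination of the two level losses."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    return alpha * fl_base + (1.0 - alpha) * fl_sub


def update_alpha(state: LossState, fl_base: float, fl_sub: float) -> LossState:
    """Momentum-smoothed pull of alpha toward the base-level loss share.

    When both losses are zero the ratio is undefined; alpha stays put (both
    levels are perfect, there is nothing to rebalance).
    """
    if fl_base < 0 or fl_sub < 0:
        raise ValidationError("focal losses are non-negative")
    denom = fl_base + fl_sub
    if denom == 0:
        new_alpha = state.alpha
    else:
        new_alpha = state.beta * state.alpha + (1.0 - state.beta) * fl_base / denom
    return LossState(
        alpha=new_alpha,
        beta=state.beta,
        gamma=state.gamma,
        last_fl_base=fl_base,
        last_fl_sub=fl_sub,
        step=state.step + 1,
    )


def hierarchical_loss_step(
    base_probs: np.ndarray,
    sub_probs: np.ndarray | None,
    base_idx: np.ndarray,
    sub_idx: np.ndarray,
    state: LossState,
) -> tuple[float, LossState]:
    """One training step's combined loss and the advanced loss state.

    FL_base averages over every cell; FL_sub averages over the cells with a
    real (non-sentinel) subtype label.  L_total is formed with the *current*
    alpha_t; the returned state carries alpha_{t+1} for the next step.
    """
    fl_base = focal_loss(base_probs, base_idx, state.gamma)
    labeled = np.flatnonzero(np.asarray(sub_idx) != NO_SUBTYPE)
    if sub_probs is not None and labeled.size:
        fl_sub = focal_loss(
            np.asarray(sub_probs)[labeled], np.asarray(sub_idx)[labeled], state.gamma
        )
        l_total = total_loss(fl_base, fl_sub, state.alpha)
        new_state = update_alpha(state, fl_base, fl_sub)
    else:
        fl_sub = 0.0
        l_total = state.alpha * fl_base
        new_state = LossState(
            alpha=state.alpha, beta=state.beta, gamma=state.gamma,
            last_fl_base=fl_base, last_fl_sub=0.0, step=state.step + 1,
        )
    return l_total, new_state


def focal_loss_grad_logits(
    logits: np.ndarray, true_class: np.ndarray, gamma: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Batch-mean focal loss and its gradient w.r.t. the logits.

    With p = softmax(z) and t the true class,
        dFL/dp_t = gamma (1-p_t)^{gamma-1} log p_t - (1-p_t)^gamma / p_t
        dp_t/dz_i = p_t (1[i=t] - p_i),
    chained and divided by the batch size (mean reduction).  Returns
    (loss, dloss/dlogits, probs).
    """
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n, k = probs.shape
    t = np.asarray(true_class)
    p_t = np.clip(probs[np.arange(n), t], P_EPS, 1.0)
    one_m = 1.0 - p_t
    loss = float(np.mean(-(one_m ** gamma) * np.log(p_t)))
    if gamma == 0:
        dfl_dpt = -1.0 / p_t
    else:
        dfl_dpt = gamma * (one_m ** (gamma - 1.0)) * np.log(p_t) - (one_m ** gamma) / p_t
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), t] = 1.0
    dloss = (dfl_dpt * p_t)[:, None] * (onehot - probs) / n
    return loss, dloss, probs
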