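"""Training loop and two-level evaluation metrics.

Training minimizes the adaptive hierarchical focal loss with Adam on
mini-batches of rendered (and randomly masked) cell images.  The split is
stratified by subtype (falling back to base type for groups too small to
split), one master seed fans out to independent split / masking / init
streams, and the best-validation-loss weights are kept.  Evaluation
reports accuracy, macro precision, macro F1 and macro AUPRC at both
levels, computed from the masked hierarchical predictions; subtype
metrics cover only cells that carry a real subtype label.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from ._utils import ValidationError, spawn_rng
from .hierarchy import NO_SUBTYPE, CellTypeHierarchy
from .image_mapper import PixelMap, random_mask_batch
from .loss import LossState, focal_loss_grad_logits, total_loss, update_alpha
from .model import (HierarchicalClassifier, HierarchicalClassifierConfig,
                    mask_subtype_probs, softmax)


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 3e-3
    optimizer_name: str = "adam"
    seed: int = 0
    mask_fraction: float = 0.1
    validation_fraction: float = 0.2
    early_stop_patience: int = 15

    def __post_init__(self):
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValidationError("validation_fraction must be in (0, 1)")
        if self.optimizer_name != "adam":
            raise ValidationError("only the 'adam' optimizer is implemented")


@dataclass
class LevelMetrics:
    accuracy: float
    macro_precision: float
    macro_f1: float
    macro_auprc: float
    per_class: pd.DataFrame     # class, support, precision, recall
    confusion: pd.DataFrame     # true x predicted counts


@dataclass
class MetricsReport:
    base: LevelMetrics
    subtype: LevelMetrics | None


@dataclass
class TrainResult:
    classifier: HierarchicalClassifier
    loss_state: LossState
    step_log: pd.DataFrame    # step, epoch, fl_base, fl_sub, alpha, l_total
    epoch_log: pd.DataFrame   # epoch, train_loss, val_loss, val accs
    best_epoch: int


def stratified_split(
    base_idx: np.ndarray, sub_idx: np.ndarray, val_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(base, subtype) group split; groups of one cell go to training.

    A (base, subtype) group with fewer than 2 members falls back to its
    base-level stratum before splitting.
    """
    n = len(base_idx)
    keys = np.array([f"{b}|{s}" for b, s in zip(base_idx, sub_idx)])
    uniq, counts = np.unique(keys, return_counts=True)
    small = {k for k, c in zip(uniq, counts) if c < 2}
    keys = np.array([f"{b}|*" if k in small else k
                     for k, b in zip(keys, base_idx)])
    train, val = [], []
    for key in np.unique(keys):
        members = np.flatnonzero(keys == key)
        members = members[rng.permutation(members.size)]
        if members.size < 2:
            train.extend(members)
            continue
        n_val = int(round(val_fraction * members.size))
        n_val = min(max(n_val, 1), members.size - 1)
        val.extend(members[:n_val])
        train.extend(members[n_val:])
    return np.sort(np.array(train, dtype=np.int64)), np.sort(np.array(val, dtype=np.int64))


def train_model(
    images: np.ndarray,
    base_idx: np.ndarray,
    sub_idx: np.ndarray,
    hier: CellTypeHierarchy,
    model_cfg: HierarchicalClassifierConfig,
    train_cfg: TrainConfig,
    loss_state: LossState | None = None,
    pixel_map: PixelMap | None = None,
) -> TrainResult:
    """Fit the hierarchical classifier; returns the best-validation model.

    ``images`` is the full (N, C, H, W) stack of rendered cells; random
    masking is re-drawn on the training images every epoch when a pixel map
    is provided.
    """
    base_idx = np.asarray(base_idx)
    sub_idx = np.asarray(sub_idx)
    n = images.shape[0]
    if not (len(base_idx) == len(sub_idx) == n):
        raise ValidationError("images and label vectors must align")
    state = loss_state or LossState()

    split_rng = spawn_rng(train_cfg.seed, "split")
    mask_rng = spawn_rng(train_cfg.seed, "mask")
    order_rng = spawn_rng(train_cfg.seed, "order")
    tr, va = stratified_split(base_idx, sub_idx, train_cfg.validation_fraction, split_rng)

    missing = set(range(hier.K_sub)) - set(int(s) for s in sub_idx[tr]) - {NO_SUBTYPE}
    if missing:
        names = [hier.subtype_names[i] for i in sorted(missing)]
        warnings.warn(
            f"subtype class(es) with zero training support after the split: {names}"
        )

    clf = HierarchicalClassifier(
        model_cfg, hier, seed=train_cfg.seed,
        pixel_map_fingerprint=pixel_map.fingerprint() if pixel_map else "",
    )
    opt = nn.Adam(list(clf._modules().values()), lr=train_cfg.learning_rate)

    step_rows, epoch_rows = [], []
    best = (np.inf, -1, None)  # val loss, epoch, weights
    patience_left = train_cfg.early_stop_patience
    step = 0
    for epoch in range(train_cfg.epochs):
        train_imgs = images[tr]
        if pixel_map is not None and train_cfg.mask_fraction > 0:
            train_imgs = random_mask_batch(
                train_imgs, train_cfg.mask_fraction, mask_rng, pixel_map
            )
        order = order_rng.permutation(tr.size)
        epoch_losses = []
        for start in range(0, tr.size, train_cfg.batch_size):
            pick = order[start:start + train_cfg.batch_size]
            xb = train_imgs[pick]
            yb_base = base_idx[tr][pick]
            yb_sub = sub_idx[tr][pick]

            opt.zero_grad()
            base_logits, sub_logits = clf.forward(xb)
            fl_base, dbase, _ = focal_loss_grad_logits(base_logits, yb_base, state.gamma)
            labeled = np.flatnonzero(yb_sub != NO_SUBTYPE)
            dsub = None
            if sub_logits is not None and labeled.size:
                fl_sub, dsub_sel, _ = focal_loss_grad_logits(
                    sub_logits[labeled], yb_sub[labeled], state.gamma
                )
                dsub = np.zeros_like(sub_logits)
                dsub[labeled] = (1.0 - state.alpha) * dsub_sel
                l_total = total_loss(fl_base, fl_sub, state.alpha)
                next_state = update_alpha(state, fl_base, fl_sub)
            else:
                fl_sub = 0.0
                l_total = state.alpha * fl_base
                next_state = LossState(
                    alpha=state.alpha, beta=state.beta, gamma=state.gamma,
                    last_fl_base=fl_base, last_fl_sub=0.0, step=state.step + 1,
                )
            clf.backward(state.alpha * dbase, dsub)
            opt.step()
            step_rows.append((step, epoch, fl_base, fl_sub, state.alpha, l_total))
            state = next_state
            epoch_losses.append(l_total)
            step += 1

        val_loss, val_base_acc, val_sub_acc = _validation_pass(
            clf, images[va], base_idx[va], sub_idx[va], state
        )
        epoch_rows.append((epoch, float(np.mean(epoch_losses)), val_loss,
                           val_base_acc, val_sub_acc, state.alpha))
        if val_loss < best[0] - 1e-9:
            best = (val_loss, epoch, copy.deepcopy(nn.state_dict(clf._modules())))
            patience_left = train_cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    if best[2] is not None:
        nn.load_state_dict(clf._modules(), best[2])
    return TrainResult(
        classifier=clf,
        loss_state=state,
        step_log=pd.DataFrame(
            step_rows, columns=["step", "epoch", "fl_base", "fl_sub", "alpha", "l_total"]
        ),
        epoch_log=pd.DataFrame(
            epoch_rows,
            columns=["epoch", "train_loss", "val_loss", "val_base_acc",
                     "val_sub_acc", "alpha"],
        ),
        best_epoch=best[1],
    )


def train_ensemble(
    images: np.ndarray,
    base_idx: np.ndarray,
    sub_idx: np.ndarray,
    hier: CellTypeHierarchy,
    model_cfg: HierarchicalClassifierConfig,
    train_cfg: TrainConfig,
    n_members: int = 3,
    loss_state: LossState | None = None,
    pixel_map: PixelMap | None = None,
) -> list[TrainResult]:
    """Train ``n_members`` independently initialized models (a small deep
    ensemble).  Averaging the members' predicted probabilities gives the
    better-calibrated uncertainty needed for rare-population scoring; member
    k uses master seed ``train_cfg.seed + k``.
    """
    if n_members < 1:
        raise ValidationError("n_members must be >= 1")
    results = []
    for k in range(n_members):
        cfg_k = TrainConfig(
            epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
            learning_rate=train_cfg.learning_rate,
            optimizer_name=train_cfg.optimizer_name,
            seed=train_cfg.seed + k, mask_fraction=train_cfg.mask_fraction,
            validation_fraction=train_cfg.validation_fraction,
            early_stop_patience=train_cfg.early_stop_patience,
        )
        results.append(
            train_model(images, base_idx, sub_idx, hier, model_cfg, cfg_k,
                        loss_state=loss_state, pixel_map=pixel_map)
        )
    return results


def _validation_pass(clf, images, base_idx, sub_idx, state) -> tuple[float, float, float]:
    from .loss import focal_loss

    base_probs, sub_probs = clf.predict_proba(images)
    fl_base = focal_loss(base_probs, base_idx, state.gamma)
    labeled = np.flatnonzero(sub_idx != NO_SUBTYPE)
    fl_sub = (
        focal_loss(sub_probs[labeled], sub_idx[labeled], state.gamma)
        if labeled.size else 0.0
    )
    val_loss = total_loss(fl_base, fl_sub, state.alpha)
    base_acc = float(np.mean(np.argmax(base_probs, axis=1) == base_idx)) \
        if len(base_idx) else 0.0
    if labeled.size:
        masked = mask_subtype_probs(base_probs[labeled], sub_probs[labeled], clf.hier)
        pred = _masked_argmax(masked)
        sub_acc = float(np.mean(pred == sub_idx[labeled]))
    else:
        sub_acc = 0.0
    return val_loss, base_acc, sub_acc


def _masked_argmax(masked: np.ndarray) -> np.ndarray:
    """Subtype call from masked probabilities; all-zero rows (terminal-leaf
    base wins) yield the sentinel."""
    pred = np.argmax(masked, axis=1) if masked.shape[1] else np.zeros(len(masked), int)
    pred = np.where(masked.sum(axis=1) > 0, pred, NO_SUBTYPE)
    return pred.astype(np.int64)


def evaluate(
    clf: HierarchicalClassifier,
    images: np.ndarray,
    base_idx: np.ndarray,
    sub_idx: np.ndarray,
) -> MetricsReport:
    """Metrics at both levels from masked hierarchical predictions."""
    hier = clf.hier
    base_probs, sub_probs = clf.predict_proba(images)
    base_pred = np.argmax(base_probs, axis=1)
    base = _level_metrics(
        np.asarray(base_idx), base_pred, base_probs, list(hier.base_names)
    )
    labeled = np.flatnonzero(np.asarray(sub_idx) != NO_SUBTYPE)
    subtype = None
    if hier.K_sub and labeled.size:
        masked = mask_subtype_probs(base_probs[labeled], sub_probs[labeled], hier)
        sub_pred = _masked_argmax(masked)
        subtype = _level_metrics(
            np.asarray(sub_idx)[labeled], sub_pred, masked, list(hier.subtype_names)
        )
    return MetricsReport(base=base, subtype=subtype)


def _level_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, probs: np.ndarray, names: list[str]
) -> LevelMetrics:
    from sklearn.metrics import (accuracy_score, average_precision_score,
                                 confusion_matrix, precision_recall_fscore_support)

    k = len(names)
    labels = list(range(k))
    acc = float(accuracy_score(y_true, y_pred))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    present = [c for c in labels if np.any(y_true == c)]
    macro_prec = float(np.mean(prec[present]))
    macro_f1 = float(np.mean(f1[present]))
    # one-vs-rest AUPRC per class; classes without positives carry no curve
    auprcs = [
        float(average_precision_score((y_true == c).astype(int), probs[:, c]))
        for c in present
    ]
    macro_auprc = float(np.mean(auprcs)) if auprcs else 0.0
    # sentinel predictions (terminal-leaf base won) get their own column so
    # confusion-matrix row sums always equal per-class support
    has_sentinel = bool(np.any(y_pred == NO_SUBTYPE))
    y_pred_cm = np.where(y_pred == NO_SUBTYPE, k, y_pred)
    cm = confusion_matrix(y_true, y_pred_cm, labels=list(range(k + 1)))[:k]
    col_names = names + ["(no subtype)"]
    if not has_sentinel:
        cm = cm[:, :k]
        col_names = names
    per_class = pd.DataFrame(
        {"class": names, "support": support, "precision": prec, "recall": rec, "f1": f1}
    )
    confusion = pd.DataFrame(cm, index=pd.Index(names, name="true"), columns=col_names)
    return LevelMetrics(
        accuracy=acc, macro_precision=macro_prec, macro_f1=macro_f1,
        macro_auprc=macro_auprc, per_class=per_class, confusion=confusion,
    )
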