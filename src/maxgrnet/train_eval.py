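"""Training loop, confusion-matrix metrics, OvR ROC and 5-fold CV harness.

Metrics follow the one-vs-rest convention: per class c, TP/FP/TN/FN are
counted against all other classes pooled, giving per-class accuracy
(TP+TN)/N, precision TP/(TP+FP), recall TP/(TP+FN) and F1 = 2PR/(P+R);
macro values are unweighted means over classes, and the overall accuracy is
the confusion-matrix trace over the sample count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import nn
from .architecture import MaxGRNet
from .errors import LeakageError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the full-scale study configuration."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-5
    weight_decay: float = 3e-5
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0 \
                or self.weight_decay < 0:
            raise ValidationError("invalid training configuration")


@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class: dict[str, np.ndarray]      # tp/fp/tn/fn/accuracy/precision/recall/f1
    macro: dict[str, float]
    overall_accuracy: float
    ovr_auc: np.ndarray | None = None     # per-class, nan where undefined
    macro_auc: float | None = None

    def scalar(self, name: str) -> float:
        if name == "accuracy":
            return self.overall_accuracy
        if name == "auc":
            return self.macro_auc
        return self.macro[name]


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]
    fold_vectors: dict[str, np.ndarray]   # per-fold scalars for paired testing


# ----------------------------------------------------------------------
def confusion_and_metrics(true_labels, pred_labels, num_classes: int) -> MetricsReport:
    y, p = np.asarray(true_labels), np.asarray(pred_labels)
    if y.shape != p.shape or y.ndim != 1:
        raise ValidationError("labels must be matching 1-D arrays")
    if ((y < 0) | (y >= num_classes) | (p < 0) | (p >= num_classes)).any():
        raise ValidationError(f"labels outside [0, {num_classes})")
    cm = _sk_confusion(y, p, labels=np.arange(num_classes))
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _ratio(num, den, name):
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if not ok.all():
            log.warning("zero denominator in %s for classes %s; reporting 0",
                        name, np.flatnonzero(~ok).tolist())
        return out

    per = {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "accuracy": (tp + tn) / total,
        "precision": _ratio(tp, tp + fp, "precision"),
        "recall": _ratio(tp, tp + fn, "recall"),
    }
    pr_sum = per["precision"] + per["recall"]
    per["f1"] = _ratio(2 * per["precision"] * per["recall"], pr_sum, "f1")
    macro = {k: float(per[k].mean()) for k in ("accuracy", "precision", "recall", "f1")}
    return MetricsReport(confusion=cm, per_class=per, macro=macro,
                         overall_accuracy=float(tp.sum() / total))


def ovr_roc_auc(true_labels, class_scores) -> tuple[np.ndarray, float]:
    """Per-class one-vs-rest ROC AUC and their unweighted (macro) mean.

    Classes absent from the labels get nan and are excluded from the macro.
    """
    y = np.asarray(true_labels)
    s = np.asarray(class_scores, dtype=float)
    if s.ndim != 2 or s.shape[0] != y.size:
        raise ValidationError("scores must be an (N, K) matrix matching labels")
    k = s.shape[1]
    aucs = np.full(k, np.nan)
    for c in range(k):
        pos = y == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} absent (or alone) in labels; AUC undefined, "
                          "excluded from macro")
            continue
        aucs[c] = roc_auc_score(pos.astype(int), s[:, c])
    return aucs, float(np.nanmean(aucs))


def evaluate_model(model, images, labels, num_classes: int) -> MetricsReport:
    probs = model.predict_proba(images)
    report = confusion_and_metrics(labels, probs.argmax(axis=1), num_classes)
    report.ovr_auc, report.macro_auc = ovr_roc_auc(labels, probs)
    return report


# ----------------------------------------------------------------------
def stratified_kfold(labels, k: int, seed: int = 0, stratify: bool = True):
    """k disjoint (train_ids, test_ids) splits covering all samples."""
    y = np.asarray(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if stratify and (counts < k).any():
        small = classes[counts < k].tolist()
        raise ValidationError(f"classes {small} have fewer than k={k} members")
    if stratify:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros_like(y), y)]


def _check_disjoint(train_ids, test_ids) -> None:
    overlap = set(map(str, train_ids)) & set(map(str, test_ids))
    if overlap:
        raise LeakageError(f"train/eval subsets share ids: {sorted(overlap)[:5]} ...")


def train_model(model: MaxGRNet, train_data, val_data, cfg: TrainConfig,
                augment=None):
    """Seeded cross-entropy training with per-epoch accuracy history.

    ``train_data``/``val_data`` are (images, labels) or (images, labels, ids)
    tuples; when ids are supplied, train/val overlap is a hard error.  The
    optional ``augment(images, rng) -> images`` hook is applied to training
    batches only; every call is logged in the returned history for
    provenance auditing.
    """
    xtr, ytr = np.asarray(train_data[0], np.float32), np.asarray(train_data[1])
    xva, yva = np.asarray(val_data[0], np.float32), np.asarray(val_data[1])
    if len(train_data) > 2 and len(val_data) > 2:
        _check_disjoint(train_data[2], val_data[2])
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    history = {"epoch": [], "train_acc": [], "val_acc": [], "train_loss": [],
               "augment_calls": []}
    n_aug = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xtr))
        losses, correct = [], 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            if augment is not None:
                xb = augment(xb, rng)
                n_aug += 1
            opt.zero_grad()
            logits = model.forward(xb)
            loss = nn.cross_entropy(logits, yb)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        val_acc = float((model.predict(xva) == yva).mean())
        history["epoch"].append(epoch)
        history["train_acc"].append(correct / len(xtr))
        history["val_acc"].append(val_acc)
        history["train_loss"].append(float(np.mean(losses)))
        history["augment_calls"].append(n_aug)
        log.info("epoch %d: loss %.4f train_acc %.3f val_acc %.3f",
                 epoch, history["train_loss"][-1], history["train_acc"][-1], val_acc)
    return model, history


def run_crossval(model_factory, dataset, k: int, train_cfg: TrainConfig,
                 seed: int = 0, augment=None, stratify: bool = True) -> CVResult:
    """k-fold CV: fresh model per fold, train on k-1 folds, evaluate held-out.

    Augmentation (if any) happens inside :func:`train_model`, i.e. only on the
    training split of each fold.  Mean/std use ddof=1 across folds.
    """
    images, labels = np.asarray(dataset[0], np.float32), np.asarray(dataset[1])
    ids = np.asarray(dataset[2]) if len(dataset) > 2 else np.arange(len(labels))
    num_classes = int(labels.max()) + 1
    reports = []
    for fold, (tr, te) in enumerate(stratified_kfold(labels, k, seed=seed,
                                                     stratify=stratify)):
        _check_disjoint(ids[tr], ids[te])
        model = model_factory()
        cfg = TrainConfig(epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
                          learning_rate=train_cfg.learning_rate,
                          weight_decay=train_cfg.weight_decay,
                          seed=train_cfg.seed + fold)
        model, _ = train_model(model, (images[tr], labels[tr]),
                               (images[te], labels[te]), cfg, augment=augment)
        reports.append(evaluate_model(model, images[te], labels[te], num_classes))
    names = ("accuracy", "precision", "recall", "f1")
    vectors = {"accuracy": np.array([r.overall_accuracy for r in reports])}
    for nme in names[1:]:
        vectors[nme] = np.array([r.macro[nme] for r in reports])
    mean = {nme: float(v.mean()) for nme, v in vectors.items()}
    std = {nme: float(v.std(ddof=1)) for nme, v in vectors.items()}
    return CVResult(fold_reports=reports, mean=mean, std=std, fold_vectors=vectors)
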