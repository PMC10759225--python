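"""Training loop with early stopping, prediction, and evaluation metrics.

Training minimizes binary cross-entropy with Adam and stops once the
monitored BCE has failed to improve for ``patience`` consecutive epoch-level
evaluations, restoring the weights at the minimum.  Evaluation reports ROC
AUC, average precision, and a thresholded confusion matrix with precision /
recall / F1, optionally at the F1-maximizing threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, average_precision_score

from .dataset_io import InteractionDataset
from .encoding import build_batch, TokenBatch
from .model import CrossAttentionModel, ModelConfig, bce_loss

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "EarlyStopping", "TrainResult", "EvalReport",
    "train", "predict", "evaluate",
    "roc_auc", "average_precision", "confusion_at", "best_f1_threshold",
    "fold_enrichment", "per_peptide_report",
]


@dataclass
class TrainConfig:
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    monitor: str = "train_bce"          # or "val_bce"
    val_fraction: float = 0.1           # used only when monitor == "val_bce"


class EarlyStopping:
    """Stop after ``patience`` consecutive evaluations without strict improvement.

    The evaluation at index 0 (initial weights) is a candidate for the best.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_index = -1
        self.counter = 0
        self.n_seen = 0

    def update(self, value: float) -> bool:
        """Record one monitored value; returns True when training should stop."""
        if value < self.best:
            self.best = value
            self.best_index = self.n_seen
            self.counter = 0
        else:
            self.counter += 1
        self.n_seen += 1
        return self.counter >= self.patience


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class TrainResult:
    model: CrossAttentionModel
    history: list[float]          # monitored BCE; index 0 = initial weights
    best_epoch: int
    stopped_epoch: int


def _dataset_batch(ds: InteractionDataset, cfg: ModelConfig,
                   vocab=None) -> TokenBatch:
    return build_batch(ds.records, cfg.max_len_cdr3a, cfg.max_len_cdr3b,
                       cfg.max_len_peptide, vocab)


def train(train_ds: InteractionDataset, cfg: TrainConfig,
          model_cfg: ModelConfig | None = None) -> TrainResult:
    """Train a :class:`CrossAttentionModel` on an interaction dataset.

    If ``model_cfg`` is omitted, padded lengths are taken from the observed
    training maxima with default hyperparameters.  Returns the model with the
    weights that achieved the minimum monitored BCE, plus the loss history.
    """
    labels = train_ds.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both labels")
    if model_cfg is None:
        train_ds.compute_length_limits()
        model_cfg = ModelConfig(
            max_len_cdr3a=train_ds.max_len_cdr3a,
            max_len_cdr3b=train_ds.max_len_cdr3b,
            max_len_peptide=train_ds.max_len_peptide,
            seed=cfg.seed,
        )
    model = CrossAttentionModel(model_cfg)
    rng = np.random.default_rng(cfg.seed)

    records = list(train_ds.records)
    if cfg.monitor == "val_bce":
        n_val = max(1, int(round(cfg.val_fraction * len(records))))
        perm = rng.permutation(len(records))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, fit_idx = None, np.arange(len(records))

    full_batch = _dataset_batch(train_ds, model_cfg, model.vocab)
    y = labels.astype(float)

    def monitored() -> float:
        idx = val_idx if val_idx is not None else np.arange(len(records))
        # evaluate in chunks: attention activations scale with batch x L^2
        conf = np.concatenate([
            model.forward(full_batch.select(idx[s:s + 128])).confidence
            for s in range(0, len(idx), 128)])
        return bce_loss(conf, y[idx])

    stopper = EarlyStopping(cfg.patience)
    history = [monitored()]
    best_params = {k: t.data.copy() for k, t in model.params.items()}
    stopper.update(history[0])

    opt = _Adam(model.params, lr=cfg.learning_rate)
    stopped = cfg.max_epochs
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(fit_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            loss = model.loss(full_batch.select(idx), y[idx], training=True, rng=rng)
            loss.backward()
            opt.step()
        value = monitored()
        history.append(value)
        improved = value < stopper.best
        stop = stopper.update(value)
        if improved:
            best_params = {k: t.data.copy() for k, t in model.params.items()}
        if stop:
            stopped = epoch
            break
    for k, t in model.params.items():
        t.data = best_params[k]
    logger.info("training stopped at epoch %d; best epoch %d (monitored %.4f)",
                stopped, stopper.best_index, stopper.best)
    return TrainResult(model=model, history=history,
                       best_epoch=stopper.best_index, stopped_epoch=stopped)


def predict(model: CrossAttentionModel, ds: InteractionDataset,
            batch_size: int = 128) -> np.ndarray:
    """Order-preserving confidence vector for every record of ``ds``."""
    if len(ds) == 0:
        return np.zeros(0)
    batch = _dataset_batch(ds, model.cfg, model.vocab)
    out = [model.forward(batch.select(np.arange(s, min(s + batch_size, len(ds)))))
           .confidence for s in range(0, len(ds), batch_size)]
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# metrics

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank / Mann-Whitney formulation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))

def average_precision(scores, labels) -> float:
    """Average precision (step-wise area under the precision-recall curve)."""
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("average precision requires at least one positive")
    return float(average_precision_score(labels, scores))


def confusion_at(scores, labels, threshold: float) -> dict:
    """Confusion counts and precision/recall/F1 at ``score >= threshold``."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": precision, "recall": recall, "f1": f1,
            "threshold": float(threshold)}


def best_f1_threshold(scores, labels) -> float:
    """The observed score maximizing F1 (ties broken toward the smallest)."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    if y.sum() < 1:
        raise ValueError("needs at least one positive")
    candidates = np.unique(s)
    # sweep thresholds descending; at threshold t, predictions are s >= t
    order = np.argsort(-s, kind="stable")
    sorted_s, sorted_y = s[order], y[order]
    cum_tp = np.cumsum(sorted_y)
    n_pos = sorted_y.sum()
    # index of last prediction included for each candidate threshold
    best_f1, best_t = -1.0, candidates[0]
    for t in candidates:
        k = np.searchsorted(-sorted_s, -t, side="right")   # count of s >= t
        tp = cum_tp[k - 1] if k else 0
        prec = tp / k if k else 0.0
        rec = tp / n_pos
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if f1 > best_f1 or (f1 == best_f1 and t < best_t):
            best_f1, best_t = f1, t
    return float(best_t)


def fold_enrichment(precision: float, base_rate: float) -> float:
    """How much better than random selection: precision / base positive rate."""
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    return precision / base_rate


def per_peptide_report(scores, ds: InteractionDataset, top_k: int = 8) -> pd.DataFrame:
    """Record count, positive rate, and APS for the top-k most frequent peptides."""
    df = ds.to_frame()
    df["score"] = np.asarray(scores, float)
    counts = df["peptide"].value_counts()
    rows = []
    for pep in counts.index[:top_k]:
        sub = df[df["peptide"] == pep]
        aps = (average_precision(sub["score"].to_numpy(),
                                 sub["label"].astype(int).to_numpy())
               if sub["label"].astype(int).sum() else float("nan"))
        rows.append({"peptide": pep, "n_records": len(sub),
                     "positive_rate": float(sub["label"].astype(int).mean()),
                     "aps": aps})
    return pd.DataFrame(rows, columns=["peptide", "n_records", "positive_rate", "aps"])


@dataclass
class EvalReport:
    roc_auc: float
    average_precision: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    per_peptide: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def evaluate(scores, labels, ds: InteractionDataset | None = None,
             threshold: float | None = None, top_k: int = 8) -> EvalReport:
    """Full evaluation: AUC, APS and a confusion matrix.

    ``threshold=None`` uses the F1-maximizing observed score.
    """
    if threshold is None:
        threshold = best_f1_threshold(scores, labels)
    conf = confusion_at(scores, labels, threshold)
    per_pep = (per_peptide_report(scores, ds, top_k).to_dict("records")
               if ds is not None else [])
    return EvalReport(
        roc_auc=roc_auc(scores, labels),
        average_precision=average_precision(scores, labels),
        threshold=float(threshold), per_peptide=per_pep, **{
            k: conf[k] for k in ("tp", "fp", "fn", "tn",
                                 "precision", "recall", "f1")})
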