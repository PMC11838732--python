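"""Transfer heads on frozen study embeddings: multi-label diagnosis and
referral (positive-weighted binary cross-entropy), 3-class acuity
(categorical cross-entropy), age regression (L2), and a 5-fold linear-probe
protocol reporting mean +/- sd AUROC with a 2-layer MLP and a single logit.

The backbone is never touched: heads consume precomputed embedding arrays.
Checkpoint selection returns the parameters of the best validation epoch
(ties broken toward the earliest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import nn

CLAMP_EPS = 1e-7

TASKS = ("diagnosis", "referral", "acuity", "age", "probe")


@dataclass
class HeadConfig:
    task: str = "diagnosis"
    out_dim: int = 4
    hidden: int | None = None     # default max(32, out_dim, d // 4)
    epochs: int = 60
    lr: float = 1e-2
    batch_size: int = 32

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def layers(self):
        return 2 if self.task == "probe" else 3


def compute_positive_weights(labels: np.ndarray) -> np.ndarray:
    """Per-label (#negatives / #positives) on the training split."""
    labels = np.asarray(labels)
    pos = labels.sum(axis=0)
    for i, p in enumerate(pos):
        if p == 0:
            raise ValueError(f"label column {i} has zero positives")
    return (labels.shape[0] - pos) / pos


def multilabel_bce(y_hat, y, p):
    """Positive-weighted multi-label binary cross-entropy.

    -(1/L) sum_i [p_i y_i log yhat_i + (1 - y_i) log(1 - yhat_i)],
    averaged over rows when 2-D.  Probabilities at exactly 0/1 are clamped
    to [eps, 1-eps] with a warning.
    """
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if np.any(y_hat <= 0.0) or np.any(y_hat >= 1.0):
        warnings.warn("probabilities clamped to (eps, 1-eps)")
        y_hat = np.clip(y_hat, CLAMP_EPS, 1.0 - CLAMP_EPS)
    L = y_hat.shape[-1]
    terms = p * y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat)
    return float(-terms.sum(axis=-1).mean() / L)


def _bce_tensor(logits: nn.Tensor, y: np.ndarray, p: np.ndarray) -> nn.Tensor:
    """Trainable counterpart of multilabel_bce on raw logits."""
    L = y.shape[-1]
    y_t, p_t = nn.Tensor(y.astype(np.float32)), nn.Tensor(p.astype(np.float32))
    # log sigmoid / log(1-sigmoid) via softplus for stability
    sp = ((-logits.abs()).exp() + 1.0).log()
    log_sig = logits * nn.Tensor((logits.data < 0).astype(np.float32)) - sp
    log_one_minus = -logits * nn.Tensor((logits.data >= 0).astype(np.float32)) - sp
    terms = p_t * y_t * log_sig + (1.0 - y_t) * log_one_minus
    return -terms.sum(axis=-1).mean() / L


def _softmax_ce(logits: nn.Tensor, y_idx: np.ndarray) -> nn.Tensor:
    onehot = np.zeros(logits.shape, dtype=np.float32)
    onehot[np.arange(len(y_idx)), y_idx] = 1.0
    return -(logits.log_softmax(axis=-1) * nn.Tensor(onehot)).sum() / len(y_idx)


class _ScaledHead(nn.Module):
    """MLP whose scalar output is rescaled to the target's train-split
    mean/SD (regression heads start predicting the mean)."""

    def __init__(self, mlp, mu, sd):
        self.mlp = mlp
        self.mu, self.sd = mu, sd

    def __call__(self, x):
        return self.mlp(x) * self.sd + self.mu


def _validation_score(task, head, x_val, targets_val, pos_w=None):
    with nn.no_grad():
        out = head(nn.Tensor(x_val)).data
    if task in ("diagnosis", "referral", "probe"):
        probs = 1.0 / (1.0 + np.exp(-out))
        aucs = []
        t = np.atleast_2d(targets_val.T).T
        pr = probs if probs.ndim == 2 else probs[:, None]
        for i in range(t.shape[1]):
            col = t[:, i]
            if 0 < col.sum() < len(col):
                aucs.append(roc_auc_score(col, pr[:, i]))
        return float(np.mean(aucs)) if aucs else 0.5
    if task == "acuity":
        return float((out.argmax(axis=1) == targets_val).mean())
    # age: negative MAE so higher is better
    return -float(np.mean(np.abs(out[:, 0] - targets_val)))


def train_head(embeddings, targets, config: HeadConfig, seed=0,
               train_idx=None, val_idx=None):
    """Train an MLP head on frozen embeddings.

    targets: (n, L) multi-hot for diagnosis/referral, (n,) int class for
    acuity, (n,) float for age, (n,) binary for probe.  Returns
    (head, trace, best_state) where trace holds per-epoch validation scores
    (AUROC / accuracy / negative MAE) and best_state is the checkpoint of
    the argmax-validation epoch (earliest on ties).
    """
    x = np.asarray(embeddings, dtype=np.float32)
    rng = np.random.default_rng(seed)
    n, d = x.shape
    if train_idx is None:
        order = rng.permutation(n)
        n_val = max(1, n // 5)
        val_idx, train_idx = order[:n_val], order[n_val:]
    train_idx, val_idx = np.asarray(train_idx), np.asarray(val_idx)

    task = config.task
    targets = np.asarray(targets)
    if task in ("diagnosis", "referral"):
        if targets.ndim != 2 or targets.shape[1] != config.out_dim:
            raise ValueError("target shape does not match head out_dim")
        pos_w = compute_positive_weights(targets[train_idx])
    elif task == "probe":
        targets = targets.reshape(n, 1)
        pos_w = compute_positive_weights(targets[train_idx])
    elif task == "acuity":
        if targets.ndim != 1:
            raise ValueError("acuity targets must be 1-D class indices")
        pos_w = None
    elif task == "age":
        pos_w = None
        # standardize the regression target so the output layer starts
        # near the training mean
        t_mu = float(targets[train_idx].mean())
        t_sd = float(targets[train_idx].std() + 1e-8)

    hidden = config.hidden or max(32, config.out_dim, d // 4)
    dims = [d] + [hidden] * (config.layers - 1) + [config.out_dim]
    head = nn.MLP(rng, dims)
    if task == "age":
        head = _ScaledHead(head, t_mu, t_sd)
    opt = nn.AdamW(head.parameters(), lr=config.lr, clip_norm=1.0)

    x_tr, x_val = x[train_idx], x[val_idx]
    t_tr, t_val = targets[train_idx], targets[val_idx]
    trace, best_score, best_state = [], -np.inf, None
    for _ in range(config.epochs):
        perm = rng.permutation(len(x_tr))
        for s in range(0, len(x_tr), config.batch_size):
            idx = perm[s:s + config.batch_size]
            logits = head(nn.Tensor(x_tr[idx]))
            if task in ("diagnosis", "referral", "probe"):
                loss = _bce_tensor(logits, t_tr[idx], pos_w)
            elif task == "acuity":
                loss = _softmax_ce(logits, t_tr[idx])
            else:
                diff = logits[:, 0] - nn.Tensor(t_tr[idx].astype(np.float32))
                loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        score = _validation_score(task, head, x_val, t_val, pos_w)
        trace.append(score)
        if score > best_score:
            best_score = score
            best_state = [p.data.copy() for p in head.parameters()]
    for p, w in zip(head.parameters(), best_state):
        p.data = w.copy()
    return head, trace, best_state


def predict_head(head, embeddings):
    with nn.no_grad():
        return head(nn.Tensor(np.asarray(embeddings, dtype=np.float32))).data


def linear_probe_cv(embeddings, binary_target, folds=5, seed=0, epochs=40):
    """Stratified k-fold probe protocol: 2-layer MLP, single logit, BCE.

    Returns (mean, sd) of per-fold validation AUROC.
    """
    x = np.asarray(embeddings, dtype=np.float32)
    y = np.asarray(binary_target).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("probe target must contain both classes")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for fold, (tr, va) in enumerate(skf.split(x, y)):
        cfg = HeadConfig(task="probe", out_dim=1, epochs=epochs)
        # checkpoint selection uses an internal split of the training fold;
        # the held-out fold is touched only for the reported score
        head, _, _ = train_head(x[tr], y[tr], cfg, seed=seed + fold)
        scores = predict_head(head, x[va])[:, 0]
        aucs.append(roc_auc_score(y[va], scores))
    return float(np.mean(aucs)), float(np.std(aucs))
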