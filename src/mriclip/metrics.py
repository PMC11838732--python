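"""Alignment and cohort evaluation metrics: top-k study/report retrieval,
grouped retrieval, multi-label AUROC, neighbor-based normalized positive
rate (NPR), and priority-score correlation."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score


def topk_retrieval(sim, k):
    """Fraction of rows whose matched column index (the diagonal) is among
    the k largest entries; ties broken toward the lowest index."""
    sim = np.asarray(sim)
    n = sim.shape[0]
    if not 1 <= k <= sim.shape[1]:
        raise ValueError("k must lie in [1, N]")
    order = np.argsort(-sim, axis=1, kind="stable")
    hits = (order[:, :k] == np.arange(n)[:, None]).any(axis=1)
    return float(hits.mean())


def grouped_retrieval(sim, group_size=100, seed=0):
    """Mean within-group Top-1 over random disjoint groups of `group_size`.

    Remainder items (N mod group_size) are dropped.
    """
    sim = np.asarray(sim)
    n = sim.shape[0]
    if n < group_size:
        raise ValueError("need at least one full group")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    accs = []
    for s in range(0, n - group_size + 1, group_size):
        idx = perm[s:s + group_size]
        accs.append(topk_retrieval(sim[np.ix_(idx, idx)], 1))
    return float(np.mean(accs))


def multilabel_auroc(scores, labels):
    """Per-label rank-based AUROC (midrank ties) and their mean.

    Labels with a single class are reported as nan and excluded from the
    mean with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float).T).T
    labels = np.atleast_2d(np.asarray(labels).T).T
    per_label = np.full(labels.shape[1], np.nan)
    for i in range(labels.shape[1]):
        col = labels[:, i]
        if 0 < col.sum() < len(col):
            per_label[i] = roc_auc_score(col, scores[:, i])
    if np.isnan(per_label).any():
        warnings.warn("labels with one class excluded from mean AUROC")
    mean = float(np.nanmean(per_label)) if not np.isnan(per_label).all() else np.nan
    return per_label, mean


def npr(embeddings_query, embeddings_reference, labels_reference,
        query_labels=None, k=20, self_exclude=None):
    """Normalized positive rate of the top-k cosine nearest reference
    neighbors: (mean positive rate among neighbors) / (reference base rate).

    Returns (mean NPR over all queries, mean NPR over positive queries).
    When the query set is the reference set, each query's self-neighbor is
    removed (override with `self_exclude`).
    """
    q = np.asarray(embeddings_query, dtype=float)
    ref = np.asarray(embeddings_reference, dtype=float)
    y = np.asarray(labels_reference).astype(float)
    base = y.mean()
    if base <= 0:
        raise ValueError("reference base rate is zero")
    if self_exclude is None:
        self_exclude = q.shape == ref.shape and np.array_equal(q, ref)
    qn = q / np.linalg.norm(q, axis=1, keepdims=True)
    rn = ref / np.linalg.norm(ref, axis=1, keepdims=True)
    sim = qn @ rn.T
    if self_exclude:
        np.fill_diagonal(sim, -np.inf)
    nn_idx = np.argsort(-sim, axis=1, kind="stable")[:, :k]
    rates = y[nn_idx].mean(axis=1)
    npr_all = rates / base
    mean_all = float(npr_all.mean())
    mean_pos = np.nan
    if query_labels is not None:
        ql = np.asarray(query_labels).astype(bool)
        if ql.any():
            mean_pos = float(npr_all[ql].mean())
    return mean_all, mean_pos


def priority_correlation(priority_score, priority_truth, method="pearson"):
    """Correlation of a [0, 1] priority score with ordinal truth {0, 1, 2}.

    Returns (r, (lo, hi)) with a Fisher-z 95% confidence interval.
    """
    x = np.asarray(priority_score, dtype=float)
    y = np.asarray(priority_truth, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if method == "pearson":
        r, _ = stats.pearsonr(x, y)
    elif method == "spearman":
        r, _ = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(len(x) - 3)
    lo, hi = np.tanh(z - 1.959964 * se), np.tanh(z + 1.959964 * se)
    return float(r), (float(lo), float(hi))


def normalized_priority_score(acuity_logits):
    """Softmax-expected class index of 3-level acuity logits, rescaled to
    [0, 1] (0 = normal, 1 = high)."""
    logits = np.asarray(acuity_logits, dtype=float)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    return (p @ np.arange(logits.shape[1])) / (logits.shape[1] - 1)
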