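"""LIME token attribution for volume-token models.

One sequence of a study is perturbed by token removal: random binary masks
select token subsets, the model's target-label logit is evaluated per
masked input, and a locality-weighted least-squares linear surrogate maps
masks to logits.  Coefficients rank token importance; rankings can be scored
against ground-truth lesion masks via the tokenizer's patch grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class LimeExplanation:
    weights: np.ndarray           # (n_tokens,) surrogate coefficients
    ranking: np.ndarray           # token indices, weight descending
    grid_coords: np.ndarray       # (n_tokens, 3) token grid coordinates
    intercept: float = 0.0


def sample_masks(n_tokens, n_samples=3000, keep_prob=0.5, seed=0):
    """(n_samples, n_tokens) binary keep-masks.

    The first mask is all-ones; the rest are i.i.d. Bernoulli(keep_prob)
    with all-zero draws resampled.
    """
    if n_tokens < 1:
        raise ValueError("need at least one token")
    if not 0.0 < keep_prob <= 1.0:
        raise ValueError("keep_prob must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    masks = np.ones((n_samples, n_tokens), dtype=np.int8)
    for i in range(1, n_samples):
        m = (rng.random(n_tokens) < keep_prob).astype(np.int8)
        while not m.any():
            m = (rng.random(n_tokens) < keep_prob).astype(np.int8)
        masks[i] = m
    return masks


def locality_weights(masks, sigma=0.25):
    """exp(-(1 - s)^2 / sigma^2) with s = cosine(mask, all-ones mask)."""
    m = np.asarray(masks, dtype=float)
    n = m.shape[1]
    s = m.sum(axis=1) / (np.sqrt(n) * np.sqrt(m.sum(axis=1)))
    return np.exp(-((1.0 - s) ** 2) / sigma ** 2)


def _wls(masks, logits, weights, ridge=0.0):
    X = np.concatenate([np.ones((masks.shape[0], 1)), masks], axis=1).astype(float)
    sw = np.sqrt(weights)[:, None]
    A, b = X * sw, logits * sw[:, 0]
    if ridge > 0:
        d = X.shape[1]
        reg = np.sqrt(ridge) * np.eye(d)
        reg[0, 0] = 0.0
        A = np.concatenate([A, reg], axis=0)
        b = np.concatenate([b, np.zeros(d)])
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return coef[0], coef[1:]


def explain(model, tok_seq, target_label, n_samples=3000, keep_prob=0.5,
            seed=0, sigma=0.25, ridge=0.0):
    """Fit the LIME surrogate for one tokenized sequence.

    `model` must implement masked_logits(tok_seq, masks, target_label) ->
    (n_samples,) array of the target-label logit for each token subset.
    Ties in the ranking break toward the lexicographically lowest grid
    coordinate.  Deterministic given `seed`.
    """
    n_tokens = tok_seq.tokens.shape[0]
    if n_tokens < 2:
        raise ValueError("need >= 2 tokens to perturb")
    masks = sample_masks(n_tokens, n_samples, keep_prob, seed)
    if (masks == masks[0]).all():
        raise ValueError("degenerate design: all masks identical")
    logits = np.asarray(model.masked_logits(tok_seq, masks, target_label),
                        dtype=float)
    w = locality_weights(masks, sigma)
    intercept, coef = _wls(masks, logits, w, ridge)
    coords = np.asarray(tok_seq.grid_coords)
    order = sorted(range(n_tokens),
                   key=lambda i: (-coef[i], tuple(coords[i])))
    return LimeExplanation(weights=coef, ranking=np.array(order),
                           grid_coords=coords, intercept=float(intercept))


def topk_overlap_accuracy(explanations, lesion_token_sets, k=3):
    """Fraction of cases where >= 1 of the top-k ranked tokens lies in the
    lesion token set; cases with empty lesion sets are excluded (warned)."""
    hits, total = 0, 0
    for expl, lesion in zip(explanations, lesion_token_sets):
        if not lesion:
            warnings.warn("case with empty lesion token set excluded")
            continue
        total += 1
        top = expl.ranking[:k]
        if any(tuple(expl.grid_coords[i]) in lesion for i in top):
            hits += 1
    if total == 0:
        return np.nan
    return hits / total
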