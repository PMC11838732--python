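"""Equalized-opportunity fairness audit and prospective design statistics.

True-positive-rate disparity (subgroup TPR minus population TPR, in
[-1, 1]) is the deviation measure; subgroup-vs-population differences are
tested by bootstrap resampling (200 draws with replacement per side,
diagnosis-matched population samples, 20 iterations) with a one-sided
Mann-Whitney U test whose null is that the subgroup TPR distribution is not
less than the population's.  Turnaround-time disparities use Fisher's exact
test with Haldane-Anscombe-corrected odds ratios and family-wise p-value
correction across an attribute's levels.  A two-group superiority sample
size calculator covers prospective design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class DisparityResult:
    tpr_group: float
    tpr_pop: float
    disparity: float              # tpr_group - tpr_pop
    p_value: float | None = None
    n_boot: int = 0
    ci: tuple | None = None       # bootstrap percentile CI on the disparity


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(table)


def tpr(table, subset=None) -> float:
    """Exact TPR (correct positives / positives) over an optional row subset."""
    df = _as_frame(table)
    if subset is not None:
        df = df.loc[subset] if not isinstance(subset, np.ndarray) else df[subset]
    y = df["y"].to_numpy().astype(int)
    y_hat = df["y_hat"].to_numpy().astype(int)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("subset contains no positives; TPR undefined")
    return float(((y == 1) & (y_hat == 1)).sum() / n_pos)


def tpr_disparity(table, group) -> DisparityResult:
    """Point-estimate TPR disparity: subgroup TPR minus population TPR."""
    t_g = tpr(table, group)
    t_p = tpr(table)
    return DisparityResult(tpr_group=t_g, tpr_pop=t_p, disparity=t_g - t_p)


def _matched_sample(rng, y_pop, group_y_draw, n):
    """Population indices matched to the subgroup draw's label frequency."""
    n_pos = int(round(n * group_y_draw.mean()))
    n_pos = min(max(n_pos, 1), n)
    pos_idx = np.flatnonzero(y_pop == 1)
    neg_idx = np.flatnonzero(y_pop == 0)
    take_pos = rng.choice(pos_idx, size=n_pos, replace=True)
    if n - n_pos > 0 and len(neg_idx):
        take_neg = rng.choice(neg_idx, size=n - n_pos, replace=True)
        return np.concatenate([take_pos, take_neg])
    return take_pos


def bootstrap_disparity_test(table, group, n_per_draw=200, iterations=20,
                             seed=0) -> DisparityResult:
    """Bootstrap equalized-opportunity test for one subgroup.

    Per iteration: resample `n_per_draw` patients with replacement from the
    subgroup and a diagnosis-matched sample from the whole population;
    compute both TPRs.  One-sided Mann-Whitney U with null "subgroup TPR is
    not less than population TPR".
    """
    df = _as_frame(table)
    gmask = np.asarray(group, dtype=bool)
    y_g = df["y"].to_numpy().astype(int)[gmask]
    yh_g = df["y_hat"].to_numpy().astype(int)[gmask]
    if y_g.sum() < 1:
        raise ValueError("subgroup has no positives")
    y_p = df["y"].to_numpy().astype(int)
    yh_p = df["y_hat"].to_numpy().astype(int)
    rng = np.random.default_rng(seed)
    t_group, t_pop = [], []
    for _ in range(iterations):
        gi = rng.integers(len(y_g), size=n_per_draw)
        while y_g[gi].sum() == 0:
            gi = rng.integers(len(y_g), size=n_per_draw)
        pi = _matched_sample(rng, y_p, y_g[gi], n_per_draw)
        t_group.append(yh_g[gi][y_g[gi] == 1].mean())
        t_pop.append(yh_p[pi][y_p[pi] == 1].mean())
    t_group, t_pop = np.array(t_group), np.array(t_pop)
    _, p = stats.mannwhitneyu(t_group, t_pop, alternative="less")
    diffs = t_group - t_pop
    point = tpr_disparity(df, gmask)
    return DisparityResult(
        tpr_group=float(t_group.mean()), tpr_pop=float(t_pop.mean()),
        disparity=point.disparity, p_value=float(p), n_boot=iterations,
        ci=(float(np.quantile(diffs, 0.025)), float(np.quantile(diffs, 0.975))))


def odds_ratio_fisher(exposed, reference, correction="haldane"):
    """Odds ratio with exact two-sided Fisher p-value and a 95% Woolf CI.

    exposed/reference: (events, non-events) counts.  Zero cells get the
    Haldane-Anscombe 0.5 continuity correction for the OR and CI (flagged in
    the result); the p-value is the exact conditional test on raw counts.
    Returns dict(or, ci, p, corrected_cells).
    """
    a, b = exposed
    c, d = reference
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("table is all-zero")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected and correction == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(oratio) - 1.959964 * se))
    hi = float(np.exp(np.log(oratio) + 1.959964 * se))
    return {"or": float(oratio), "ci": (lo, hi), "p": float(p),
            "corrected_cells": corrected}


def turnaround_odds_ratios(meta_table, attribute, threshold_days=7.0,
                           reference=None, method="holm"):
    """Per-level odds of long turnaround (> threshold) vs the reference
    level, with family-wise corrected Fisher p-values.

    meta_table: DataFrame with `turnaround_days` and attribute columns.
    Returns {level: result dict} incl. `p_corrected`.
    """
    df = _as_frame(meta_table)
    long = df["turnaround_days"].to_numpy() > threshold_days
    values = df[attribute].to_numpy()
    levels = sorted(set(values))
    if reference is None:
        # most common level is the reference
        reference = max(levels, key=lambda v: (values == v).sum())
    ref_mask = values == reference
    ref_counts = (int(long[ref_mask].sum()), int((~long[ref_mask]).sum()))
    out = {}
    for lv in levels:
        if lv == reference:
            continue
        m = values == lv
        res = odds_ratio_fisher(
            (int(long[m].sum()), int((~long[m]).sum())), ref_counts)
        out[lv] = res
    if out:
        keys = list(out)
        _, p_corr, _, _ = multipletests([out[k]["p"] for k in keys],
                                        method=method)
        for k, pc in zip(keys, p_corr):
            out[k]["p_corrected"] = float(pc)
    return out, reference


def superiority_sample_size(p_control, p_experimental, margin, alpha=0.01,
                            power=0.90, allocation=1.0):
    """Total n for a parallel two-group superiority trial, binary outcome.

    Normal-approximation formula (one-sided alpha):
    n_control = (z_{1-a} + z_{1-b})^2 (pc(1-pc)/r + pe(1-pe)) / (pe-pc-m)^2,
    per-group sizes rounded up; returns control + experimental total.
    """
    for p in (p_control, p_experimental):
        if not 0.0 < p < 1.0:
            raise ValueError("proportions must lie in (0, 1)")
    if margin <= 0:
        raise ValueError("superiority margin must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(power)
    r = allocation
    num = (z_a + z_b) ** 2 * (p_control * (1 - p_control) / r
                              + p_experimental * (1 - p_experimental))
    den = (p_experimental - p_control - margin) ** 2
    n_exp = int(np.ceil(num / den))
    n_con = int(np.ceil(n_exp / r))
    return n_exp + n_con
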