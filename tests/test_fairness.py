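"""Fairness audit: TPR disparity identities and bounds, bootstrap test
calibration and power, Fisher exact odds ratios vs hypergeometric
enumeration, and the superiority sample-size formula."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from mriclip.fairness import (bootstrap_disparity_test, odds_ratio_fisher,
                              superiority_sample_size, tpr, tpr_disparity,
                              turnaround_odds_ratios)


def _table(y, y_hat, **cols):
    return pd.DataFrame({"y": y, "y_hat": y_hat, **cols})


def test_tpr_counting():
    t = _table([1, 1, 1, 1, 0], [1, 1, 1, 0, 1])
    assert tpr(t) == pytest.approx(0.75)
    t2 = _table([1, 1], [1, 1])
    assert tpr(t2) == 1.0
    with pytest.raises(ValueError):
        tpr(_table([0, 0], [1, 0]))


def test_tpr_matches_brute_force_row_scan():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = (rng.random(50) < 0.4).astype(int)
        if y.sum() == 0:
            continue
        y_hat = (rng.random(50) < 0.5).astype(int)
        expected = sum(1 for a, b in zip(y, y_hat) if a == 1 and b == 1) / y.sum()
        assert tpr(_table(y, y_hat)) == pytest.approx(expected)


def test_disparity_identity_and_arithmetic():
    t = _table([1, 1, 1, 0], [1, 0, 1, 1])
    full = np.ones(4, dtype=bool)
    assert tpr_disparity(t, full).disparity == pytest.approx(0.0)
    # group TPR 0.6 vs population 0.8 -> -0.2
    y = [1] * 10
    y_hat = [1] * 8 + [0] * 2
    group = np.zeros(10, dtype=bool)
    group[3:8] = True              # group TPR 5/5 positives -> pick values
    t2 = _table(y, y_hat)
    d = tpr_disparity(t2, group)
    assert d.disparity == pytest.approx(d.tpr_group - d.tpr_pop)


def test_disparity_bounds_on_random_tables():
    rng = np.random.default_rng(1)
    checked = 0
    for _ in range(1000):
        y = (rng.random(30) < 0.5).astype(int)
        y_hat = (rng.random(30) < 0.5).astype(int)
        g = rng.random(30) < 0.4
        if y.sum() == 0 or y[g].sum() == 0:
            continue
        d = tpr_disparity(_table(y, y_hat), g).disparity
        assert -1.0 <= d <= 1.0
        checked += 1
    assert checked > 500


def _fisher_p_oracle(a, b, c, d):
    """Exact conditional two-sided p by hypergeometric enumeration."""
    n1, n0 = a + b, c + d
    m = a + c
    total = n1 + n0

    def prob(x):
        return comb(n1, x) * comb(n0, m - x) / comb(total, m)

    p_obs = prob(a)
    lo = max(0, m - n0)
    hi = min(m, n1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def test_fisher_or_symmetric_table_is_one():
    res = odds_ratio_fisher((10, 10), (10, 10))
    assert res["or"] == pytest.approx(1.0)
    assert res["p"] == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_enumeration():
    res = odds_ratio_fisher((20, 10), (10, 20))
    assert res["or"] == pytest.approx(4.0)
    assert res["p"] == pytest.approx(_fisher_p_oracle(20, 10, 10, 20),
                                     rel=1e-6)
    rng = np.random.default_rng(2)
    for _ in range(15):
        a, b, c, d = rng.integers(1, 15, size=4)
        res = odds_ratio_fisher((a, b), (c, d))
        assert res["p"] == pytest.approx(_fisher_p_oracle(a, b, c, d),
                                         rel=1e-6)


def test_fisher_zero_cell_haldane_flagged():
    res = odds_ratio_fisher((5, 0), (3, 7))
    assert res["corrected_cells"]
    assert np.isfinite(res["or"]) and res["or"] > 1
    with pytest.raises(ValueError):
        odds_ratio_fisher((-1, 2), (3, 4))
    with pytest.raises(ValueError):
        odds_ratio_fisher((0, 0), (0, 0))


def test_turnaround_odds_ratios_family_correction():
    rng = np.random.default_rng(3)
    n = 300
    region = rng.choice(["urban", "suburban", "rural"], size=n)
    days = rng.exponential(4, size=n)
    df = pd.DataFrame({"turnaround_days": days, "region": region})
    results, ref = turnaround_odds_ratios(df, "region")
    assert ref == "urban" or ref in ("suburban", "rural")
    for lv, res in results.items():
        assert res["p_corrected"] >= res["p"] - 1e-12


def test_sample_size_reproduces_printed_total():
    assert superiority_sample_size(0.78, 0.78, margin=0.02, alpha=0.01,
                                   power=0.90) == 22338


def test_sample_size_quantile_formula_oracle():
    z_a = stats.norm.ppf(0.99)
    z_b = stats.norm.ppf(0.90)
    per_group = np.ceil((z_a + z_b) ** 2 * 2 * 0.78 * 0.22 / 0.02 ** 2)
    assert superiority_sample_size(0.78, 0.78, 0.02, 0.01, 0.90) == 2 * per_group


def test_sample_size_monotonicity_and_margin_scaling():
    base = superiority_sample_size(0.78, 0.78, 0.02, 0.01, 0.90)
    doubled = superiority_sample_size(0.78, 0.78, 0.04, 0.01, 0.90)
    assert doubled == pytest.approx(base / 4, rel=0.01)
    assert superiority_sample_size(0.78, 0.78, 0.02, 0.01, 0.95) > base
    assert superiority_sample_size(0.78, 0.78, 0.03, 0.01, 0.90) < base
    with pytest.raises(ValueError):
        superiority_sample_size(1.2, 0.5, 0.02)
    with pytest.raises(ValueError):
        superiority_sample_size(0.5, 0.5, -0.1)


def _synthetic_table(rng, n, group_frac, tpr_group, tpr_other):
    g = rng.random(n) < group_frac
    y = (rng.random(n) < 0.5).astype(int)
    p_hit = np.where(g, tpr_group, tpr_other)
    y_hat = ((rng.random(n) < p_hit) & (y == 1)).astype(int)
    return _table(y, y_hat, group=g), g


def test_bootstrap_null_calibration():
    """No planted disparity: p > 0.05 in at least 18 of 20 cohorts.

    Cohorts are prospective-scale (30k patients): the 200-patient bootstrap
    draws are then the dominant noise source and the test is calibrated;
    in much smaller cohorts the subgroup's own sampling error shifts the
    whole bootstrap distribution and the test becomes anticonservative.
    """
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        t, g = _synthetic_table(rng, 30000, 0.3, 0.8, 0.8)
        res = bootstrap_disparity_test(t, g, seed=seed)
        ok += res.p_value > 0.05
    assert ok >= 18


def test_bootstrap_detects_planted_disparity():
    """Subgroup TPR 0.3 vs population 0.9: p < 0.05 in >= 18/20 cohorts,
    and the point disparity falls inside the bootstrap CI in >= 90%."""
    sig = cover = 0
    for seed in range(20):
        rng = np.random.default_rng(300 + seed)
        t, g = _synthetic_table(rng, 500, 0.3, 0.3, 0.9)
        res = bootstrap_disparity_test(t, g, seed=seed)
        sig += res.p_value < 0.05
        cover += res.ci[0] <= res.disparity <= res.ci[1]
        assert res.disparity < 0
    assert sig >= 18
    assert cover >= 18


def test_bootstrap_requires_group_positives():
    t = _table([0, 0, 1, 1], [0, 0, 1, 1])
    g = np.array([True, True, False, False])
    with pytest.raises(ValueError):
        bootstrap_disparity_test(t, g)
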