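"""Classical store-comparison tests against hand and reference oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from immersim.stats_battery import (
    GroupSummary,
    ks_two_sample,
    pearson_correlation,
    pooled_t_test,
    summary_battery,
    two_proportion_chi2,
)


def t_sf_reference(t, df):
    """Student-t upper tail via the regularised incomplete beta function."""
    x = df / (df + t * t)
    p = 0.5 * special.betainc(df / 2.0, 0.5, x)
    return p if t >= 0 else 1.0 - p


def test_identical_groups_give_null_result():
    g = GroupSummary(10, 5.0, 1.0)
    res = pooled_t_test(g, g)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_pooled_t_hand_example():
    res = pooled_t_test(GroupSummary(5, 10.0, 2.0), GroupSummary(5, 8.0, 2.0))
    assert res.statistic == pytest.approx(1.5811, abs=1e-4)
    assert res.df == 8


def test_summary_matches_raw_sample():
    rng = np.random.default_rng(1)
    a = rng.normal(3, 1, 20)
    b = rng.normal(2.5, 1.4, 15)
    raw = pooled_t_test(a, b)
    summ = pooled_t_test(
        GroupSummary(len(a), float(a.mean()), float(np.std(a, ddof=1))),
        GroupSummary(len(b), float(b.mean()), float(np.std(b, ddof=1))),
    )
    assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
    assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)


def test_one_tailed_halves_two_tailed():
    a = GroupSummary(12, 5.5, 1.0)
    b = GroupSummary(12, 5.0, 1.0)
    assert pooled_t_test(a, b, "one").p_value == pytest.approx(
        pooled_t_test(a, b, "two").p_value / 2
    )


def test_t_pvalues_match_incomplete_beta_reference():
    """The t tail probability the battery relies on agrees with a direct
    incomplete-beta evaluation on a grid of statistics and df."""
    rng = np.random.default_rng(8)
    for df in (5, 24, 54, 200):
        n_a = df // 2 + 1
        n_b = df - n_a + 2
        a = rng.normal(1.0, 1.0, n_a)
        b = rng.normal(0.5, 1.0, n_b)
        res = pooled_t_test(a, b)
        assert res.p_value == pytest.approx(2 * t_sf_reference(abs(res.statistic), res.df), abs=1e-8)


def test_chi2_equal_proportions_null():
    res = two_proportion_chi2(10, 20, 10, 20)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_chi2_hand_oracle():
    # 2x2 shortcut formula n(ad-bc)^2 / (row/col products)
    a, b, c, d = 23, 8, 13, 12
    n = a + b + c + d
    expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    res = two_proportion_chi2(23, 31, 13, 25, yates=False)
    assert res.statistic == pytest.approx(expected, abs=1e-10)
    assert res.statistic == pytest.approx(2.969, abs=0.01)
    res_y = two_proportion_chi2(23, 31, 13, 25, yates=True)
    assert res_y.statistic == pytest.approx(2.08, abs=0.01)
    assert res_y.statistic < res.statistic


def test_chi2_zero_marginal_rejected():
    with pytest.raises(ValueError):
        two_proportion_chi2(0, 10, 0, 12)


def test_pearson_exact_lines():
    x = np.arange(1.0, 11.0)
    assert pearson_correlation(x, 2 * x).estimate == pytest.approx(1.0)
    assert pearson_correlation(x, -x).estimate == pytest.approx(-1.0)


def test_pearson_hand_example():
    res = pearson_correlation([1, 2, 3], [1, 2, 4])
    assert res.estimate == pytest.approx(0.9820, abs=1e-4)
    one = pearson_correlation([1, 2, 3], [1, 2, 4], tails="one")
    assert one.p_value == pytest.approx(res.p_value / 2)


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValueError):
        pearson_correlation([1, 1, 1], [1, 2, 3])


def test_ks_identical_and_disjoint():
    x = np.linspace(0, 1, 50)
    res = ks_two_sample(x, x)
    assert res.statistic == 0.0
    far = ks_two_sample(x, x + 10)
    assert far.statistic == 1.0
    assert far.p_value < 1e-6


def test_ks_type_one_error_calibrated():
    rng = np.random.default_rng(2024)
    rejections = 0
    reps = 400
    for _ in range(reps):
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        if ks_two_sample(x, y).p_value < 0.05:
            rejections += 1
    assert 0.02 <= rejections / reps <= 0.08


def test_summary_battery_batch(tmp_path):
    df = pd.DataFrame(
        {
            "label": ["dwell", "dwell", "amount", "amount"],
            "group": ["WS", "MS", "WS", "MS"],
            "n": [31, 25, 31, 25],
            "mean": [32.15, 14.69, 265.79, 140.12],
            "sd": [35.37, 10.93, 517.37, 229.42],
        }
    )
    out = summary_battery(df)
    assert list(out["label"]) == ["dwell", "amount"]
    assert out.loc[0, "t"] == pytest.approx(2.372, abs=0.02)
    assert out.loc[1, "t"] == pytest.approx(1.125, abs=0.02)
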