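"""Statistical layer: regression oracles, group tests, mixed models, exact
set-overlap distributions."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import gliaquant as gq


# ---------------------------------------------------------------------------
# OLS / multiple regression
# ---------------------------------------------------------------------------

def test_ols_trivial_lines():
    r = gq.ols_fit([0, 1, 2], [0, 1, 2])
    assert r.slope == pytest.approx(1.0) and r.r_squared == pytest.approx(1.0)
    r = gq.ols_fit([0, 1, 2, 3], [5, 5, 5, 5])
    assert r.slope == pytest.approx(0.0, abs=1e-12)
    assert r.r_squared == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        gq.ols_fit([2, 2, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        gq.ols_fit([1, 2], [1, 2])


def test_ols_matches_normal_equations():
    rng = np.random.default_rng(0)
    for _ in range(5):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        r = gq.ols_fit(x, y)
        X = np.column_stack([np.ones(25), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert r.intercept == pytest.approx(beta[0], abs=1e-10)
        assert r.slope == pytest.approx(beta[1], abs=1e-10)


def test_multiple_regression_exact_and_oracle():
    rng = np.random.default_rng(1)
    treat = np.repeat([0.0, 1.0], 10)
    cov = rng.normal(50, 10, 20)
    y = 3.0 - 100.0 * treat + 0.2 * cov   # noise-free construction
    r = gq.multiple_regression(y, treat, cov)
    assert r.params["treatment"] == pytest.approx(-100.0, abs=1e-9)
    assert r.params["covariate"] == pytest.approx(0.2, abs=1e-10)
    # against the 2-predictor normal equations on a random design
    y2 = rng.normal(size=20)
    r2 = gq.multiple_regression(y2, treat, cov)
    X = np.column_stack([np.ones(20), treat, cov])
    beta = np.linalg.solve(X.T @ X, X.T @ y2)
    assert r2.params["treatment"] == pytest.approx(beta[1], abs=1e-10)
    assert r2.params["covariate"] == pytest.approx(beta[2], abs=1e-10)
    with pytest.raises(ValueError):
        gq.multiple_regression(y, treat, treat * 2.0)


def test_permutation_calibration_of_treatment_p():
    """Permuting the treatment labels makes the treatment p-value uniform:
    rejection rate at alpha = 0.05 lies in [0.02, 0.09]."""
    rng = np.random.default_rng(2)
    n = 40
    cov = rng.normal(0, 1, n)
    y = 0.5 * cov + rng.normal(0, 1, n)
    treat = np.repeat([0.0, 1.0], n // 2)
    rejections = 0
    n_perm = 200
    for _ in range(n_perm):
        r = gq.multiple_regression(y, rng.permutation(treat), cov)
        rejections += r.pvalues["treatment"] < 0.05
    assert 0.02 <= rejections / n_perm <= 0.09


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def test_anova_identical_and_separated_groups():
    g = [1.0, 2.0, 3.0, 4.0]
    r = gq.anova_tukey([g, list(g), list(g)])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert (r.pairwise["p-adj"].astype(float) > 0.9).all()
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 10)
    b = rng.normal(10, 1, 10)   # 10 SD shift
    r = gq.anova_tukey([a, b], labels=["a", "b"])
    assert r.p_value < 1e-6
    t = gq.unpaired_t(a, b)
    assert t.p_value < 1e-6
    w = gq.unpaired_t(a, b, welch=True)
    assert w.p_value < 1e-6
    flagged = gq.anova_tukey([[1.0, 1.0], [2.0, 3.0]])
    assert flagged.flags


def test_anova_type_one_error_calibrated():
    rng = np.random.default_rng(4)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        _, p = sps.f_oneway(*groups)
        rejections += p < 0.05
    # 3 SE binomial band around 0.05
    band = 3 * np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rejections / n_sim - 0.05) <= band


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _lmm_table(seed, n_mice=20, per=30, slope=-0.01, re_sd=0.3, noise=0.2):
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        b = rng.normal(0, re_sd)
        d = rng.uniform(5, 45, per)
        y = -2.0 + slope * d + b + rng.normal(0, noise, per)
        rows += [dict(mouse=m, diameter=dd, log_asm=yy) for dd, yy in zip(d, y)]
    return pd.DataFrame(rows)


def test_lmm_degenerate_limit_equals_pooled_ols():
    df = _lmm_table(0, re_sd=0.0)
    spec = gq.MixedModelSpec(response="log_asm", fixed_effects=["diameter"],
                             group="mouse")
    res = gq.fit_mixed_model(spec, df)
    assert res.random_intercept_var == pytest.approx(0.0, abs=1e-3)
    ols = gq.ols_fit(df["diameter"], df["log_asm"])
    assert res.params["diameter"] == pytest.approx(ols.slope, abs=1e-4)


def test_lmm_recovers_diameter_slope():
    ests = [gq.fit_mixed_model(
        gq.MixedModelSpec(response="log_asm", fixed_effects=["diameter"],
                          group="mouse"),
        _lmm_table(100 + rep)).params["diameter"] for rep in range(25)]
    assert abs(np.mean(ests) - (-0.01)) <= 0.001  # within 10% of truth


def test_binomial_glmm_recovers_group_effect():
    ests = []
    for rep in range(15):
        rng = np.random.default_rng(7000 + rep)
        rows = []
        for m in range(30):
            b = rng.normal(0, 0.3)
            grp = m % 2
            eta = -0.5 + 1.0 * grp + b
            y = rng.random(60) < 1 / (1 + np.exp(-eta))
            rows += [dict(mouse=m, grp=grp, y=int(v)) for v in y]
        spec = gq.MixedModelSpec(response="y", fixed_effects=["grp"],
                                 group="mouse", family="binomial")
        ests.append(gq.fit_mixed_model(spec, pd.DataFrame(rows)).params["grp"])
    assert abs(np.mean(ests) - 1.0) <= 0.15


def test_mixed_model_spec_validation():
    with pytest.raises(ValueError):
        gq.MixedModelSpec(response="y", fixed_effects=[], group="m",
                          family="poisson")
    df = pd.DataFrame({"y": [1.0, 2.0], "m": ["a", "a"]})
    with pytest.raises(ValueError):
        gq.fit_mixed_model(gq.MixedModelSpec(response="y", fixed_effects=[],
                                             group="m"), df)


# ---------------------------------------------------------------------------
# multiset intersection / enrichment
# ---------------------------------------------------------------------------

def multiset_pmf_enumeration(N, sizes):
    """Exhaustive oracle: iterate every combination of subsets."""
    pools = [list(combinations(range(N), n)) for n in sizes]
    counts = np.zeros(min(sizes) + 1)
    total = 0

    def rec(i, inter):
        nonlocal total
        if i == len(pools):
            counts[len(inter)] += 1
            total += 1
            return
        for s in pools[i]:
            rec(i + 1, inter & set(s))
    for s0 in pools[0]:
        rec(1, set(s0))
    return counts / total


def test_multiset_pmf_sums_to_one():
    for N, sizes in ((30, (10, 12)), (60, (20, 25, 15)), (57, (9, 9, 9, 9))):
        pmf = gq.multiset_intersection_pmf(N, sizes)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (pmf >= 0).all()


def test_multiset_reduces_to_hypergeometric():
    # express the 2-set problem as 3 sets, one being the full background
    N, n1, n2 = 40, 12, 17
    pmf3 = gq.multiset_intersection_pmf(N, (n1, n2, N))
    ref = sps.hypergeom.pmf(np.arange(min(n1, n2) + 1), N, n1, n2)
    np.testing.assert_allclose(pmf3, ref, rtol=1e-12)
    r = gq.multiset_exact_test(10, (5, 5), 3)
    assert r.tail_p == pytest.approx(0.5, rel=1e-12)


def test_multiset_matches_exhaustive_enumeration():
    ref = multiset_pmf_enumeration(4, (3, 3, 3))
    pmf = gq.multiset_intersection_pmf(4, (3, 3, 3))
    np.testing.assert_allclose(pmf, ref, atol=1e-12)
    assert pmf[3] == pytest.approx(1 / 16)
    ref = multiset_pmf_enumeration(6, (3, 2, 4))
    pmf = gq.multiset_intersection_pmf(6, (3, 2, 4))
    np.testing.assert_allclose(pmf, ref, atol=1e-12)
    # forced full overlap
    r = gq.multiset_exact_test(3, (3, 3, 3), 3)
    assert r.pmf[3] == pytest.approx(1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(5, 80), st.lists(st.integers(1, 30), min_size=2,
                                    max_size=4))
def test_multiset_pmf_is_a_distribution(N, sizes):
    """For any background and set sizes the intersection pmf is a proper
    distribution and its tail test is monotone in k."""
    sizes = [min(s, N) for s in sizes]
    pmf = gq.multiset_intersection_pmf(N, sizes)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
    assert (pmf >= -1e-15).all()
    tails = [gq.multiset_exact_test(N, sizes, k).tail_p
             for k in range(min(sizes) + 1)]
    assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))
    assert tails[0] == pytest.approx(1.0, abs=1e-9)


def test_multiset_input_validation():
    with pytest.raises(ValueError):
        gq.multiset_exact_test(10, (5, 5), 6)
    with pytest.raises(ValueError):
        gq.multiset_intersection_pmf(10, (11, 5))


def test_multiset_monte_carlo_small_scale():
    rng = np.random.default_rng(11)
    N, sizes = 50, (15, 20, 12)
    draws = 20000
    ks = np.zeros(draws, int)
    for i in range(draws):
        inter = set(rng.choice(N, sizes[0], replace=False))
        for n in sizes[1:]:
            inter &= set(rng.choice(N, n, replace=False))
        ks[i] = len(inter)
    pmf = gq.multiset_intersection_pmf(N, sizes)
    for k in range(4):
        phat = (ks == k).mean()
        se = np.sqrt(max(phat * (1 - phat), 1e-9) / draws)
        assert abs(phat - pmf[k]) <= 4 * se


def test_enrichment_and_fisher():
    p, _ = gq.enrichment_tests(10, 8, 0, 100)
    assert p == pytest.approx(1.0)
    p, padj = gq.enrichment_tests(20, 30, 15, 100, n_tests=10)
    assert padj == pytest.approx(min(1.0, p * 10))
    fp, _ = gq.fisher_exact_2x2([[1, 9], [11, 3]])
    assert fp == pytest.approx(0.00276, abs=5e-5)
    with pytest.raises(ValueError):
        gq.enrichment_tests(5, 5, 6, 100)
    # hypergeometric equals the multiset machinery at m = 2
    N, n1, n2, k = 200, 40, 55, 15
    tail = gq.multiset_exact_test(N, (n1, n2), k).tail_p
    assert tail == pytest.approx(float(sps.hypergeom.sf(k - 1, N, n1, n2)),
                                 rel=1e-12)
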