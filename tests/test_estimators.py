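"""MR estimator point estimates and SEs against independent closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from helpers import make_hset
from medimr.estimators import (InsufficientInstrumentsError,
                               NoInstrumentsError, bayesian_weighted, egger,
                               ivw, simple_mode, wald_ratio, weighted_median)


def random_hset(seed, k=8, theta=0.5):
    rng = np.random.default_rng(seed)
    be = rng.normal(0.1, 0.04, k)
    be[np.abs(be) < 0.01] = 0.05
    se_e = rng.uniform(0.005, 0.02, k)
    so = rng.uniform(0.02, 0.1, k)
    bo = rng.normal(theta * be, so)
    return make_hset(be, se_e, bo, so)


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def test_wald_ratio_point_and_zero_numerator():
    assert wald_ratio(0.1, 0.01, 0.2, 0.05).beta == pytest.approx(2.0)
    assert wald_ratio(0.1, 0.01, 0.0, 0.05).beta == 0.0


def test_wald_ratio_first_order_se():
    est = wald_ratio(0.1, 0.01, 0.05, 0.01)
    assert est.se == pytest.approx(0.1)  # se_out / |beta_exp|
    assert est.ci_low == pytest.approx(est.beta - 1.959963984540054 * est.se)


def test_wald_ratio_zero_denominator_raises():
    with pytest.raises(ZeroDivisionError):
        wald_ratio(0.0, 0.01, 0.1, 0.05)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_ivw_equal_weights_is_mean_of_ratios():
    # equal ratio SEs (se_out / |beta_exp| identical) -> simple mean
    hset = make_hset([0.1, 0.1], [0.01, 0.01], [0.1, 0.3], [0.05, 0.05])
    assert ivw(hset).beta == pytest.approx(2.0)


def test_ivw_identical_ratios_fixed_equals_random():
    hset = make_hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20],
                     [0.05, 0.08, 0.03])
    fixed = ivw(hset, "fixed")
    random = ivw(hset, "random")
    assert fixed.beta == pytest.approx(0.5)
    assert random.beta == pytest.approx(0.5)
    assert random.se == pytest.approx(fixed.se)  # Q = 0 -> floor at 1


@pytest.mark.parametrize("seed", range(5))
def test_ivw_equals_wls_through_origin(seed):
    """IVW of Wald ratios == WLS of bo on be with weights 1/se_out²."""
    hset = random_hset(seed)
    be, _, bo, so = hset.arrays()
    w = 1.0 / so**2
    beta_wls = np.sum(w * be * bo) / np.sum(w * be**2)
    se_wls = np.sqrt(1.0 / np.sum(w * be**2))
    est = ivw(hset)
    assert est.beta == pytest.approx(beta_wls, rel=1e-10)
    assert est.se == pytest.approx(se_wls, rel=1e-10)


def test_ivw_cross_checked_against_statsmodels():
    import statsmodels.api as sm
    hset = random_hset(99)
    be, _, bo, so = hset.arrays()
    fit = sm.WLS(bo, be, weights=1.0 / so**2).fit()
    assert ivw(hset).beta == pytest.approx(fit.params[0], rel=1e-10)


def test_ivw_single_snp_delegates_to_wald():
    hset = make_hset([0.1], [0.01], [0.2], [0.05])
    est = ivw(hset)
    assert est.method == "wald_ratio"
    assert est.beta == pytest.approx(2.0)


def test_ivw_no_instruments_raises():
    hset = make_hset([], [], [], [])
    with pytest.raises(NoInstrumentsError):
        ivw(hset)


def test_random_effects_se_never_below_fixed():
    for seed in range(20):
        hset = random_hset(seed, k=6)
        assert ivw(hset, "random").se >= ivw(hset, "fixed").se - 1e-15


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_exact_line_through_origin():
    be = np.array([0.05, 0.1, 0.15, 0.2])
    hset = make_hset(be, [0.01] * 4, 2.0 * be, [0.05] * 4)
    slope, intercept = egger(hset)
    assert slope.beta == pytest.approx(2.0, abs=1e-12)
    assert intercept.beta == pytest.approx(0.0, abs=1e-12)
    assert intercept.pval == pytest.approx(1.0)  # zero effect, no evidence


def test_egger_exact_affine_fit():
    be = np.array([0.05, 0.1, 0.15, 0.25])
    hset = make_hset(be, [0.01] * 4, 0.1 + 2.0 * be, [0.05] * 4)
    slope, intercept = egger(hset)
    assert slope.beta == pytest.approx(2.0, abs=1e-12)
    assert intercept.beta == pytest.approx(0.1, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_egger_matches_normal_equations(seed):
    """Closed-form WLS with overdispersion floored at 1, t p-values (k-2 df)."""
    hset = random_hset(seed, k=10)
    be, _, bo, so = hset.arrays()
    sign = np.where(be < 0, -1.0, 1.0)
    x, y, w = be * sign, bo * sign, 1.0 / so**2
    X = np.column_stack([np.ones_like(x), x])
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ coef
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / (len(x) - 2))
    cov = sigma2 * np.linalg.inv(XtWX)
    slope, intercept = egger(hset)
    assert slope.beta == pytest.approx(coef[1], rel=1e-10)
    assert intercept.beta == pytest.approx(coef[0], rel=1e-10)
    assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-10)
    assert intercept.se == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-10)
    expect_p = 2 * stats.t.sf(abs(coef[1]) / np.sqrt(cov[1, 1]), len(x) - 2)
    assert slope.pval == pytest.approx(expect_p, rel=1e-10)


def test_egger_orientation_invariant_to_allele_recoding():
    """Flipping the coding of some variants must not move the Egger slope."""
    hset = random_hset(3, k=8)
    be, se_e, bo, so = hset.arrays()
    flip = np.array([1, -1, 1, -1, -1, 1, 1, -1], dtype=float)
    flipped = make_hset(be * flip, se_e, bo * flip, so)
    s1, i1 = egger(hset)
    s2, i2 = egger(flipped)
    assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
    assert i1.beta == pytest.approx(i2.beta, rel=1e-12)


def test_egger_requires_three_snps():
    with pytest.raises(InsufficientInstrumentsError):
        egger(make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2))


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_equal_weights_is_median():
    # ratios 1, 2, 3 with identical ratio SEs
    hset = make_hset([0.1] * 3, [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
    assert weighted_median(hset, n_boot=50, seed=1).beta == pytest.approx(2.0)


def test_weighted_median_majority_weight_snp_wins():
    # first SNP's ratio weight dominates (>50% of total); the cumulative-weight
    # interpolation lands within a whisker of its ratio
    hset = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.5, 0.1, 0.1],
                     [0.005, 0.2, 0.2])
    assert weighted_median(hset, n_boot=50, seed=1).beta == \
        pytest.approx(5.0, abs=0.01)


def _brute_weighted_median(ratios, weights):
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    p = (np.cumsum(w) - w / 2) / w.sum()
    below = np.searchsorted(p, 0.5)
    if below == 0:
        return r[0]
    if below == len(r):
        return r[-1]
    frac = (0.5 - p[below - 1]) / (p[below] - p[below - 1])
    return r[below - 1] + frac * (r[below] - r[below - 1])


def test_weighted_median_matches_cumulative_weight_oracle():
    rng = np.random.default_rng(17)
    be = rng.uniform(0.05, 0.2, 7)
    so = rng.uniform(0.01, 0.1, 7)
    bo = rng.normal(0.3 * be, so)
    hset = make_hset(be, [0.01] * 7, bo, so)
    ratios = bo / be
    weights = (be / so) ** 2
    expected = _brute_weighted_median(ratios, weights)
    assert weighted_median(hset, n_boot=50, seed=1).beta == \
        pytest.approx(expected, rel=1e-12)


def test_weighted_median_equal_weights_matches_numpy_median():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        k = 9
        be = np.full(k, 0.1)
        bo = rng.normal(0.05, 0.03, k)
        hset = make_hset(be, [0.01] * k, bo, np.full(k, 0.05))
        assert weighted_median(hset, n_boot=10, seed=0).beta == \
            pytest.approx(np.median(bo / be), rel=1e-12)


# ---------------------------------------------------------------------------
# Simple mode
# ---------------------------------------------------------------------------

def test_simple_mode_dominant_cluster():
    hset = make_hset([0.1] * 4, [0.005] * 4, [0.1, 0.1, 0.1, 0.5],
                     [0.02] * 4)
    assert simple_mode(hset, n_boot=20, seed=1).beta == pytest.approx(1.0)


def test_simple_mode_all_ratios_equal():
    hset = make_hset([0.1, 0.2, 0.4], [0.005] * 3, [0.07, 0.14, 0.28],
                     [0.02] * 3)
    assert simple_mode(hset, n_boot=20, seed=1).beta == pytest.approx(0.7)


def test_simple_mode_bimodal_larger_cluster_wins():
    """Grid-search oracle over the kernel density on a 9-SNP bimodal set."""
    ratios = np.array([1.0, 1.05, 0.95, 1.02, 0.98, 3.0, 3.1, 2.9, 3.05])
    be = np.full(9, 0.1)
    hset = make_hset(be, [0.005] * 9, ratios * be, [0.02] * 9)
    est = simple_mode(hset, n_boot=20, seed=1)
    mad = np.median(np.abs(ratios - np.median(ratios)))
    h = 0.9 * 1.4826 * mad * 9 ** (-1 / 5)
    grid = np.linspace(0, 4, 20001)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios) / h) ** 2).sum(axis=1)
    oracle = grid[np.argmax(dens)]
    assert abs(est.beta - oracle) < 0.01
    assert 0.9 < est.beta < 1.1   # larger cluster


# ---------------------------------------------------------------------------
# Bayesian weighted
# ---------------------------------------------------------------------------

def test_bayes_flat_prior_no_pleiotropy_recovers_ivw():
    hset = random_hset(11, k=6)
    est = bayesian_weighted(hset, prior_sd_theta=1e3, fix_tau=0.0)
    ref = ivw(hset)
    assert est.beta == pytest.approx(ref.beta, abs=2e-3 * max(1, abs(ref.beta)))
    assert est.se == pytest.approx(ref.se, rel=0.02)


def test_bayes_single_snp_conjugate_shrinkage():
    """tau = 0, one SNP: closed-form normal-normal posterior update."""
    be, se_e, bo, so = 0.1, 0.01, 0.05, 0.02
    prior_sd = 0.5
    hset = make_hset([be], [se_e], [bo], [so])
    est = bayesian_weighted(hset, prior_sd_theta=prior_sd, fix_tau=0.0)
    prec = be**2 / so**2 + 1.0 / prior_sd**2
    mean = (be * bo / so**2) / prec
    assert est.beta == pytest.approx(mean, rel=1e-3)
    assert est.se == pytest.approx(np.sqrt(1.0 / prec), rel=1e-2)
    assert abs(est.beta) < abs(bo / be)  # shrunk toward zero


def test_bayes_more_robust_than_ivw_under_high_weight_outlier():
    """One high-precision pleiotropic outlier: posterior mean should beat
    fixed-effects IVW in most replicates."""
    theta = 0.2
    wins = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        be = rng.uniform(0.08, 0.2, 5)
        so = np.array([0.01, 0.08, 0.08, 0.08, 0.08])
        alpha = np.array([0.15, 0, 0, 0, 0])      # outlier carries big weight
        bo = rng.normal(theta * be + alpha, so)
        hset = make_hset(be, [0.005] * 5, bo, so)
        bayes = bayesian_weighted(hset)
        fixed = ivw(hset, "fixed")
        if abs(bayes.beta - theta) < abs(fixed.beta - theta):
            wins += 1
    assert wins >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# Equivariance properties
# ---------------------------------------------------------------------------

@settings(deadline=None, max_examples=15)
@given(st.integers(0, 2**31 - 1))
def test_sign_equivariance(seed):
    """Negating every outcome beta negates every estimator's beta."""
    hset = random_hset(seed, k=6)
    be, se_e, bo, so = hset.arrays()
    neg = make_hset(be, se_e, -bo, so)
    assert ivw(neg).beta == pytest.approx(-ivw(hset).beta, rel=1e-12)
    s1, _ = egger(hset)
    s2, _ = egger(neg)
    assert s2.beta == pytest.approx(-s1.beta, rel=1e-12)
    assert weighted_median(neg, n_boot=20, seed=7).beta == \
        pytest.approx(-weighted_median(hset, n_boot=20, seed=7).beta,
                      rel=1e-12)


@settings(deadline=None, max_examples=15)
@given(st.integers(0, 2**31 - 1), st.floats(0.2, 5.0))
def test_scale_equivariance(seed, c):
    """Scaling all exposure betas by c divides causal estimates by c."""
    hset = random_hset(seed, k=6)
    be, se_e, bo, so = hset.arrays()
    scaled = make_hset(c * be, se_e, bo, so)
    assert ivw(scaled).beta == pytest.approx(ivw(hset).beta / c, rel=1e-10)
    assert weighted_median(scaled, n_boot=10, seed=3).beta == \
        pytest.approx(weighted_median(hset, n_boot=10, seed=3).beta / c,
                      rel=1e-10)


def test_odds_ratio_reporting_is_exp_of_beta():
    est = ivw(random_hset(2))
    assert est.odds_ratio == pytest.approx(np.exp(est.beta))
    assert est.or_ci_low == pytest.approx(np.exp(est.ci_low))
    assert est.ci_low < est.beta < est.ci_high
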