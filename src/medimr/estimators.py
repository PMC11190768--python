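"""Causal-effect estimators for two-sample MR on harmonized summary data.

Per-variant effects give Wald ratios rho_j = beta_outcome_j / beta_exposure_j
with first-order SE se_outcome_j / |beta_exposure_j|. The estimators combine
the ratios under different robustness assumptions:

* IVW — inverse-variance-weighted mean of the ratios, equivalently weighted
  least squares of outcome on exposure betas through the origin. The primary
  estimator. Random-effects variant inflates the SE multiplicatively by
  sqrt(Q/(k-1)) floored at 1 under heterogeneity.
* MR-Egger — WLS with an intercept; the slope is the causal estimate and the
  intercept the average directional pleiotropy.
* Weighted median — consistent when valid instruments carry a majority of the
  weight; SE by parametric bootstrap.
* Simple mode — kernel-density mode of the unweighted ratios (ZEMPA-style
  plurality-valid assumption); SE by parametric bootstrap.
* Bayesian weighted — normal pleiotropy model bo_j ~ N(theta*be_j + a_j, so²)
  with a_j ~ N(0, tau²), priors theta ~ N(0, prior_sd²) and
  tau ~ half-Normal(0, 0.5); posterior by dense-grid integration over
  (theta, tau).

Binary-outcome betas are log odds ratios throughout; odds-ratio fields are
exp-transformed at reporting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

logger = logging.getLogger("medimr")

Z95 = stats.norm.ppf(0.975)


class NoInstrumentsError(ValueError):
    """An estimator was invoked with no usable instruments."""


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator's minimum."""


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate (beta on the log-OR scale)."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)

    def as_dict(self) -> dict:
        return {"method": self.method, "beta": self.beta, "se": self.se,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "pval": self.pval, "n_snps": self.n_snps,
                "odds_ratio": self.odds_ratio,
                "or_ci_low": self.or_ci_low, "or_ci_high": self.or_ci_high}


def _normal_estimate(method: str, beta: float, se: float, k: int) -> MREstimate:
    if se > 0:
        z = beta / se
        pval = 2.0 * stats.norm.sf(abs(z))
    else:
        pval = 1.0 if beta == 0 else 0.0
    pval = float(min(max(pval, np.nextafter(0, 1)), 1.0))
    return MREstimate(method, float(beta), float(se),
                      float(beta - Z95 * se), float(beta + Z95 * se),
                      pval, k)


def wald_ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratios and first-order SEs."""
    be, _, bo, so = hset.arrays()
    if np.any(be == 0):
        raise ZeroDivisionError("beta_exposure = 0 yields an undefined ratio")
    return bo / be, so / np.abs(be)


def wald_ratio(beta_exposure: float, se_exposure: float,
               beta_outcome: float, se_outcome: float) -> MREstimate:
    """Single-variant causal estimate, outcome effect over exposure effect."""
    if beta_exposure == 0:
        raise ZeroDivisionError("beta_exposure = 0 yields an undefined ratio")
    beta = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return _normal_estimate("wald_ratio", beta, se, 1)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(hset: HarmonizedSet, effects: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    ``effects="random"`` applies multiplicative SE inflation by
    sqrt(max(1, Q/(k-1))), nesting the fixed model.
    """
    if effects not in ("fixed", "random"):
        raise ValueError(f"unknown effects model {effects!r}")
    k = hset.n_snps
    if k == 0:
        raise NoInstrumentsError(
            f"no instruments for {hset.exposure_id} -> {hset.outcome_id}")
    if k == 1:
        ins = hset.instruments.iloc[0]
        return wald_ratio(ins["beta_exposure"], ins["se_exposure"],
                          ins["beta_outcome"], ins["se_outcome"])
    rho, se_rho = wald_ratios(hset)
    w = 1.0 / se_rho**2
    beta = float(np.sum(w * rho) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    if effects == "random":
        q = float(np.sum(w * (rho - beta) ** 2))
        se *= math.sqrt(max(1.0, q / (k - 1)))
    method = "ivw_fixed" if effects == "fixed" else "ivw_random"
    return _normal_estimate(method, beta, se, k)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Exposure effects are oriented non-negative first (outcome betas flipped
    with them) since the regression is not invariant to allele recoding.
    Weights are 1/se_outcome²; SEs use residual overdispersion floored at 1,
    the convention in two-sample MR; p-values from t with k-2 df.
    """
    k = hset.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {k}")
    be, _, bo, so = hset.arrays()
    flip = np.sign(be)
    flip[flip == 0] = 1.0
    x = be * flip
    y = bo * flip
    w = 1.0 / so**2
    sw, sx, sy = np.sum(w), np.sum(w * x), np.sum(w * y)
    sxx, sxy = np.sum(w * x * x), np.sum(w * x * y)
    denom = sw * sxx - sx**2
    if denom <= 0:
        raise InsufficientInstrumentsError(
            "degenerate design: exposure effects carry no spread")
    slope = (sw * sxy - sx * sy) / denom
    intercept = (sxx * sy - sx * sxy) / denom
    resid = y - intercept - slope * x
    sigma2 = max(1.0, float(np.sum(w * resid**2)) / (k - 2))
    se_slope = math.sqrt(sigma2 * sw / denom)
    se_int = math.sqrt(sigma2 * sxx / denom)

    def _t_est(method: str, b: float, se: float) -> MREstimate:
        tcrit = stats.t.ppf(0.975, k - 2)
        pval = 2.0 * stats.t.sf(abs(b) / se, k - 2) if se > 0 else \
            (1.0 if b == 0 else 0.0)
        pval = float(min(max(pval, np.nextafter(0, 1)), 1.0))
        return MREstimate(method, float(b), float(se),
                          float(b - tcrit * se), float(b + tcrit * se),
                          pval, k)

    return _t_est("egger_slope", slope, se_slope), \
        _t_est("egger_intercept", intercept, se_int)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    p = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000,
                    seed: int = 0) -> MREstimate:
    """Inverse-variance weighted median of the Wald ratios.

    The estimate is the ratio at normalized cumulative weight 0.5 with linear
    interpolation; the SE comes from a parametric bootstrap that redraws
    per-variant betas from their normal sampling distributions.
    """
    k = hset.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median needs >= 3 SNPs, got {k}")
    be, se_e, bo, so = hset.arrays()
    rho, se_rho = wald_ratios(hset)
    point = _weighted_median_point(rho, 1.0 / se_rho**2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(bo, so)
        be_s[be_s == 0] = np.finfo(float).tiny
        r = bo_s / be_s
        w = (np.abs(be_s) / so) ** 2
        boots[i] = _weighted_median_point(r, w)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", point, se, k)


# ---------------------------------------------------------------------------
# Simple mode
# ---------------------------------------------------------------------------

def _kde_mode(ratios: np.ndarray, bandwidth: float) -> float:
    if bandwidth <= 0 or not np.isfinite(bandwidth):
        # degenerate spread: plurality value
        vals, counts = np.unique(ratios, return_counts=True)
        return float(vals[np.argmax(counts)])
    lo = ratios.min() - 3 * bandwidth
    hi = ratios.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, 2048)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bandwidth) ** 2
                  ).sum(axis=1)
    return float(grid[np.argmax(dens)])


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    mad = np.median(np.abs(ratios - np.median(ratios)))
    scale = 1.4826 * mad
    if scale == 0:
        return 0.0
    return factor * 0.9 * scale * len(ratios) ** (-1 / 5)


def simple_mode(hset: HarmonizedSet, bandwidth_factor: float = 1.0,
                n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the unweighted Wald-ratio density under normal-kernel smoothing.

    Bandwidth is ``bandwidth_factor`` times a MAD-based scale; the SE comes
    from the same parametric bootstrap engine as the weighted median.
    """
    k = hset.n_snps
    if k < 3:
        raise InsufficientInstrumentsError(
            f"simple mode needs >= 3 SNPs, got {k}")
    be, se_e, bo, so = hset.arrays()
    rho, _ = wald_ratios(hset)
    point = _kde_mode(rho, _mode_bandwidth(rho, bandwidth_factor))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(bo, so)
        be_s[be_s == 0] = np.finfo(float).tiny
        r = bo_s / be_s
        boots[i] = _kde_mode(r, _mode_bandwidth(r, bandwidth_factor))
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("simple_mode", point, se, k)


# ---------------------------------------------------------------------------
# Bayesian weighted
# ---------------------------------------------------------------------------

def bayesian_weighted(hset: HarmonizedSet, prior_sd_theta: float = 1.0,
                      tau_prior_sd: float = 0.5, fix_tau: float | None = None,
                      n_draws: int = 1000, seed: int = 0,
                      n_grid_theta: int = 601,
                      n_grid_tau: int = 61) -> MREstimate:
    """Posterior mean/SD for the causal effect under a normal pleiotropy model.

    Model: bo_j ~ N(theta*be_j + a_j, so_j²) with pleiotropy a_j ~ N(0, tau²)
    marginalised analytically, so bo_j ~ N(theta*be_j, so_j² + tau²).
    Priors: theta ~ N(0, prior_sd_theta²), tau ~ half-Normal(0, tau_prior_sd).
    The joint posterior is integrated on a dense (theta, tau) grid, which is
    deterministic; ``n_draws``/``seed`` are accepted for interface stability
    with sampling-based backends. ``fix_tau`` pins the pleiotropy scale (0
    recovers the conjugate no-pleiotropy model). The p-value is the two-sided
    tail of 0 under the normal approximation to the posterior.
    """
    k = hset.n_snps
    if k < 1 or (fix_tau is None and k < 2):
        raise InsufficientInstrumentsError(
            f"Bayesian weighted MR needs >= 2 SNPs, got {k}")
    be, _, bo, so = hset.arrays()

    # centre the theta grid on the weighted-least-squares solution
    w0 = be**2 / so**2
    denom = np.sum(w0)
    centre = float(np.sum(be * bo / so**2) / denom) if denom > 0 else 0.0
    scale = math.sqrt(1.0 / denom) if denom > 0 else prior_sd_theta
    post_sd_cap = min(scale * math.sqrt(max(1.0, k)), prior_sd_theta) \
        if denom > 0 else prior_sd_theta
    half = 12.0 * max(scale, 1e-8)

    for _attempt in range(3):
        theta = np.linspace(centre - half, centre + half, n_grid_theta)
        if fix_tau is not None:
            tau = np.array([fix_tau])
        else:
            tau = np.linspace(0.0, 4.0 * tau_prior_sd, n_grid_tau)
        var = so[None, :] ** 2 + tau[:, None] ** 2           # (T, k)
        resid = bo[None, None, :] - theta[:, None, None] * be[None, None, :]
        loglik = -0.5 * np.sum(resid**2 / var[None, :, :]
                               + np.log(var)[None, :, :], axis=2)  # (Th, T)
        logprior_theta = -0.5 * (theta / prior_sd_theta) ** 2
        if fix_tau is None and tau_prior_sd > 0:
            logprior_tau = -0.5 * (tau / tau_prior_sd) ** 2
        else:
            logprior_tau = np.zeros_like(tau)
        logpost = loglik + logprior_theta[:, None] + logprior_tau[None, :]
        logpost -= logpost.max()
        marg = np.exp(logpost).sum(axis=1)
        total = marg.sum()
        if total == 0:
            half *= 4
            continue
        p = marg / total
        edge_mass = p[0] + p[-1]
        if edge_mass > 1e-4 and half < 1e6 * max(post_sd_cap, 1e-8):
            half *= 3
            continue
        break
    else:
        logger.warning("Bayesian posterior grid did not stabilise; "
                       "estimate returned from widest grid")

    mean = float(np.sum(p * theta))
    sd = float(math.sqrt(max(np.sum(p * (theta - mean) ** 2), 0.0)))
    cdf = np.cumsum(p)
    ci_low = float(np.interp(0.025, cdf, theta))
    ci_high = float(np.interp(0.975, cdf, theta))
    if sd > 0:
        pval = 2.0 * stats.norm.sf(abs(mean) / sd)
    else:
        pval = 1.0 if mean == 0 else 0.0
    pval = float(min(max(pval, np.nextafter(0, 1)), 1.0))
    return MREstimate("bayesian_weighted", mean, sd, ci_low, ci_high, pval, k)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

METHOD_ALIASES = {
    "ivw": "ivw_fixed", "wm": "weighted_median", "median": "weighted_median",
    "mode": "simple_mode", "bayes": "bayesian_weighted",
    "egger": "egger_slope",
}


def estimate_all(hset: HarmonizedSet, methods: list[str] | None = None,
                 seed: int = 0, n_boot: int = 1000,
                 effects: str = "fixed") -> dict[str, MREstimate]:
    """Run a set of estimators; returns a method-tag -> estimate map."""
    methods = methods or ["ivw", "egger", "wm", "mode", "bayes"]
    out: dict[str, MREstimate] = {}
    for m in methods:
        tag = METHOD_ALIASES.get(m, m)
        try:
            if tag in ("ivw_fixed", "ivw_random"):
                eff = "random" if tag == "ivw_random" else effects
                est = ivw(hset, effects=eff)
                out[est.method] = est
            elif tag in ("egger_slope", "egger_intercept"):
                slope, intercept = egger(hset)
                out[slope.method] = slope
                out[intercept.method] = intercept
            elif tag == "weighted_median":
                out[tag] = weighted_median(hset, n_boot=n_boot, seed=seed)
            elif tag == "simple_mode":
                out[tag] = simple_mode(hset, n_boot=n_boot, seed=seed + 1)
            elif tag == "bayesian_weighted":
                out[tag] = bayesian_weighted(hset, seed=seed + 2)
            else:
                raise ValueError(f"unknown estimator {m!r}")
        except (InsufficientInstrumentsError, NoInstrumentsError) as exc:
            logger.warning("estimator %s skipped: %s", tag, exc)
    return out
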