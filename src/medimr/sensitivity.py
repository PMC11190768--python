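"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Cochran's Q over the Wald ratios drives the fixed- vs random-effects IVW
choice (random iff Q's p < 0.05); the MR-Egger intercept tests average
directional pleiotropy; MR-PRESSO detects per-variant pleiotropic outliers by
comparing observed leave-one-out residual sums of squares with their
distribution under a simulated no-pleiotropy model; leave-one-out re-estimates
the IVW effect with each variant removed to expose influential instruments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate, egger, ivw, wald_ratios
from .harmonize import HarmonizedSet

logger = logging.getLogger("medimr")

HETEROGENEITY_ALPHA = 0.05


@dataclass
class SensitivityReport:
    """Bundle of diagnostics for one exposure->outcome analysis."""

    q_stat: float
    q_df: int
    q_pval: float
    effects_model_chosen: str                     # "fixed" | "random"
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    presso_global_pval: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_distortion_pval: float | None = None   # None => not run
    loo_estimates: dict[str, MREstimate] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "q_stat": self.q_stat, "q_df": self.q_df, "q_pval": self.q_pval,
            "effects_model_chosen": self.effects_model_chosen,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso_global_pval": self.presso_global_pval,
            "presso_outliers": list(self.presso_outliers),
            "presso_distortion_pval": self.presso_distortion_pval,
            "loo_estimates": {k: v.as_dict()
                              for k, v in self.loo_estimates.items()},
        }


def cochran_q(hset: HarmonizedSet) -> tuple[float, int, float]:
    """Cochran's Q over the Wald ratios: (Q, df, p).

    Q = sum_j w_j (rho_j - beta_IVW)² with w_j the inverse ratio variances;
    p from chi-square with k-1 df. Requires k >= 2.
    """
    k = hset.n_snps
    if k < 2:
        raise ValueError(f"Cochran's Q needs >= 2 SNPs, got {k}")
    rho, se_rho = wald_ratios(hset)
    w = 1.0 / se_rho**2
    beta = np.sum(w * rho) / np.sum(w)
    q = float(np.sum(w * (rho - beta) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def choose_effects_model(hset: HarmonizedSet,
                         alpha: float = HETEROGENEITY_ALPHA) -> str:
    """"random" iff Q's p < alpha, else "fixed"; single decision per analysis."""
    if hset.n_snps < 2:
        return "fixed"
    _, _, p = cochran_q(hset)
    return "random" if p < alpha else "fixed"


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float, float]:
    """MR-Egger intercept triple (intercept, SE, p); pleiotropy if p < 0.05."""
    _, intercept = egger(hset)
    return intercept.beta, intercept.se, intercept.pval


def leave_one_out(hset: HarmonizedSet,
                  effects: str = "fixed") -> dict[str, MREstimate]:
    """IVW on the remaining k-1 instruments for each variant removed."""
    if hset.n_snps < 3:
        raise ValueError(f"leave-one-out needs >= 3 SNPs, got {hset.n_snps}")
    out: dict[str, MREstimate] = {}
    for snp in hset.instruments["snp_id"]:
        out[snp] = ivw(hset.drop([snp]), effects=effects)
    return out


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_betas(be: np.ndarray, bo: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out WLS-through-origin slopes for every variant at once."""
    sxy = np.sum(w * be * bo, axis=-1, keepdims=True)
    sxx = np.sum(w * be * be, axis=-1, keepdims=True)
    return (sxy - w * be * bo) / (sxx - w * be * be)


def mr_presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
              outlier_p: float = 0.05, effects: str = "fixed",
              ) -> tuple[float, list[str], float | None, MREstimate]:
    """Three-stage pleiotropy residual sum and outlier test.

    Global test: the observed weighted residual sum of squares — residuals of
    each variant against its leave-one-out IVW prediction — is compared with
    its distribution over ``n_sim`` parametric simulations under the
    no-pleiotropy model (betas redrawn from their sampling distributions
    around the leave-one-out fit). Outlier test: each variant's observed
    squared residual against its own simulated distribution, Bonferroni
    adjusted over k; variants below ``outlier_p`` are removed and IVW
    re-estimated as the corrected result. Distortion test: the relative change
    between full and corrected estimates is compared with changes from
    removing equally many variants resampled from the inliers.
    """
    k = hset.n_snps
    if k < 4:
        raise ValueError(f"MR-PRESSO needs >= 4 SNPs, got {k}")
    rng = np.random.default_rng(seed)
    be, se_e, bo, so = hset.arrays()
    w = 1.0 / so**2
    snp_ids = hset.instruments["snp_id"].to_numpy()

    beta_loo = _loo_betas(be[None, :], bo[None, :], w[None, :])[0]
    res2_obs = w * (bo - beta_loo * be) ** 2
    rss_obs = float(res2_obs.sum())

    be_sim = rng.normal(be, se_e, size=(n_sim, k))
    bo_sim = rng.normal(beta_loo * be, so, size=(n_sim, k))
    beta_loo_sim = _loo_betas(be_sim, bo_sim, w)
    res2_sim = w * (bo_sim - beta_loo_sim * be_sim) ** 2
    rss_sim = res2_sim.sum(axis=1)

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    p_snp = (np.sum(res2_sim >= res2_obs, axis=0) + 1) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_snp * k)
    outliers = [str(s) for s in snp_ids[p_adj < outlier_p]]

    original = ivw(hset, effects=effects)
    if not outliers:
        return global_pval, [], None, original

    inlier_set = hset.drop(outliers)
    if inlier_set.n_snps == 0:
        logger.warning("MR-PRESSO flagged every instrument; "
                       "corrected estimate falls back to the original")
        return global_pval, outliers, None, original
    corrected = ivw(inlier_set, effects=effects)

    distortion_pval: float | None = None
    if corrected.beta != 0 and inlier_set.n_snps >= 2:
        d_obs = (original.beta - corrected.beta) / abs(corrected.beta)
        inlier_idx = np.where(~np.isin(snp_ids, outliers))[0]
        n_out = len(outliers)
        d_null = []
        for _ in range(n_sim):
            removed = rng.choice(inlier_idx, size=n_out, replace=True)
            keep = np.setdiff1d(np.arange(k), removed)
            if len(keep) < 1:
                continue
            sw = np.sum(w[keep] * be[keep] ** 2)
            b_sub = np.sum(w[keep] * be[keep] * bo[keep]) / sw
            if b_sub != 0:
                d_null.append((original.beta - b_sub) / abs(b_sub))
        if d_null:
            d_null = np.asarray(d_null)
            distortion_pval = float(
                (np.sum(np.abs(d_null) >= abs(d_obs)) + 1) / (len(d_null) + 1))
    return global_pval, outliers, distortion_pval, corrected


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------

def sensitivity_report(hset: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
                       outlier_p: float = 0.05) -> SensitivityReport:
    """Run every applicable diagnostic on one harmonized analysis.

    Diagnostics with minimum-instrument requirements above the available k are
    skipped and left as None; the fixed/random decision is made once here and
    reused for every downstream IVW call (including leave-one-out).
    """
    k = hset.n_snps
    if k >= 2:
        q, df, q_pval = cochran_q(hset)
    else:
        q, df, q_pval = math.nan, 0, math.nan
    model = "random" if (k >= 2 and q_pval < HETEROGENEITY_ALPHA) else "fixed"
    report = SensitivityReport(q_stat=q, q_df=df, q_pval=q_pval,
                               effects_model_chosen=model)
    if k >= 3:
        report.egger_intercept, report.egger_intercept_se, \
            report.egger_intercept_pval = egger_intercept_test(hset)
        report.loo_estimates = leave_one_out(hset, effects=model)
    if k >= 4:
        gp, outliers, dp, _ = mr_presso(hset, n_sim=n_sim, seed=seed,
                                        outlier_p=outlier_p, effects=model)
        report.presso_global_pval = gp
        report.presso_outliers = outliers
        report.presso_distortion_pval = dp
    return report
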