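"""Screening, bidirectional gating and two-step mediation decomposition.

The pipeline mirrors the study design: candidate exposures are screened
against the outcome with a primary estimator (IVW, fixed or random effects per
Cochran's Q) plus confirmation estimators (weighted median by default) that
must agree in significance and sign; reverse-direction MR must be null on
every edge before mediation is attempted; and the total effect is then
decomposed on the log-OR scale as

    indirect = beta1 * beta2          (exposure->mediator, mediator->outcome)
    direct   = total - indirect
    proportion mediated = indirect / total

with the indirect-effect SE by the first-order product-of-coefficients
(Sobel) formula and the proportion CI by delta-method propagation of the
ratio. A negative proportion means the indirect and total effects oppose —
inconsistent mediation, the negative-feedback pattern.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from scipy import stats

from .estimators import (MREstimate, NoInstrumentsError, estimate_all, ivw,
                         weighted_median)
from .gwas_io import LDReference, SummaryStatTable
from .harmonize import HarmonizedSet, SelectionConfig, select_instruments
from .sensitivity import SensitivityReport, choose_effects_model, sensitivity_report

logger = logging.getLogger("medimr")


class MediationRefusedError(RuntimeError):
    """A bidirectional gate failed; mediation must not proceed on this triple."""

    def __init__(self, edge: str, detail: str = ""):
        self.edge = edge
        super().__init__(f"mediation refused: gate failed on edge {edge}"
                         + (f" ({detail})" if detail else ""))


@dataclass
class GatingPolicy:
    """Multi-estimator screening and reverse-nullity rules."""

    primary_method: str = "ivw"
    alpha: float = 0.05
    confirm_methods: list[str] = field(default_factory=lambda: ["weighted_median"])
    require_sign_agreement: bool = True
    reverse_null_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.reverse_null_alpha < 1.0):
            raise ValueError("alpha and reverse_null_alpha must lie in (0, 1)")


@dataclass
class ScreenResult:
    exposure_id: str
    passed: bool
    reason: str                      # "" on pass, else first failed gate
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition of the total effect."""

    total_effect: float
    beta1: float
    beta2: float
    indirect_effect: float
    direct_effect: float
    proportion_mediated: float | None
    se_indirect: float
    prop_ci_low: float | None
    prop_ci_high: float | None
    reverse_checks: dict[str, float] = field(default_factory=dict)
    edge_estimates: dict[str, MREstimate] = field(default_factory=dict)
    edge_sensitivity: dict[str, SensitivityReport] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "total_effect": self.total_effect, "beta1": self.beta1,
            "beta2": self.beta2, "indirect_effect": self.indirect_effect,
            "direct_effect": self.direct_effect,
            "proportion_mediated": self.proportion_mediated,
            "se_indirect": self.se_indirect,
            "prop_ci_low": self.prop_ci_low, "prop_ci_high": self.prop_ci_high,
            "reverse_checks": dict(self.reverse_checks),
            "edge_estimates": {k: v.as_dict()
                               for k, v in self.edge_estimates.items()},
            "edge_sensitivity": {k: v.as_dict()
                                 for k, v in self.edge_sensitivity.items()},
        }


# ---------------------------------------------------------------------------
# Single-edge MR
# ---------------------------------------------------------------------------

def run_mr_edge(exposure: SummaryStatTable, outcome: SummaryStatTable,
                ld: LDReference | None = None,
                blocklist: set[str] | None = None,
                config: SelectionConfig | None = None,
                seed: int = 0, n_boot: int = 1000,
                methods: list[str] | None = None,
                ) -> tuple[HarmonizedSet, dict[str, MREstimate], str]:
    """Select instruments, harmonize and estimate one exposure->outcome edge.

    The fixed/random IVW decision is made once from Cochran's Q and applied to
    every estimate on the edge. Returns (harmonized set, estimates, model).
    """
    hset = select_instruments(exposure, outcome, ld, blocklist, config)
    if hset.n_snps == 0:
        return hset, {}, "fixed"
    model = choose_effects_model(hset)
    ests = estimate_all(hset, methods=methods, seed=seed, n_boot=n_boot,
                        effects=model)
    return hset, ests, model


def _primary_estimate(ests: dict[str, MREstimate],
                      policy: GatingPolicy) -> MREstimate | None:
    tag = policy.primary_method
    if tag == "ivw":
        return ests.get("ivw_fixed") or ests.get("ivw_random") \
            or ests.get("wald_ratio")
    return ests.get(tag)


# ---------------------------------------------------------------------------
# Screening and gates
# ---------------------------------------------------------------------------

def screen_exposures(candidates: list[SummaryStatTable],
                     outcome: SummaryStatTable,
                     policy: GatingPolicy | None = None,
                     ld: LDReference | None = None,
                     blocklist: set[str] | None = None,
                     config: SelectionConfig | None = None,
                     seed: int = 0, n_boot: int = 1000) -> list[ScreenResult]:
    """Multi-estimator screen of candidate exposures against the outcome.

    A candidate passes iff the primary estimator's p < alpha, every
    confirmation estimator's p < alpha, and (optionally) all gated estimators
    agree in sign. The reason string names the first failed gate.
    """
    if not candidates:
        raise ValueError("screen_exposures requires at least one candidate")
    policy = policy or GatingPolicy()
    results: list[ScreenResult] = []
    for cand in candidates:
        methods = ["ivw"] + [m for m in policy.confirm_methods if m != "ivw"]
        hset, ests, _ = run_mr_edge(cand, outcome, ld, blocklist, config,
                                    seed=seed, n_boot=n_boot, methods=methods)
        if hset.n_snps == 0 or not ests:
            results.append(ScreenResult(cand.trait_id, False, "no-instruments"))
            continue
        primary = _primary_estimate(ests, policy)
        gated = [primary]
        reason = ""
        if primary is None or primary.pval >= policy.alpha:
            reason = "primary-p"
        else:
            for m in policy.confirm_methods:
                tag = {"wm": "weighted_median"}.get(m, m)
                est = ests.get(tag)
                if est is None or est.pval >= policy.alpha:
                    reason = "confirm-p"
                    break
                gated.append(est)
        if not reason and policy.require_sign_agreement:
            signs = {math.copysign(1.0, e.beta) for e in gated if e.beta != 0}
            if len(signs) > 1:
                reason = "sign-disagreement"
        results.append(ScreenResult(cand.trait_id, reason == "", reason, ests))
    return results


def reverse_gate(outcome_as_exposure: SummaryStatTable,
                 exposure_as_outcome: SummaryStatTable,
                 policy: GatingPolicy | None = None,
                 ld: LDReference | None = None,
                 blocklist: set[str] | None = None,
                 config: SelectionConfig | None = None,
                 seed: int = 0) -> tuple[float, bool]:
    """Reverse-direction MR nullity gate.

    Passes iff the reverse primary estimate's p >= reverse_null_alpha (no
    detectable reverse causality). Zero selectable reverse instruments pass
    with a warning — there is then no evidence of a reverse effect.
    """
    policy = policy or GatingPolicy()
    hset = select_instruments(outcome_as_exposure, exposure_as_outcome,
                              ld, blocklist, config)
    if hset.n_snps == 0:
        logger.warning("reverse gate %s -> %s: no instruments selectable; "
                       "passing with warning",
                       outcome_as_exposure.trait_id,
                       exposure_as_outcome.trait_id)
        return math.nan, True
    try:
        est = ivw(hset, effects=choose_effects_model(hset))
    except NoInstrumentsError:
        return math.nan, True
    return est.pval, est.pval >= policy.reverse_null_alpha


# ---------------------------------------------------------------------------
# Delta-method uncertainty
# ---------------------------------------------------------------------------

def delta_method_ci(beta1: float, se1: float, beta2: float, se2: float,
                    total: float, se_total: float, level: float = 0.95,
                    ) -> tuple[float, float | None, float | None]:
    """(Sobel SE of beta1*beta2, proportion CI) by first-order propagation.

    se_indirect = sqrt(beta2²·se1² + beta1²·se2²). The proportion CI treats
    the indirect and total effects as independent (two-sample designs) and
    propagates var(indirect/total) to first order. A total effect at machine
    zero leaves the proportion CI undefined.
    """
    if se1 < 0 or se2 < 0 or se_total < 0:
        raise ValueError("standard errors must be non-negative")
    se_ind = math.sqrt(beta2**2 * se1**2 + beta1**2 * se2**2)
    if abs(total) < 1e-300:
        logger.warning("total effect at machine zero: proportion CI undefined")
        return se_ind, None, None
    indirect = beta1 * beta2
    prop = indirect / total
    try:
        # ratio form avoids underflow of total**4 for tiny totals
        var_prop = (se_ind / total) ** 2 + (prop * se_total / total) ** 2
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * math.sqrt(var_prop)
    except OverflowError:
        half = math.inf
    if not math.isfinite(half):
        logger.warning("proportion CI overflowed for near-zero total effect")
        return se_ind, None, None
    return se_ind, prop - half, prop + half


# ---------------------------------------------------------------------------
# Two-step mediation
# ---------------------------------------------------------------------------

def mediation_from_estimates(total: MREstimate, b1: MREstimate,
                             b2: MREstimate, level: float = 0.95,
                             ) -> MediationResult:
    """Decompose a total effect given the three edge estimates."""
    indirect = b1.beta * b2.beta
    direct = total.beta - indirect
    prop = indirect / total.beta if total.beta != 0 else None
    se_ind, lo, hi = delta_method_ci(b1.beta, b1.se, b2.beta, b2.se,
                                     total.beta, total.se, level)
    return MediationResult(
        total_effect=total.beta, beta1=b1.beta, beta2=b2.beta,
        indirect_effect=indirect, direct_effect=direct,
        proportion_mediated=prop, se_indirect=se_ind,
        prop_ci_low=lo, prop_ci_high=hi,
        edge_estimates={"exposure->outcome": total,
                        "exposure->mediator": b1,
                        "mediator->outcome": b2})


def proportion_from_odds_ratios(or_total: float, or_beta1: float,
                                or_beta2: float) -> float:
    """Proportion mediated from three printed odds ratios, as a fraction.

    All arithmetic is on the log-OR scale: ln(or_beta1)·ln(or_beta2)/ln(or_total).
    """
    if min(or_total, or_beta1, or_beta2) <= 0 or or_total == 1.0:
        raise ValueError("odds ratios must be positive with or_total != 1")
    return math.log(or_beta1) * math.log(or_beta2) / math.log(or_total)


def mediation_edge_estimates(exposure: SummaryStatTable,
                             mediator: SummaryStatTable,
                             outcome: SummaryStatTable,
                             policy: GatingPolicy | None = None,
                             ld: LDReference | None = None,
                             blocklist: set[str] | None = None,
                             config: SelectionConfig | None = None,
                             seed: int = 0,
                             ) -> tuple[dict[str, MREstimate],
                                        dict[str, HarmonizedSet]]:
    """Primary estimates for the three forward edges of the mediation DAG.

    For the mediator->outcome step, variants already associated with the
    exposure (below the selection p-threshold) are excluded from the mediator
    instrument set, so beta2 is identified by mediator-specific instruments
    rather than upstream-pathway variants.
    """
    policy = policy or GatingPolicy()
    cfg = config or SelectionConfig()
    pathway = set(exposure.df.loc[exposure.df["pval"] < cfg.p_max, "snp_id"])
    edges: dict[str, MREstimate] = {}
    hsets: dict[str, HarmonizedSet] = {}
    for name, exp_t, out_t, extra_block in (
            ("exposure->outcome", exposure, outcome, set()),
            ("exposure->mediator", exposure, mediator, set()),
            ("mediator->outcome", mediator, outcome, pathway)):
        block = (blocklist or set()) | extra_block
        hset, ests, _ = run_mr_edge(exp_t, out_t, ld, block, cfg,
                                    seed=seed, methods=["ivw"])
        primary = _primary_estimate(ests, policy)
        if primary is None:
            raise MediationRefusedError(name, "no instruments")
        edges[name] = primary
        hsets[name] = hset
    return edges, hsets


def two_step_mediation(exposure: SummaryStatTable, mediator: SummaryStatTable,
                       outcome: SummaryStatTable,
                       policy: GatingPolicy | None = None,
                       ld: LDReference | None = None,
                       blocklist: set[str] | None = None,
                       config: SelectionConfig | None = None,
                       seed: int = 0, n_boot: int = 1000,
                       n_presso_sim: int = 1000,
                       run_sensitivity: bool = True) -> MediationResult:
    """Full two-step mediation with bidirectional gating.

    Forward edges give the total effect (exposure->outcome), beta1
    (exposure->mediator) and beta2 (mediator->outcome), each via the primary
    estimator under its own fixed/random decision. All three reverse gates
    (outcome->exposure, mediator->exposure, outcome->mediator) must be null,
    else mediation is refused naming the failed edge.
    """
    policy = policy or GatingPolicy()
    reverse_checks: dict[str, float] = {}
    gates = [
        ("outcome->exposure", outcome, exposure),
        ("mediator->exposure", mediator, exposure),
        ("outcome->mediator", outcome, mediator),
    ]
    for edge, rev_exp, rev_out in gates:
        pval, ok = reverse_gate(rev_exp, rev_out, policy, ld, blocklist,
                                config, seed=seed)
        reverse_checks[edge] = pval
        if not ok:
            raise MediationRefusedError(edge, f"reverse p = {pval:.3g}")

    edges, hsets = mediation_edge_estimates(exposure, mediator, outcome,
                                            policy, ld, blocklist, config,
                                            seed=seed)
    sens = {}
    if run_sensitivity:
        for name, hset in hsets.items():
            if hset.n_snps >= 2:
                sens[name] = sensitivity_report(hset, n_sim=n_presso_sim,
                                                seed=seed)

    result = mediation_from_estimates(edges["exposure->outcome"],
                                      edges["exposure->mediator"],
                                      edges["mediator->outcome"])
    result.reverse_checks = reverse_checks
    result.edge_sensitivity = sens
    return result
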