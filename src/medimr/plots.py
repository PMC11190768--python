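"""Diagnostic plots: scatter, forest, funnel and leave-one-out forest.

Presentation-only output; every figure is written straight to a file path.
"""

from __future__ import annotations

import numpy as np

from .estimators import MREstimate, wald_ratios
from .harmonize import HarmonizedSet


def _axes():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def scatter_plot(hset: HarmonizedSet, estimates: dict[str, MREstimate],
                 path) -> None:
    """Per-variant outcome vs exposure betas with per-method fit lines."""
    plt = _axes()
    be, se_e, bo, so = hset.arrays()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(be, bo, xerr=1.96 * se_e, yerr=1.96 * so, fmt="o", ms=4,
                color="0.3", ecolor="0.7", lw=0.8)
    xs = np.linspace(min(0, be.min()), max(0, be.max()), 50)
    for tag, est in estimates.items():
        if tag == "egger_intercept":
            continue
        icept = estimates["egger_intercept"].beta \
            if tag == "egger_slope" and "egger_intercept" in estimates else 0.0
        ax.plot(xs, icept + est.beta * xs, label=tag, lw=1.2)
    ax.axhline(0, color="0.8", lw=0.6)
    ax.axvline(0, color="0.8", lw=0.6)
    ax.set_xlabel("beta (exposure)")
    ax.set_ylabel("beta (outcome)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def forest_plot(hset: HarmonizedSet, overall: MREstimate, path) -> None:
    """Per-variant Wald ratios with 95% CIs and the combined estimate."""
    plt = _axes()
    rho, se_rho = wald_ratios(hset)
    ids = list(hset.instruments["snp_id"]) + ["combined"]
    vals = np.append(rho, overall.beta)
    los = np.append(rho - 1.96 * se_rho, overall.ci_low)
    his = np.append(rho + 1.96 * se_rho, overall.ci_high)
    y = np.arange(len(ids))[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(ids) + 1.5))
    ax.hlines(y, los, his, color="0.4", lw=1)
    ax.plot(vals, y, "s", ms=4, color="0.1")
    ax.axvline(0, color="0.8", lw=0.6)
    ax.set_yticks(y)
    ax.set_yticklabels(ids, fontsize=7)
    ax.set_xlabel("causal estimate (Wald ratio)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def funnel_plot(hset: HarmonizedSet, overall: MREstimate, path) -> None:
    """Wald ratio vs instrument precision (1/SE); asymmetry suggests bias."""
    plt = _axes()
    rho, se_rho = wald_ratios(hset)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(rho, 1.0 / se_rho, "o", ms=4, color="0.3")
    ax.axvline(overall.beta, color="C0", lw=1, label=overall.method)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def loo_forest_plot(loo: dict[str, MREstimate], overall: MREstimate,
                    path) -> None:
    """Leave-one-out IVW estimates against the full-set estimate."""
    plt = _axes()
    ids = list(loo) + ["all SNPs"]
    vals = [e.beta for e in loo.values()] + [overall.beta]
    los = [e.ci_low for e in loo.values()] + [overall.ci_low]
    his = [e.ci_high for e in loo.values()] + [overall.ci_high]
    y = np.arange(len(ids))[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(ids) + 1.5))
    ax.hlines(y, los, his, color="0.4", lw=1)
    ax.plot(vals, y, "s", ms=4, color="0.1")
    ax.axvline(overall.beta, color="C0", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(ids, fontsize=7)
    ax.set_xlabel("IVW estimate with SNP removed")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
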