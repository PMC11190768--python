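"""Synthetic multi-trait GWAS summary statistics under a known causal DAG.

The generator emulates the two-step study design directly at the
summary-statistic level: an exposure (e.g. a gut-microbiota taxon), a mediator
(a plasma metabolite) and an outcome (a binary disease trait, betas on the
log-OR scale) linked by true effects theta_xm (exposure->mediator), theta_my
(mediator->outcome) and theta_xy_direct, so the true total effect is
theta_xy_direct + theta_xm*theta_my.

Three instrument sets are generated: exposure instruments with per-variant
effects gamma_j from a point-normal, whose mediator and outcome marginal
effects follow the DAG; mediator-specific instruments with effects delta_j,
which act on the outcome only through the mediator; and outcome-specific
instruments with effects epsilon_j, which feed back on the exposure only under
a non-zero reverse effect theta_yx (the bidirectional-violation knob).
Observed betas add sampling noise with SE 1/sqrt(2*maf*(1-maf)*n)
(standardized-trait approximation); for the binary outcome n is the effective
sample size 4/(1/cases + 1/controls), so a rare disease yields realistically
wide log-OR standard errors. Optional horizontal pleiotropy (balanced,
directional, or InSIDE-violating), LD blocks with a chosen within-block r²,
and palindromic allele codings exercise every pipeline defence.

Default cohort sizes mirror the source GWAS of the motivating study: 7,738
(Dutch Microbiome Project), 8,299 (CLSA metabolites) and 500 hepatocellular
carcinoma cases / 314,193 controls (FinnGen R10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import COMPLEMENT, LDReference, SummaryStatTable

logger = logging.getLogger("medimr")

# ordered so palindromic pairs can be appended deliberately
_NON_PALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                          ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_snps: int = 20                   # exposure instruments
    n_mediator_snps: int | None = None  # mediator-specific; default = n_snps
    n_outcome_snps: int | None = None   # outcome-specific; default = n_snps
    n_exposure: int = 7738
    n_mediator: int = 8299
    n_cases: int = 500
    n_controls: int = 314193
    n_outcome: int | None = None       # overrides the binary effective n
    theta_xm: float = 0.0
    theta_my: float = 0.0
    theta_xy_direct: float = 0.0
    theta_yx: float = 0.0              # reverse outcome->exposure feedback
    gamma_sd: float = 0.15             # slab SD of true instrument effects
    frac_causal: float = 1.0           # point-normal: P(gamma_j != 0)
    pleiotropy_mode: str = "none"      # none|balanced|directional|inside_violating
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    frac_palindromic: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        if not 0.0 <= self.frac_palindromic <= 1.0:
            raise ValueError("frac_palindromic must be in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "inside_violating"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    @property
    def outcome_effective_n(self) -> float:
        """Effective GWAS sample size for the binary outcome."""
        if self.n_outcome is not None:
            return float(self.n_outcome)
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)

    @property
    def true_total_effect(self) -> float:
        return self.theta_xy_direct + self.theta_xm * self.theta_my

    @property
    def true_proportion_mediated(self) -> float | None:
        total = self.true_total_effect
        if total == 0:
            return None
        return self.theta_xm * self.theta_my / total


def _draw_alleles(rng: np.random.Generator, k: int,
                  frac_palindromic: float) -> tuple[np.ndarray, np.ndarray]:
    pal = rng.random(k) < frac_palindromic
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    for j in range(k):
        pool = _PALINDROMIC_PAIRS if pal[j] else _NON_PALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]
    return ea, oa


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.nextafter(0, 1), 1.0)


def _alpha(rng: np.random.Generator, cfg: SimulationConfig,
           gamma: np.ndarray) -> np.ndarray:
    """Per-variant horizontal pleiotropy on the outcome, per mode."""
    k = len(gamma)
    if k == 0 or cfg.pleiotropy_mode == "none" or cfg.pleiotropy_sd == 0 and \
            cfg.pleiotropy_mean == 0:
        return np.zeros(k)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_sd, k)
    if cfg.pleiotropy_mode == "directional":
        return rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, k)
    # inside_violating: pleiotropy correlated with instrument strength
    g_sd = gamma.std() or 1.0
    rho = 0.8
    noise = rng.normal(0.0, 1.0, k)
    return cfg.pleiotropy_mean + cfg.pleiotropy_sd * (
        rho * (gamma - gamma.mean()) / g_sd + np.sqrt(1 - rho**2) * noise)


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[SummaryStatTable, SummaryStatTable,
                                SummaryStatTable, LDReference, dict]:
    """Generate (exposure, mediator, outcome) tables, LD reference and truth.

    Deterministic given config (the seed is part of the config): identical
    configs yield bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    k_exp = cfg.n_snps
    k_med = cfg.n_mediator_snps if cfg.n_mediator_snps is not None else cfg.n_snps
    k_out = cfg.n_outcome_snps if cfg.n_outcome_snps is not None else cfg.n_snps
    k = k_exp + k_med + k_out

    maf = rng.uniform(*cfg.maf_range, size=k)
    ea, oa = _draw_alleles(rng, k, cfg.frac_palindromic)

    # genomic layout: blocks of ld_block_size SNPs, blocks separated by > 2 Mb
    # so clumping conflicts arise only within a block
    n_blocks = int(np.ceil(k / cfg.ld_block_size))
    chroms = np.empty(k, dtype=object)
    pos = np.empty(k, dtype=int)
    pairwise: dict[tuple[str, str], float] = {}
    snp_ids = np.array([f"rs{1000 + j}" for j in range(k)], dtype=object)
    for b in range(n_blocks):
        idx = np.arange(b * cfg.ld_block_size,
                        min((b + 1) * cfg.ld_block_size, k))
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 5_000_000
        for off, j in enumerate(idx):
            chroms[j] = chrom
            pos[j] = base + off * 10_000
        for a_i, i in enumerate(idx):
            for jdx in idx[a_i + 1:]:
                pairwise[(str(snp_ids[i]), str(snp_ids[jdx]))] = cfg.ld_within_r2
                pairwise[(str(snp_ids[jdx]), str(snp_ids[i]))] = cfg.ld_within_r2

    # true per-variant effects
    gamma = rng.normal(0.0, cfg.gamma_sd, k_exp)
    gamma *= rng.random(k_exp) < cfg.frac_causal
    delta = rng.normal(0.0, cfg.gamma_sd, k_med)
    epsilon = rng.normal(0.0, cfg.gamma_sd, k_out)
    alpha_exp = _alpha(rng, cfg, gamma)
    alpha_med = _alpha(rng, cfg, delta)

    total = cfg.true_total_effect
    true_exp = np.concatenate([gamma, np.zeros(k_med), cfg.theta_yx * epsilon])
    true_med = np.concatenate([cfg.theta_xm * gamma, delta,
                               cfg.theta_yx * cfg.theta_xm * epsilon])
    true_out = np.concatenate([total * gamma + alpha_exp,
                               cfg.theta_my * delta + alpha_med,
                               epsilon])

    tables = []
    for trait_id, n, n_report, true_beta, trait_type in (
            ("exposure", cfg.n_exposure, cfg.n_exposure, true_exp,
             "quantitative"),
            ("mediator", cfg.n_mediator, cfg.n_mediator, true_med,
             "quantitative"),
            ("outcome", cfg.outcome_effective_n,
             cfg.n_cases + cfg.n_controls, true_out, "binary")):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
        beta = rng.normal(true_beta, se)
        df = pd.DataFrame({
            "snp_id": snp_ids, "chrom": chroms, "pos": pos,
            "ea": ea, "oa": oa, "eaf": maf,
            "beta": beta, "se": se, "pval": _pvals(beta, se),
            "n": float(n_report),
        })
        tables.append(SummaryStatTable(trait_id, df, trait_type,
                                       provenance="simulated"))

    truth = {
        "theta_xm": cfg.theta_xm, "theta_my": cfg.theta_my,
        "theta_xy_direct": cfg.theta_xy_direct,
        "theta_yx": cfg.theta_yx,
        "total_effect": total,
        "indirect_effect": cfg.theta_xm * cfg.theta_my,
        "proportion_mediated": cfg.true_proportion_mediated,
        "gamma": gamma.tolist(), "delta": delta.tolist(),
        "epsilon": epsilon.tolist(),
        "alpha_exposure_snps": alpha_exp.tolist(),
        "alpha_mediator_snps": alpha_med.tolist(),
        "exposure_snp_ids": [str(s) for s in snp_ids[:k_exp]],
        "mediator_snp_ids": [str(s) for s in snp_ids[k_exp:k_exp + k_med]],
        "outcome_snp_ids": [str(s) for s in snp_ids[k_exp + k_med:]],
        "seed": cfg.seed,
    }
    return tables[0], tables[1], tables[2], LDReference(pairwise_r2=pairwise), truth


def perturb_alleles(table: SummaryStatTable, frac_swap: float = 0.0,
                    frac_strandflip: float = 0.0,
                    seed: int = 0) -> SummaryStatTable:
    """Semantics-preserving allele recoding, as a harmonization test fixture.

    A swapped row exchanges effect/other alleles, negating beta and
    complementing eaf; a strand-flipped row complements both alleles. A row
    may receive both perturbations.
    """
    if not (0.0 <= frac_swap <= 1.0 and 0.0 <= frac_strandflip <= 1.0):
        raise ValueError("perturbation fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = table.df.copy()
    swap = rng.random(len(df)) < frac_swap
    flip = rng.random(len(df)) < frac_strandflip
    ea = df["ea"].to_numpy(object).copy()
    oa = df["oa"].to_numpy(object).copy()
    ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, "eaf"] = 1.0 - df.loc[swap, "eaf"]
    comp = np.vectorize(COMPLEMENT.get)
    if flip.any():
        ea[flip] = comp(ea[flip])
        oa[flip] = comp(oa[flip])
    df["ea"] = ea
    df["oa"] = oa
    return table.with_df(df)
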