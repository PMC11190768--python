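"""Instrument selection and exposure/outcome allele harmonization.

Selection follows the standard two-sample MR recipe: keep variants associated
with the exposure below a p-value threshold, prune correlated variants by
greedy LD clumping (r² > ``r2_max`` within ``window_kb`` on the same
chromosome), require per-variant instrument strength F = beta²/se² >= ``f_min``
and remove variants on a confounder blocklist.

Harmonization puts exposure and outcome effects on a shared effect-allele
convention. Allele codings that differ by effect/other swap get a sign flip,
codings that differ by strand get a complement flip, and palindromic variants
(A/T or C/G) are dropped by default because their strand cannot be resolved
from alleles alone; an optional allele-frequency rescue is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import COMPLEMENT, LDReference, SummaryStatTable

logger = logging.getLogger("medimr")

#: columns of the harmonized instrument frame
INSTRUMENT_COLUMNS = [
    "snp_id", "chrom", "pos",
    "beta_exposure", "se_exposure", "pval_exposure", "eaf_exposure",
    "beta_outcome", "se_outcome", "pval_outcome", "eaf_outcome",
    "f_stat", "harmonization_action",
]


@dataclass
class SelectionConfig:
    """Thresholds for instrument selection, defaults per the study protocol."""

    p_max: float = 1e-5
    r2_max: float = 0.001
    window_kb: int = 1000
    f_min: float = 10.0
    palindrome_policy: str = "drop"   # or "eaf_rescue"
    eaf_tolerance: float = 0.08


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a shared effect-allele convention."""

    exposure_id: str
    outcome_id: str
    instruments: pd.DataFrame
    selection_log: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.instruments)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) as arrays."""
        ins = self.instruments
        return (ins["beta_exposure"].to_numpy(float),
                ins["se_exposure"].to_numpy(float),
                ins["beta_outcome"].to_numpy(float),
                ins["se_outcome"].to_numpy(float))

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.instruments["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.instruments.loc[keep].reset_index(drop=True),
                             dict(self.selection_log))

    def drop(self, snp_ids) -> "HarmonizedSet":
        keep = ~self.instruments["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.instruments.loc[keep].reset_index(drop=True),
                             dict(self.selection_log))


# ---------------------------------------------------------------------------
# Row-local filters
# ---------------------------------------------------------------------------

def filter_by_pvalue(table: SummaryStatTable, p_max: float = 1e-5) -> SummaryStatTable:
    """Keep variants with exposure p strictly below ``p_max``."""
    if not 0.0 < p_max <= 1.0:
        raise ValueError(f"p_max must be in (0, 1], got {p_max}")
    out = table.with_df(table.df.loc[table.df["pval"] < p_max])
    if len(out) == 0:
        logger.warning("p-value filter at %g left zero variants for %s",
                       p_max, table.trait_id)
    return out


def f_statistic(df: pd.DataFrame) -> pd.Series:
    """Per-variant instrument-strength F = beta² / se²."""
    return (df["beta"] / df["se"]) ** 2


def filter_by_f_stat(table: SummaryStatTable, f_min: float = 10.0) -> SummaryStatTable:
    """Keep variants with F = beta²/se² >= ``f_min`` (weak-instrument guard)."""
    return table.with_df(table.df.loc[f_statistic(table.df) >= f_min])


def apply_blocklist(table: SummaryStatTable, blocklist: set[str]) -> SummaryStatTable:
    """Remove variants whose id is on the confounder blocklist."""
    out = table.with_df(table.df.loc[~table.df["snp_id"].isin(blocklist)])
    dropped = len(table) - len(out)
    if dropped:
        logger.info("blocklist removed %d variant(s) from %s",
                    dropped, table.trait_id)
    if len(out) == 0:
        logger.warning("blocklist removed every variant from %s", table.trait_id)
    return out


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def ld_clump(table: SummaryStatTable, ld: LDReference,
             r2_max: float = 0.001, window_kb: int = 1000) -> SummaryStatTable:
    """Greedy LD clumping by ascending p-value.

    Variants are visited from most to least significant (ties broken by
    ascending (chrom, pos) then snp_id, so output is deterministic); a variant
    is retained iff no already-retained variant on the same chromosome lies
    within ``window_kb`` and correlates with it above ``r2_max``. Pairs absent
    from the LD reference count as r² = 0.
    """
    df = table.df.sort_values(["pval", "chrom", "pos", "snp_id"],
                              kind="mergesort")
    kept: list[tuple[str, str, float]] = []  # (snp_id, chrom, pos)
    keep_ids = []
    window = window_kb * 1000.0
    for row in df.itertuples(index=False):
        ok = True
        for kid, kchrom, kpos in kept:
            if kchrom == row.chrom and abs(kpos - row.pos) <= window \
                    and ld.r2(kid, row.snp_id) > r2_max:
                ok = False
                break
        if ok:
            kept.append((row.snp_id, row.chrom, float(row.pos)))
            keep_ids.append(row.snp_id)
    out_df = table.df.loc[table.df["snp_id"].isin(set(keep_ids))]
    return table.with_df(out_df)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def _classify(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> str | None:
    """Action aligning an outcome allele coding to the exposure's.

    Returns one of none/sign_flip/strand_flip/strand_flip_and_sign_flip, or
    None when irreconcilable. Only meaningful for non-palindromic pairs.
    """
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "none"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "sign_flip"
    cx, cox = COMPLEMENT[ea_x], COMPLEMENT[oa_x]
    if (ea_y, oa_y) == (cx, cox):
        return "strand_flip"
    if (ea_y, oa_y) == (cox, cx):
        return "strand_flip_and_sign_flip"
    return None


def harmonize(exposure: SummaryStatTable, outcome: SummaryStatTable,
              palindrome_policy: str = "drop",
              eaf_tolerance: float = 0.08) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    Variants present in both tables are paired; outcome betas are sign-flipped
    when the outcome's effect allele is the exposure's other allele (directly
    or on the complementary strand). Palindromic variants are dropped under the
    default policy; under ``eaf_rescue`` they are aligned by allele frequency
    and kept only when both frequencies are informative (outside
    0.5 ± ``eaf_tolerance``).
    """
    if palindrome_policy not in ("drop", "eaf_rescue"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    merged = exposure.df.merge(outcome.df, on="snp_id",
                               suffixes=("_exposure", "_outcome"))
    log = {"missing_in_outcome": len(exposure) - len(merged),
           "palindrome": 0, "irreconcilable": 0}
    rows = []
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.ea_exposure, r.oa_exposure
        ea_y, oa_y = r.ea_outcome, r.oa_outcome
        beta_y, eaf_y = r.beta_outcome, r.eaf_outcome
        if _is_palindromic(ea_x, oa_x):
            # outcome coding must still be the same allele pair
            if {ea_y, oa_y} != {ea_x, oa_x}:
                log["irreconcilable"] += 1
                continue
            if palindrome_policy == "drop":
                log["palindrome"] += 1
                continue
            eaf_x = r.eaf_exposure
            lo, hi = 0.5 - eaf_tolerance, 0.5 + eaf_tolerance
            informative = (pd.notna(eaf_x) and pd.notna(eaf_y)
                           and not lo <= eaf_x <= hi and not lo <= eaf_y <= hi)
            if not informative:
                log["palindrome"] += 1
                continue
            # align by frequency: same side of 0.5 means same allele tracked
            if (eaf_x - 0.5) * (eaf_y - 0.5) > 0:
                action = "none"
            else:
                action = "sign_flip"
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
        else:
            action = _classify(ea_x, oa_x, ea_y, oa_y)
            if action is None:
                log["irreconcilable"] += 1
                logger.info("irreconcilable alleles for %s: %s/%s vs %s/%s",
                            r.snp_id, ea_x, oa_x, ea_y, oa_y)
                continue
            if action in ("sign_flip", "strand_flip_and_sign_flip"):
                beta_y = -beta_y
                if pd.notna(eaf_y):
                    eaf_y = 1.0 - eaf_y
        rows.append({
            "snp_id": r.snp_id, "chrom": r.chrom_exposure, "pos": r.pos_exposure,
            "beta_exposure": r.beta_exposure, "se_exposure": r.se_exposure,
            "pval_exposure": r.pval_exposure, "eaf_exposure": r.eaf_exposure,
            "beta_outcome": beta_y, "se_outcome": r.se_outcome,
            "pval_outcome": r.pval_outcome, "eaf_outcome": eaf_y,
            "f_stat": (r.beta_exposure / r.se_exposure) ** 2,
            "harmonization_action": action,
        })
    instruments = pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS)
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, instruments, log)


# ---------------------------------------------------------------------------
# Full selection pipeline
# ---------------------------------------------------------------------------

def select_instruments(exposure: SummaryStatTable, outcome: SummaryStatTable,
                       ld: LDReference | None = None,
                       blocklist: set[str] | None = None,
                       config: SelectionConfig | None = None) -> HarmonizedSet:
    """p-filter -> LD clump -> F-filter -> blocklist -> harmonize.

    The selection log records the count dropped at each stage; the counts sum
    to input size minus retained size.
    """
    cfg = config or SelectionConfig()
    n0 = len(exposure)
    t = filter_by_pvalue(exposure, cfg.p_max)
    log = {"input": n0, "p_threshold": n0 - len(t)}
    if ld is not None:
        t2 = ld_clump(t, ld, cfg.r2_max, cfg.window_kb)
    else:
        t2 = t
    log["clumping"] = len(t) - len(t2)
    t3 = filter_by_f_stat(t2, cfg.f_min)
    log["f_stat"] = len(t2) - len(t3)
    t4 = apply_blocklist(t3, blocklist or set())
    log["blocklist"] = len(t3) - len(t4)
    hset = harmonize(t4, outcome, cfg.palindrome_policy, cfg.eaf_tolerance)
    log.update(hset.selection_log)
    log["retained"] = hset.n_snps
    hset.selection_log = log
    return hset
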