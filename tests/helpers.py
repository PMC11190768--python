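"""Shared builders for constructing small fixtures in-memory."""

from __future__ import annotations

import numpy as np
import pandas as pd

from medimr.harmonize import INSTRUMENT_COLUMNS, HarmonizedSet
from medimr.gwas_io import SummaryStatTable


def make_hset(beta_exposure, se_exposure, beta_outcome, se_outcome,
              snp_ids=None, exposure_id="X", outcome_id="Y") -> HarmonizedSet:
    """HarmonizedSet straight from effect arrays (bypasses selection)."""
    be = np.asarray(beta_exposure, float)
    se_e = np.asarray(se_exposure, float)
    bo = np.asarray(beta_outcome, float)
    so = np.asarray(se_outcome, float)
    k = len(be)
    ids = list(snp_ids) if snp_ids is not None else [f"rs{i}" for i in range(k)]
    df = pd.DataFrame({
        "snp_id": ids, "chrom": ["1"] * k,
        "pos": np.arange(k) * 5_000_000 + 1_000_000,
        "beta_exposure": be, "se_exposure": se_e,
        "pval_exposure": np.full(k, 1e-8), "eaf_exposure": np.full(k, 0.3),
        "beta_outcome": bo, "se_outcome": so,
        "pval_outcome": np.full(k, 0.01), "eaf_outcome": np.full(k, 0.3),
        "f_stat": (be / se_e) ** 2, "harmonization_action": ["none"] * k,
    }, columns=INSTRUMENT_COLUMNS)
    return HarmonizedSet(exposure_id, outcome_id, df)


def make_table(snp_ids, beta, se, pval=None, *, chrom=None, pos=None,
               ea="A", oa="G", eaf=0.3, n=10000.0, trait_id="trait",
               trait_type="quantitative") -> SummaryStatTable:
    """SummaryStatTable from arrays with broadcastable scalar defaults."""
    k = len(snp_ids)

    def col(x, default=None):
        if x is None:
            x = default
        x = np.asarray(x if np.ndim(x) else [x] * k)
        return x

    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if pval is None:
        from scipy import stats
        pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)),
                       np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({
        "snp_id": list(snp_ids),
        "chrom": col(chrom, ["1"] * k),
        "pos": col(pos, list(np.arange(k) * 5_000_000 + 1_000_000)),
        "ea": col(ea), "oa": col(oa), "eaf": col(eaf).astype(float),
        "beta": beta, "se": se, "pval": np.asarray(pval, float),
        "n": col(n).astype(float),
    })
    return SummaryStatTable(trait_id, df, trait_type)
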