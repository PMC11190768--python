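"""Reading, validating and writing GWAS summary statistics and LD references.

Summary statistics are row-per-variant delimited text tables. Files in any
column-name dialect (e.g. FinnGen's ``rsids/#chrom/alt/ref/af_alt``) are mapped
onto one canonical in-memory schema, so every downstream step sees the same
semantic columns regardless of the source cohort's header conventions.

LD may be supplied either as a genotype dosage matrix (individuals x variants,
dosages 0-2) from which pairwise r² is computed, or as a precomputed pairwise
r² table; both normalise to the same symmetric map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("medimr")

#: canonical column order of a summary-statistic table in memory
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n",
]

#: default on-disk header, tab separated
DEFAULT_HEADER = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "PVAL", "N"]

#: built-in column-name dialects: semantic name -> file column
DIALECTS: dict[str, dict[str, str]] = {
    "default": dict(zip(CANONICAL_COLUMNS, DEFAULT_HEADER)),
    "finngen": {
        "snp_id": "rsids", "chrom": "#chrom", "pos": "pos",
        "ea": "alt", "oa": "ref", "eaf": "af_alt",
        "beta": "beta", "se": "sebeta", "pval": "pval", "n": "n",
    },
}

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SummaryStatError(ValueError):
    """Fatal configuration or data error while ingesting summary statistics."""


@dataclass
class SummaryStatTable:
    """One trait's GWAS summary statistics.

    ``df`` holds the canonical columns ``snp_id chrom pos ea oa eaf beta se
    pval n``; ``eaf`` and ``n`` may be NaN. snp_ids are unique within a table.
    """

    trait_id: str
    df: pd.DataFrame
    trait_type: str = "quantitative"  # or "binary" (betas are log-ORs)
    provenance: str = ""
    validation_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise SummaryStatError(f"duplicate snp_id {dup!r} in {self.trait_id}")

    def __len__(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "SummaryStatTable":
        """Copy of this table carrying a new record frame."""
        return SummaryStatTable(self.trait_id, df.reset_index(drop=True),
                                self.trait_type, self.provenance,
                                dict(self.validation_log))


def _validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating the per-variant invariants; count drops by reason."""
    log: dict[str, int] = {}
    df = df.copy()
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        n = int(mask.sum())
        if n:
            log[reason] = log.get(reason, 0) + n
            logger.warning("dropping %d row(s): %s", n, reason)
            df = df.loc[~mask]

    drop(~df["ea"].isin(VALID_ALLELES) | ~df["oa"].isin(VALID_ALLELES),
         "non_biallelic_snp_allele")
    drop(df["ea"] == df["oa"], "identical_alleles")
    drop(~(df["se"] > 0), "nonpositive_se")
    drop(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval_out_of_range")
    drop(df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1)),
         "eaf_out_of_range")
    drop(df["pos"].notna() & (df["pos"] < 1), "nonpositive_position")
    drop(df["n"].notna() & ~(df["n"] > 0), "nonpositive_n")
    return df.reset_index(drop=True), log


def read_summary_stats(path, dialect: dict[str, str] | str | None = None, *,
                       trait_id: str | None = None,
                       trait_type: str = "quantitative",
                       sep: str = "\t") -> SummaryStatTable:
    """Read a delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Mapping of canonical column names to file column names, or the name of
        a built-in dialect (``"default"``, ``"finngen"``). Dialect mapping is a
        pure renaming: numbers are never altered.
    """
    if dialect is None:
        dialect = DIALECTS["default"]
    elif isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    raw = pd.read_csv(path, sep=sep, dtype={dialect["snp_id"]: str,
                                            dialect["chrom"]: str})
    missing = [col for col in dialect.values() if col not in raw.columns]
    if missing:
        raise SummaryStatError(
            f"required column(s) {missing} absent from {path} "
            f"(present: {list(raw.columns)})")
    df = raw[[dialect[c] for c in CANONICAL_COLUMNS]].copy()
    df.columns = CANONICAL_COLUMNS
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df, log = _validate_records(df)
    if len(df) == 0:
        raise SummaryStatError(f"no valid rows in {path} after validation")
    return SummaryStatTable(trait_id=trait_id or str(path), df=df,
                            trait_type=trait_type, provenance=str(path),
                            validation_log=log)


def write_summary_stats(table: SummaryStatTable, path,
                        dialect: dict[str, str] | str | None = None,
                        sep: str = "\t") -> None:
    """Write a table back to disk (default dialect unless another is given).

    Floats are written with shortest round-trip repr, so read-after-write
    reproduces every numeric field exactly.
    """
    if dialect is None:
        dialect = DIALECTS["default"]
    elif isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    out = table.df[CANONICAL_COLUMNS].copy()
    out.columns = [dialect[c] for c in CANONICAL_COLUMNS]
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# LD reference
# ---------------------------------------------------------------------------

@dataclass
class LDReference:
    """Pairwise LD, as genotype dosages and/or a precomputed r² map.

    ``genotypes`` is individuals x variants with dosages in [0, 2] and variant
    ids as columns. ``pairwise_r2`` maps unordered id pairs to r² in [0, 1];
    self-pairs are implicitly 1.
    """

    genotypes: pd.DataFrame | None = None
    pairwise_r2: dict[tuple[str, str], float] | None = None

    def r2(self, a: str, b: str) -> float:
        """r² between two variants; unknown pairs are treated as 0."""
        if a == b:
            return 1.0
        if self.pairwise_r2 is not None:
            got = self.pairwise_r2.get((a, b))
            if got is None:
                got = self.pairwise_r2.get((b, a))
            if got is not None:
                return got
        if self.genotypes is not None and \
                a in self.genotypes.columns and b in self.genotypes.columns:
            return compute_pairwise_r2(self, [a, b])[(a, b)]
        logger.debug("r2 pair (%s, %s) absent from LD reference; using 0", a, b)
        return 0.0


def compute_pairwise_r2(ld: LDReference, ids: list[str]) -> dict[tuple[str, str], float]:
    """Pairwise r² = squared Pearson correlation of dosage vectors.

    Zero-variance variants yield undefined correlations; their pairs are
    flagged with a warning and reported as r² = 0.
    """
    if ld.genotypes is None:
        raise ValueError("LD reference carries no genotype matrix")
    missing = [i for i in ids if i not in ld.genotypes.columns]
    if missing:
        raise KeyError(f"variant id(s) {missing} absent from genotype matrix")
    dos = ld.genotypes[ids].to_numpy(dtype=float)
    sd = dos.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("zero-variance dosage for %s; pairs treated as r2=0",
                       [i for i, bad in zip(ids, degenerate) if bad])
    out: dict[tuple[str, str], float] = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(dos, rowvar=False) if len(ids) > 1 else np.ones((1, 1))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            if degenerate[i] or degenerate[j]:
                r2 = 0.0
            else:
                r2 = float(np.clip(corr[i, j] ** 2, 0.0, 1.0))
            out[(a, b)] = r2
            out[(b, a)] = r2
        out[(a, a)] = 1.0
    return out


def read_ld_genotypes(path, sep: str = "\t") -> LDReference:
    """Genotype dosage TSV: first column individual id, one column per variant."""
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    return LDReference(genotypes=df.astype(float))


def read_ld_table(path, sep: str = "\t") -> LDReference:
    """Precomputed pairwise table: columns ``SNP1 SNP2 R2``."""
    df = pd.read_csv(path, sep=sep)
    pairs: dict[tuple[str, str], float] = {}
    for a, b, r2 in df.itertuples(index=False):
        r2 = float(r2)
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 {r2} for pair ({a}, {b}) outside [0, 1]")
        pairs[(str(a), str(b))] = r2
        pairs[(str(b), str(a))] = r2
    return LDReference(pairwise_r2=pairs)


def write_ld_table(ld: LDReference, path, sep: str = "\t") -> None:
    if ld.pairwise_r2 is None:
        raise ValueError("LD reference carries no pairwise map")
    seen = set()
    rows = []
    for (a, b), r2 in ld.pairwise_r2.items():
        key = tuple(sorted((a, b)))
        if key in seen or a == b:
            continue
        seen.add(key)
        rows.append((a, b, r2))
    pd.DataFrame(rows, columns=["SNP1", "SNP2", "R2"]).to_csv(
        path, sep=sep, index=False)


def read_blocklist(path) -> set[str]:
    """Confounder-variant blocklist: one id per line, ``#`` comments allowed."""
    ids: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.add(line)
    return ids
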