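"""Read, quality-control and harmonize GWAS summary statistics.

The on-disk dialect is the munged-sumstats convention: tab-delimited with
header ``SNP A1 A2 Z N`` and optional ``MAF`` / ``INFO`` columns.  The
allele registry (the allowed-SNP list, HapMap3-style) is tab-delimited
``SNP A1 A2 CHR BP``.

`munge` restricts a raw table to registry SNPs, aligns the effect allele
to the registry orientation (flipping the z sign when the pair is
reversed), applies strict MAF and imputation-quality filters, drops
strand-ambiguous pairs, and excludes configured genomic regions (the MHC
by default).  Every dropped record is attributed to exactly one rule so
the QC report is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyOutputError, InvalidArgumentError

__all__ = [
    "REQUIRED_COLUMNS",
    "DEFAULT_MHC",
    "QCReport",
    "read_sumstats",
    "write_sumstats",
    "read_registry",
    "write_registry",
    "registry_from_battery",
    "munge",
    "effective_sample_size",
]

REQUIRED_COLUMNS = ("SNP", "A1", "A2", "Z", "N")
VALID_BASES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

#: Default excluded region: the MHC, chr6:26,000,000-34,000,000 (1-based
#: inclusive).  The boundaries are a package convention; override via
#: ``exclude_regions``.
DEFAULT_MHC = (("6", 26_000_000, 34_000_000),)

#: Attribution order when a record violates several rules at once.
RULE_ORDER = ("not_in_registry", "region", "maf", "info", "ambiguous",
              "allele_mismatch")


@dataclass
class QCReport:
    """Counts of records dropped per rule plus the retained count."""

    n_input: int
    retained: int
    dropped: dict = field(default_factory=dict)

    def __post_init__(self):
        for rule in RULE_ORDER:
            self.dropped.setdefault(rule, 0)
        if sum(self.dropped.values()) + self.retained != self.n_input:
            raise InvalidArgumentError("QC report does not conserve records")

    def __str__(self):
        lines = [f"input records: {self.n_input}"]
        for rule in RULE_ORDER:
            lines.append(f"  dropped ({rule}): {self.dropped[rule]}")
        lines.append(f"retained: {self.retained}")
        return "\n".join(lines)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise InvalidArgumentError(f"missing required column {col!r}")
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise InvalidArgumentError(f"duplicate SNP id {dup!r}")
    if (df["A1"] == df["A2"]).any():
        raise InvalidArgumentError("records with identical alleles present")
    if not np.isfinite(df["Z"].to_numpy(dtype=float)).all():
        raise InvalidArgumentError("non-finite z-statistics present")
    return df


def read_sumstats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_sumstats(df)


def write_sumstats(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_registry(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    for col in ("SNP", "A1", "A2", "CHR", "BP"):
        if col not in df.columns:
            raise InvalidArgumentError(f"registry missing column {col!r}")
    return df


def write_registry(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def registry_from_battery(table: pd.DataFrame, ld: pd.DataFrame) -> pd.DataFrame:
    """Build an allele registry from one simulated table plus LD coordinates."""
    reg = table[["SNP", "A1", "A2"]].merge(ld[["SNP", "CHR", "BP"]], on="SNP")
    reg["CHR"] = reg["CHR"].astype(str)
    return reg


def munge(raw: pd.DataFrame, registry: pd.DataFrame, maf_min: float = 0.01,
          info_min: float = 0.9, exclude_regions=DEFAULT_MHC):
    """Quality-control one raw table against the allele registry.

    Filters are strict inequalities (retain only ``MAF > maf_min`` and
    ``INFO > info_min``); records lacking an optional column pass that
    filter.  Returns ``(munged_table, QCReport)``; the munged table keeps
    SNP, A1, A2, Z, N with registry allele orientation.  Raises
    :class:`EmptyOutputError` when nothing survives.
    """
    if not 0.0 <= maf_min <= 1.0 or not 0.0 <= info_min <= 1.0:
        raise InvalidArgumentError("maf_min and info_min must be in [0, 1]")
    validate_sumstats(raw)
    n_input = len(raw)
    df = raw.merge(
        registry.rename(columns={"A1": "REG_A1", "A2": "REG_A2"}),
        on="SNP", how="left")

    in_registry = df["REG_A1"].notna()
    chrom = df["CHR"].astype(str) if "CHR" in df else pd.Series("", index=df.index)
    in_region = pd.Series(False, index=df.index)
    for reg_chrom, start, end in exclude_regions or ():
        in_region |= (chrom == str(reg_chrom)) & (df["BP"] >= start) & (df["BP"] <= end)

    if "MAF" in df.columns:
        maf_fail = df["MAF"].notna() & ~(df["MAF"] > maf_min)
    else:
        maf_fail = pd.Series(False, index=df.index)
    if "INFO" in df.columns:
        info_fail = df["INFO"].notna() & ~(df["INFO"] > info_min)
    else:
        info_fail = pd.Series(False, index=df.index)

    pairs = list(zip(df["A1"], df["A2"]))
    ambiguous = pd.Series([p in AMBIGUOUS_PAIRS for p in pairs], index=df.index)
    direct = (df["A1"] == df["REG_A1"]) & (df["A2"] == df["REG_A2"])
    flipped = (df["A1"] == df["REG_A2"]) & (df["A2"] == df["REG_A1"])
    mismatch = in_registry & ~(direct | flipped)

    reasons = pd.Series("", index=df.index, dtype=object)

    def attribute(rule, mask):
        free = mask & (reasons == "")
        reasons[free] = rule

    attribute("not_in_registry", ~in_registry)
    attribute("region", in_region)
    attribute("maf", maf_fail)
    attribute("info", info_fail)
    attribute("ambiguous", ambiguous)
    attribute("allele_mismatch", mismatch)

    keep = reasons == ""
    out = df[keep].copy()
    z = np.where(flipped[keep], -out["Z"].to_numpy(dtype=float),
                 out["Z"].to_numpy(dtype=float))
    out["Z"] = z
    out["A1"] = out["REG_A1"]
    out["A2"] = out["REG_A2"]
    cols = ["SNP", "A1", "A2", "Z", "N"]
    for extra in ("MAF", "INFO"):
        if extra in out.columns:
            cols.append(extra)
    out = out[cols].reset_index(drop=True)

    counts = reasons[~keep].value_counts().to_dict()
    report = QCReport(n_input=n_input, retained=len(out), dropped=counts)
    if len(out) == 0:
        raise EmptyOutputError("quality control removed every record")
    return out, report


def effective_sample_size(n_cases: int, n_controls: int) -> float:
    """Effective sample size of a case-control GWAS: 4/(1/n_ca + 1/n_co)."""
    if n_cases <= 0 or n_controls <= 0:
        raise InvalidArgumentError("case and control counts must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)
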