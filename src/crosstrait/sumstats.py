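"""Reading, validation and harmonization of GWAS summary statistics.

Two studies can only be combined per variant once their signed statistics
refer to the same effect allele.  This module reads whitespace/tab-delimited
summary-statistics tables into a validated :class:`SumStatsTable`, and
harmonizes two tables onto a shared variant set and effect-allele
orientation, resolving allele swaps and strand flips and (by default)
dropping strand-ambiguous palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary-statistics table
STANDARD_COLUMNS = ("snp_id", "chrom", "pos", "a1", "a2", "eaf", "z", "n", "p")

#: canonical column order of a harmonized two-trait table
HARMONIZED_COLUMNS = (
    "snp_id", "chrom", "pos", "ea", "oa",
    "z1", "z2", "n1", "n2", "p1", "p2",
)

# lower-cased header aliases recognised without an explicit column_map
_ALIASES = {
    "snp_id": ("snp_id", "snp", "rsid", "markername", "id", "variant_id"),
    "chrom": ("chrom", "chr", "chromosome"),
    "pos": ("pos", "bp", "position", "base_pair_location"),
    "a1": ("a1", "effect_allele", "allele1", "ea"),
    "a2": ("a2", "other_allele", "allele2", "oa", "noneffect_allele"),
    "eaf": ("eaf", "frq", "freq", "af", "effect_allele_frequency"),
    "z": ("z", "zscore", "z_score", "stat"),
    "beta": ("beta", "b", "effect", "log_odds"),
    "se": ("se", "stderr", "standard_error"),
    "n": ("n", "nobs", "sample_size", "neff"),
    "p": ("p", "pval", "p_value", "pvalue"),
}


def zscore_from_beta(beta, se):
    """Signed Z statistic ``beta / se``.

    Accepts scalars or arrays; every standard error must be positive.
    """
    se_arr = np.asarray(se, dtype=float)
    if np.any(se_arr <= 0):
        raise ValueError("standard errors must be positive")
    return np.asarray(beta, dtype=float) / se_arr


@dataclass
class SumStatsTable:
    """One trait's per-variant association summaries.

    ``df`` holds the :data:`STANDARD_COLUMNS`; rows are unique on ``snp_id``
    and sorted by (chrom, pos).  ``m_total`` is the genome-wide SNP count the
    study represents (used as the LD-score-regression denominator); by
    default the number of rows.
    """

    df: pd.DataFrame
    trait: str = "trait"
    m_total: int = field(default=0)

    def __post_init__(self):
        if self.m_total == 0:
            self.m_total = len(self.df)

    def __len__(self) -> int:
        return len(self.df)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric chromosomes first in natural order, then others lexically."""
    s = chrom.astype(str)
    num = pd.to_numeric(s, errors="coerce")
    others = {c: 1e6 + i for i, c in enumerate(sorted(s[num.isna()].unique()))}
    return num.fillna(s.map(others))


def _resolve_columns(header: list[str], column_map: dict | None) -> dict:
    """Map standard field names to actual file columns."""
    lower = {c.lower(): c for c in header}
    out = {}
    for std, aliases in _ALIASES.items():
        if column_map and std in column_map:
            if column_map[std] in header:
                out[std] = column_map[std]
            continue
        for a in aliases:
            if a in lower:
                out[std] = lower[a]
                break
    return out


def read_sumstats(
    path,
    column_map: dict | None = None,
    trait: str = "trait",
    n_default: float | None = None,
    m_total: int | None = None,
    z_p_rtol: float = 1e-6,
) -> SumStatsTable:
    """Read a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        File path; gzip is handled transparently.
    column_map
        Optional mapping from standard names (``snp_id``, ``chrom``, ``pos``,
        ``a1``, ``a2``, ``eaf``, ``z``, ``beta``, ``se``, ``n``, ``p``) to the
        file's column names, overriding the built-in alias table.
    trait
        Label stored on the returned table.
    n_default
        Per-file sample size used when the file has no N column.
    m_total
        Genome-wide SNP count; defaults to the number of valid rows.
    z_p_rtol
        Relative tolerance for the consistency check ``p ~= 2*Phi(-|z|)``;
        inconsistent rows keep their Z and have p recomputed from it, with a
        logged count.

    Raises
    ------
    ValueError
        If a mandatory column is missing (the error names it) or no valid
        rows remain after validation.
    """
    df = pd.read_csv(path, sep=r"\s+", compression="infer",
                     dtype={"chrom": str}, float_precision="round_trip")
    cols = _resolve_columns(list(df.columns), column_map)

    for mandatory in ("snp_id", "chrom", "pos", "a1", "a2"):
        if mandatory not in cols:
            raise ValueError(f"missing mandatory column: {mandatory}")
    if "z" not in cols and not ("beta" in cols and "se" in cols):
        raise ValueError("missing mandatory column: z (or beta and se)")

    out = pd.DataFrame(
        {
            "snp_id": df[cols["snp_id"]].astype(str),
            "chrom": df[cols["chrom"]].astype(str),
            "pos": pd.to_numeric(df[cols["pos"]], errors="coerce"),
            "a1": df[cols["a1"]].astype(str).str.upper(),
            "a2": df[cols["a2"]].astype(str).str.upper(),
        }
    )
    out["eaf"] = (
        pd.to_numeric(df[cols["eaf"]], errors="coerce") if "eaf" in cols else np.nan
    )
    if "z" in cols:
        out["z"] = pd.to_numeric(df[cols["z"]], errors="coerce")
    else:
        beta = pd.to_numeric(df[cols["beta"]], errors="coerce")
        se = pd.to_numeric(df[cols["se"]], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            out["z"] = np.where(se > 0, beta / se, np.nan)
    if "n" in cols:
        out["n"] = pd.to_numeric(df[cols["n"]], errors="coerce")
        if n_default is not None:
            out["n"] = out["n"].fillna(n_default)
    elif n_default is not None:
        out["n"] = float(n_default)
    else:
        raise ValueError("missing mandatory column: n (and no n_default given)")
    out["p"] = pd.to_numeric(df[cols["p"]], errors="coerce") if "p" in cols else np.nan

    n_raw = len(out)
    p_from_z = 2.0 * stats.norm.sf(np.abs(out["z"]))
    out["p"] = out["p"].fillna(pd.Series(p_from_z, index=out.index))

    # flag z/p inconsistencies beyond rounding and repair p from z
    # (only for p inside its domain; p <= 0 or > 1 is dropped as invalid)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(out["p"] - p_from_z) / np.maximum(p_from_z, 1e-300)
    inconsistent = (
        (rel > z_p_rtol) & out["z"].notna() & (out["p"] > 0) & (out["p"] <= 1)
    )
    if inconsistent.any():
        log.warning(
            "%s: %d records with p inconsistent with z; p recomputed from z",
            trait, int(inconsistent.sum()),
        )
        out.loc[inconsistent, "p"] = p_from_z[inconsistent.to_numpy()]

    valid = (
        out["a1"].isin(VALID_BASES)
        & out["a2"].isin(VALID_BASES)
        & (out["a1"] != out["a2"])
        & out["z"].notna()
        & np.isfinite(out["z"])
        & (out["n"] > 0)
        & (out["p"] > 0)
        & (out["p"] <= 1)
        & out["pos"].notna()
        & (out["eaf"].isna() | ((out["eaf"] >= 0) & (out["eaf"] <= 1)))
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.warning("%s: dropped %d invalid records of %d", trait, n_dropped, n_raw)
    out = out[valid]

    dup = out["snp_id"].duplicated()
    if dup.any():
        log.warning("%s: dropped %d duplicate snp_id records", trait, int(dup.sum()))
        out = out[~dup]

    if out.empty:
        raise ValueError(f"{path}: no valid records")

    out = out.assign(pos=out["pos"].astype(np.int64))
    out = out.sort_values(
        ["chrom", "pos"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return SumStatsTable(out[list(STANDARD_COLUMNS)], trait=trait,
                         m_total=m_total or len(out))


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table back as TSV in the standard column order.

    Floats use 17 significant digits so a write/read round trip is
    bit-exact.
    """
    table.df[list(STANDARD_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _orientation(a1: str, a2: str, b1: str, b2: str) -> int:
    """Sign relating study 2's effect allele (b1) to study 1's (a1).

    +1: same effect allele (directly or via strand complement);
    -1: swapped alleles (z must be negated); 0: irreconcilable.
    """
    if (b1, b2) == (a1, a2):
        return 1
    if (b1, b2) == (a2, a1):
        return -1
    fb1, fb2 = COMPLEMENT.get(b1), COMPLEMENT.get(b2)
    if (fb1, fb2) == (a1, a2):
        return 1
    if (fb1, fb2) == (a2, a1):
        return -1
    return 0


def harmonize_pair(
    t1: SumStatsTable,
    t2: SumStatsTable,
    drop_palindromic: bool = True,
    freq_rescue: bool = False,
    freq_margin: float = 0.08,
) -> pd.DataFrame:
    """Align two studies' Z-scores onto study 1's effect alleles.

    Variants are intersected on ``snp_id``.  Where study 2 reports the swapped
    allele pair (directly or on the opposite strand), ``z2`` is negated.
    Palindromic (A/T, C/G) variants have no strand-unambiguous orientation and
    are dropped by default; with ``freq_rescue`` they are kept when both
    studies' effect-allele frequencies are decisively away from 0.5
    (``|eaf-0.5| > freq_margin``), using frequency concordance to fix the sign.
    Allele pairs not reconcilable by swap and/or strand complement are dropped
    with a logged count.

    Returns a DataFrame in :data:`HARMONIZED_COLUMNS` order, preserving
    study 1's (chrom, pos) ordering.
    """
    merged = t1.df.merge(
        t2.df, on="snp_id", how="inner", suffixes=("", "_2"), sort=False
    )
    if merged.empty:
        raise ValueError("no shared variants between the two tables")

    a1 = merged["a1"].to_numpy()
    a2 = merged["a2"].to_numpy()
    b1 = merged["a1_2"].to_numpy()
    b2 = merged["a2_2"].to_numpy()
    fb1 = merged["a1_2"].map(COMPLEMENT).to_numpy()
    fb2 = merged["a2_2"].map(COMPLEMENT).to_numpy()

    same = ((b1 == a1) & (b2 == a2)) | ((fb1 == a1) & (fb2 == a2))
    swap = ((b1 == a2) & (b2 == a1)) | ((fb1 == a2) & (fb2 == a1))
    sign = np.where(same, 1, np.where(swap, -1, 0))
    palindromic = merged["a2"].map(COMPLEMENT).to_numpy() == a1

    n_mismatch = int((sign == 0).sum())
    keep = sign != 0
    n_palin = 0
    if palindromic.any() and (drop_palindromic or freq_rescue):
        if freq_rescue:
            eaf1 = merged["eaf"].to_numpy(float)
            eaf2 = merged["eaf_2"].to_numpy(float)
            eaf2 = np.where(sign == -1, 1.0 - eaf2, eaf2)  # refer to a1
            decisive = (
                np.isfinite(eaf1) & np.isfinite(eaf2)
                & (np.abs(eaf1 - 0.5) > freq_margin)
                & (np.abs(eaf2 - 0.5) > freq_margin)
            )
            # frequency-discordant orientation: flip the allele-based sign
            sign = np.where(
                palindromic & decisive & ((eaf1 - 0.5) * (eaf2 - 0.5) < 0),
                -sign, sign,
            )
            ambiguous = palindromic & ~decisive
        else:
            ambiguous = palindromic
        n_palin = int((keep & ambiguous).sum())
        keep &= ~ambiguous

    if n_mismatch:
        log.warning("harmonize: dropped %d variants with irreconcilable alleles",
                    n_mismatch)
    if n_palin:
        log.warning("harmonize: dropped %d ambiguous palindromic variants", n_palin)
    if not keep.any():
        raise ValueError("no harmonizable variants remain")

    out = pd.DataFrame(
        {
            "snp_id": merged["snp_id"],
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "ea": merged["a1"],
            "oa": merged["a2"],
            "z1": merged["z"],
            "z2": sign * merged["z_2"].to_numpy(float),
            "n1": merged["n"],
            "n2": merged["n_2"],
            "p1": merged["p"],
            "p2": merged["p_2"],
        }
    )
    return out[keep].reset_index(drop=True)


def write_harmonized(pairs: pd.DataFrame, path) -> None:
    pairs[list(HARMONIZED_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(HARMONIZED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"harmonized table missing columns: {sorted(missing)}")
    return df[list(HARMONIZED_COLUMNS)]
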