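"""GWAS summary-statistic I/O, QC/harmonization, imputation, meta-analysis.

Harmonization aligns a raw summary-statistic table to a reference variant
table (the panel all analyses are standardized against): strand-ambiguous
variants are dropped, alleles are flipped/swapped into the reference
orientation, and per-variant filters on imputation quality, allele
frequency, frequency discrepancy with the reference, p-value validity,
duplicate identifiers, and sample-size range are applied. Each removal is
attributed to exactly one rule so the QC report counts are additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "QCReport",
    "read_sumstats",
    "write_sumstats",
    "harmonize_sumstats",
    "impute_beta_se",
    "meta_analyze",
    "to_standardized_units",
    "from_standardized_units",
]

REQUIRED_COLUMNS = ["SNP", "A1", "A2"]

#: accepted header synonyms, mapped to canonical names on read
COLUMN_SYNONYMS: dict[str, list[str]] = {
    "SNP": ["SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"],
    "CHR": ["CHR", "CHROM", "CHROMOSOME", "#CHROM"],
    "BP": ["BP", "POS", "POSITION", "BASE_PAIR_LOCATION"],
    "A1": ["A1", "EA", "EFFECT_ALLELE", "ALLELE1"],
    "A2": ["A2", "OA", "NEA", "OTHER_ALLELE", "ALLELE2", "ALLELE0"],
    "FREQ": ["FREQ", "EAF", "AF", "A1FREQ", "EFFECT_ALLELE_FREQUENCY"],
    "BETA": ["BETA", "B", "EFFECT", "EFFECT_SIZE"],
    "OR": ["OR", "ODDS_RATIO"],
    "SE": ["SE", "STDERR", "STANDARD_ERROR"],
    "P": ["P", "PVAL", "P_VALUE", "PVALUE", "P_BOLT_LMM"],
    "N": ["N", "NMISS", "SAMPLE_SIZE", "NEFF"],
    "INFO": ["INFO", "IMPINFO", "IMPUTATION_QUALITY"],
    "DIR": ["DIR", "DIRECTION"],
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")

QC_RULES = [
    "invalid_allele",
    "ambiguous",
    "duplicate_id",
    "unmatched",
    "info",
    "maf",
    "maf_discrepancy",
    "invalid_p",
    "n_range",
]


@dataclass
class QCReport:
    """Per-rule removal counts plus alignment statistics.

    Invariant: ``sum(removed.values()) + retained == n_input``.
    """

    n_input: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in QC_RULES})
    flipped_strand: int = 0
    swapped_allele: int = 0
    retained: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "flipped_strand": self.flipped_strand,
            "swapped_allele": self.swapped_allele,
            "retained": self.retained,
            "notes": list(self.notes),
        }


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    upper = {c.upper(): c for c in df.columns}
    for canon, synonyms in COLUMN_SYNONYMS.items():
        if canon in df.columns:
            continue
        for syn in synonyms:
            if syn in upper:
                rename[upper[syn]] = canon
                break
    return df.rename(columns=rename)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read delimited (tab/comma, optionally gzipped) summary statistics."""
    df = pd.read_csv(path, sep=None, engine="python", compression="infer")
    df = _canonicalize_columns(df)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing mandatory columns: {missing}")
    for col in ("A1", "A2"):
        df[col] = df[col].astype(str).str.upper()
    df["SNP"] = df["SNP"].astype(str)
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N", "INFO"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def harmonize_sumstats(
    raw: pd.DataFrame,
    reference: pd.DataFrame,
    ref_freq_col: str = "FREQ",
    info_threshold: float = 0.9,
    maf_threshold: float = 0.01,
    freq_discrepancy: float = 0.2,
    n_mad: float = 3.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Align summary statistics to a reference and apply QC filters.

    Rules, applied sequentially (each record is counted under the first
    rule it fails): invalid alleles; strand-ambiguous (A/T, C/G);
    duplicated SNP ids (all copies removed); not matchable to the reference
    (by id, after considering allele swap and strand flip); INFO below
    ``info_threshold`` (skipped when the column is absent); MAF below
    ``maf_threshold`` in GWAS or reference; |FREQ - refFREQ| beyond
    ``freq_discrepancy`` after alignment; P outside (0, 1]; N outside
    median +/- ``n_mad`` x MAD (only when N varies).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"summary statistics missing mandatory columns: {missing}")
    for col in ("SNP", ref_freq_col, "A1", "A2"):
        if col not in reference.columns:
            raise ValueError(f"reference table missing column: {col}")

    report = QCReport(n_input=len(raw))
    df = raw.drop(columns=["REF_FREQ"], errors="ignore").copy()
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    df["SNP"] = df["SNP"].astype(str)

    valid = df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES) & (df["A1"] != df["A2"])
    report.removed["invalid_allele"] = int((~valid).sum())
    df = df[valid]

    ambiguous = df["A2"] == df["A1"].map(_COMPLEMENT)
    report.removed["ambiguous"] = int(ambiguous.sum())
    df = df[~ambiguous]

    dup = df["SNP"].duplicated(keep=False)
    report.removed["duplicate_id"] = int(dup.sum())
    df = df[~dup]

    ref = reference[["SNP", "A1", "A2", ref_freq_col]].rename(
        columns={"A1": "_refA1", "A2": "_refA2", ref_freq_col: "_refFREQ"}
    )
    ref = ref.drop_duplicates("SNP")
    df = df.merge(ref, on="SNP", how="left")

    c_a1 = df["A1"].map(_COMPLEMENT)
    c_a2 = df["A2"].map(_COMPLEMENT)
    same = (df["A1"] == df["_refA1"]) & (df["A2"] == df["_refA2"])
    swap = (df["A1"] == df["_refA2"]) & (df["A2"] == df["_refA1"])
    flip = (c_a1 == df["_refA1"]) & (c_a2 == df["_refA2"]) & ~same & ~swap
    flipswap = (c_a1 == df["_refA2"]) & (c_a2 == df["_refA1"]) & ~same & ~swap
    matched = (same | swap | flip | flipswap) & df["_refA1"].notna()
    report.removed["unmatched"] = int((~matched).sum())
    df = df[matched].copy()
    same, swap, flip, flipswap = (m[matched] for m in (same, swap, flip, flipswap))

    do_swap = swap | flipswap
    if "BETA" in df.columns:
        df.loc[do_swap, "BETA"] = -df.loc[do_swap, "BETA"]
    if "FREQ" in df.columns:
        df.loc[do_swap, "FREQ"] = 1 - df.loc[do_swap, "FREQ"]
    df["A1"] = df["_refA1"]
    df["A2"] = df["_refA2"]
    report.swapped_allele = int(do_swap.sum())
    report.flipped_strand = int((flip | flipswap).sum())

    if "INFO" in df.columns and df["INFO"].notna().any():
        bad = df["INFO"].fillna(1.0) < info_threshold
        report.removed["info"] = int(bad.sum())
        df = df[~bad]
    else:
        report.notes.append("INFO column absent; imputation-quality filter skipped")

    if "FREQ" in df.columns:
        maf_gwas = np.minimum(df["FREQ"], 1 - df["FREQ"])
        maf_ref = np.minimum(df["_refFREQ"], 1 - df["_refFREQ"])
        bad = (maf_gwas < maf_threshold) | (maf_ref < maf_threshold)
        report.removed["maf"] = int(bad.sum())
        df = df[~bad]
        bad = (df["FREQ"] - df["_refFREQ"]).abs() > freq_discrepancy
        report.removed["maf_discrepancy"] = int(bad.sum())
        df = df[~bad]
    else:
        maf_ref = np.minimum(df["_refFREQ"], 1 - df["_refFREQ"])
        bad = maf_ref < maf_threshold
        report.removed["maf"] = int(bad.sum())
        df = df[~bad]
        report.notes.append("FREQ column absent; GWAS-side MAF filter skipped")

    if "P" in df.columns:
        p = pd.to_numeric(df["P"], errors="coerce")
        bad = ~((p > 0) & (p <= 1))
        report.removed["invalid_p"] = int(bad.sum())
        df = df[~bad]

    if "N" in df.columns and df["N"].nunique() > 1:
        n = df["N"].astype(float)
        med = n.median()
        mad = (n - med).abs().median()
        if mad > 0:
            bad = (n - med).abs() > n_mad * mad
            report.removed["n_range"] = int(bad.sum())
            df = df[~bad]

    df = df.drop(columns=["_refA1", "_refA2"]).rename(columns={"_refFREQ": "REF_FREQ"})
    report.retained = len(df)
    if report.retained == 0:
        raise ValueError("no variants retained after harmonization")
    return df.reset_index(drop=True), report


def impute_beta_se(df: pd.DataFrame) -> pd.DataFrame:
    """Fill missing BETA / SE / P from the available association fields.

    BETA = ln(OR) when only an odds ratio is given; SE = |BETA|/z with
    z the two-sided normal quantile of P; BETA = sign * z * SE when only
    (P, SE, direction) are available; P recomputed from BETA/SE when
    absent. Imputed fields are listed in an ``IMPUTED`` column; records
    whose SE is undefined (P = 1 with BETA != 0 unavailable workarounds)
    are flagged ``se_undefined``.
    """
    df = df.copy()
    for col in ("BETA", "SE", "P"):
        if col not in df.columns:
            df[col] = np.nan
    imputed = np.array([""] * len(df), dtype=object)

    if "OR" in df.columns:
        use = df["BETA"].isna() & df["OR"].notna()
        df.loc[use, "BETA"] = np.log(df.loc[use, "OR"].astype(float))
        imputed[use.to_numpy()] = _append(imputed[use.to_numpy()], "BETA")

    have_bp = df["SE"].isna() & df["BETA"].notna() & df["P"].notna()
    z = stats.norm.isf(df.loc[have_bp, "P"].astype(float) / 2)
    good = z > 0
    idx = have_bp[have_bp].index
    df.loc[idx[good], "SE"] = (df.loc[idx[good], "BETA"].abs() / z[good]).astype(float)
    imputed[df.index.get_indexer(idx[good])] = _append(imputed[df.index.get_indexer(idx[good])], "SE")
    undefined = df.index.get_indexer(idx[~good])

    have_ps = df["BETA"].isna() & df["SE"].notna() & df["P"].notna()
    if have_ps.any():
        if "DIR" not in df.columns:
            raise ValueError("cannot impute BETA from (P, SE) without a direction column")
        sign = np.where(df.loc[have_ps, "DIR"].astype(str).isin(["-", "-1"]), -1.0, 1.0)
        z = stats.norm.isf(df.loc[have_ps, "P"].astype(float) / 2)
        df.loc[have_ps, "BETA"] = sign * z * df.loc[have_ps, "SE"].astype(float)
        imputed[have_ps.to_numpy()] = _append(imputed[have_ps.to_numpy()], "BETA")

    have_bs = df["P"].isna() & df["BETA"].notna() & df["SE"].notna()
    if have_bs.any():
        zz = (df.loc[have_bs, "BETA"] / df.loc[have_bs, "SE"]).abs()
        df.loc[have_bs, "P"] = 2 * stats.norm.sf(zz)
        imputed[have_bs.to_numpy()] = _append(imputed[have_bs.to_numpy()], "P")

    insufficient = df["BETA"].isna() | (df["SE"].isna() & df["P"].isna())
    if insufficient.any():
        raise ValueError(
            f"{int(insufficient.sum())} records lack enough fields to recover BETA/SE/P"
        )
    df["IMPUTED"] = imputed
    if len(undefined):
        df.loc[df.index[undefined], "IMPUTED"] = "se_undefined"
    return df


def _append(existing: np.ndarray, tag: str) -> np.ndarray:
    return np.array([e + ("," if e else "") + tag for e in existing], dtype=object)


def meta_analyze(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance fixed-effect meta-analysis of two harmonized inputs.

    Shared variants: BETA = sum(beta_i/SE_i^2)/sum(1/SE_i^2),
    SE = sqrt(1/sum(1/SE_i^2)), N summed, P recomputed from the z score.
    Variants present in only one input are carried through and flagged in
    the ``META`` column.
    """
    if len(a) == 0:
        out = b.copy()
        out["META"] = "b_only"
        return out
    if len(b) == 0:
        out = a.copy()
        out["META"] = "a_only"
        return out
    keep = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]
    a = a[[c for c in keep if c in a.columns]].copy()
    b = b[[c for c in keep if c in b.columns]].copy()
    merged = a.merge(b, on="SNP", how="outer", suffixes=("_a", "_b"), indicator=True)
    both = merged["_merge"] == "both"
    if both.any():
        mismatch = merged.loc[both, "A1_a"] != merged.loc[both, "A1_b"]
        if mismatch.any():
            bad = merged.loc[both].loc[mismatch.to_numpy(), "SNP"].tolist()[:5]
            raise ValueError(f"allele mismatch between harmonized inputs, e.g. {bad}")
    rows = []
    for _, r in merged.iterrows():
        if r["_merge"] == "both":
            w1, w2 = 1 / r["SE_a"] ** 2, 1 / r["SE_b"] ** 2
            beta = (r["BETA_a"] * w1 + r["BETA_b"] * w2) / (w1 + w2)
            se = np.sqrt(1 / (w1 + w2))
            freq_cols = [r.get("FREQ_a"), r.get("FREQ_b")]
            freq = np.nanmean([f for f in freq_cols if f is not None]) if any(
                f is not None for f in freq_cols
            ) else np.nan
            rows.append(
                {
                    "SNP": r["SNP"],
                    "CHR": r.get("CHR_a"),
                    "BP": r.get("BP_a"),
                    "A1": r["A1_a"],
                    "A2": r["A2_a"],
                    "FREQ": freq,
                    "BETA": beta,
                    "SE": se,
                    "P": 2 * stats.norm.sf(abs(beta / se)),
                    "N": (r.get("N_a") or 0) + (r.get("N_b") or 0),
                    "META": "meta",
                }
            )
        else:
            side = "a" if r["_merge"] == "left_only" else "b"
            rows.append(
                {
                    "SNP": r["SNP"],
                    "CHR": r.get(f"CHR_{side}"),
                    "BP": r.get(f"BP_{side}"),
                    "A1": r[f"A1_{side}"],
                    "A2": r[f"A2_{side}"],
                    "FREQ": r.get(f"FREQ_{side}"),
                    "BETA": r[f"BETA_{side}"],
                    "SE": r[f"SE_{side}"],
                    "P": r.get(f"P_{side}"),
                    "N": r.get(f"N_{side}"),
                    "META": f"{side}_only",
                }
            )
    return pd.DataFrame(rows)


def to_standardized_units(df: pd.DataFrame) -> pd.DataFrame:
    """Convert per-allele BETA/SE to the standardized-genotype scale.

    Multiplies both by sqrt(2*FREQ*(1-FREQ)); the z score is unchanged.
    """
    if "FREQ" not in df.columns:
        raise ValueError("FREQ column required for unit conversion")
    f = df["FREQ"].astype(float)
    if ((f <= 0) | (f >= 1)).any():
        raise ValueError("FREQ must be strictly inside (0, 1) for unit conversion")
    scale = np.sqrt(2 * f * (1 - f))
    out = df.copy()
    out["BETA"] = df["BETA"] * scale
    if "SE" in df.columns:
        out["SE"] = df["SE"] * scale
    out.attrs["units"] = "standardized"
    return out


def from_standardized_units(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_standardized_units` (identity round trip)."""
    f = df["FREQ"].astype(float)
    scale = np.sqrt(2 * f * (1 - f))
    out = df.copy()
    out["BETA"] = df["BETA"] / scale
    if "SE" in df.columns:
        out["SE"] = df["SE"] / scale
    out.attrs["units"] = "per-allele"
    return out
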