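"""Polygenic score derivation and application.

Two weight-derivation methods are provided:

* :func:`pt_clump` — exact p-value thresholding and clumping: greedy
  selection of index variants by ascending p value, removing correlated
  neighbours (r^2 above threshold within a window), then one weight column
  per p-value threshold.
* :func:`shrink_auto` — an infinitesimal ridge shrinkage that needs no
  individual-level tuning data: per LD block,
  ``w = (R + (M/(N*h2)) I)^-1 beta_std``, converted back to per-allele
  units. This is the summary-statistic-only ("auto") weight generator used
  by the LEOPARD-style combination machinery; SNP heritability can come
  from :func:`estimate_h2`, a minimal LD-score-regression slope estimator.

:func:`apply_scores` follows PLINK ``--score`` semantics (sum of allele
counts times weights, mean imputation of missing genotypes, allele-flip
resolution against the panel's A1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .reference import LDBlockSet, ld_scores
from .sumstats import to_standardized_units

__all__ = [
    "ClumpParams",
    "pt_clump",
    "shrink_auto",
    "estimate_h2",
    "apply_scores",
    "standardize_scores",
    "read_score_file",
    "write_score_file",
]

DEFAULT_PT_GRID = [1e-8, 1e-6, 1e-4, 1e-2, 0.1, 0.5, 1.0]


@dataclass
class ClumpParams:
    """Clumping hyperparameters: r^2 threshold, window (variant count),
    and the ascending p-value threshold grid."""

    r2: float = 0.1
    window: int = 250
    p_thresholds: tuple[float, ...] = tuple(DEFAULT_PT_GRID)

    def __post_init__(self) -> None:
        if not 0 < self.r2 <= 1:
            raise ValueError("r2 threshold must be in (0, 1]")
        if self.window < 1:
            raise ValueError("window must be positive")
        self.p_thresholds = tuple(sorted(self.p_thresholds))
        for p in self.p_thresholds:
            if not 0 < p <= 1:
                raise ValueError("p thresholds must be in (0, 1]")


def _pt_label(p: float) -> str:
    return f"P_{p:g}"


def pt_clump(
    sumstats: pd.DataFrame,
    ld: LDBlockSet,
    params: ClumpParams | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping followed by p-value thresholding.

    Variants are visited by ascending P (ties broken by CHR, BP); each
    retained index variant removes not-yet-retained variants within
    ``params.window`` positions that have r^2 > ``params.r2`` with it.
    One weight column per threshold contains BETA for retained variants
    with P <= pT, zero otherwise. Variants absent from the LD set are
    treated as unlinked and flagged.
    """
    if len(sumstats) == 0:
        raise ValueError("empty summary statistics")
    params = params or ClumpParams()
    df = sumstats.dropna(subset=["BETA", "P"]).copy()
    df = df.sort_values(["CHR", "BP"]).reset_index(drop=True)
    m = len(df)
    block_idx = ld.block_of()
    snps = df["SNP"].tolist()
    in_block = np.array([block_idx.get(s, -1) for s in snps])
    unlinked = [s for s, b in zip(snps, in_block) if b < 0]
    if unlinked:
        warnings.warn(f"{len(unlinked)} variants absent from LD set treated as unlinked", stacklevel=2)
    pos_in_block = {}
    for b, block in enumerate(ld.blocks):
        for j, s in enumerate(block.snps):
            pos_in_block[s] = j

    order = np.lexsort((df["BP"].to_numpy(), df["CHR"].to_numpy(), df["P"].to_numpy()))
    removed = np.zeros(m, dtype=bool)
    retained = np.zeros(m, dtype=bool)
    for i in order:
        if removed[i]:
            continue
        retained[i] = True
        b = in_block[i]
        if b < 0:
            continue
        lo, hi = max(0, i - params.window), min(m, i + params.window + 1)
        block = ld.blocks[b]
        ji = pos_in_block[snps[i]]
        for j in range(lo, hi):
            if j == i or removed[j] or retained[j]:
                continue
            if in_block[j] != b:
                continue
            r = block.R[ji, pos_in_block[snps[j]]]
            if r * r > params.r2:
                removed[j] = True

    out = df[["SNP", "A1"]].copy()
    beta = df["BETA"].to_numpy()
    pvals = df["P"].to_numpy()
    for pt in params.p_thresholds:
        out[_pt_label(pt)] = np.where(retained & (pvals <= pt), beta, 0.0)
    out.attrs["method"] = "ptclump"
    out.attrs["unlinked"] = unlinked
    return out


def shrink_auto(
    sumstats: pd.DataFrame,
    ld: LDBlockSet,
    h2: float,
    n: float | None = None,
    m_total: int | None = None,
    column: str = "AUTO",
) -> pd.DataFrame:
    """Infinitesimal ridge weights from marginal summary statistics.

    Per LD block, ``w_std = (R + lambda I)^-1 beta_std`` with
    ``lambda = M / (N * h2)``; weights are returned in per-allele units.
    Requires FREQ (for unit conversion) and N (unless ``n`` is given).
    Variants absent from the LD set are treated as unlinked (R = 1).
    """
    if h2 <= 0:
        raise ValueError("h2 must be positive; estimate it with estimate_h2 or set a floor")
    if len(sumstats) == 0:
        raise ValueError("empty summary statistics")
    df = sumstats.dropna(subset=["BETA"]).reset_index(drop=True)
    std = to_standardized_units(df)
    n_eff = float(n if n is not None else df["N"].median())
    m = int(m_total if m_total is not None else len(df))
    lam = m / (n_eff * h2)
    beta_std = std["BETA"].to_numpy()
    snp_pos = {s: i for i, s in enumerate(df["SNP"])}
    w_std = np.zeros(len(df))
    seen = np.zeros(len(df), dtype=bool)
    for block in ld:
        idx = [snp_pos[s] for s in block.snps if s in snp_pos]
        if not idx:
            continue
        sub = [j for j, s in enumerate(block.snps) if s in snp_pos]
        r = block.R[np.ix_(sub, sub)]
        rhs = beta_std[idx]
        w_std[idx] = np.linalg.solve(r + lam * np.eye(len(idx)), rhs)
        seen[idx] = True
    w_std[~seen] = beta_std[~seen] / (1 + lam)
    scale = np.sqrt(2 * df["FREQ"].to_numpy() * (1 - df["FREQ"].to_numpy()))
    out = df[["SNP", "A1"]].copy()
    out[column] = w_std / scale
    out.attrs["method"] = "shrink_auto"
    out.attrs["lambda"] = lam
    out.attrs["tuning"] = "SumStatTune"
    return out


def estimate_h2(
    sumstats: pd.DataFrame,
    ld: LDBlockSet | pd.Series,
    clamp: tuple[float, float] = (0.001, 1.0),
    constrain_intercept: bool = True,
) -> dict:
    """Minimal LD-score-regression heritability estimate.

    Regresses per-variant chi-square on LD scores; the slope times M/N is
    the SNP heritability. By default the regression intercept is
    constrained to 1 (no confounding), which is far more precise at block
    counts typical of desk-scale panels; the free-intercept fit is always
    reported as a confounding diagnostic, and ``constrain_intercept=False``
    uses it for the estimate instead. The estimate is clamped to ``clamp``
    and the report says when clamping occurred.
    """
    if len(sumstats) < 200:
        raise ValueError("at least 200 variants required for h2 estimation")
    scores = ld if isinstance(ld, pd.Series) else ld_scores(ld)
    df = sumstats.dropna(subset=["BETA", "SE"])
    ell = df["SNP"].map(scores)
    ok = ell.notna()
    df, ell = df[ok], ell[ok].to_numpy(dtype=float)
    chi2 = (df["BETA"] / df["SE"]).to_numpy() ** 2
    if np.std(ell) == 0:  # rank-deficient free fit: no LD-score spread
        intercept, free_slope = float(np.mean(chi2)), 0.0
    else:
        x = np.column_stack([np.ones(ell.size), ell])
        (intercept, free_slope), *_ = np.linalg.lstsq(x, chi2, rcond=None)
    if constrain_intercept:
        slope = float(np.sum(ell * (chi2 - 1)) / np.sum(ell**2))
    else:
        slope = float(free_slope)
    n_bar = float(df["N"].mean())
    m = len(df)
    h2 = slope * m / n_bar
    clamped = not (clamp[0] <= h2 <= clamp[1])
    if clamped and h2 < clamp[0]:
        warnings.warn(f"h2 estimate {h2:.4f} clamped to floor {clamp[0]}", stacklevel=2)
    return {
        "h2": float(np.clip(h2, *clamp)),
        "h2_raw": float(h2),
        "intercept": float(intercept),
        "clamped": clamped,
        "m": m,
        "n": n_bar,
    }


def apply_scores(panel: GenotypePanel, weights: pd.DataFrame) -> pd.DataFrame:
    """PGS per sample: sum over variants of allele count times weight.

    Weights are matched to panel variants by SNP id; when the weight's
    effect allele is the panel's A2, the variant's count is flipped
    (2 - count). Missing genotypes are imputed to twice the panel allele
    frequency. Returns a samples x scores DataFrame (IID index) with the
    overlap fraction in ``attrs``.
    """
    score_cols = [c for c in weights.columns if c not in ("SNP", "A1", "A2")]
    pv = panel.variants
    merged = weights.merge(
        pv[["SNP", "A1", "A2"]].rename(columns={"A1": "_pA1", "A2": "_pA2"}),
        on="SNP",
        how="inner",
    )
    aligned = merged["A1"] == merged["_pA1"]
    flipped = merged["A1"] == merged["_pA2"]
    usable = merged[aligned | flipped]
    overlap = len(usable) / len(weights) if len(weights) else 0.0
    if len(usable) == 0:
        raise ValueError("no overlap between weight variants and panel")
    if overlap < 0.5:
        warnings.warn(f"only {overlap:.1%} of weight variants overlap the panel", stacklevel=2)

    col_of = {s: j for j, s in enumerate(pv["SNP"])}
    cols = np.array([col_of[s] for s in usable["SNP"]])
    sign = np.where((usable["A1"] == usable["_pA1"]).to_numpy(), 1.0, -1.0)
    x = panel.genotypes[:, cols].astype(float)
    if np.isnan(x).any():
        fill = np.nanmean(x, axis=0)  # mean count = 2 * allele frequency
        inds = np.where(np.isnan(x))
        x[inds] = np.take(fill, inds[1])
    # flipped variants contribute w * (2 - count) = -w*count + 2w
    result = {}
    for c in score_cols:
        w = usable[c].to_numpy(dtype=float) * sign
        const = float(np.sum(usable[c].to_numpy(dtype=float)[sign < 0] * 2))
        result[c] = x @ w + const
    out = pd.DataFrame(result, index=pd.Index(panel.samples["IID"], name="IID"))
    out.attrs["overlap"] = overlap
    out.attrs["scaling"] = "raw"
    return out


def write_score_file(weights: pd.DataFrame, path) -> None:
    """Write weights in the PLINK2 ``--score`` layout (SNP A1 SCORE...)."""
    weights.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_score_file(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str})
    if "SNP" not in df.columns or "A1" not in df.columns:
        raise ValueError("score file must have SNP and A1 columns")
    return df


def standardize_scores(pgs: pd.DataFrame, reference_pgs: pd.DataFrame) -> pd.DataFrame:
    """Scale PGS columns by the reference distribution (mean 0, SD 1).

    Columns with zero reference SD are left unscaled and flagged.
    """
    out = pgs.copy()
    flagged = []
    for c in pgs.columns:
        mu = float(reference_pgs[c].mean())
        sd = float(reference_pgs[c].std(ddof=0))
        if sd == 0:
            flagged.append(c)
            continue
        out[c] = (pgs[c] - mu) / sd
    out.attrs["scaling"] = "reference-standardized"
    out.attrs["zero_sd_columns"] = flagged
    return out
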