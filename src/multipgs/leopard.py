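"""Estimating the linear combination of population-specific PGSs.

The summary-statistic route ("SumStatTune") follows the LEOPARD recipe:

1. each population's GWAS is split into pseudo training/testing summary
   statistics by conditional-normal subsampling (the perturbation added to
   the marginal effects has covariance ``(1/f - 1) D^1/2 R D^1/2`` with
   ``D = SE^2`` and R the block LD of reference part 1, so that the
   training subset behaves like an independent GWAS of f*N samples);
2. one weight set per population is trained on its training subset with
   the summary-statistic "auto" shrinkage (LD from reference part 2);
3. mixing weights are solved from the target population's testing subset:
   ``alpha_raw = V^-1 c`` with ``c_k = w_k' beta_test`` and
   ``V_kl = w_k' R w_l`` from reference part 3, then rescaled so the
   coefficients apply to PGSs standardized to SD 1.

Steps 1-3 are repeated (default 4 times) and the SD-1-scaled coefficients
averaged. The individual-level route ("IndivTune") is ordinary least
squares of the prepared phenotype on the standardized PGSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reference import LDBlockSet
from .scoring import estimate_h2, shrink_auto
from .sumstats import to_standardized_units

__all__ = [
    "LeopardParams",
    "MixWeights",
    "subsample_sumstats",
    "estimate_mix_weights",
    "leopard",
    "tune_mix_weights_individual",
    "combine_scores",
]


@dataclass
class LeopardParams:
    """Train fraction, repeat count and seed for the subsampling procedure."""

    train_fraction: float = 0.75
    repeats: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class MixWeights:
    """Per-population coefficients on SD-1-scaled population PGSs."""

    populations: list[str]
    alpha: np.ndarray
    mode: str  # "SumStatTune" | "IndivTune"
    target: str = ""
    per_repeat: list[np.ndarray] = field(default_factory=list)
    component_sd: np.ndarray | None = None
    seeds: list[int] = field(default_factory=list)
    ill_conditioned: bool = False

    def as_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "alpha": [float(a) for a in self.alpha],
            "mode": self.mode,
            "target": self.target,
            "per_repeat": [[float(a) for a in rep] for rep in self.per_repeat],
            "component_sd": None
            if self.component_sd is None
            else [float(s) for s in self.component_sd],
            "seeds": [int(s) for s in self.seeds],
            "ill_conditioned": self.ill_conditioned,
        }


def subsample_sumstats(
    sumstats: pd.DataFrame,
    ld: LDBlockSet,
    f: float = 0.75,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split one GWAS into pseudo training/testing summary statistics.

    ``beta_train = beta + e`` with ``e ~ N(0, (1/f - 1) D^1/2 R D^1/2)``
    (D = SE^2, R from the supplied LD blocks), so the training subset has
    the sampling variance of an f*N-sample GWAS; ``beta_test`` is defined
    by the exact identity ``f beta_train + (1-f) beta_test = beta``.
    Sample sizes and standard errors are rescaled accordingly and P values
    recomputed.
    """
    if not 0 < f < 1:
        raise ValueError("f must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = sumstats.reset_index(drop=True)
    m = len(df)
    se = df["SE"].to_numpy(dtype=float)
    beta = df["BETA"].to_numpy(dtype=float)
    if np.isnan(se).any() or np.isnan(beta).any():
        raise ValueError("subsampling requires complete BETA and SE")
    e = np.zeros(m)
    snp_pos = {s: i for i, s in enumerate(df["SNP"])}
    c = 1 / f - 1
    seen = np.zeros(m, dtype=bool)
    for bi, block in enumerate(ld):
        idx = [snp_pos[s] for s in block.snps if s in snp_pos]
        if not idx:
            continue
        sub = [j for j, s in enumerate(block.snps) if s in snp_pos]
        r = block.R[np.ix_(sub, sub)]
        d = se[idx]
        sigma = c * (r * np.outer(d, d))
        try:
            chol = np.linalg.cholesky(sigma + 1e-12 * np.diag(d) ** 2)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"block {bi} covariance not positive definite") from err
        e[idx] = chol @ rng.standard_normal(len(idx))
        seen[idx] = True
    e[~seen] = rng.standard_normal((~seen).sum()) * np.sqrt(c) * se[~seen]

    train = df.copy()
    test = df.copy()
    train["BETA"] = beta + e
    test["BETA"] = (beta - f * train["BETA"].to_numpy()) / (1 - f)
    train["SE"] = se / np.sqrt(f)
    test["SE"] = se / np.sqrt(1 - f)
    if "N" in df.columns:
        train["N"] = df["N"] * f
        test["N"] = df["N"] * (1 - f)
    for part in (train, test):
        z = part["BETA"].to_numpy() / part["SE"].to_numpy()
        part["P"] = 2 * stats.norm.sf(np.abs(z))
    return train, test


def _pgs_covariance(
    weights: np.ndarray, snps: list[str], ld: LDBlockSet
) -> np.ndarray:
    """V_kl = w_k' R w_l accumulated block-wise (cross-block r = 0)."""
    k = weights.shape[1]
    snp_pos = {s: i for i, s in enumerate(snps)}
    v = np.zeros((k, k))
    seen = np.zeros(len(snps), dtype=bool)
    for block in ld:
        idx = [snp_pos[s] for s in block.snps if s in snp_pos]
        if not idx:
            continue
        sub = [j for j, s in enumerate(block.snps) if s in snp_pos]
        r = block.R[np.ix_(sub, sub)]
        w = weights[idx]
        v += w.T @ r @ w
        seen[idx] = True
    if (~seen).any():  # unlinked variants contribute w^2 on the diagonal scale
        w = weights[~seen]
        v += w.T @ w
    return v


def estimate_mix_weights(
    weights_by_pop: dict[str, pd.DataFrame],
    test_sumstats: pd.DataFrame,
    target_ld: LDBlockSet,
    condition_limit: float = 1e8,
) -> MixWeights:
    """Solve the per-repeat linear combination from testing sumstats.

    Inputs must be in standardized-genotype units: each ScoreWeights must
    carry exactly one weight column, and ``test_sumstats`` is converted
    internally. ``alpha_raw = V^-1 c``; the returned alpha is
    ``alpha_raw_k * sqrt(V_kk)`` so it applies to SD-1-scaled PGSs.
    """
    pops = list(weights_by_pop)
    std_test = to_standardized_units(test_sumstats.dropna(subset=["BETA"]))
    beta_test = std_test.set_index("SNP")["BETA"]
    freq = test_sumstats.dropna(subset=["BETA"]).set_index("SNP")["FREQ"]

    union: list[str] = []
    seen = set()
    for df in weights_by_pop.values():
        cols = [c for c in df.columns if c not in ("SNP", "A1", "A2")]
        if len(cols) != 1:
            raise ValueError("each population must supply exactly one weight column")
        for s in df["SNP"]:
            if s not in seen:
                seen.add(s)
                union.append(s)
    union = [s for s in union if s in freq.index]
    scale = np.sqrt(2 * freq.loc[union] * (1 - freq.loc[union])).to_numpy()
    w = np.zeros((len(union), len(pops)))
    pos = {s: i for i, s in enumerate(union)}
    for k, pop in enumerate(pops):
        df = weights_by_pop[pop]
        col = [c for c in df.columns if c not in ("SNP", "A1", "A2")][0]
        for s, val in zip(df["SNP"], df[col]):
            if s in pos:
                w[pos[s], k] = val
    w_std = w * scale[:, None]  # per-allele -> standardized units

    c_vec = w_std.T @ beta_test.loc[union].to_numpy()
    v = _pgs_covariance(w_std, union, target_ld)
    diag = np.sqrt(np.clip(np.diag(v), 0, None))
    ill = False
    if np.linalg.cond(v) > condition_limit:
        ill = True
        v = v + 1e-6 * np.trace(v) / len(pops) * np.eye(len(pops))
    alpha_raw = np.linalg.solve(v, c_vec)
    alpha = alpha_raw * diag
    return MixWeights(
        populations=pops,
        alpha=alpha,
        mode="SumStatTune",
        component_sd=diag,
        ill_conditioned=ill,
    )


def leopard(
    sumstats_by_pop: dict[str, pd.DataFrame],
    ld_parts_by_pop: dict[str, tuple[LDBlockSet, LDBlockSet, LDBlockSet]],
    target: str,
    params: LeopardParams | None = None,
    h2_by_pop: dict[str, float] | None = None,
) -> MixWeights:
    """Summary-statistic estimation of the PGS mixing weights.

    ``ld_parts_by_pop[pop]`` holds the three LD block sets computed from
    the disjoint reference split (part 1 -> subsampling, part 2 -> weight
    training, part 3 -> weight estimation). Every population's GWAS is
    subsampled each repeat; weights are trained per population on its
    training subset and mixing weights estimated against the target
    population's testing subset. The final coefficients are the mean of
    the SD-1-scaled per-repeat estimates.
    """
    params = params or LeopardParams()
    pops = list(sumstats_by_pop)
    if len(pops) < 2:
        raise ValueError("at least two harmonized GWASs required")
    if target not in pops:
        raise ValueError(f"target {target!r} not among GWAS populations {pops}")
    for pop, ss in sumstats_by_pop.items():
        if "N" in ss.columns and params.train_fraction * ss["N"].median() < 50:
            import warnings

            warnings.warn(f"training subset for {pop} has fewer than 50 samples", stacklevel=2)

    root = np.random.SeedSequence((params.seed, 0x1E0))
    repeat_seeds = root.spawn(params.repeats)
    per_repeat: list[np.ndarray] = []
    sds: list[np.ndarray] = []
    for rep_seq in repeat_seeds:
        child = rep_seq.spawn(len(pops))
        weights: dict[str, pd.DataFrame] = {}
        test_target: pd.DataFrame | None = None
        for k, pop in enumerate(pops):
            ld1, ld2, _ = ld_parts_by_pop[pop]
            rng = np.random.default_rng(child[k])
            train, test = subsample_sumstats(
                sumstats_by_pop[pop], ld1, f=params.train_fraction, seed=rng
            )
            if h2_by_pop and pop in h2_by_pop:
                h2 = h2_by_pop[pop]
            else:
                h2 = estimate_h2(train, ld2)["h2"]
            weights[pop] = shrink_auto(train, ld2, h2=h2)
            if pop == target:
                test_target = test
        mix = estimate_mix_weights(weights, test_target, ld_parts_by_pop[target][2])
        per_repeat.append(mix.alpha)
        sds.append(mix.component_sd)
    alpha = np.mean(per_repeat, axis=0)
    return MixWeights(
        populations=pops,
        alpha=alpha,
        mode="SumStatTune",
        target=target,
        per_repeat=per_repeat,
        component_sd=np.mean(sds, axis=0),
        seeds=[params.seed],
    )


def tune_mix_weights_individual(
    pgs: pd.DataFrame,
    phenotype: pd.Series | np.ndarray,
    target: str = "",
) -> MixWeights:
    """OLS of the prepared trait on standardized population PGS columns."""
    y = np.asarray(phenotype, dtype=float)
    x = pgs.to_numpy(dtype=float)
    n, k = x.shape
    if n <= k:
        raise ValueError(f"n={n} samples cannot identify {k} coefficients")
    design = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MixWeights(
        populations=list(pgs.columns),
        alpha=coef[1:],
        mode="IndivTune",
        target=target,
    )


def combine_scores(
    weights_by_pop: dict[str, pd.DataFrame],
    mix: MixWeights,
    reference_sd: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Merge per-population weights into one portable combined score file.

    ``w_combined_j = sum_k (alpha_k / SD_k) w_kj`` over the union of
    variants (absent entries contribute zero). ``reference_sd`` holds the
    raw-PGS standard deviations used for SD-1 scaling; defaults to the
    component SDs recorded in ``mix``.
    """
    if reference_sd is None:
        if mix.component_sd is None:
            raise ValueError("reference PGS standard deviations are required")
        reference_sd = dict(zip(mix.populations, mix.component_sd))
    rows: dict[str, dict] = {}
    for pop, a in zip(mix.populations, mix.alpha):
        df = weights_by_pop[pop]
        col = [c for c in df.columns if c not in ("SNP", "A1", "A2")][0]
        sd = reference_sd[pop]
        if sd <= 0:
            raise ValueError(f"non-positive reference SD for {pop}")
        for snp, a1, wval in zip(df["SNP"], df["A1"], df[col]):
            if snp in rows:
                if rows[snp]["A1"] != a1:
                    raise ValueError(f"allele orientation conflict at {snp}")
                rows[snp]["COMBINED"] += a / sd * wval
            else:
                rows[snp] = {"SNP": snp, "A1": a1, "COMBINED": a / sd * wval}
    out = pd.DataFrame(list(rows.values()))
    out.attrs["method"] = "combined"
    out.attrs["components"] = list(mix.populations)
    out.attrs["alpha"] = [float(a) for a in mix.alpha]
    out.attrs["tuning"] = mix.mode
    return out
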