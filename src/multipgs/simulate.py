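"""Two-or-more population genotype / trait / GWAS simulator.

The generator produces everything the downstream toolkit consumes — reference
and target genotype panels, polygenic architectures, phenotypes, and marginal
GWAS summary statistics — with the statistical structure the methods assume:

* allele-frequency divergence between populations follows a Balding-Nichols
  model around shared ancestral frequencies (parameterized by Fst);
* linkage disequilibrium is block-structured: haplotypes are thresholded
  latent Gaussians with AR(1) correlation within each block and independence
  across blocks;
* causal effects are shared across populations and drawn from a multivariate
  normal with cross-population correlation rg, scaled so the genetic variance
  equals the configured SNP heritability per population;
* GWAS output is per-variant marginal least squares on allele counts.

Diploid genotypes are the sum of two independent haplotypes (Hardy-Weinberg).
Because thresholding a latent Gaussian attenuates correlation, the latent
AR(1) parameter is ``sin(pi*rho/2)`` — the inverse of the tetrachoric mapping
at allele frequency 0.5 — so that realized genotype LD between adjacent
variants approximates the configured ``rho`` for common variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

__all__ = [
    "SimConfig",
    "TrueEffects",
    "simulate_reference_panel",
    "simulate_architecture",
    "simulate_phenotypes",
    "run_gwas",
]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass
class SimConfig:
    """Configuration for a multi-population simulation.

    Parameters
    ----------
    n_populations
        Number of populations (>= 1).
    n_variants
        Total number of variants M.
    block_sizes
        Variants per LD block; must sum to ``n_variants``.
    rho
        Per-population AR(1) LD parameter in (-1, 1). A scalar is broadcast.
    fst
        Balding-Nichols divergence in [0, 1). 0 collapses to shared
        ancestral frequencies.
    base_freq_range
        Interval within (0.01, 0.99) for ancestral allele frequencies.
    h2
        SNP heritability per population in [0, 1]. Scalar broadcast.
    pi0
        Proportion of null variants in [0, 1]. ``pi0 = 1`` is only allowed
        when every h2 is 0.
    rg
        Cross-population genetic correlation in [-1, 1].
    n_gwas
        Per-population GWAS sample sizes.
    n_target
        Per-population target sample sizes.
    seed
        Base seed; all outputs are bit-reproducible given (config, seed).
    """

    n_populations: int = 2
    n_variants: int = 1000
    block_sizes: list[int] | None = None
    rho: float | list[float] = 0.5
    fst: float = 0.1
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    h2: float | list[float] = 0.3
    pi0: float = 0.5
    rg: float = 0.7
    n_gwas: list[int] = field(default_factory=lambda: [2000, 2000])
    n_target: list[int] = field(default_factory=lambda: [1000, 1000])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if self.block_sizes is None:
            size = min(100, self.n_variants)
            n_full, rem = divmod(self.n_variants, size)
            self.block_sizes = [size] * n_full + ([rem] if rem else [])
        if sum(self.block_sizes) != self.n_variants:
            raise ValueError(
                f"block_sizes sum to {sum(self.block_sizes)}, expected {self.n_variants}"
            )
        if np.isscalar(self.rho):
            self.rho = [float(self.rho)] * self.n_populations
        if np.isscalar(self.h2):
            self.h2 = [float(self.h2)] * self.n_populations
        for r in self.rho:
            if not -1 < r < 1:
                raise ValueError(f"rho must be in (-1, 1), got {r}")
        for h in self.h2:
            if not 0 <= h <= 1:
                raise ValueError(f"h2 must be in [0, 1], got {h}")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not -1 <= self.rg <= 1:
            raise ValueError(f"rg must be in [-1, 1], got {self.rg}")
        if not 0 <= self.pi0 <= 1:
            raise ValueError("pi0 must be in [0, 1]")
        if self.pi0 == 1 and any(h > 0 for h in self.h2):
            raise ValueError("pi0 = 1 is incompatible with h2 > 0")
        lo, hi = self.base_freq_range
        if not (0.01 <= lo < hi <= 0.99):
            raise ValueError("base_freq_range must lie within (0.01, 0.99)")
        if any(n < 1 for n in self.n_gwas) or any(n < 1 for n in self.n_target):
            raise ValueError("sample sizes must be positive")
        if len(self.n_gwas) != self.n_populations or len(self.n_target) != self.n_populations:
            raise ValueError("n_gwas / n_target must have one entry per population")

    @property
    def population_labels(self) -> list[str]:
        return [f"POP{k + 1}" for k in range(self.n_populations)]


@dataclass
class TrueEffects:
    """Per-population causal effects on the standardized-genotype scale.

    ``beta`` is (M, K); non-causal rows are exactly zero.
    """

    beta: np.ndarray
    causal: np.ndarray
    populations: list[str]

    def column(self, population: str) -> np.ndarray:
        return self.beta[:, self.populations.index(population)]


def _variant_table(config: SimConfig, freqs: dict[str, np.ndarray]) -> pd.DataFrame:
    m = config.n_variants
    idx = np.arange(m)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in idx]
    tab = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in idx],
            "CHR": np.ones(m, dtype=int),
            "BP": (idx + 1) * 1000,
            "A1": [p[0] for p in pairs],
            "A2": [p[1] for p in pairs],
        }
    )
    for pop, f in freqs.items():
        tab[f"FREQ_{pop}"] = f
    return tab


def _population_frequencies(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    # Ancestral frequencies are drawn per LD block with small per-variant
    # jitter: variants in strong LD share genealogy, so their frequencies are
    # similar — without this, frequency mismatch caps the attainable LD far
    # below the configured rho.
    lo, hi = config.base_freq_range
    jitter = min(0.05, (hi - lo) / 4)
    base = rng.uniform(lo, hi, size=len(config.block_sizes))
    p0 = np.clip(
        np.repeat(base, config.block_sizes)
        + rng.uniform(-jitter, jitter, size=config.n_variants),
        lo,
        hi,
    )
    freqs: dict[str, np.ndarray] = {}
    for pop in config.population_labels:
        if config.fst == 0:
            p = p0.copy()
        else:
            a = p0 * (1 - config.fst) / config.fst
            b = (1 - p0) * (1 - config.fst) / config.fst
            p = rng.beta(a, b)
        freqs[pop] = np.clip(p, 1e-3, 1 - 1e-3)
    return freqs


def _haplotypes(
    n: int,
    p: np.ndarray,
    block_sizes: list[int],
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One haplotype per row: thresholded block-AR(1) latent Gaussian."""
    rho_lat = np.sign(rho) * np.sin(np.pi * abs(rho) / 2)
    thresholds = stats.norm.ppf(p)
    out = np.empty((n, p.size), dtype=np.int8)
    start = 0
    for size in block_sizes:
        e = rng.standard_normal((n, size))
        z = np.empty_like(e)
        z[:, 0] = e[:, 0]
        scale = np.sqrt(1 - rho_lat**2)
        for j in range(1, size):
            z[:, j] = rho_lat * z[:, j - 1] + scale * e[:, j]
        out[:, start : start + size] = z < thresholds[start : start + size]
        start += size
    return out


def _genotypes(
    n: int,
    p: np.ndarray,
    block_sizes: list[int],
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h1 = _haplotypes(n, p, block_sizes, rho, rng)
    h2 = _haplotypes(n, p, block_sizes, rho, rng)
    return h1 + h2


def simulate_reference_panel(config: SimConfig, n_per_population: int = 500) -> dict[str, GenotypePanel]:
    """Simulate one reference GenotypePanel per population.

    Panels share the variant table (with per-population FREQ columns);
    the reference defaults to 500 samples per population, roughly the
    per-population scale of public reference panels.
    """
    return simulate_panels(
        config, {pop: n_per_population for pop in config.population_labels}, stream="reference"
    )


def simulate_panels(
    config: SimConfig,
    n_samples: dict[str, int],
    stream: str = "panel",
) -> dict[str, GenotypePanel]:
    """Simulate genotype panels with ``n_samples[pop]`` individuals each.

    ``stream`` namespaces the random draws so reference / target / GWAS
    panels from the same config are independent but individually
    reproducible. Population allele frequencies are always drawn from the
    config seed, so panels from different streams share the same underlying
    populations.
    """
    for pop, n in n_samples.items():
        if n < 1:
            raise ValueError(f"non-positive sample count for {pop}")
    freq_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xF)))
    freqs = _population_frequencies(config, freq_rng)
    variants = _variant_table(config, freqs)
    stream_key = int.from_bytes(stream.encode(), "little") % (2**31)
    panels: dict[str, GenotypePanel] = {}
    for k, pop in enumerate(config.population_labels):
        if pop not in n_samples:
            continue
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, stream_key, k)))
        geno = _genotypes(n_samples[pop], freqs[pop], config.block_sizes, config.rho[k], rng)
        samples = pd.DataFrame(
            {
                "FID": [f"{pop}_{stream}_{i}" for i in range(n_samples[pop])],
                "IID": [f"{pop}_{stream}_{i}" for i in range(n_samples[pop])],
                "population": pop,
            }
        )
        panels[pop] = GenotypePanel(genotypes=geno, variants=variants.copy(), samples=samples)
    return panels


def simulate_architecture(config: SimConfig) -> TrueEffects:
    """Draw shared-causal-set effects with cross-population correlation rg.

    Effects are on the standardized-genotype scale and scaled so that the
    sum of squared effects equals h2 per population (the LD-aware genetic
    variance is recalibrated exactly in :func:`simulate_phenotypes`).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA)))
    m, k = config.n_variants, config.n_populations
    n_causal = int(round((1 - config.pi0) * m))
    causal = np.zeros(m, dtype=bool)
    if n_causal > 0:
        causal[rng.choice(m, size=n_causal, replace=False)] = True
    beta = np.zeros((m, k))
    if n_causal > 0:
        corr = np.full((k, k), config.rg, dtype=float)
        np.fill_diagonal(corr, 1.0)
        # eigen decomposition keeps rg = +/-1 exactly representable
        w, v = np.linalg.eigh(corr)
        root = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
        raw = rng.standard_normal((n_causal, k)) @ root.T
        for j in range(k):
            ss = float(np.sum(raw[:, j] ** 2))
            if config.h2[j] > 0 and ss > 0:
                beta[causal, j] = raw[:, j] * np.sqrt(config.h2[j] / ss)
    return TrueEffects(beta=beta, causal=causal, populations=config.population_labels)


def simulate_phenotypes(
    panel: GenotypePanel,
    effects: TrueEffects | np.ndarray,
    h2: float,
    seed: int = 0,
    population: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Phenotypes = standardized genotypes x effects + Gaussian noise.

    The realized genetic value is rescaled to sample variance exactly
    ``h2`` (so heritability is calibrated regardless of LD between causal
    variants), noise has variance ``1 - h2``, and the final phenotype is
    centered and scaled. Returns ``(phenotype table, genetic values)``.
    """
    if isinstance(effects, TrueEffects):
        pop = population or panel.samples["population"].iloc[0]
        beta = effects.column(pop)
    else:
        beta = np.asarray(effects, dtype=float)
    if beta.shape[0] != panel.n_variants:
        raise KeyError(
            f"effects cover {beta.shape[0]} variants, panel has {panel.n_variants}"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBEE)))
    n = panel.n_samples
    g = panel.standardized() @ beta if (h2 > 0 and np.any(beta != 0)) else np.zeros(n)
    vg = float(np.var(g))
    if h2 > 0 and vg > 0:
        g = g * np.sqrt(h2 / vg)
    else:
        g = np.zeros(n)
    if h2 >= 1:
        y = g.copy()
    else:
        y = g + rng.normal(0.0, np.sqrt(1 - h2), size=n)
    y = (y - y.mean()) / y.std()
    pheno = pd.DataFrame({"FID": panel.samples["FID"], "IID": panel.samples["IID"], "PHENO": y})
    return pheno, g


def run_gwas(panel: GenotypePanel, phenotype: pd.DataFrame) -> pd.DataFrame:
    """Marginal per-variant OLS of the phenotype on allele counts.

    Returns summary statistics with columns SNP CHR BP A1 A2 FREQ BETA SE P
    N INFO. Monomorphic variants are emitted with NA effect and flagged in
    a ``FLAG`` column, never dropped.
    """
    merged = panel.samples[["IID"]].merge(phenotype, on="IID", how="inner")
    if len(merged) != panel.n_samples:
        raise ValueError("phenotype is not aligned to panel samples")
    y = merged["PHENO"].to_numpy(dtype=float)
    n = y.size
    y_c = y - y.mean()
    syy = float(y_c @ y_c)
    m = panel.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    freq = np.empty(m)
    # chunk over variants to keep the float copy of the genotype matrix small
    step = 512
    for s in range(0, m, step):
        x = panel.genotypes[:, s : s + step].astype(np.float64)
        xm = x.mean(axis=0)
        sxx = np.einsum("ij,ij->j", x, x) - n * xm**2
        sxy = x.T @ y_c
        ok = sxx > 0
        b = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        sigma2 = np.clip(syy - b * sxy, 0, None) / max(n - 2, 1)
        beta[s : s + step] = b
        se[s : s + step] = np.where(ok, np.sqrt(sigma2 / np.where(ok, sxx, 1.0)), np.nan)
        freq[s : s + step] = xm / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    out = panel.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    out["FREQ"] = freq
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = pvals
    out["N"] = n
    out["INFO"] = 1.0
    out["FLAG"] = np.where(np.isnan(beta), "monomorphic", "")
    return out
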