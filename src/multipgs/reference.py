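"""Reference-panel operations: allele frequencies, block LD matrices,
the disjoint three-way reference split, and principal-component projection.

LD is summarized as a set of non-overlapping blocks of variants; the
correlation of standardized allele counts is computed within each block and
cross-block correlation is zero by construction. Each block matrix is
ridge-regularized, R <- (1-eps)R + eps*I, because reference panels of
1KG-scale sample size yield near-singular blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "LDBlock",
    "LDBlockSet",
    "PCProjection",
    "allele_frequencies",
    "compute_ld_blocks",
    "ld_scores",
    "split_reference",
    "fit_pc_projection",
]


@dataclass
class LDBlock:
    snps: list[str]
    R: np.ndarray
    population: str = ""
    n: int = 0
    flagged: list[str] = field(default_factory=list)


@dataclass
class LDBlockSet:
    blocks: list[LDBlock]

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def snps(self) -> list[str]:
        return [s for b in self.blocks for s in b.snps]

    def block_of(self) -> dict[str, int]:
        """Map SNP id -> block index."""
        return {s: i for i, b in enumerate(self.blocks) for s in b.snps}


def allele_frequencies(panel: GenotypePanel, population: str | None = None) -> pd.DataFrame:
    """Effect-allele (A1) frequency per variant for one population."""
    if population is not None:
        mask = (panel.samples["population"] == population).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"no samples in population {population!r}")
        if mask.sum() < 2:
            raise ValueError(f"population {population!r} has fewer than 2 samples")
        panel = panel.subset_samples(np.where(mask)[0])
    elif panel.n_samples < 2:
        raise ValueError("panel has fewer than 2 samples")
    return pd.DataFrame({"SNP": panel.variants["SNP"], "FREQ": panel.allele_frequencies()})


def compute_ld_blocks(
    panel: GenotypePanel,
    block_sizes: list[int] | None = None,
    window: int = 100,
    ridge: float = 0.01,
    population: str = "",
) -> LDBlockSet:
    """Pearson correlation of standardized counts within each block.

    ``block_sizes`` overrides the fixed ``window`` (in variant count).
    Zero-variance variants get an identity row/column and are flagged.
    """
    n = panel.n_samples
    if n < 30:
        warnings.warn(f"LD estimated from only {n} samples", stacklevel=2)
    m = panel.n_variants
    if block_sizes is None:
        size = max(1, min(window, m))
        n_full, rem = divmod(m, size)
        block_sizes = [size] * n_full + ([rem] if rem else [])
    if sum(block_sizes) != m:
        raise ValueError("block sizes do not partition the variant set")
    x = panel.standardized()
    snps = panel.variants["SNP"].tolist()
    blocks = []
    start = 0
    for size in block_sizes:
        sub = x[:, start : start + size]
        sd = sub.std(axis=0)
        degenerate = sd == 0
        with np.errstate(invalid="ignore"):
            r = (sub.T @ sub) / n
        # standardized() zeroes degenerate columns; force identity rows
        for j in np.where(degenerate)[0]:
            r[j, :] = 0.0
            r[:, j] = 0.0
        np.fill_diagonal(r, 1.0)
        if ridge > 0:
            r = (1 - ridge) * r + ridge * np.eye(size)
        blocks.append(
            LDBlock(
                snps=snps[start : start + size],
                R=r,
                population=population,
                n=n,
                flagged=[snps[start + j] for j in np.where(degenerate)[0]],
            )
        )
        start += size
    return LDBlockSet(blocks=blocks)


def ld_scores(ld: LDBlockSet) -> pd.Series:
    """Per-variant LD score: sum of r^2 with all block members (incl. self)."""
    vals, idx = [], []
    for block in ld:
        scores = (block.R**2).sum(axis=1)
        vals.extend(scores.tolist())
        idx.extend(block.snps)
    return pd.Series(vals, index=idx, name="LDSCORE")


def split_reference(panel: GenotypePanel, k: int = 3, seed: int = 0) -> list[np.ndarray]:
    """Random equal partition of samples, stratified by population label.

    Returns ``k`` disjoint integer index arrays covering the panel; part
    sizes within each population differ by at most 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > panel.n_samples:
        raise ValueError(f"cannot split {panel.n_samples} samples into {k} parts")
    rng = np.random.default_rng(seed)
    pops = (
        panel.samples["population"]
        if "population" in panel.samples.columns
        else pd.Series(["ALL"] * panel.n_samples)
    )
    parts: list[list[int]] = [[] for _ in range(k)]
    for _, idx in pops.groupby(pops).groups.items():
        order = rng.permutation(np.asarray(idx))
        for i, sample in enumerate(order):
            parts[i % k].append(int(sample))
    return [np.sort(np.array(p, dtype=int)) for p in parts]


@dataclass
class PCProjection:
    """SVD loadings of a reference panel plus projection helpers.

    Loadings are on standardized counts; variants with zero variance in the
    reference are excluded. Component signs are fixed (largest-magnitude
    loading positive) so projections are reproducible.
    """

    snps: list[str]
    mean: np.ndarray  # 2 * reference allele frequency
    sd: np.ndarray
    loadings: np.ndarray  # (M_used, n_components)
    ref_scores: pd.DataFrame

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def project_panel(self, panel: GenotypePanel) -> pd.DataFrame:
        order = panel.variants.set_index("SNP")
        present = [s for s in self.snps if s in order.index]
        if len(present) == 0:
            raise ValueError("no overlapping variants between panel and loadings")
        if len(present) < 50:
            warnings.warn(f"only {len(present)} overlapping variants for projection", stacklevel=2)
        keep = [i for i, s in enumerate(self.snps) if s in set(present)]
        pos = panel.variants["SNP"].tolist()
        col = {s: j for j, s in enumerate(pos)}
        cols = [col[self.snps[i]] for i in keep]
        x = panel.genotypes[:, cols].astype(float)
        x = np.nan_to_num(x, nan=0.0)
        z = (x - self.mean[keep]) / self.sd[keep]
        scores = z @ self.loadings[keep]
        out = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(self.n_components)])
        out.insert(0, "IID", panel.samples["IID"].to_numpy())
        return out

    def project_frequencies(self, freqs: pd.Series | pd.DataFrame) -> np.ndarray:
        """Project a GWAS allele-frequency vector as a 2*FREQ pseudo-individual."""
        if isinstance(freqs, pd.DataFrame):
            freqs = freqs.set_index("SNP")["FREQ"]
        keep = [i for i, s in enumerate(self.snps) if s in freqs.index]
        if len(keep) == 0:
            raise ValueError("no overlapping variants between frequencies and loadings")
        f = freqs.loc[[self.snps[i] for i in keep]].to_numpy(dtype=float)
        z = (2 * f - self.mean[keep]) / self.sd[keep]
        return z @ self.loadings[keep]


def fit_pc_projection(panel: GenotypePanel, n_components: int = 6) -> PCProjection:
    """Principal components of standardized reference counts via SVD."""
    x = panel.genotypes.astype(float)
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    keep = sd > 0
    z = (np.nan_to_num(x[:, keep]) - mu[keep]) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[:n_components].T
    # deterministic sign: largest |loading| positive per component
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    scores = z @ v
    ref_scores = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(v.shape[1])])
    ref_scores.insert(0, "IID", panel.samples["IID"].to_numpy())
    if "population" in panel.samples.columns:
        ref_scores["population"] = panel.samples["population"].to_numpy()
    return PCProjection(
        snps=panel.variants.loc[keep, "SNP"].tolist(),
        mean=mu[keep],
        sd=sd[keep],
        loadings=v,
        ref_scores=ref_scores,
    )
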