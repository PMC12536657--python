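"""In-memory genotype container shared by every module."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel"]


@dataclass
class GenotypePanel:
    """Samples x variants allele-count matrix with metadata.

    ``genotypes`` holds A1 allele counts in {0, 1, 2} (np.nan allowed for
    missing when dtype is float). ``variants`` has at least columns
    SNP CHR BP A1 A2; ``samples`` at least FID IID, optionally
    ``population``.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} genotype rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} genotype columns")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """A1 allele frequency per variant (missing-aware)."""
        return np.nanmean(self.genotypes.astype(float), axis=0) / 2

    def standardized(self) -> np.ndarray:
        """Column-standardized counts; zero-variance columns become 0."""
        x = self.genotypes.astype(np.float64)
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        out = (x - mu) / sd_safe
        out[:, sd == 0] = 0.0
        if np.isnan(x).any():
            out = np.nan_to_num(out)
        return out

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            genotypes=self.genotypes[index],
            variants=self.variants,
            samples=self.samples.iloc[index].reset_index(drop=True),
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            genotypes=self.genotypes[:, mask],
            variants=self.variants.loc[mask].reset_index(drop=True),
            samples=self.samples,
        )
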