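"""Minimal PLINK1 bed/bim/fam reader and writer.

Variant-major .bed layout: three magic bytes (0x6c, 0x1b, 0x01) followed by
one block of ceil(n/4) bytes per variant, two bits per sample:

    00 -> homozygous A1 (count 2)    10 -> heterozygous (count 1)
    11 -> homozygous A2 (count 0)    01 -> missing (NaN)

.bim columns: CHR SNP CM BP A1 A2; .fam: FID IID PID MID SEX PHENO.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# count -> 2-bit code and back
_CODE_FOR_COUNT = {2: 0b00, np.nan: 0b01, 1: 0b10, 0: 0b11}
_COUNT_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno = panel.genotypes.astype(float)
    n, m = geno.shape
    codes = np.full(geno.shape, 0b01, dtype=np.uint8)  # missing by default
    codes[geno == 2] = 0b00
    codes[geno == 1] = 0b10
    codes[geno == 0] = 0b11
    n_pad = (-n) % 4
    if n_pad:
        pad = np.full((n_pad, m), 0b11, dtype=np.uint8)  # padding is hom A2
        codes = np.vstack([codes, pad])
    quads = codes.T.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "CHR": panel.variants["CHR"],
            "SNP": panel.variants["SNP"],
            "CM": 0,
            "BP": panel.variants["BP"],
            "A1": panel.variants["A1"],
            "A2": panel.variants["A2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "FID": panel.samples["FID"],
            "IID": panel.samples["IID"],
            "PID": 0,
            "MID": 0,
            "SEX": 0,
            "PHENO": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["CHR", "SNP", "CM", "BP", "A1", "A2"],
        dtype={"SNP": str, "A1": str, "A2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["FID", "IID", "PID", "MID", "SEX", "PHENO"],
        dtype={"FID": str, "IID": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _MAGIC:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK1 bed file")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != m * bytes_per_variant:
        raise ValueError("bed size inconsistent with bim/fam dimensions")
    blocks = body.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    codes[:, 0::4] = blocks & 0b11
    codes[:, 1::4] = (blocks >> 2) & 0b11
    codes[:, 2::4] = (blocks >> 4) & 0b11
    codes[:, 3::4] = (blocks >> 6) & 0b11
    geno = _COUNT_FOR_CODE[codes[:, :n]].T
    if not np.isnan(geno).any():
        geno = geno.astype(np.int8)
    variants = bim[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    samples = fam[["FID", "IID"]].copy()
    return GenotypePanel(genotypes=geno, variants=variants, samples=samples)
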