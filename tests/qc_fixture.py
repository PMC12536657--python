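"""Hand-built 12-row harmonization fixture: one violation per QC rule.

Expected outcome, derived by hand:

row  SNP   alleles vs reference      fate
1    rs1   exact match               retained
2    rs2   A1/A2 swapped             retained (BETA negated, FREQ complemented)
3    rs3   strand-flipped            retained
4    rs4   A/T                       removed: ambiguous
5    rs5   exact, INFO=0.85          removed: info (<0.9)
6    rs6   exact, FREQ=0.005         removed: maf (<0.01)
7    rs7   exact, FREQ 0.3 vs 0.6    removed: maf_discrepancy (>0.2)
8    rs8   exact, P=0                removed: invalid_p
9,10 rs9   duplicated id (x2)        removed: duplicate_id (both copies)
11   rs10  exact, N=100              removed: n_range
                                     (surviving N = 1000,1005,995,100:
                                      median 1002.5, MAD 5, cut 15)
12   rs11  not in reference          removed: unmatched

Retained: rs1, rs2, rs3. Swapped alignments: 1; strand flips: 1.
"""

import pandas as pd

EXPECTED_RETAINED = ["rs1", "rs2", "rs3"]
EXPECTED_REMOVED = {
    "invalid_allele": 0,
    "ambiguous": 1,
    "duplicate_id": 2,
    "unmatched": 1,
    "info": 1,
    "maf": 1,
    "maf_discrepancy": 1,
    "invalid_p": 1,
    "n_range": 1,
}
EXPECTED_SWAPPED = 1
EXPECTED_FLIPPED = 1


def raw_sumstats() -> pd.DataFrame:
    cols = ["SNP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N", "INFO"]
    rows = [
        ("rs1", "A", "G", 0.50, 0.10, 0.05, 0.0455, 1000, 0.95),
        ("rs2", "T", "C", 0.30, -0.20, 0.08, 0.0124, 1005, 0.99),
        ("rs3", "A", "G", 0.40, 0.05, 0.04, 0.2113, 995, 0.97),
        ("rs4", "A", "T", 0.50, 0.01, 0.05, 0.8415, 1000, 0.95),
        ("rs5", "C", "A", 0.45, 0.02, 0.05, 0.6892, 1000, 0.85),
        ("rs6", "A", "C", 0.005, 0.30, 0.15, 0.0455, 1000, 0.95),
        ("rs7", "G", "T", 0.30, 0.04, 0.05, 0.4237, 1000, 0.95),
        ("rs8", "C", "A", 0.40, 0.06, 0.05, 0.0, 1000, 0.95),
        ("rs9", "A", "C", 0.50, 0.03, 0.05, 0.5485, 1000, 0.95),
        ("rs9", "A", "C", 0.50, 0.03, 0.05, 0.5485, 1000, 0.95),
        ("rs10", "T", "G", 0.60, 0.02, 0.05, 0.6892, 100, 0.95),
        ("rs11", "A", "G", 0.50, 0.07, 0.05, 0.1615, 1000, 0.95),
    ]
    return pd.DataFrame(rows, columns=cols)


def reference_table() -> pd.DataFrame:
    cols = ["SNP", "A1", "A2", "FREQ"]
    rows = [
        ("rs1", "A", "G", 0.50),
        ("rs2", "C", "T", 0.68),  # swapped orientation; ref freq of C = 1-0.30 ~ 0.68
        ("rs3", "T", "C", 0.42),  # strand complement of (A, G)
        ("rs4", "A", "T", 0.50),
        ("rs5", "C", "A", 0.45),
        ("rs6", "A", "C", 0.02),
        ("rs7", "G", "T", 0.60),
        ("rs8", "C", "A", 0.45),
        ("rs9", "A", "C", 0.50),
        ("rs10", "T", "G", 0.62),
    ]
    return pd.DataFrame(rows, columns=cols)
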