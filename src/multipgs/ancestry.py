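"""Ancestry assignment and GWAS ancestry-composition estimation.

Target individuals are assigned to reference populations with a penalized
multinomial logistic model on projected principal components; a hard label
is given only when the maximum class probability strictly exceeds a
threshold (default 0.95). Within-population outliers are detected from
k-means centroid distances. The ancestry composition of a GWAS is
deconvolved from its allele-frequency vector by non-negative least squares
against per-population reference frequencies, renormalized to the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegressionCV

__all__ = [
    "PopulationClassifier",
    "AncestryProportions",
    "fit_population_classifier",
    "assign_population",
    "detect_outliers",
    "estimate_gwas_ancestry",
]


@dataclass
class PopulationClassifier:
    model: LogisticRegressionCV
    classes: list[str]
    pc_columns: list[str]

    def predict_proba(self, scores: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.pc_columns if c not in scores.columns]
        if missing:
            raise ValueError(f"PC columns missing from input: {missing}")
        proba = self.model.predict_proba(scores[self.pc_columns].to_numpy())
        return pd.DataFrame(proba, columns=self.classes, index=scores.index)


@dataclass
class AncestryProportions:
    populations: list[str]
    q: np.ndarray
    ill_conditioned: bool = False

    def as_dict(self) -> dict:
        return {
            "proportions": {p: float(v) for p, v in zip(self.populations, self.q)},
            "ill_conditioned": self.ill_conditioned,
        }


def fit_population_classifier(
    scores: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_pcs: int = 6,
    l1_ratio: float = 0.5,
    seed: int = 0,
) -> PopulationClassifier:
    """Elastic-net multinomial logistic regression on the leading PCs.

    Penalty strength is chosen by internal cross-validation over a small
    grid; deterministic given ``seed``.
    """
    labels = pd.Series(np.asarray(labels))
    if labels.nunique() < 2:
        raise ValueError("at least two populations required to fit a classifier")
    counts = labels.value_counts()
    if (counts < 10).any():
        import warnings

        warnings.warn(f"small population(s): {counts[counts < 10].to_dict()}", stacklevel=2)
    pc_cols = [f"PC{i + 1}" for i in range(n_pcs) if f"PC{i + 1}" in scores.columns]
    x = scores[pc_cols].to_numpy()
    cv = min(5, int(counts.min()))
    model = LogisticRegressionCV(
        Cs=[0.01, 0.1, 1.0, 10.0],
        cv=max(2, cv),
        penalty="elasticnet",
        solver="saga",
        l1_ratios=[l1_ratio],
        max_iter=5000,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(x, labels.to_numpy())
    return PopulationClassifier(model=model, classes=list(model.classes_), pc_columns=pc_cols)


def assign_population(
    classifier: PopulationClassifier,
    scores: pd.DataFrame,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Hard-assign samples only when max class probability > threshold."""
    proba = classifier.predict_proba(scores)
    best = proba.to_numpy().argmax(axis=1)
    maxp = proba.to_numpy().max(axis=1)
    label = np.where(maxp > threshold, np.array(classifier.classes)[best], "unassigned")
    out = pd.DataFrame({"IID": scores.get("IID", pd.Series(scores.index).astype(str))})
    for c in classifier.classes:
        out[f"prob_{c}"] = proba[c].to_numpy()
    out["label"] = label
    return out


def detect_outliers(
    scores: pd.DataFrame,
    n_pcs: int = 10,
    k: int = 5,
    sd_mult: float = 3.0,
    seed: int = 0,
) -> np.ndarray:
    """Flag within-population outliers from k-means centroid distances.

    A sample is an outlier when its Euclidean distance to its assigned
    centroid exceeds mean + ``sd_mult`` * SD of all within-cluster
    distances. Returns a boolean keep mask (True = keep).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pc_cols = [f"PC{i + 1}" for i in range(n_pcs) if f"PC{i + 1}" in scores.columns]
    x = scores[pc_cols].to_numpy(dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"k={k} exceeds sample count {n}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(x)
    dist = np.linalg.norm(x - km.cluster_centers_[assign], axis=1)
    cutoff = dist.mean() + sd_mult * dist.std()
    if not np.isfinite(cutoff):
        return np.ones(n, dtype=bool)
    return dist <= cutoff


def estimate_gwas_ancestry(
    gwas_freq: pd.Series | np.ndarray,
    ref_freqs: pd.DataFrame,
) -> AncestryProportions:
    """Deconvolve GWAS ancestry proportions from allele frequencies.

    Minimizes ||f_gwas - F_ref q||^2 subject to q >= 0 via non-negative
    least squares, then renormalizes q onto the simplex. ``ref_freqs`` has
    one column per reference population (aligned to the same variants as
    ``gwas_freq``; a SNP index/column is used for alignment when present).
    """
    pops = [c for c in ref_freqs.columns if c != "SNP"]
    if isinstance(gwas_freq, pd.Series) and "SNP" in ref_freqs.columns:
        ref = ref_freqs.set_index("SNP")
        common = ref.index.intersection(gwas_freq.index)
        f = gwas_freq.loc[common].to_numpy(dtype=float)
        F = ref.loc[common, pops].to_numpy(dtype=float)
    else:
        f = np.asarray(gwas_freq, dtype=float)
        F = ref_freqs[pops].to_numpy(dtype=float)
    if F.shape[0] != f.size:
        raise ValueError("frequency vector and reference matrix are misaligned")
    if f.size < 100:
        import warnings

        warnings.warn(f"only {f.size} overlapping variants for ancestry estimation", stacklevel=2)
    gram = F.T @ F
    cond = np.linalg.cond(gram)
    q, _ = nnls(F, f)
    total = q.sum()
    if total <= 0:
        raise ValueError("degenerate NNLS solution; cannot normalize proportions")
    return AncestryProportions(
        populations=pops, q=q / total, ill_conditioned=bool(cond > 1e8)
    )
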