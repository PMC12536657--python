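"""Phenotype preparation, cross-validated model selection, and the
statistics used to compare polygenic score models.

Traits are rank-based inverse-normal transformed (Blom offset 3/8),
residualized on covariates, and scaled to mean 0 / SD 1. Model performance
is the Pearson correlation between predicted and observed values; dependent
correlations sharing the observed trait are compared with the
Hotelling-Williams test, and per-trait correlations are pooled with the
BHHR composite-effect method using a between-trait correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .leopard import MixWeights

__all__ = [
    "PreparedPhenotype",
    "EvalResult",
    "prepare_phenotype",
    "cross_validate_top1",
    "correlation_with_se",
    "hotelling_williams",
    "aggregate_bhhr",
    "weight_rmse",
    "relative_improvement",
]


@dataclass
class EvalResult:
    method: str
    r: float
    se: float
    n: int
    fold_r: list[float] = field(default_factory=list)
    selected: list[dict] = field(default_factory=list)
    coefficients: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "r": float(self.r),
            "se": float(self.se),
            "n": int(self.n),
            "fold_r": [float(v) for v in self.fold_r],
            "selected": self.selected,
            "coefficients": self.coefficients,
        }


def prepare_phenotype(
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.Series:
    """Inverse-normal transform, residualize on covariates, center/scale.

    The transform maps average ranks through the Blom quantile
    ``Phi^-1((rank - 3/8)/(n + 1/4))``; covariates (aligned by index) are
    removed by OLS and the residuals standardized to mean 0, SD 1. Samples
    with missing trait or covariates are dropped.
    """
    y = trait.dropna()
    if covariates is not None:
        covariates = covariates.loc[covariates.index.intersection(y.index)].dropna()
        dropped = len(y) - len(covariates)
        y = y.loc[covariates.index]
        if dropped:
            import warnings

            warnings.warn(f"{dropped} samples dropped for missing covariates", stacklevel=2)
    if len(y) < 10:
        raise ValueError("need at least 10 non-missing phenotype values")
    if y.nunique() == 1:
        raise ValueError("constant trait cannot be transformed")
    ranks = stats.rankdata(y.to_numpy(), method="average")
    z = stats.norm.ppf((ranks - 3 / 8) / (len(y) + 1 / 4))
    if covariates is not None and covariates.shape[1] > 0:
        x = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(x, z, rcond=None)
        z = z - x @ coef
    z = (z - z.mean()) / z.std()
    return pd.Series(z, index=y.index, name="PHENO")


def correlation_with_se(predicted: np.ndarray, observed: np.ndarray) -> tuple[float, float]:
    """Pearson R and its large-sample SE, sqrt((1 - R^2)/(n - 2))."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = predicted.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if predicted.std() == 0 or observed.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(predicted, observed)[0, 1])
    se = float(np.sqrt((1 - r**2) / (n - 2)))
    return r, se


def _kfold(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, k)]


def cross_validate_top1(
    candidates: dict[str, pd.DataFrame] | pd.DataFrame,
    phenotype: pd.Series | np.ndarray,
    k: int = 10,
    seed: int = 0,
    method: str = "top1",
) -> EvalResult:
    """k-fold cross-validated "top-1" model builder.

    ``candidates`` maps a source-group name to a DataFrame of candidate
    score columns (a bare DataFrame is treated as a single group). Within
    each fold's training samples the best column per group is picked by
    absolute training correlation, an OLS combination of the selected
    columns is fitted, and the held-out fold is predicted. The pooled R is
    computed on the concatenated held-out predictions. Passing every
    method's scores as separate groups yields the "All" model.
    """
    if isinstance(candidates, pd.DataFrame):
        candidates = {"scores": candidates}
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if n < 5 * k:
        import warnings

        warnings.warn(f"only {n} samples for {k}-fold CV", stacklevel=2)
    mats = {g: df.to_numpy(dtype=float) for g, df in candidates.items()}
    names = {g: list(df.columns) for g, df in candidates.items()}
    folds = _kfold(n, k, seed)
    pred = np.full(n, np.nan)
    fold_r, selected, coefficients = [], [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_tr = y[train_idx]
        chosen_cols = {}
        x_parts = []
        for g, mat in mats.items():
            tr = mat[train_idx]
            sd = tr.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = ((tr - tr.mean(axis=0)).T @ (y_tr - y_tr.mean())) / (
                    len(train_idx) * np.where(sd > 0, sd, np.inf) * y_tr.std()
                )
            best = int(np.nanargmax(np.abs(r)))
            chosen_cols[g] = names[g][best]
            x_parts.append(mat[:, [best]] if mat.ndim == 2 else mat)
        x = np.column_stack([p[:, 0] for p in x_parts])
        design = np.column_stack([np.ones(len(train_idx)), x[train_idx]])
        coef, *_ = np.linalg.lstsq(design, y_tr, rcond=None)
        pred[test_idx] = np.column_stack([np.ones(len(test_idx)), x[test_idx]]) @ coef
        selected.append(chosen_cols)
        coefficients.append(
            {"intercept": float(coef[0]), **{g: float(c) for g, c in zip(mats, coef[1:])}}
        )
        if pred[test_idx].std() > 0 and y[test_idx].std() > 0 and len(test_idx) >= 4:
            fold_r.append(float(np.corrcoef(pred[test_idx], y[test_idx])[0, 1]))
        else:
            fold_r.append(np.nan)
    r, se = correlation_with_se(pred, y)
    return EvalResult(
        method=method, r=r, se=se, n=n, fold_r=fold_r, selected=selected, coefficients=coefficients
    )


def hotelling_williams(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams' t for two dependent correlations sharing one variable.

    Compares ``r13`` and ``r23`` (each model's correlation with the shared
    observed variable 3) given the correlation ``r12`` between the two
    model predictions; df = n - 3, two-sided p.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if abs(r) > 1:
            raise ValueError(f"{name} outside [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    if det < 0:
        raise ValueError(
            f"correlation matrix not positive semi-definite: r12={r12}, r13={r13}, r23={r23}"
        )
    if r13 == r23:
        return 0.0, 1.0
    rbar = (r13 + r23) / 2
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r12) ** 3
    t = (r13 - r23) * np.sqrt((n - 1) * (1 + r12) / denom)
    p = 2 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def aggregate_bhhr(
    r: np.ndarray,
    variance: np.ndarray,
    trait_correlation: np.ndarray,
) -> tuple[float, float]:
    """BHHR composite pooling of correlated per-trait effects.

    Composite effect = mean of per-trait R; composite variance =
    ``(1/m^2) sum_ij rho_ij SE_i SE_j`` with rho from the between-trait
    correlation matrix. Returns (pooled R, pooled SE).
    """
    r = np.asarray(r, dtype=float)
    variance = np.asarray(variance, dtype=float)
    rho = np.atleast_2d(np.asarray(trait_correlation, dtype=float))
    m = r.size
    if rho.shape != (m, m):
        raise ValueError(f"trait correlation matrix {rho.shape} does not match {m} traits")
    if not np.allclose(rho, rho.T):
        raise ValueError("trait correlation matrix must be symmetric")
    se = np.sqrt(variance)
    pooled_var = float(se @ rho @ se) / m**2
    return float(r.mean()), float(np.sqrt(pooled_var))


def weight_rmse(estimated: MixWeights, observed: MixWeights) -> float:
    """RMSE between estimated and observed mixing weights (matched by
    population label)."""
    if set(estimated.populations) != set(observed.populations):
        raise ValueError(
            f"population sets differ: {estimated.populations} vs {observed.populations}"
        )
    obs = dict(zip(observed.populations, observed.alpha))
    diff = np.array([a - obs[p] for p, a in zip(estimated.populations, estimated.alpha)])
    return float(np.sqrt(np.mean(diff**2)))


def relative_improvement(
    r_a: float,
    r_b: float,
    se_a: float | None = None,
    se_b: float | None = None,
    r_ab: float | None = None,
) -> dict:
    """Percent improvement of model a over model b, 100*(r_a - r_b)/r_b.

    When SEs are supplied, the SE of the percentage is propagated by the
    delta method; dependence between the two correlations is absorbed via
    the cross-model prediction correlation ``r_ab`` (cov ~ r_ab SE_a SE_b).
    """
    if r_b == 0:
        raise ValueError("reference correlation r_b must be non-zero")
    pct = 100 * (r_a - r_b) / r_b
    out = {"percent": float(pct)}
    if se_a is not None and se_b is not None:
        cov = (r_ab or 0.0) * se_a * se_b
        da = 100 / r_b
        db = -100 * r_a / r_b**2
        var = da**2 * se_a**2 + db**2 * se_b**2 + 2 * da * db * cov
        out["se"] = float(np.sqrt(max(var, 0.0)))
    return out
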