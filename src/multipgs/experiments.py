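"""Reproducible simulation studies exercising the whole toolkit.

These drivers wire the simulator through scoring, LEOPARD combination and
evaluation at a desk scale chosen to mirror the motivating study design:
two populations with a small target-matched GWAS and a much larger
external GWAS (N = 2,000 vs 20,000 by default, emulating the AFR vs EUR
sample-size imbalance at reduced scale), M = 2,000 variants in 100 LD
blocks, SNP heritability 0.3, cross-population genetic correlation 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .leopard import LeopardParams, leopard, tune_mix_weights_individual
from .evaluation import correlation_with_se, cross_validate_top1, weight_rmse
from .reference import compute_ld_blocks, split_reference
from .scoring import apply_scores, shrink_auto, estimate_h2, standardize_scores
from .simulate import SimConfig, run_gwas, simulate_architecture, simulate_panels, simulate_phenotypes
from .sumstats import harmonize_sumstats

__all__ = ["StudyConditions", "leopard_replicate", "run_leopard_study", "leopard_repeat_variance"]


@dataclass
class StudyConditions:
    """Simulation conditions for the two-population LEOPARD study."""

    m: int = 2000
    n_blocks: int = 100
    n_gwas: tuple[int, int] = (2000, 20000)
    n_target: int = 2000
    n_reference: int = 900
    h2: float = 0.3
    rg: float = 0.7
    fst: float = 0.1
    rho: float = 0.5
    pi0: float = 0.5
    repeats: int = 4
    train_fraction: float = 0.75

    def config(self, seed: int) -> SimConfig:
        block = self.m // self.n_blocks
        return SimConfig(
            n_populations=2,
            n_variants=self.m,
            block_sizes=[block] * self.n_blocks,
            rho=self.rho,
            fst=self.fst,
            h2=self.h2,
            pi0=self.pi0,
            rg=self.rg,
            n_gwas=list(self.n_gwas),
            n_target=[self.n_target, self.n_target],
            seed=seed,
        )


def leopard_replicate(seed: int, conditions: StudyConditions | None = None) -> dict:
    """One end-to-end replicate of the two-population study.

    Simulates GWASs for both populations, reference and target panels for
    the target population (POP1), estimates the mixing weights by LEOPARD
    subsampling (SumStatTune) and by regression on individual-level target
    data (IndivTune), and evaluates single-source and combined PGSs in the
    target sample.
    """
    cond = conditions or StudyConditions()
    cfg = cond.config(seed)
    pops = cfg.population_labels
    target = pops[0]

    effects = simulate_architecture(cfg)
    gwas_panels = simulate_panels(cfg, dict(zip(pops, cond.n_gwas)), stream="gwas")
    sumstats = {}
    for pop in pops:
        pheno, _ = simulate_phenotypes(gwas_panels[pop], effects, cond.h2, seed=cfg.seed + 11, population=pop)
        raw = run_gwas(gwas_panels[pop], pheno)
        reference = raw[["SNP", "A1", "A2"]].copy()
        reference["FREQ"] = gwas_panels[pop].variants[f"FREQ_{pop}"].to_numpy()
        sumstats[pop], _ = harmonize_sumstats(raw, reference)
    del gwas_panels

    ref_panels = simulate_panels(cfg, {p: cond.n_reference for p in pops}, stream="reference")
    ld_parts = {}
    ld_full = {}
    for pop in pops:
        parts = split_reference(ref_panels[pop], k=3, seed=cfg.seed + 17)
        ld_parts[pop] = tuple(
            compute_ld_blocks(
                ref_panels[pop].subset_samples(part), block_sizes=cfg.block_sizes, population=pop
            )
            for part in parts
        )
        ld_full[pop] = compute_ld_blocks(
            ref_panels[pop], block_sizes=cfg.block_sizes, population=pop
        )

    mix_ss = leopard(
        sumstats,
        ld_parts,
        target=target,
        params=LeopardParams(
            train_fraction=cond.train_fraction, repeats=cond.repeats, seed=cfg.seed + 23
        ),
    )

    # full-GWAS weights, target-sample PGS, and individual-level tuning
    weights = {
        pop: shrink_auto(
            sumstats[pop], ld_full[pop], h2=estimate_h2(sumstats[pop], ld_full[pop])["h2"]
        )
        for pop in pops
    }
    target_panel = simulate_panels(cfg, {target: cond.n_target}, stream="target")[target]
    pheno_target, _ = simulate_phenotypes(
        target_panel, effects, cond.h2, seed=cfg.seed + 29, population=target
    )
    y = pheno_target["PHENO"].to_numpy()

    pgs_cols = {}
    for pop in pops:
        raw = apply_scores(target_panel, weights[pop])
        ref_raw = apply_scores(ref_panels[target], weights[pop])
        pgs_cols[pop] = standardize_scores(raw, ref_raw).iloc[:, 0].to_numpy()
    pgs = pd.DataFrame(pgs_cols, index=target_panel.samples["IID"])

    mix_ind = tune_mix_weights_individual(pgs, y, target=target)

    # all models are evaluated through the same 10-fold CV machinery: the
    # SumStatTune combined PGS enters as one fixed column, IndivTune refits
    # the per-population coefficients within each fold's training samples
    r_single = {pop: correlation_with_se(pgs[pop].to_numpy(), y)[0] for pop in pops}
    combined_ss = pgs.to_numpy() @ np.asarray(mix_ss.alpha)
    cv_ss = cross_validate_top1(
        {"combined": pd.DataFrame({"combined": combined_ss}, index=pgs.index)},
        y,
        k=10,
        seed=cfg.seed + 31,
    )
    r_combined_ss = cv_ss.r
    cv = cross_validate_top1({p: pgs[[p]] for p in pops}, y, k=10, seed=cfg.seed + 31)

    return {
        "seed": seed,
        "alpha_sumstat": np.asarray(mix_ss.alpha),
        "alpha_indiv": np.asarray(mix_ind.alpha),
        "alpha_per_repeat": [np.asarray(a) for a in mix_ss.per_repeat],
        "rmse": weight_rmse(mix_ss, mix_ind),
        "r_single": r_single,
        "r_combined_sumstat": r_combined_ss,
        "r_combined_indiv": cv.r,
        "populations": pops,
        "target": target,
    }


def run_leopard_study(
    n_replicates: int = 10,
    seed: int = 0,
    conditions: StudyConditions | None = None,
) -> list[dict]:
    """Independent replicates of :func:`leopard_replicate`."""
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    return [leopard_replicate(int(s), conditions) for s in base]


def leopard_repeat_variance(
    n_values: tuple[int, ...] = (2000, 10000, 50000),
    n_replicates: int = 3,
    seed: int = 0,
    conditions: StudyConditions | None = None,
) -> dict[int, float]:
    """Mean across-repeat variance of the LEOPARD coefficients vs GWAS N.

    The target-matched GWAS sample size is varied; the other population's
    GWAS stays at the study default. Returns mean (over replicates and
    populations) variance of the per-repeat SD-1-scaled coefficients.
    """
    cond = conditions or StudyConditions()
    out: dict[int, float] = {}
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    for n in n_values:
        variances = []
        for s in base:
            c = StudyConditions(**{**cond.__dict__, "n_gwas": (n, cond.n_gwas[1])})
            rep = leopard_replicate(int(s), c)
            per = np.vstack(rep["alpha_per_repeat"])
            variances.append(per.var(axis=0, ddof=1).mean())
        out[n] = float(np.mean(variances))
    return out
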