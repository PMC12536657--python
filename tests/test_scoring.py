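"""Clumping (vs an exhaustive oracle), ridge shrinkage, h2, score application."""

import numpy as np
import pandas as pd
import pytest

from multipgs import (
    ClumpParams,
    SimConfig,
    apply_scores,
    compute_ld_blocks,
    estimate_h2,
    pt_clump,
    run_gwas,
    shrink_auto,
    simulate_architecture,
    simulate_panels,
    simulate_phenotypes,
    standardize_scores,
)
from multipgs.panel import GenotypePanel
from multipgs.reference import LDBlock, LDBlockSet, ld_scores

from conftest import make_sumstats
from test_reference import toy_panel


def greedy_clump_oracle(snps, chrom, bp, pvals, r2_matrix, window, r2_threshold):
    """Independent exhaustive greedy clumping on a dense r^2 matrix.

    Variants ordered by (P, CHR, BP); each retained index removes every
    not-yet-retained variant within `window` positions with r^2 above the
    threshold. Returns the retained SNP set.
    """
    order = sorted(range(len(snps)), key=lambda i: (pvals[i], chrom[i], bp[i]))
    removed, retained = set(), []
    for i in order:
        if i in removed:
            continue
        retained.append(i)
        for j in range(len(snps)):
            if j == i or j in removed or j in [k for k in retained]:
                continue
            if abs(i - j) <= window and r2_matrix[i, j] > r2_threshold:
                removed.add(j)
    return {snps[i] for i in retained}


def sumstats_with_ld(m, seed, block=10, n_ref=400, rho=0.7):
    cfg = SimConfig(
        n_populations=1,
        n_variants=m,
        block_sizes=[block] * (m // block),
        rho=rho,
        fst=0.05,
        h2=[0.3],
        pi0=0.5,
        n_gwas=[100],
        n_target=[100],
        seed=seed,
    )
    panel = simulate_panels(cfg, {"POP1": n_ref}, stream="ref")["POP1"]
    ld = compute_ld_blocks(panel, block_sizes=cfg.block_sizes, ridge=0.0)
    rng = np.random.default_rng(seed)
    ss = make_sumstats(m, seed=seed)
    ss["P"] = rng.uniform(0, 1, m)
    return ss, ld, panel


class TestPtClump:
    def test_no_ld_every_variant_is_index(self):
        ss = make_sumstats(12, seed=1)
        ld = LDBlockSet([LDBlock(snps=ss["SNP"].tolist(), R=np.eye(12))])
        out = pt_clump(ss, ld, ClumpParams(r2=0.1, window=12, p_thresholds=(1.0,)))
        assert (out["P_1"] != 0).sum() == 12

    def test_perfect_ld_keeps_most_significant(self):
        ss = make_sumstats(2, seed=2)
        ss["P"] = [1e-8, 1e-4]
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        ld = LDBlockSet([LDBlock(snps=ss["SNP"].tolist(), R=r)])
        out = pt_clump(ss, ld, ClumpParams(r2=0.5, window=10, p_thresholds=(1.0,)))
        assert out.loc[out["SNP"] == "rs1", "P_1"].iloc[0] != 0
        assert out.loc[out["SNP"] == "rs2", "P_1"].iloc[0] == 0

    def test_matches_exhaustive_oracle_on_random_instances(self):
        for seed in range(30):
            ss, ld, _ = sumstats_with_ld(50, seed=1000 + seed)
            params = ClumpParams(r2=0.1, window=25, p_thresholds=(1.0,))
            out = pt_clump(ss, ld, params)
            got = set(out.loc[out["P_1"] != 0, "SNP"])
            # dense r^2 matrix with zero cross-block entries
            dense = np.zeros((50, 50))
            pos = {s: i for i, s in enumerate(ss.sort_values(["CHR", "BP"])["SNP"])}
            for b in ld:
                idx = [pos[s] for s in b.snps]
                dense[np.ix_(idx, idx)] = b.R**2
            srt = ss.sort_values(["CHR", "BP"]).reset_index(drop=True)
            expected = greedy_clump_oracle(
                srt["SNP"].tolist(),
                srt["CHR"].tolist(),
                srt["BP"].tolist(),
                srt["P"].tolist(),
                dense,
                params.window,
                params.r2,
            )
            assert got == expected, f"seed {seed}"

    def test_threshold_nesting(self):
        ss, ld, _ = sumstats_with_ld(100, seed=3)
        out = pt_clump(ss, ld, ClumpParams(p_thresholds=(0.01, 0.1, 1.0)))
        s1 = set(out.loc[out["P_0.01"] != 0, "SNP"])
        s2 = set(out.loc[out["P_0.1"] != 0, "SNP"])
        s3 = set(out.loc[out["P_1"] != 0, "SNP"])
        assert s1 <= s2 <= s3

    def test_empty_input_raises(self):
        ld = LDBlockSet([])
        with pytest.raises(ValueError):
            pt_clump(make_sumstats(0), ld)


class TestShrinkAuto:
    def test_identity_ld_no_shrinkage_limit(self):
        ss = make_sumstats(10, seed=4, n_samples=10**12)
        ld = LDBlockSet([LDBlock(snps=ss["SNP"].tolist(), R=np.eye(10))])
        out = shrink_auto(ss, ld, h2=0.5)
        np.testing.assert_allclose(out["AUTO"], ss["BETA"], atol=1e-8)

    def test_full_shrinkage_limit(self):
        ss = make_sumstats(10, seed=5, n_samples=5000)
        ld = LDBlockSet([LDBlock(snps=ss["SNP"].tolist(), R=np.eye(10))])
        out = shrink_auto(ss, ld, h2=1e-12)
        np.testing.assert_allclose(out["AUTO"], 0.0, atol=1e-6)

    def test_two_variant_closed_form(self):
        ss = make_sumstats(2, seed=6)
        freq = ss["FREQ"].to_numpy()
        scale = np.sqrt(2 * freq * (1 - freq))
        beta_std = np.array([0.03, 0.01])
        ss["BETA"] = beta_std / scale  # so standardized betas are exactly these
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LDBlockSet([LDBlock(snps=ss["SNP"].tolist(), R=r)])
        lam = 0.5  # M/(N*h2): M=2 => N*h2 = 4
        ss["N"] = 4
        out = shrink_auto(ss, ld, h2=1.0, m_total=2)
        expected_std = np.linalg.solve(r + lam * np.eye(2), beta_std)
        np.testing.assert_allclose(out["AUTO"], expected_std / scale, atol=1e-12)

    def test_nonpositive_h2_raises(self):
        ss = make_sumstats(5, seed=7)
        ld = LDBlockSet([LDBlock(snps=ss["SNP"].tolist(), R=np.eye(5))])
        with pytest.raises(ValueError, match="estimate_h2"):
            shrink_auto(ss, ld, h2=0.0)

    def test_accuracy_nondecreasing_in_n(self):
        # prediction accuracy of the auto weights should grow with GWAS N
        cfg_kwargs = dict(
            n_populations=1,
            n_variants=300,
            block_sizes=[10] * 30,
            rho=0.5,
            fst=0.05,
            h2=[0.4],
            pi0=0.5,
            n_target=[100],
        )
        corrs = []
        for n in (500, 2000, 8000):
            vals = []
            for rep in range(5):
                cfg = SimConfig(n_gwas=[n], seed=900 + rep, **cfg_kwargs)
                eff = simulate_architecture(cfg)
                gpanel = simulate_panels(cfg, {"POP1": n}, stream="gwas")["POP1"]
                pheno, _ = simulate_phenotypes(gpanel, eff, 0.4, seed=rep)
                ss = run_gwas(gpanel, pheno)
                ref = simulate_panels(cfg, {"POP1": 400}, stream="ref")["POP1"]
                ld = compute_ld_blocks(ref, block_sizes=cfg.block_sizes)
                w = shrink_auto(ss, ld, h2=0.4)
                target = simulate_panels(cfg, {"POP1": 800}, stream="tgt")["POP1"]
                tp, _ = simulate_phenotypes(target, eff, 0.4, seed=100 + rep)
                pgs = apply_scores(target, w)
                vals.append(np.corrcoef(pgs.iloc[:, 0], tp["PHENO"])[0, 1])
            corrs.append(np.mean(vals))
        # allow at most one inversion across the N grid
        inversions = sum(1 for a, b in zip(corrs, corrs[1:]) if b < a)
        assert inversions <= 1
        assert corrs[-1] > corrs[0]


class TestEstimateH2:
    def test_null_simulation_near_zero(self):
        cfg = SimConfig(
            n_populations=1,
            n_variants=2000,
            block_sizes=[20] * 100,
            rho=0.3,
            h2=[0.0],
            pi0=1.0,
            n_gwas=[5000],
            n_target=[100],
            seed=31,
        )
        panel = simulate_panels(cfg, {"POP1": 5000}, stream="g")["POP1"]
        rng = np.random.default_rng(0)
        pheno = pd.DataFrame(
            {"FID": panel.samples["FID"], "IID": panel.samples["IID"],
             "PHENO": rng.standard_normal(5000)}
        )
        ss = run_gwas(panel, pheno)
        ld = compute_ld_blocks(panel, block_sizes=cfg.block_sizes)
        est = estimate_h2(ss, ld)
        assert est["h2"] <= 0.02 or est["clamped"]

    def test_constant_ld_scores_clamped_floor(self):
        ss = make_sumstats(300, seed=8)
        ss["BETA"] = ss["SE"]  # chi2 exactly 1 everywhere
        scores = pd.Series(1.0, index=ss["SNP"])
        with pytest.warns(UserWarning):
            est = estimate_h2(ss, scores)
        assert est["h2"] == 0.001 and est["clamped"]

    def test_too_few_variants_raise(self):
        with pytest.raises(ValueError):
            estimate_h2(make_sumstats(50), pd.Series(dtype=float))


class TestApplyScores:
    def weights(self, snps, a1, values, col="W"):
        return pd.DataFrame({"SNP": snps, "A1": a1, col: values})

    def test_hand_example(self):
        panel = toy_panel([[0, 1, 2], [2, 0, 1]])
        w = self.weights(["v0", "v1", "v2"], ["A"] * 3, [0.1, -0.2, 0.3])
        out = apply_scores(panel, w)
        np.testing.assert_allclose(out["W"], [0.4, 0.5], atol=1e-12)

    def test_zero_weights_zero_scores(self):
        panel = toy_panel([[0, 1], [2, 1]])
        out = apply_scores(panel, self.weights(["v0", "v1"], ["A", "A"], [0.0, 0.0]))
        np.testing.assert_allclose(out["W"], 0.0)

    def test_allele_flip_invariance_after_standardization(self, small_panels):
        panel = small_panels["POP1"]
        snps = panel.variants["SNP"].iloc[:20].tolist()
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.1, 20)
        w1 = self.weights(snps, panel.variants["A1"].iloc[:20].tolist(), vals)
        # flip first variant: effect allele becomes A2, weight negated
        a1_flipped = w1["A1"].tolist()
        a1_flipped[0] = panel.variants["A2"].iloc[0]
        vals2 = vals.copy()
        vals2[0] = -vals2[0]
        w2 = self.weights(snps, a1_flipped, vals2)
        s1, s2 = apply_scores(panel, w1), apply_scores(panel, w2)
        # equal up to a constant shift; identical after standardization
        np.testing.assert_allclose(np.diff(s1["W"]), np.diff(s2["W"]), atol=1e-10)
        z1 = standardize_scores(s1, s1)
        z2 = standardize_scores(s2, s2)
        np.testing.assert_allclose(z1["W"], z2["W"], atol=1e-10)

    def test_linearity_in_weights(self):
        panel = toy_panel([[0, 1, 2], [1, 2, 0], [2, 2, 1]])
        rng = np.random.default_rng(10)
        wa, wb = rng.normal(size=3), rng.normal(size=3)
        s_a = apply_scores(panel, self.weights(["v0", "v1", "v2"], ["A"] * 3, wa))
        s_b = apply_scores(panel, self.weights(["v0", "v1", "v2"], ["A"] * 3, wb))
        s_ab = apply_scores(panel, self.weights(["v0", "v1", "v2"], ["A"] * 3, wa + wb))
        np.testing.assert_allclose(s_ab["W"], s_a["W"] + s_b["W"], atol=1e-10)

    def test_missing_genotype_mean_imputed(self):
        panel = toy_panel([[0, 1], [2, 1], [1, 1]])
        panel.genotypes = panel.genotypes.astype(float)
        panel.genotypes[0, 0] = np.nan
        out = apply_scores(panel, self.weights(["v0", "v1"], ["A", "A"], [1.0, 0.0]))
        assert out["W"].iloc[0] == pytest.approx(1.5)  # mean of (2, 1)

    def test_no_overlap_raises(self):
        panel = toy_panel([[0, 1]])
        with pytest.raises(ValueError):
            apply_scores(panel, self.weights(["zz"], ["A"], [1.0]))


class TestStandardizeScores:
    def test_reference_against_itself(self, rng):
        pgs = pd.DataFrame({"S": rng.normal(5, 3, 200)})
        out = standardize_scores(pgs, pgs)
        assert out["S"].mean() == pytest.approx(0.0, abs=1e-8)
        assert out["S"].std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_location_scale_invariance(self, rng):
        ref = pd.DataFrame({"S": rng.normal(0, 1, 500)})
        tgt = pd.DataFrame({"S": rng.normal(0, 1, 100)})
        a = standardize_scores(tgt, ref)
        b = standardize_scores(tgt * 3 + 7, ref * 3 + 7)
        np.testing.assert_allclose(a["S"], b["S"], atol=1e-10)

    def test_zero_sd_column_flagged(self):
        ref = pd.DataFrame({"S": np.ones(10)})
        out = standardize_scores(ref, ref)
        assert out.attrs["zero_sd_columns"] == ["S"]
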