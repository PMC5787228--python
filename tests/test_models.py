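"""Prediction engines: oracle equivalences (Henderson MME, closed-form
ridge), RR-BLUP/G-BLUP identity, GWAS calibration and power, MAS, bivariate
model reductions, and the selection index."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wheatgs._reml import (
    _em_step_complete,
    _em_step_dense,
    _prepare_complete,
    _prepare_dense,
    reml_kernel,
)
from wheatgs.containers import KinshipMatrix, MarkerMap, MarkerMatrix
from wheatgs.models import (
    fit_gblup,
    fit_mas,
    fit_multitrait,
    fit_rrblup,
    fit_selection_index,
    gwas_scan,
    select_mas_markers,
)
from wheatgs.qc import centered_markers, compute_kinship

from conftest import random_markers


def phenotype(panel, trait="STAB", h2=0.5, seed=7, mean=0.0):
    rng = np.random.default_rng(seed)
    g = panel["truth"].true_bv[trait]
    noise_sd = g.std(ddof=1) * np.sqrt((1 - h2) / h2)
    return pd.Series(g + rng.normal(0, noise_sd, len(g)) + mean, index=g.index, name=trait)


class TestRrblup:
    def test_zero_variance_phenotype_constant_gebv(self, panel):
        y = pd.Series(3.0, index=panel["markers"].line_ids[:50])
        res, comps = fit_rrblup(y, panel["markers"])
        assert res.gebv.std() == pytest.approx(0.0, abs=1e-9)
        assert comps.sigma_u2 == 0.0

    def test_closed_form_ridge_solution(self, panel):
        """Fixed lambda: effects match (Z'Z + lambda I)^-1 Z'(y - Xb)."""
        mm = MarkerMatrix(panel["markers"].calls.iloc[:8, :3].copy())
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=8), index=mm.line_ids)
        lam = 1.7
        res, _ = fit_rrblup(y, mm, lambda_=lam)
        W, _ = centered_markers(mm)
        X = np.ones((8, 1))
        C = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + lam * np.eye(3)]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y.values, W.T @ y.values]))
        assert np.allclose(res.marker_effects.to_numpy(), sol[1:], atol=1e-10)
        u_direct = np.linalg.solve(
            W.T @ W + lam * np.eye(3), W.T @ (y.values - X[:, 0] * sol[0])
        )
        assert np.allclose(res.marker_effects.to_numpy(), u_direct, atol=1e-10)

    def test_equivalence_with_gblup(self, panel, stab_blues):
        """Same markers, K = WW'/denominator: GEBV correlation 1 within 1e-6."""
        train = stab_blues.iloc[:150]
        rr, _ = fit_rrblup(train, panel["markers"])
        gb, _ = fit_gblup(train, panel["kinship"])
        r = np.corrcoef(rr.gebv, gb.gebv)[0, 1]
        assert r > 1 - 1e-6

    def test_collinear_fixed_marker_dropped_with_warning(self, panel):
        mm = panel["markers"]
        calls = mm.calls.iloc[:40, :5].copy()
        calls["mono"] = 1.0  # centred column is all zero -> collinear with intercept
        mm2 = MarkerMatrix(calls)
        y = pd.Series(np.random.default_rng(2).normal(size=40), index=mm2.line_ids)
        with pytest.warns(UserWarning, match="collinear"):
            res, _ = fit_rrblup(y, mm2, fixed_marker_ids=["mono"])
        assert "mono" not in res.fixed_effects


class TestGblup:
    def test_henderson_mme_oracle(self, panel, stab_blues):
        """Joint BLUP solution equals a direct mixed-model-equation solve."""
        lines = panel["markers"].line_ids[:30]
        K = panel["kinship"]
        Ksub = KinshipMatrix(K.submatrix(lines, lines), line_ids=lines)
        y = stab_blues.loc[lines]
        res, comps = fit_gblup(y, Ksub)
        lam = comps.lambda2
        X = np.ones((30, 1))
        Kinv = np.linalg.inv(Ksub.values)
        C = np.block([[X.T @ X, X.T], [X, np.eye(30) + lam * Kinv]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y.values, y.values]))
        assert abs(sol[0] - res.fixed_effects["intercept"]) < 1e-8
        assert np.max(np.abs(sol[1:] - res.gebv.loc[lines].to_numpy())) < 1e-8

    def test_identity_kinship_gives_no_information_flow(self, stab_blues):
        lines = list(stab_blues.index)
        K = KinshipMatrix(np.eye(len(lines)), line_ids=lines)
        res, _ = fit_gblup(stab_blues.iloc[:100], K)
        unobserved = lines[100:]
        assert np.max(np.abs(res.gebv.loc[unobserved].to_numpy())) < 1e-8

    def test_noiseless_limit_recovers_centred_phenotype(self, panel):
        g = panel["truth"].true_bv["ENG"]
        y = g + 100.0  # heritable, noise-free
        res, comps = fit_gblup(y, panel["kinship"])
        assert comps.lambda2 < 1e-3
        r = np.corrcoef(res.gebv.loc[y.index], y - y.mean())[0, 1]
        assert r > 0.999

    def test_non_psd_kinship_advises_ridge(self, stab_blues):
        lines = list(stab_blues.index[:20])
        vals = -np.eye(20)
        K = KinshipMatrix(vals, line_ids=lines)
        with pytest.raises(ValueError, match="ridge"):
            fit_gblup(stab_blues.loc[lines], K)


class TestGwas:
    def test_null_pvalues_roughly_uniform(self, panel):
        """Pure-noise trait: Bonferroni threshold rarely crossed."""
        markers, mmap, K = panel["markers"], panel["map"], panel["kinship"]
        n_hits = 0
        reps = 20
        for seed in range(reps):
            y = pd.Series(np.random.default_rng(100 + seed).normal(size=200),
                          index=markers.line_ids)
            gw = gwas_scan(y, markers, mmap, K)
            m = len(gw.table)
            if gw.table["pvalue"].min() < 0.05 / m:
                n_hits += 1
            if seed == 0:
                # calibration: p-value quartiles near uniform
                q = gw.table["pvalue"].quantile([0.25, 0.5, 0.75]).to_numpy()
                assert np.all(np.abs(q - [0.25, 0.5, 0.75]) < 0.12)
        assert n_hits <= 0.1 * reps + 1

    def test_planted_qtl_is_top_ranked(self, panel):
        """A single locus explaining ~30 % of variance ranks first in most scans."""
        markers, mmap, K = panel["markers"], panel["map"], panel["kinship"]
        mid = markers.marker_ids[57]
        z = markers.calls[mid].to_numpy()
        zc = z - z.mean()
        wins = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            beta = np.sqrt(0.30 / (0.70 * zc.var()))
            y = pd.Series(beta * zc + rng.normal(0, 1, len(zc)),
                          index=markers.line_ids)
            gw = gwas_scan(y, markers, mmap, K)
            if gw.top_markers(1)[0] == mid:
                wins += 1
        assert wins >= 0.9 * reps

    def test_identity_kinship_reduces_to_ols(self, stab_blues, panel):
        markers, mmap = panel["markers"], panel["map"]
        lines = list(stab_blues.index)
        K = KinshipMatrix(np.eye(len(lines)), line_ids=lines)
        gw = gwas_scan(stab_blues, markers, mmap, K)
        # OLS oracle for a handful of markers
        from scipy import stats as sps

        for mid in gw.table["marker"].head(5):
            z = markers.calls[mid].to_numpy()
            y = stab_blues.to_numpy()
            X = np.column_stack([np.ones_like(z), z])
            beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
            dof = len(y) - 2
            sigma2 = float(res_ss[0]) / dof
            se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            p_ols = 2 * sps.t.sf(abs(beta[1] / se), dof)
            p_scan = float(gw.table.set_index("marker").loc[mid, "pvalue"])
            assert p_scan == pytest.approx(p_ols, abs=1e-6)


class TestMarkerSelection:
    def test_denovo_picks_smallest_pvalues(self):
        tab = pd.DataFrame({
            "marker": list("abcd"), "chrom": 1, "pos_cM": [1.0, 2.0, 3.0, 4.0],
            "effect": 0.0, "stat": 0.0, "pvalue": [0.001, 0.2, 0.01, 0.5],
        })
        from wheatgs.models import GwasResult

        got = select_mas_markers("denovo_top3", gwas=GwasResult(tab))
        assert got == ["a", "c", "b"]

    def test_combined_union_without_duplicates(self):
        tab = pd.DataFrame({
            "marker": ["glu1", "x", "y"], "chrom": 1, "pos_cM": [1.0, 2.0, 3.0],
            "effect": 0.0, "stat": 0.0, "pvalue": [0.001, 0.01, 0.02],
        })
        from wheatgs.models import GwasResult

        got = select_mas_markers("combined", gwas=GwasResult(tab),
                                 glu_ids=["glu1", "glu2"])
        assert got == ["glu1", "glu2", "x", "y"]

    def test_glu_only_ignores_pvalues(self):
        assert select_mas_markers("glu_only", glu_ids=["a", "b", "c"]) == ["a", "b", "c"]


class TestMas:
    def test_single_causal_marker_perfect_on_noiseless_trait(self, panel):
        markers = panel["markers"]
        mid = panel["glu_ids"][0]
        y = pd.Series(2.0 * markers.calls[mid] + 1.0, index=markers.line_ids)
        res = fit_mas(y.iloc[:150], markers, [mid])
        test = markers.line_ids[150:]
        r = np.corrcoef(res.gebv.loc[test], y.loc[test])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_flagged_grand_mean(self, stab_blues, panel):
        res = fit_mas(stab_blues, panel["markers"], [])
        assert res.gebv.std() == 0.0
        assert any("empty" in f for f in res.flags)

    def test_three_marker_normal_equations_oracle(self, panel):
        markers = MarkerMatrix(panel["markers"].calls.iloc[:10, 10:13].copy())
        y = pd.Series(np.random.default_rng(3).normal(size=10), index=markers.line_ids)
        res = fit_mas(y, markers, list(markers.marker_ids))
        W, _ = centered_markers(markers)
        X = np.column_stack([np.ones(10), W])
        beta = np.linalg.solve(X.T @ X, X.T @ y.values)
        assert np.allclose(res.gebv.to_numpy(), W @ beta[1:], atol=1e-9)


class TestMultitrait:
    def test_em_routes_agree(self, panel, stab_blues):
        """Dense-MME and eigen-rotated EM steps are numerically identical."""
        lines = panel["markers"].line_ids[:40]
        K = panel["kinship"].submatrix(lines, lines)
        rng = np.random.default_rng(5)
        Y = np.column_stack([stab_blues.loc[lines], rng.normal(size=40)])
        obs = [np.arange(40)] * 2
        sg = np.array([[1.0, 0.2], [0.2, 1.0]])
        se = np.array([[1.0, 0.1], [0.1, 1.0]])
        dd = _em_step_dense(_prepare_dense([Y[:, 0], Y[:, 1]], obs, K), sg, se)
        cc = _em_step_complete(_prepare_complete([Y[:, 0], Y[:, 1]], K), sg, se)
        for a, b in zip(dd[:2], cc[:2]):
            assert np.allclose(a, b, atol=1e-9)
        assert dd[2] == pytest.approx(cc[2], abs=1e-7)
        assert np.allclose(dd[4], cc[4], atol=1e-8)

    def test_zero_covariance_matches_single_trait(self, panel):
        """Independent traits: bivariate target GEBVs track the single-trait fit."""
        rng = np.random.default_rng(6)
        g1 = panel["truth"].true_bv["WAT"]
        y1 = pd.Series(g1 + rng.normal(0, g1.std(), len(g1)), index=g1.index)
        y2 = pd.Series(rng.normal(size=len(g1)), index=g1.index)  # unrelated
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mt, _ = fit_multitrait(y1, y2, panel["kinship"], on_nonconvergence="warn")
        st, _ = fit_gblup(y1, panel["kinship"])
        r = np.corrcoef(mt.gebv["target"], st.gebv)[0, 1]
        assert r > 0.99

    def test_duplicate_trait_drives_genetic_correlation_to_one(self, panel, stab_blues):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mt, comps = fit_multitrait(stab_blues, stab_blues.copy(),
                                       panel["kinship"], on_nonconvergence="warn")
        rg = comps.Sigma_g[0, 1] / np.sqrt(comps.Sigma_g[0, 0] * comps.Sigma_g[1, 1])
        assert rg > 0.98

    def test_genetic_correlation_recovery(self, panel):
        """PROT-DEV simulated at r_g = 0.85: mean estimate within 0.15."""
        rng = np.random.default_rng(8)
        truth = panel["truth"].true_bv
        ests = []
        for rep in range(5):
            y1 = truth["DEV"] + rng.normal(0, truth["DEV"].std(), 200)
            y2 = truth["PROT"] + rng.normal(0, truth["PROT"].std(), 200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, comps = fit_multitrait(pd.Series(y1, index=truth.index),
                                          pd.Series(y2, index=truth.index),
                                          panel["kinship"], on_nonconvergence="warn")
            ests.append(comps.Sigma_g[0, 1]
                        / np.sqrt(comps.Sigma_g[0, 0] * comps.Sigma_g[1, 1]))
        assert abs(float(np.mean(ests)) - 0.85) < 0.15


class TestSelectionIndex:
    def test_no_genetic_correlation_reduces_to_single_trait(self, panel):
        rng = np.random.default_rng(9)
        g = panel["truth"].true_bv["WAT"]
        y = pd.Series(g + rng.normal(0, g.std(), len(g)), index=g.index)
        prot = pd.Series(rng.normal(size=len(g)), index=g.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idx, _ = fit_selection_index(y.iloc[:150], prot, panel["kinship"])
        st, _ = fit_gblup(y.iloc[:150], panel["kinship"])
        r = np.corrcoef(idx.gebv, st.gebv)[0, 1]
        assert r > 0.98

    def test_correlated_trait_transfers_information(self, panel):
        """High-heritability protein boosts a low-heritability correlated trait
        in most replicates (r_g ~ 0.85 between DEV and PROT)."""
        truth = panel["truth"].true_bv
        wins = 0
        reps = 15
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            dev = pd.Series(
                truth["DEV"] + rng.normal(0, truth["DEV"].std() * np.sqrt(7 / 3), 200),
                index=truth.index,
            )  # h2 = 0.3
            prot = pd.Series(
                truth["PROT"] + rng.normal(0, truth["PROT"].std() * 0.5, 200),
                index=truth.index,
            )  # h2 = 0.8
            train = truth.index[:140]
            test = truth.index[140:]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                idx, _ = fit_selection_index(dev.loc[train], prot, panel["kinship"])
            st, _ = fit_gblup(dev.loc[train], panel["kinship"])
            r_idx = np.corrcoef(idx.gebv.loc[test], truth.loc[test, "DEV"])[0, 1]
            r_st = np.corrcoef(st.gebv.loc[test], truth.loc[test, "DEV"])[0, 1]
            wins += r_idx >= r_st
        assert wins >= 0.7 * reps

    def test_oracle_protein_at_least_as_good_as_estimated(self, panel):
        """Using true protein BVs as the covariate cannot hurt on average."""
        truth = panel["truth"].true_bv
        diffs = []
        for seed in range(8):
            rng = np.random.default_rng(400 + seed)
            dev = pd.Series(
                truth["DEV"] + rng.normal(0, truth["DEV"].std() * np.sqrt(7 / 3), 200),
                index=truth.index,
            )
            prot_obs = pd.Series(
                truth["PROT"] + rng.normal(0, truth["PROT"].std() * 0.5, 200),
                index=truth.index,
            )
            train, test = truth.index[:140], truth.index[140:]
            K = panel["kinship"]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est, _ = fit_selection_index(dev.loc[train], prot_obs, K)
                oracle, _ = fit_gblup(
                    dev.loc[train], K,
                    covariates=truth["PROT"].rename("x_protein").to_frame(),
                )
            x = truth["PROT"]
            b = oracle.fixed_effects.get("x_protein", 0.0)
            oracle_gebv = oracle.gebv + x * b
            r_o = np.corrcoef(oracle_gebv.loc[test], truth.loc[test, "DEV"])[0, 1]
            r_e = np.corrcoef(est.gebv.loc[test], truth.loc[test, "DEV"])[0, 1]
            diffs.append(r_o - r_e)
        assert float(np.mean(diffs)) > -0.02
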