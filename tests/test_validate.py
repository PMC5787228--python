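"""Validation schemes: accuracy definition, random CV, the inside-trading
diagnostic, explained-variance estimator, threshold sweep, and multi-trait
scenarios."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wheatgs.validate import (
    accuracy,
    cv_random,
    explained_variance_cv,
    run_inside_trading_suite,
    run_multitrait_scenarios,
    threshold_sweep,
)
from wheatgs.models import fit_rrblup


class TestAccuracy:
    def test_identical_and_negated_vectors(self):
        a = pd.Series([1.0, 2.0, 5.0], index=list("abc"))
        assert accuracy(a, a) == pytest.approx(1.0)
        assert accuracy(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_fixture(self):
        gebv = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        obs = pd.Series([2.0, 4.0, 5.0], index=list("abc"))
        assert accuracy(gebv, obs) == pytest.approx(0.9820, abs=5e-5)

    def test_degenerate_inputs_flagged_nan(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(accuracy(a, b))
        assert np.isnan(accuracy(b.iloc[:2], b.iloc[:2]))


class TestCvRandom:
    def test_oracle_predictor_scores_one(self, stab_blues):
        res = cv_random(stab_blues, lambda tb, ids: stab_blues, reps=5, seed=0)
        assert all(a == pytest.approx(1.0) for a in res.accuracies)

    def test_pure_noise_scores_near_zero(self, panel):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=200), index=panel["markers"].line_ids)

        def predictor(tb, ids):
            return fit_rrblup(tb, panel["markers"])[0].gebv

        res = cv_random(y, predictor, reps=10, seed=1)
        assert abs(res.mean) < 0.15

    def test_informative_trait_scores_positive(self, panel, stab_blues):
        def predictor(tb, ids):
            return fit_rrblup(tb, panel["markers"])[0].gebv

        res = cv_random(stab_blues, predictor, reps=10, seed=2)
        assert res.mean > 0.3

    def test_too_few_lines_rejected(self):
        y = pd.Series(np.arange(5, dtype=float), index=list("abcde"))
        with pytest.raises(ValueError, match="at least 10"):
            cv_random(y, lambda tb, ids: y, reps=2, seed=0)


class TestInsideTrading:
    @pytest.fixture(scope="class")
    def null_suite(self, panel):
        """Suite on a pure-noise trait: de novo markers are spurious."""
        rng = np.random.default_rng(77)
        lines = panel["markers"].line_ids
        basis = pd.Series(rng.normal(size=120), index=lines[:120])
        forward = {
            "vp1": pd.Series(rng.normal(size=40), index=lines[120:160]),
            "vp2": pd.Series(rng.normal(size=40), index=lines[160:200]),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return run_inside_trading_suite(
                basis, panel["markers"], panel["map"], panel["kinship"], forward,
                glu_ids=panel["glu_ids"], reps=8, seed=3,
            )

    def test_inside_cv_inflates_null_denovo_accuracy(self, null_suite):
        """Scheme A reports spurious skill for GWAS-selected markers on a
        null trait; forward accuracy vanishes."""
        mas = null_suite[null_suite["strategy"] == "mas_denovo"]
        acc_a = mas[mas["scheme"] == "A_inside_cv"]["accuracy"].mean()
        acc_c = mas[mas["scheme"] == "C_forward"]["accuracy"].mean()
        assert acc_a > acc_c
        assert acc_a > 0.1
        assert abs(acc_c) < 0.15

    def test_oracle_predictor_perfect_in_all_schemes(self, panel):
        rng = np.random.default_rng(5)
        lines = panel["markers"].line_ids
        basis = pd.Series(rng.normal(size=100), index=lines[:100])
        forward = {"vp": pd.Series(rng.normal(size=30), index=lines[100:130])}
        everything = pd.concat([basis, forward["vp"]])

        def oracle(tb, ids):
            return everything

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            suite = run_inside_trading_suite(
                basis, panel["markers"], panel["map"], panel["kinship"], forward,
                glu_ids=panel["glu_ids"], reps=2, seed=0,
                predictors={"oracle": oracle},
            )
        oracle_rows = suite[suite["strategy"] == "oracle"]
        assert np.allclose(oracle_rows["accuracy"], 1.0, atol=1e-9)

    def test_overlap_between_basis_and_forward_rejected(self, panel):
        lines = panel["markers"].line_ids
        basis = pd.Series(1.0, index=lines[:50])
        forward = {"bad": pd.Series(1.0, index=lines[40:60])}
        with pytest.raises(ValueError, match="overlap"):
            run_inside_trading_suite(
                basis, panel["markers"], panel["map"], panel["kinship"], forward,
                glu_ids=panel["glu_ids"], reps=1, seed=0,
            )


class TestExplainedVariance:
    def test_null_marker_near_zero(self, panel):
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=200), index=panel["markers"].line_ids, name="X")
        ev = explained_variance_cv(y, panel["markers"].calls.iloc[:, 5], h2=0.5,
                                   reps=20, seed=2)
        assert ev.value < 0.05

    def test_sole_qtl_of_noiseless_trait_near_one(self, panel):
        z = panel["markers"].calls.iloc[:, 9]
        y = pd.Series(3.0 * z + 10.0, index=z.index, name="X")
        ev = explained_variance_cv(y, z, h2=1.0, reps=10, seed=3)
        assert ev.value > 0.95

    def test_thirty_percent_locus_recovered_within_ten_points(self, panel):
        """Stability's Glu-D1 analogue targeted at 33.9 % of genetic variance,
        h2 = 0.47 phenotype: estimate within 10 percentage points."""
        rng = np.random.default_rng(4)
        g = panel["truth"].true_bv["STAB"]
        h2 = 0.47
        y = pd.Series(g + rng.normal(0, g.std() * np.sqrt((1 - h2) / h2), len(g)),
                      index=g.index, name="STAB")
        ev = explained_variance_cv(y, panel["markers"].calls[panel["glu_ids"][2]],
                                   h2=h2, reps=30, seed=5)
        assert ev.value == pytest.approx(0.339, abs=0.10)

    def test_invalid_h2_rejected(self, stab_blues, panel):
        with pytest.raises(ValueError, match="h2"):
            explained_variance_cv(stab_blues, panel["markers"].calls.iloc[:, 0], h2=0.0)


class TestThresholdSweep:
    @pytest.fixture(scope="class")
    def sweep(self, panel, stab_blues):
        lines = panel["markers"].line_ids
        basis = stab_blues.iloc[:140]
        forward = {"vp": stab_blues.iloc[140:]}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return threshold_sweep(
                basis, panel["markers"], panel["glu_ids"], forward, h2=0.5,
                thresholds=np.array([0.0, 5.0, 50.0]), seed=1, ev_reps=10,
            )

    def test_high_threshold_reduces_to_rrblup(self, sweep, panel, stab_blues):
        basis = stab_blues.iloc[:140]
        forward_obs = stab_blues.iloc[140:]
        base, _ = fit_rrblup(basis, panel["markers"])
        base_acc = accuracy(base.gebv.loc[forward_obs.index], forward_obs)
        top = sweep.query("threshold_pct == 50.0 and model == 'wblup'")
        assert top["n_markers_fixed"].iloc[0] == 0
        assert top["mean_accuracy"].iloc[0] == pytest.approx(base_acc, abs=1e-9)

    def test_zero_threshold_fixes_all_informative_candidates(self, sweep):
        row = sweep.query("threshold_pct == 0.0").iloc[0]
        explained = sweep.attrs["explained_pct"]
        assert row["n_markers_fixed"] == sum(v > 0 for v in explained.values())

    def test_operating_threshold_recorded(self, sweep):
        assert sweep.attrs["operating_threshold_pct"] == 5.0


class TestMultitraitScenarios:
    def test_too_small_population_rejected(self, panel):
        lines = panel["markers"].line_ids[:20]
        y = pd.Series(1.0, index=lines)
        with pytest.raises(ValueError, match="at least 30"):
            run_multitrait_scenarios(y, y, panel["kinship"], reps=1)

    def test_protein_on_validation_set_lifts_accuracy(self, panel):
        """VP (protein known for the selection candidates) beats TP on average;
        r_g(STAB, PROT) = 0.76 in the generator."""
        rng = np.random.default_rng(11)
        truth = panel["truth"].true_bv
        stab = pd.Series(truth["STAB"] + rng.normal(0, truth["STAB"].std(), 200),
                         index=truth.index)
        prot = pd.Series(truth["PROT"] + rng.normal(0, truth["PROT"].std() * 0.5, 200),
                         index=truth.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_multitrait_scenarios(
                stab, prot, panel["kinship"], reps=4, seed=2,
                scenarios=("TP", "VP"), methods=("MVM",), max_iter=300,
            )
        means = out.groupby("scenario")["accuracy"].mean()
        assert means["VP"] >= means["TP"] - 0.02

    def test_uncorrelated_protein_collapses_to_base(self):
        """A heritable but genetically uncorrelated protein trait adds no
        information: every scenario tracks the single-trait baseline."""
        from wheatgs.simulate import simulate_genome, simulate_traits
        from wheatgs.qc import compute_kinship
        from conftest import small_config

        cfg = small_config(
            n_lines=150, n_markers=300, trait_names=("Y", "P"),
            genetic_cov=np.diag([1.0, 1.0]), residual_cov=np.diag([1.0, 0.25]),
            trait_means=np.zeros(2), seed=99,
        )
        markers, _ = simulate_genome(cfg)
        truth = simulate_traits(markers, cfg).true_bv
        K = compute_kinship(markers)
        rng = np.random.default_rng(12)
        y = pd.Series(truth["Y"] + rng.normal(0, 1.0, 150), index=truth.index)
        prot = pd.Series(truth["P"] + rng.normal(0, 0.5, 150), index=truth.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = run_multitrait_scenarios(
                y, prot, K, reps=5, seed=3,
                scenarios=("BASE", "TP", "VP"), methods=("INDEX",),
            )
        means = out.groupby("scenario")["accuracy"].mean()
        assert abs(means["TP"] - means["BASE"]) < 0.05
        assert abs(means["VP"] - means["BASE"]) < 0.05
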