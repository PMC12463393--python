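"""Mendelian-randomization estimators, diagnostics and screening rules."""

import numpy as np
import pandas as pd
import pytest

from hyposcreen.config import MRThresholds
from hyposcreen.mr import (
    MRScreenResult,
    bidirectional_classify,
    compute_f,
    egger_intercept,
    fit_five_methods,
    harmonize,
    heterogeneity_q,
    screen,
    select_instruments,
    wald_ratios,
)


def instrument_frame(beta_exp, se_exp, beta_out, se_out):
    k = len(beta_exp)
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(k)],
        "effect_allele": ["A"] * k, "other_allele": ["G"] * k,
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "pval_exp": [1e-8] * k, "pval_out": [0.1] * k,
        "eaf": [0.3] * k, "F": (np.array(beta_exp) / np.array(se_exp)) ** 2,
    })


def gwas_frame(pvals, snps=None, r2=None):
    k = len(pvals)
    snps = snps or [f"rs{i}" for i in range(k)]
    return pd.DataFrame({
        "snp": snps, "effect_allele": ["A"] * k, "other_allele": ["G"] * k,
        "beta": [0.1] * k, "se": [0.01] * k, "pval": pvals,
        "eaf": [0.3] * k, "n": [50000] * k,
    })


class TestSelectInstruments:
    def test_p_threshold(self):
        sel = select_instruments(gwas_frame([1e-6, 1e-4]))
        assert sel["snp"].tolist() == ["rs0"]

    def test_greedy_clumping(self):
        exp = gwas_frame([1e-8, 1e-6], snps=["a", "b"])
        ld = pd.DataFrame({"snp_a": ["a"], "snp_b": ["b"], "r2": [0.5]})
        sel = select_instruments(exp, ld)
        assert sel["snp"].tolist() == ["a"]

    def test_independent_snps_reduce_to_p_filter(self):
        exp = gwas_frame([1e-8, 1e-6, 1e-7])
        ld = pd.DataFrame({"snp_a": ["rs0"], "snp_b": ["rs1"], "r2": [0.0]})
        assert len(select_instruments(exp, ld)) == 3

    def test_empty_selection_allowed(self):
        assert select_instruments(gwas_frame([0.5, 0.1])).empty


class TestComputeF:
    @pytest.mark.parametrize(
        "beta,se,kept", [(0.1, 0.02, True), (0.03, 0.01, False), (0.1, 0.1 / np.sqrt(10), True)],
        ids=["F25-kept", "F9-discarded", "F10-boundary-kept"],
    )
    def test_f_rule(self, beta, se, kept):
        df = gwas_frame([1e-8])
        df["beta"], df["se"] = beta, se
        out = compute_f(df)
        assert (len(out) == 1) == kept
        if kept:
            assert out["F"].iloc[0] == pytest.approx((beta / se) ** 2)

    def test_zero_se_rejected(self):
        df = gwas_frame([1e-8])
        df["se"] = 0.0
        with pytest.raises(ValueError):
            compute_f(df)


class TestHarmonize:
    def _outcome(self, ea, oa, beta=0.2):
        return pd.DataFrame({
            "snp": ["rs0"], "effect_allele": [ea], "other_allele": [oa],
            "beta": [beta], "se": [0.05], "pval": [0.01],
            "eaf": [0.4], "n": [50000],
        })

    def test_swapped_alleles_flip_sign(self):
        exp = gwas_frame([1e-8])
        harm = harmonize(exp, self._outcome("G", "A"))
        assert harm["beta_out"].iloc[0] == pytest.approx(-0.2)

    def test_concordant_unchanged(self):
        exp = gwas_frame([1e-8])
        harm = harmonize(exp, self._outcome("A", "G"))
        assert harm["beta_out"].iloc[0] == pytest.approx(0.2)
        assert harm["beta_exp"].iloc[0] == pytest.approx(0.1)

    def test_palindromic_near_half_dropped(self):
        exp = gwas_frame([1e-8])
        exp["effect_allele"], exp["other_allele"] = "A", "T"
        exp["eaf"] = 0.49
        harm = harmonize(exp, self._outcome("A", "T"))
        assert harm.empty

    def test_palindromic_clear_frequency_kept(self):
        exp = gwas_frame([1e-8])
        exp["effect_allele"], exp["other_allele"] = "A", "T"
        exp["eaf"] = 0.1
        harm = harmonize(exp, self._outcome("A", "T"))
        assert len(harm) == 1

    def test_absent_from_outcome_dropped(self):
        exp = gwas_frame([1e-8], snps=["rsX"])
        harm = harmonize(exp, self._outcome("A", "G"))
        assert harm.empty

    def test_irreconcilable_alleles_dropped(self):
        exp = gwas_frame([1e-8])
        harm = harmonize(exp, self._outcome("C", "G"))
        assert harm.empty


class TestWaldRatios:
    def test_hand_values(self):
        s = instrument_frame([0.4], [0.01], [0.2], [0.1])
        r = wald_ratios(s)
        assert r["ratio"].iloc[0] == pytest.approx(0.5)
        assert r["ratio_se"].iloc[0] == pytest.approx(0.25)

    def test_zero_outcome_beta(self):
        s = instrument_frame([0.4], [0.01], [0.0], [0.1])
        assert wald_ratios(s)["ratio"].iloc[0] == 0.0

    def test_zero_exposure_beta_dropped(self):
        s = instrument_frame([0.0, 0.4], [0.01, 0.01], [0.1, 0.2], [0.1, 0.1])
        assert len(wald_ratios(s)) == 1


class TestFiveMethods:
    def test_ivw_hand_example(self):
        s = instrument_frame([1.0, 1.0], [0.01, 0.01], [0.4, 0.8], [0.1, 0.2])
        fits = fit_five_methods(s, seed=0)
        assert fits["IVW"].estimate == pytest.approx(0.48, rel=1e-12)

    def test_degenerate_agreement_all_half(self):
        s = instrument_frame([1, 2, 1, 2.0], [0.01] * 4,
                             [0.5, 1.0, 0.5, 1.0], [0.1, 0.1, 0.2, 0.2])
        fits = fit_five_methods(s, seed=0)
        assert len(fits) == 5
        for f in fits.values():
            assert f.estimate == pytest.approx(0.5)
        q = heterogeneity_q(s)
        assert q["Q"] == pytest.approx(0.0)
        assert q["p"] == pytest.approx(1.0)

    def test_equal_ses_ivw_is_unweighted_mean(self):
        rng = np.random.default_rng(0)
        be = np.ones(10)
        bo = rng.normal(0.3, 0.05, 10)
        s = instrument_frame(be, [0.01] * 10, bo, [0.1] * 10)
        fits = fit_five_methods(s, MRThresholds(n_boot=0), seed=0)
        assert fits["IVW"].estimate == pytest.approx(bo.mean())

    def test_egger_matches_statsmodels_wls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        be = np.abs(rng.normal(0.1, 0.03, 20))
        se_out = np.full(20, 0.05)
        bo = 0.4 * be + rng.normal(0.01, 0.05, 20)
        s = instrument_frame(be, [0.01] * 20, bo, se_out)
        fits = fit_five_methods(s, MRThresholds(n_boot=0), seed=0)
        wls = sm.WLS(bo, sm.add_constant(be), weights=1 / se_out**2).fit()
        assert fits["Egger"].estimate == pytest.approx(wls.params[1])
        sigma = np.sqrt(wls.scale) if wls.scale > 1 else 1.0
        # statsmodels bse already includes sigma; our se floors it at 1
        expected_se = wls.bse[1] / np.sqrt(wls.scale) * max(1.0, np.sqrt(wls.scale))
        assert fits["Egger"].se == pytest.approx(expected_se)
        ic = egger_intercept(s)
        assert ic["intercept"] == pytest.approx(wls.params[0])

    def test_sign_equivariance(self):
        rng = np.random.default_rng(2)
        be = np.abs(rng.normal(0.1, 0.03, 15))
        bo = 0.3 * be + rng.normal(0, 0.02, 15)
        s = instrument_frame(be, [0.01] * 15, bo, [0.05] * 15)
        neg = s.copy()
        neg["beta_out"] = -neg["beta_out"]
        f1 = fit_five_methods(s, MRThresholds(n_boot=0), seed=3)
        f2 = fit_five_methods(neg, MRThresholds(n_boot=0), seed=3)
        for m in f1:
            assert f1[m].estimate == pytest.approx(-f2[m].estimate, abs=1e-9)
        assert heterogeneity_q(s)["Q"] == pytest.approx(heterogeneity_q(neg)["Q"])

    def test_two_instruments_only_ivw_and_median(self):
        s = instrument_frame([1.0, 1.0], [0.01] * 2, [0.3, 0.35], [0.1, 0.1])
        fits = fit_five_methods(s, MRThresholds(n_boot=0), seed=0)
        assert set(fits) == {"IVW", "Weighted median"}

    def test_fewer_than_two_rejected(self):
        s = instrument_frame([1.0], [0.01], [0.3], [0.1])
        with pytest.raises(ValueError):
            fit_five_methods(s, seed=0)


class TestHeterogeneity:
    def test_two_ratio_hand_example(self):
        # ratios 0 and 1 with unit weights -> Q = 0.5 about the mean 0.5
        s = instrument_frame([1.0, 1.0], [0.01] * 2, [0.0, 1.0], [1.0, 1.0])
        q = heterogeneity_q(s)
        assert q["Q"] == pytest.approx(0.5)
        assert q["df"] == 1

    def test_null_q_over_df_near_one(self):
        rng = np.random.default_rng(4)
        qs = []
        for _ in range(200):
            be = np.abs(rng.normal(0.1, 0.02, 30))
            bo = 0.2 * be + rng.normal(0, 0.05, 30)
            s = instrument_frame(be, [0.005] * 30, bo, [0.05] * 30)
            h = heterogeneity_q(s)
            qs.append(h["Q"] / h["df"])
        assert np.mean(qs) == pytest.approx(1.0, abs=0.1)


class TestScreenRules:
    def _screen(self, ratios, ses, seed=9):
        rng = np.random.default_rng(seed)
        be = np.abs(rng.normal(0.1, 0.03, len(ratios))) + 0.02
        s = instrument_frame(be, [0.01] * len(ratios),
                             np.asarray(ratios) * be, np.asarray(ses) * be)
        return screen(s, cfg=MRThresholds(n_boot=0))

    def test_concordant_significant_passes(self):
        rng = np.random.default_rng(0)
        res = self._screen(rng.normal(0.5, 0.02, 20), [0.05] * 20)
        assert res.concordant and res.ivw_p < 0.05 and res.passed

    @pytest.mark.parametrize(
        "estimates,ivw_p,passed",
        [([0.2, 0.3, 0.25, 0.2, 0.3], 0.01, True),
         ([0.2, 0.3, 0.25, 0.2, -0.1], 0.001, False),
         ([-0.2, -0.3, -0.25, -0.2, -0.3], 0.01, True),
         ([0.2, 0.3, 0.25, 0.2, 0.3], 0.06, False)],
        ids=["all-positive", "discordant", "all-negative", "weak-ivw"],
    )
    def test_rule_on_crafted_fits(self, estimates, ivw_p, passed):
        from hyposcreen.mr import METHODS, MRFit, apply_screen_rule

        fits = {
            m: MRFit(m, est, 0.1, ivw_p if m == "IVW" else 0.5, 10)
            for m, est in zip(METHODS, estimates)
        }
        concordant, p, ok = apply_screen_rule(fits)
        assert ok == passed
        if not passed and p < 0.05:
            assert not concordant

    def test_insignificant_ivw_fails(self):
        rng = np.random.default_rng(1)
        res = self._screen(rng.normal(0.01, 0.4, 20), [0.5] * 20)
        assert not res.passed

    def test_insufficient_instruments(self):
        s = instrument_frame([1.0, 1.0], [0.01] * 2, [0.5, 0.5], [0.1, 0.1])
        res = screen(s, cfg=MRThresholds(n_boot=0))
        assert not res.estimable
        assert res.reason == "insufficient instruments"


class TestBidirectionalClassify:
    def _res(self, passed):
        r = MRScreenResult("e", "o", "forward", estimable=True)
        r.passed = passed
        return r

    @pytest.mark.parametrize(
        "fwd,rev,expected",
        [(True, False, "forward-only"), (False, True, "reverse-only"),
         (True, True, "bidirectional"), (False, False, "none")],
    )
    def test_all_combinations(self, fwd, rev, expected):
        assert bidirectional_classify(self._res(fwd), self._res(rev)) == expected
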