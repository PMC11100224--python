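"""Weighted mediator model, interaction outcome model, and the
counterfactual PNIE/TNDE decomposition with its oracle and intervals."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poemediate import (
    MediatorFit,
    OutcomeFit,
    SimulationParams,
    bootstrap_ci,
    closed_form_effects,
    compute_cc_weights,
    decompose_effects,
    delta_ci,
    fit_mediator_model,
    fit_outcome_model,
    mc_counterfactual_oracle,
    predicted_methylation_by_group,
    sample_case_control,
    simulate_population,
    total_effect,
)
from poemediate.mediation import _MED_NAMES, _OUT_NAMES

from conftest import EFFECT_THETA, latent_summaries


class TestWeights:
    @pytest.mark.parametrize(
        "pi,q,wc,wn",
        [(0.06, 0.50, 0.12, 1.88), (0.50, 0.50, 1.0, 1.0), (0.01, 0.50, 0.02, 1.98)],
    )
    def test_known_weights(self, pi, q, wc, wn):
        w = compute_cc_weights(pi, q)
        assert w.w_case == pytest.approx(wc, abs=1e-12)
        assert w.w_control == pytest.approx(wn, abs=1e-12)

    @pytest.mark.parametrize("pi,q", [(0.0, 0.5), (1.0, 0.5), (0.06, 0.0), (0.06, 1.0)])
    def test_out_of_range_rejected(self, pi, q):
        with pytest.raises(ValueError):
            compute_cc_weights(pi, q)

    @given(
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
        st.floats(min_value=1e-6, max_value=1 - 1e-6),
    )
    @settings(deadline=None, derandomize=True)
    def test_weight_identity(self, pi, q):
        w = compute_cc_weights(pi, q)
        assert w.w_case * q + w.w_control * (1 - q) == pytest.approx(1.0, abs=1e-12)


class TestMediatorModel:
    def test_equal_weights_reduce_to_ols(self, cc_sample):
        import statsmodels.api as sm

        w = compute_cc_weights(0.5, 0.5)  # unit weights
        fit = fit_mediator_model(cc_sample["summaries"], cc_sample["sample"].subjects, w)
        df = cc_sample["summaries"].merge(cc_sample["sample"].subjects, on="subject_id")
        X = np.column_stack(
            [
                np.ones(len(df)),
                df["fh_category"] == "mother",
                df["fh_category"] == "father_or_sib",
                df["hla_dr34"],
            ]
        ).astype(float)
        ols = sm.OLS(df["summary_m"].to_numpy(), X).fit()
        assert fit.beta.to_numpy() == pytest.approx(np.asarray(ols.params), abs=1e-10)

    def test_collinear_design_rejected(self, cc_sample):
        pheno = cc_sample["sample"].subjects.copy()
        pheno["hla_dr34"] = 1  # constant, aliased with intercept
        with pytest.raises(ValueError, match="aliased|collinear"):
            fit_mediator_model(cc_sample["summaries"], pheno, cc_sample["weights"])

    def test_null_exposure_effect_unbiased_with_nominal_coverage(self):
        """With no exposure-methylation effect the weighted estimate is
        near zero and its robust CI covers zero at roughly 95%."""
        params = SimulationParams(
            n_population=12_000,
            beta_true=(0.0, 0.0, 0.0, 0.1),
            seed=0,
        )
        w = compute_cc_weights(0.06, 0.5)
        covered, est = 0, []
        n_rep = 100
        rng = np.random.default_rng(31)
        for _ in range(n_rep):
            p = dataclasses.replace(params, seed=int(rng.integers(2**31)))
            pop = simulate_population(p)
            s = sample_case_control(pop, 300, 300, match_vars=(), seed=int(rng.integers(2**31)))
            fit = fit_mediator_model(latent_summaries(s.subjects), s.subjects, w)
            est.append(fit.beta["fh_mother"])
            lo, hi = fit.conf_int.loc["fh_mother"]
            covered += lo <= 0.0 <= hi
        assert abs(np.mean(est)) < 0.05
        assert 0.89 <= covered / n_rep <= 0.99

    def test_weighting_corrects_case_control_selection_bias(self):
        """Weighted estimates from case-control samples track the source
        population coefficient; unweighted estimates are further off when
        methylation differs by case status."""
        params = SimulationParams(n_population=50_000, theta_true=EFFECT_THETA, seed=1)
        pop = simulate_population(params)
        import statsmodels.api as sm

        w = compute_cc_weights(0.06, 0.5)
        weighted, unweighted = [], []
        rng = np.random.default_rng(17)
        for _ in range(150):
            s = sample_case_control(
                pop, 1000, 1000, match_vars=(), seed=int(rng.integers(2**31))
            )
            summ = latent_summaries(s.subjects)
            fit = fit_mediator_model(summ, s.subjects, w)
            weighted.append(fit.beta["fh_mother"])
            df = summ.merge(s.subjects, on="subject_id")
            X = np.column_stack(
                [
                    np.ones(len(df)),
                    df["fh_category"] == "mother",
                    df["fh_category"] == "father_or_sib",
                    df["hla_dr34"],
                ]
            ).astype(float)
            unweighted.append(sm.OLS(df["summary_m"].to_numpy(), X).fit().params[1])
        truth = params.beta_true[1]
        bias_w = abs(np.mean(weighted) - truth)
        bias_u = abs(np.mean(unweighted) - truth)
        assert bias_w < 0.03
        assert bias_u > bias_w


class TestOutcomeModel:
    def test_interaction_recovery_and_sign_flip(self):
        """theta3m is recovered and the methylation-outcome slope is
        negative in the affected-mother group, positive elsewhere."""
        params = SimulationParams(
            n_population=20_000,
            theta_true=(None, 1.0, 1.0, 0.5, -0.8, 0.0, 1.0),
            seed=23,
        )
        pop = simulate_population(params)
        fit = fit_outcome_model(latent_summaries(pop.subjects), pop.subjects)
        assert fit.theta["fh_mother:m"] == pytest.approx(-0.8, abs=0.2)
        slope_mother = fit.theta["m"] + fit.theta["fh_mother:m"]
        assert slope_mother < 0 < fit.theta["m"]

    def test_constant_methylation_rejected(self, cc_sample):
        summ = cc_sample["summaries"].copy()
        summ["summary_m"] = 1.0
        with pytest.raises(ValueError, match="aliased|collinear"):
            fit_outcome_model(summ, cc_sample["sample"].subjects)

    def test_null_interaction_type_i_error_near_nominal(self):
        """Under no interaction, the p < 0.1 screening flags fire at
        roughly the nominal 10% rate."""
        flags = 0
        n_rep = 200
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            p = SimulationParams(
                n_population=1_000,
                incidence_pi=0.3,  # enough cases at small n for a stable fit
                theta_true=(None, 0.3, 0.3, 0.4, 0.0, 0.0, 0.5),
                seed=int(rng.integers(2**31)),
            )
            pop = simulate_population(p)
            fit = fit_outcome_model(latent_summaries(pop.subjects), pop.subjects)
            flags += fit.interaction_p["fh_mother:m"] < 0.1
        assert 0.05 <= flags / n_rep <= 0.16


class TestDecomposition:
    def test_no_interaction_reduces_to_product_of_coefficients(self):
        pnie, tnde, te = closed_form_effects(
            beta0=0.3, beta_a=1.0, beta2c=0.0, sigma2=0.5,
            theta1=0.25, theta2=np.log(2), theta3=0.0,
        )
        assert pnie == pytest.approx(2.0, abs=1e-12)
        assert tnde == pytest.approx(np.exp(0.25), abs=1e-12)
        assert te == pytest.approx(pnie * tnde, rel=1e-12)

    def test_hand_derived_interaction_example(self):
        pnie, tnde, _ = closed_form_effects(
            beta0=1.0, beta_a=0.2, beta2c=0.0, sigma2=0.4,
            theta1=0.1, theta2=0.3, theta3=0.5,
        )
        assert np.log(tnde) == pytest.approx(0.81, abs=1e-12)
        assert tnde == pytest.approx(2.2479, abs=1e-4)
        assert pnie == pytest.approx(np.exp(0.06), abs=1e-12)

    def test_reference_level_irrelevant_without_interaction(self):
        kw = dict(beta0=1.0, beta_a=0.2, beta2c=0.0, sigma2=0.4, theta1=0.1, theta2=0.3)
        with_int = [
            closed_form_effects(**kw, theta3=0.5, a=1, a_star=0)[0],
            1 / closed_form_effects(**kw, theta3=0.5, a=0, a_star=1)[0],
        ]
        without = [
            closed_form_effects(**kw, theta3=0.0, a=1, a_star=0)[0],
            1 / closed_form_effects(**kw, theta3=0.0, a=0, a_star=1)[0],
        ]
        assert without[0] == pytest.approx(without[1], rel=1e-12)
        assert with_int[0] != pytest.approx(with_int[1], rel=1e-6)

    def test_decomposition_identity_on_fits(self, cc_sample):
        med = fit_mediator_model(
            cc_sample["summaries"], cc_sample["sample"].subjects, cc_sample["weights"]
        )
        out = fit_outcome_model(cc_sample["summaries"], cc_sample["sample"].subjects)
        for contrast in ("mother", "father_or_sib"):
            eff = decompose_effects(med, out, contrast=contrast)
            assert eff.te_or == pytest.approx(eff.pnie_or * eff.tnde_or, rel=1e-9)

    def test_outcome_intercept_does_not_enter_effects(self, cc_sample):
        """The case-control-biased logistic intercept is absent from both
        effect formulas."""
        med = fit_mediator_model(
            cc_sample["summaries"], cc_sample["sample"].subjects, cc_sample["weights"]
        )
        out = fit_outcome_model(cc_sample["summaries"], cc_sample["sample"].subjects)
        eff1 = decompose_effects(med, out, contrast="mother")
        out.theta["intercept"] += 5.0
        eff2 = decompose_effects(med, out, contrast="mother")
        assert eff1.pnie_or == eff2.pnie_or
        assert eff1.tnde_or == eff2.tnde_or

    def test_unknown_contrast_rejected(self, cc_sample):
        med = fit_mediator_model(
            cc_sample["summaries"], cc_sample["sample"].subjects, cc_sample["weights"]
        )
        out = fit_outcome_model(cc_sample["summaries"], cc_sample["sample"].subjects)
        with pytest.raises(ValueError):
            decompose_effects(med, out, contrast="sibling")


class TestOracle:
    MED = (1.0, 0.2, 0.0, 0.4)
    OUT = (-6.0, 0.1, 0.3, 0.5, 0.0)

    def test_null_parameters_give_unit_ratios(self):
        pnie, tnde = mc_counterfactual_oracle(
            (0.0, 0.0, 0.0, 0.5), (-4.0, 0.0, 0.0, 0.0, 0.0), n_mc=200_000, seed=0
        )
        assert pnie == pytest.approx(1.0, abs=1e-6)
        assert tnde == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form_at_low_prevalence(self):
        pnie, tnde = mc_counterfactual_oracle(self.MED, self.OUT, n_mc=10**6, seed=1)
        assert pnie == pytest.approx(1.0618, rel=0.02)
        assert tnde == pytest.approx(2.2479, rel=0.02)

    def test_diverges_when_outcome_is_common(self):
        """At ~30% prevalence the rare-outcome closed form overstates the
        risk-ratio direct effect by more than 5%."""
        out_common = (-1.2, 0.1, 0.3, 0.5, 0.0)
        _, tnde = mc_counterfactual_oracle(self.MED, out_common, n_mc=10**6, seed=2)
        assert abs(tnde - 2.2479) / 2.2479 > 0.05

    def test_small_n_mc_rejected(self):
        with pytest.raises(ValueError):
            mc_counterfactual_oracle(self.MED, self.OUT, n_mc=10)


def _toy_fits(theta3: float):
    beta = pd.Series([0.1, 0.4, 0.05, 0.02], index=_MED_NAMES)
    med_cov = pd.DataFrame(np.diag([0.01, 0.04, 0.02, 0.01]), index=_MED_NAMES, columns=_MED_NAMES)
    med = MediatorFit(
        beta=beta, robust_cov=med_cov, sigma2=0.5,
        conf_int=pd.DataFrame(0.0, index=_MED_NAMES, columns=["lower", "upper"]),
        pvalues=pd.Series(1.0, index=_MED_NAMES), nobs=200, sum_weights=200.0,
    )
    theta = pd.Series([-3.0, 0.5, 0.3, 0.7, theta3, 0.0, 0.4], index=_OUT_NAMES)
    out_cov = pd.DataFrame(
        np.diag([0.1, 0.09, 0.05, 0.06, 0.03, 0.02, 0.04]),
        index=_OUT_NAMES, columns=_OUT_NAMES,
    )
    out = OutcomeFit(
        theta=theta, cov=out_cov, pvalues=pd.Series(1.0, index=_OUT_NAMES),
        interaction_p=pd.Series(1.0, index=["fh_mother:m", "fh_father_or_sib:m"]),
        nobs=200,
    )
    return med, out


class TestDeltaCI:
    def test_no_interaction_reduces_to_product_delta_formula(self):
        med, out = _toy_fits(theta3=0.0)
        eff = delta_ci(med, out, contrast="mother")
        th2, ba = out.theta["m"], med.beta["fh_mother"]
        expected = np.sqrt(th2**2 * 0.04 + ba**2 * 0.06)
        assert eff.log_se["pnie"] == pytest.approx(expected, abs=1e-10)

    def test_delta_and_bootstrap_agree_on_log_scale(self):
        params = SimulationParams(n_population=40_000, theta_true=EFFECT_THETA, seed=3)
        pop = simulate_population(params)
        s = sample_case_control(pop, 1000, 1000, match_vars=(), seed=4)
        summ = latent_summaries(s.subjects)
        w = compute_cc_weights(0.06, 0.5)
        med = fit_mediator_model(summ, s.subjects, w)
        out = fit_outcome_model(summ, s.subjects)
        d = delta_ci(med, out, contrast="mother")
        b = bootstrap_ci(summ, s.subjects, w, contrast="mother", n_boot=600, seed=5)
        for name in ("pnie", "tnde"):
            for i in (0, 1):
                ld, lb = np.log(d.ci[name][i]), np.log(b.ci[name][i])
                scale = max(abs(ld), abs(lb), 0.2)
                assert abs(ld - lb) / scale < 0.35

    def test_bootstrap_deterministic_given_seed(self, cc_sample):
        kw = dict(
            summaries=cc_sample["summaries"],
            phenotype=cc_sample["sample"].subjects,
            weights=cc_sample["weights"],
            contrast="mother",
            n_boot=200,
            seed=9,
        )
        assert bootstrap_ci(**kw).ci == bootstrap_ci(**kw).ci

    def test_bootstrap_rejects_tiny_n_boot(self, cc_sample):
        with pytest.raises(ValueError):
            bootstrap_ci(
                cc_sample["summaries"],
                cc_sample["sample"].subjects,
                cc_sample["weights"],
                n_boot=50,
            )

    def test_degenerate_mediator_fails(self, cc_sample):
        summ = cc_sample["summaries"].copy()
        summ["summary_m"] = 2.0
        with pytest.raises((ValueError, RuntimeError)):
            bootstrap_ci(
                summ, cc_sample["sample"].subjects, cc_sample["weights"], n_boot=200
            )


class TestTotalEffect:
    def test_null_gives_unit_odds_ratios(self, null_params):
        pop = simulate_population(null_params)
        te = total_effect(pop.subjects).set_index("contrast")
        for contrast in ("mother", "father_or_sib"):
            assert te.loc[contrast, "or"] == pytest.approx(1.0, abs=0.25)

    def test_recovers_known_exposure_log_odds(self):
        """With no mediation, the father/sib total-effect OR averages to
        the generating exp(theta1f) = 3."""
        ors = []
        rng = np.random.default_rng(55)
        for _ in range(100):
            p = SimulationParams(
                n_population=2_000,
                incidence_pi=0.06,
                beta_true=(0.0, 0.0, 0.0, 0.0),
                theta_true=(None, 0.3, np.log(3.0), 0.0, 0.0, 0.0, 0.8),
                seed=int(rng.integers(2**31)),
            )
            pop = simulate_population(p)
            te = total_effect(pop.subjects).set_index("contrast")
            ors.append(te.loc["father_or_sib", "or"])
        assert np.mean(ors) == pytest.approx(3.0, abs=0.5)


class TestPredictedMethylation:
    def test_saturated_six_subject_fit_is_exact(self):
        rows = []
        vals = {"mother": (1.0, 0.2), "father_or_sib": (0.5, 0.9), "none": (0.1, 0.3)}
        i = 0
        for fh, (v0, v1) in vals.items():
            for case, v in ((0, v0), (1, v1)):
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "case": case,
                        "fh_category": fh,
                        "hla_dr34": 0,
                        "sex": "male",
                        "nhw": 1,
                        "age_dx_or_censor": 5.0,
                        "summary_m": v,
                    }
                )
                i += 1
        pheno = pd.DataFrame(rows)
        summ = pheno[["subject_id", "summary_m"]].assign(cpg_id="cg1", n_visits=1)
        pred = predicted_methylation_by_group(summ, pheno[pheno.columns.drop("summary_m")])
        pred = pred.set_index(["fh_category", "case"])
        for fh, (v0, v1) in vals.items():
            assert pred.loc[(fh, 0), "predicted_m"] == pytest.approx(v0, abs=1e-10)
            assert pred.loc[(fh, 1), "predicted_m"] == pytest.approx(v1, abs=1e-10)

    def test_interaction_pattern_mother_cases_lower(self, cc_sample):
        pred = predicted_methylation_by_group(
            cc_sample["summaries"], cc_sample["sample"].subjects
        ).set_index(["fh_category", "case"])
        assert pred.loc[("mother", 1), "predicted_m"] < pred.loc[("mother", 0), "predicted_m"]
        assert pred.loc[("none", 1), "predicted_m"] >= pred.loc[("none", 0), "predicted_m"]

    def test_empty_cell_rejected(self, cc_sample):
        pheno = cc_sample["sample"].subjects
        drop = pheno[(pheno["fh_category"] == "mother") & (pheno["case"] == 1)]
        pheno2 = pheno.drop(drop.index)
        with pytest.raises(ValueError, match="mother"):
            predicted_methylation_by_group(cc_sample["summaries"], pheno2)
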