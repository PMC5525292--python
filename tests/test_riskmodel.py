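"""Risk-score panels: scoring, evaluation, persistence, multivariate Cox."""

import numpy as np
import pandas as pd
import pytest

from loopmark.coxph import CoxConvergenceError, CoxFit
from loopmark.riskmodel import (
    evaluate_panel,
    fit_risk_model,
    model_from_file,
    multivariate_cox,
    risk_score,
    score_cohort,
    write_model,
)
from loopmark.survival import (
    DegenerateSplitError,
    SurvivalRecord,
    median_dichotomize,
    records_from_clinical,
)


def _fake_fit(names, coef):
    coef = np.asarray(coef, dtype=float)
    return CoxFit(
        names=list(names), coef=coef, se=np.ones_like(coef),
        loglik=0.0, loglik_null=0.0, ties="efron", n=10, n_events=5,
        converged=True, score_norm=0.0,
    )


@pytest.fixture(scope="module")
def fitted_model(default_bundle):
    records = records_from_clinical(default_bundle.clinical, tissue="tumor")
    panel = sorted(default_bundle.truth["probe_id"])[:6]
    return fit_risk_model(default_bundle.beta, panel, records), records


class TestRiskScore:
    def test_dot_product(self):
        fit = _fake_fit(["a", "b"], [1.0, 2.0])
        panel = pd.DataFrame([[0.5, 0.25]], index=["s1"], columns=["a", "b"])
        assert risk_score(fit, panel).loc["s1"] == pytest.approx(1.0)

    def test_zero_coefficients_zero_scores(self):
        fit = _fake_fit(["a", "b"], [0.0, 0.0])
        panel = pd.DataFrame(np.random.default_rng(0).random((5, 2)), columns=["a", "b"])
        assert (risk_score(fit, panel) == 0).all()

    def test_ordering_invariant_to_column_shift(self):
        rng = np.random.default_rng(1)
        fit = _fake_fit(["a", "b"], [0.7, -1.2])
        panel = pd.DataFrame(rng.random((20, 2)), columns=["a", "b"])
        base = risk_score(fit, panel)
        shifted = risk_score(fit, panel.assign(a=panel["a"] + 0.3))
        assert (base.rank() == shifted.rank()).all()

    def test_missing_panel_value_excludes_sample(self):
        fit = _fake_fit(["a"], [1.0])
        panel = pd.DataFrame({"a": [0.5, np.nan]}, index=["s1", "s2"])
        scores = risk_score(fit, panel)
        assert list(scores.index) == ["s1"]

    def test_column_mismatch_rejected(self):
        fit = _fake_fit(["a", "b"], [1.0, 2.0])
        panel = pd.DataFrame([[0.5, 0.25]], columns=["b", "a"])
        with pytest.raises(ValueError):
            risk_score(fit, panel)


class TestEvaluatePanel:
    def test_planted_panel_separates_survival(self, fitted_model):
        model, records = fitted_model
        evaluation = evaluate_panel(model.scores, records)
        assert evaluation.high_is_worse
        assert evaluation.logrank.p_value < 0.05
        # the high-RS KM curve must lie at or below the low-RS curve late on
        last = min(evaluation.km_high.times[-1], evaluation.km_low.times[-1])
        s_high = evaluation.km_high.survival[evaluation.km_high.times <= last][-1]
        s_low = evaluation.km_low.survival[evaluation.km_low.times <= last][-1]
        assert s_high <= s_low

    def test_constant_scores_degenerate(self):
        records = [SurvivalRecord(f"s{i}", float(i + 1), 1) for i in range(4)]
        scores = pd.Series(0.5, index=[f"s{i}" for i in range(4)])
        with pytest.raises(DegenerateSplitError):
            evaluate_panel(scores, records)


class TestModelPersistence:
    def test_round_trip_reproduces_scores_exactly(self, fitted_model, tmp_path):
        model, _records = fitted_model
        path = tmp_path / "model.tsv"
        write_model(model, path)
        reloaded = model_from_file(path)
        assert reloaded.panel == model.panel
        np.testing.assert_array_equal(reloaded.cox.coef, model.cox.coef)
        np.testing.assert_array_equal(reloaded.cox.se, model.cox.se)
        assert reloaded.cox.ties == model.cox.ties

    def test_frozen_scoring_matches_original(self, fitted_model, default_bundle, tmp_path):
        model, _ = fitted_model
        path = tmp_path / "model.tsv"
        write_model(model, path)
        reloaded = model_from_file(path)
        rescored = score_cohort(reloaded, default_bundle.beta)
        common = model.scores.index
        np.testing.assert_array_equal(
            rescored.loc[common].to_numpy(), model.scores.to_numpy()
        )

    def test_frozen_validation_on_shared_biology_cohort(self, default_bundle):
        # a validation cohort sharing the planted modules (structure_seed)
        # but with fresh patients must reproduce the survival separation
        # under FROZEN discovery coefficients
        from loopmark.simulate import GeneratorConfig, generate

        records = records_from_clinical(default_bundle.clinical, tissue="tumor")
        panel = sorted(default_bundle.truth["probe_id"])
        model = fit_risk_model(default_bundle.beta, panel, records)
        validation = generate(
            GeneratorConfig(seed=default_bundle.config.seed + 1000,
                            structure_seed=default_bundle.config.seed)
        )
        pd.testing.assert_frame_equal(validation.truth, default_bundle.truth)
        v_records = records_from_clinical(validation.clinical, tissue="tumor")
        v_scores = score_cohort(model, validation.beta)
        v_eval = evaluate_panel(v_scores, v_records)
        assert v_eval.high_is_worse
        assert v_eval.logrank.p_value < 0.05

    def test_refit_differs_from_frozen_on_new_cohort(self, fitted_model):
        from loopmark.simulate import GeneratorConfig, generate

        model, _ = fitted_model
        other = generate(GeneratorConfig(seed=12))
        # score the new cohort's tumours over the same probe ids
        records = records_from_clinical(other.clinical, tissue="tumor")
        frozen = score_cohort(model, other.beta)
        refit = score_cohort(model, other.beta, refit=True, records=records)
        common = refit.index
        assert not np.allclose(frozen.loc[common].to_numpy(), refit.to_numpy())


class TestMultivariateCox:
    @staticmethod
    def _inputs(bundle):
        records = records_from_clinical(bundle.clinical, tissue="tumor")
        clinical = bundle.clinical[bundle.clinical["tissue"] == "tumor"].set_index("sample_id")
        covariates = clinical[["er", "pr", "her2", "stage34", "age_over_55", "ductal", "pam50"]]
        return records, covariates

    def test_reference_coding_layout(self, fitted_model, default_bundle):
        model, _ = fitted_model
        records, covariates = self._inputs(default_bundle)
        fit, table = multivariate_cox(
            model.scores, covariates, records, categorical={"pam50": "LuminalA"}
        )
        pam_rows = [r for r in table.index if r.startswith("pam50")]
        assert "pam50:LuminalA (Reference)" in pam_rows
        assert len(pam_rows) == 4  # reference + 3 dummies
        assert "risk_score_high" in table.index
        # HR/CI consistency with the underlying fit
        summary = fit.summary()
        np.testing.assert_allclose(summary["hr"], np.exp(summary["coef"]))

    def test_rs_effect_detected_null_covariates_cover_one(self, fitted_model, default_bundle):
        model, _ = fitted_model
        records, covariates = self._inputs(default_bundle)
        _fit, table = multivariate_cox(
            model.scores, covariates, records, categorical={"pam50": "LuminalA"}
        )
        assert table.loc["risk_score_high", "p"] < 0.05
        # the generator plants no clinical-covariate effect: most CIs cover 1
        others = table.drop(index=[r for r in table.index if "Reference" in r])
        others = others.drop(index="risk_score_high")
        covers = ((others["ci_low"] <= 1.0) & (others["ci_high"] >= 1.0)).mean()
        assert covers >= 0.7

    def test_duplicated_rs_column_collinearity(self, fitted_model, default_bundle):
        model, _ = fitted_model
        records, covariates = self._inputs(default_bundle)
        high, _low = median_dichotomize(model.scores)
        dup = covariates.copy()
        dup["rs_copy"] = dup.index.isin(high).astype(int)
        with pytest.raises(CoxConvergenceError):
            multivariate_cox(model.scores, dup, records, categorical={"pam50": "LuminalA"})
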