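#!/usr/bin/env python
"""Fit the Cox risk-score panel on the discovery cohort and evaluate it.

The panel model is fitted on the continuous beta values of the final CpGs;
RS = sum(coef_i * beta_i). Evaluation median-splits RS and applies the
log-rank test, first on the discovery cohort, then on the independent
validation cohort with FROZEN discovery coefficients. Finally the
dichotomised RS enters a multivariate Cox model against the (null-effect)
clinical covariates. Writes model and tables under results/risk_model/.
"""

import os

from loopmark.io import read_fixtures, read_pairs
from loopmark.riskmodel import (
    evaluate_panel,
    fit_risk_model,
    multivariate_cox,
    score_cohort,
    write_model,
)
from loopmark.survival import records_from_clinical

HERE = os.path.dirname(__file__)
RESULTS = os.path.join(HERE, "..", "results")
OUT = os.path.join(RESULTS, "risk_model")
os.makedirs(OUT, exist_ok=True)

panel_pairs = read_pairs(os.path.join(RESULTS, "cascade", "panel.tsv"))
panel = sorted({p.probe_id for p in panel_pairs})
discovery = read_fixtures(os.path.join(HERE, "..", "scratch", "cohorts", "discovery"))
records = records_from_clinical(discovery.clinical, tissue="tumor")

model = fit_risk_model(discovery.beta, panel, records)
write_model(model, os.path.join(OUT, "model.tsv"))
evaluation = evaluate_panel(model.scores, records)
print(f"panel of {len(panel)} CpGs; Cox fit on {model.cox.n} tumours "
      f"({model.cox.n_events} events), ties: {model.cox.ties}")
print(f"discovery: log-rank chi2 {evaluation.logrank.chi_square:.2f}, "
      f"p {evaluation.logrank.p_value:.3g}, high RS worse: {evaluation.high_is_worse}")

validation = read_fixtures(os.path.join(HERE, "..", "scratch", "cohorts", "validation"))
v_records = records_from_clinical(validation.clinical, tissue="tumor")
v_scores = score_cohort(model, validation.beta)  # frozen coefficients
v_eval = evaluate_panel(v_scores, v_records)
print(f"validation (frozen coefficients): log-rank chi2 {v_eval.logrank.chi_square:.2f}, "
      f"p {v_eval.logrank.p_value:.3g}, high RS worse: {v_eval.high_is_worse}")

clinical = discovery.clinical[discovery.clinical["tissue"] == "tumor"].set_index("sample_id")
covariates = clinical[["er", "pr", "her2", "stage34", "age_over_55", "ductal", "pam50"]]
fit, table = multivariate_cox(
    model.scores, covariates, records, categorical={"pam50": "LuminalA"}
)
table.to_csv(os.path.join(OUT, "multivariate.tsv"), sep="\t")
print("\nmultivariate Cox (dichotomised RS vs clinical covariates):")
print(table.round(4).to_string())
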