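"""Cox risk-score panels over selected CpGs, and the multivariate comparison
against clinical covariates.

A panel model is fitted on the continuous β values of the selected probes in
the discovery cohort; the per-sample risk score is the linear predictor
RS_s = Σ_i coef_i · β_{i,s}. Evaluation median-splits RS within the evaluated
cohort and applies the log-rank test (high RS expected worse). For validation
cohorts the discovery coefficients are FROZEN by default (an honest
independent-dataset evaluation); refitting is available explicitly.

The multivariate analysis enters the dichotomised RS (high vs. low) as a
binary covariate in a joint Cox model with the clinical indicators and
reference-coded dummies of one categorical factor, on complete cases only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coxph import CoxFit, fit_cox
from .survival import (
    KMCurve,
    LogrankResult,
    SurvivalRecord,
    km_estimate,
    logrank_test,
    median_dichotomize,
)

log = logging.getLogger(__name__)


@dataclass
class RiskModel:
    """A fitted CpG panel: ordered probes, their Cox fit, and sample scores."""

    panel: list[str]
    cox: CoxFit
    scores: pd.Series

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.cox.coef, index=self.panel, name="coef")


def fit_risk_model(
    beta: pd.DataFrame,
    panel: Sequence[str],
    records: Sequence[SurvivalRecord],
    ties: str = "efron",
) -> RiskModel:
    """Fit the panel Cox model on tumour β values and score the fitted samples."""
    panel = list(panel)
    missing = [p for p in panel if p not in beta.index]
    if missing:
        raise KeyError(f"panel probes absent from beta matrix: {missing}")
    by_id = {r.sample_id: r for r in records}
    samples = [s for s in beta.columns if s in by_id]
    if not samples:
        raise ValueError("no overlap between beta samples and survival records")
    x = beta.loc[panel, samples].T  # samples x panel
    time = np.array([by_id[s].time for s in samples])
    event = np.array([by_id[s].event for s in samples])
    fit = fit_cox(x, time, event, ties=ties)
    scores = risk_score(fit, x)
    return RiskModel(panel=panel, cox=fit, scores=scores)


def risk_score(fit: CoxFit, beta_panel: pd.DataFrame) -> pd.Series:
    """RS = Σ coef_i · β_i per sample (linear predictor, no baseline term).

    ``beta_panel`` is samples × panel; columns must match the fit covariates.
    Samples with any missing panel value are excluded with a log entry.
    """
    if list(beta_panel.columns) != list(fit.names):
        raise ValueError(
            f"panel columns {list(beta_panel.columns)} do not match fit covariates {fit.names}"
        )
    complete = beta_panel.dropna(axis=0, how="any")
    n_dropped = len(beta_panel) - len(complete)
    if n_dropped:
        log.info("%d samples excluded from scoring (missing panel values)", n_dropped)
    values = complete.to_numpy(dtype=float) @ fit.coef
    return pd.Series(values, index=complete.index, name="risk_score")


def score_cohort(model: RiskModel, beta: pd.DataFrame, refit: bool = False,
                 records: Sequence[SurvivalRecord] | None = None) -> pd.Series:
    """Score a (validation) cohort's samples with the panel.

    Frozen discovery coefficients by default; ``refit=True`` refits the panel
    Cox model on the new cohort (requires its survival records).
    """
    if refit:
        if records is None:
            raise ValueError("refit=True requires survival records")
        return fit_risk_model(beta, model.panel, records, ties=model.cox.ties).scores
    x = beta.loc[model.panel].T
    x.columns = model.panel
    fit = model.cox
    if list(x.columns) != list(fit.names):
        raise ValueError("panel/covariate mismatch")
    return risk_score(fit, x)


@dataclass
class PanelEvaluation:
    logrank: LogrankResult
    km_high: KMCurve
    km_low: KMCurve
    high_ids: list[str]
    low_ids: list[str]
    high_is_worse: bool


def evaluate_panel(
    scores: pd.Series, records: Sequence[SurvivalRecord]
) -> PanelEvaluation:
    """Median-split the risk scores within this cohort and run the log-rank test."""
    by_id = {r.sample_id: r for r in records}
    scores = scores[[s for s in scores.index if s in by_id]]
    high, low = median_dichotomize(scores)
    high_records = [by_id[s] for s in high]
    low_records = [by_id[s] for s in low]
    result = logrank_test(high_records, low_records)
    return PanelEvaluation(
        logrank=result,
        km_high=km_estimate(high_records),
        km_low=km_estimate(low_records),
        high_ids=high,
        low_ids=low,
        high_is_worse=result.o_minus_e_a > 0,
    )


def encode_covariates(
    covariates: pd.DataFrame,
    categorical: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Design matrix: binary indicators pass through; each categorical factor
    becomes reference-coded dummies (``{column: reference_level}``)."""
    categorical = categorical or {}
    parts = []
    for col in covariates.columns:
        if col in categorical:
            ref = categorical[col]
            levels = sorted(covariates[col].dropna().unique())
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            for level in levels:
                if level == ref:
                    continue
                parts.append(
                    (covariates[col] == level).astype(float).rename(f"{col}:{level}")
                    .where(covariates[col].notna())
                )
        else:
            parts.append(pd.to_numeric(covariates[col]).astype(float))
    return pd.concat(parts, axis=1)


def multivariate_cox(
    scores: pd.Series,
    covariates: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    categorical: dict[str, str] | None = None,
    ties: str = "efron",
) -> tuple[CoxFit, pd.DataFrame]:
    """Joint Cox fit of dichotomised RS (high vs. low) with clinical covariates.

    Complete cases only. Returns the fit and a report table with one row per
    covariate (HR, 95% CI, p) plus an explicit Reference row for each
    categorical factor, mirroring the conventional multivariate layout.
    """
    by_id = {r.sample_id: r for r in records}
    shared = [s for s in scores.index if s in by_id and s in covariates.index]
    scores = scores[shared]
    high, _low = median_dichotomize(scores)
    design = encode_covariates(covariates.loc[shared], categorical)
    design.insert(0, "risk_score_high", scores.index.isin(high).astype(float))
    design = design.dropna(axis=0, how="any")
    samples = list(design.index)
    time = np.array([by_id[s].time for s in samples])
    event = np.array([by_id[s].event for s in samples])
    fit = fit_cox(design, time, event, ties=ties)

    rows = []
    summary = fit.summary()
    ref_inserted: set[str] = set()
    for name in summary.index:
        factor = name.split(":")[0] if ":" in name else None
        if factor and factor in (categorical or {}) and factor not in ref_inserted:
            rows.append(
                {
                    "covariate": f"{factor}:{(categorical or {})[factor]} (Reference)",
                    "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                }
            )
            ref_inserted.add(factor)
        rows.append(
            {
                "covariate": name,
                "hr": summary.loc[name, "hr"],
                "ci_low": summary.loc[name, "ci_low"],
                "ci_high": summary.loc[name, "ci_high"],
                "p": summary.loc[name, "p"],
            }
        )
    return fit, pd.DataFrame(rows).set_index("covariate")


def write_model(model: RiskModel, path) -> None:
    """Persist the panel model as TSV with ``#`` metadata lines; round-trips exactly."""
    with open(path, "w") as handle:
        handle.write(f"# ties\t{model.cox.ties}\n")
        handle.write(f"# n\t{model.cox.n}\n")
        handle.write(f"# events\t{model.cox.n_events}\n")
        handle.write("probe_id\tcoefficient\tse\n")
        for probe, coef, se in zip(model.panel, model.cox.coef, model.cox.se):
            handle.write(f"{probe}\t{float(coef)!r}\t{float(se)!r}\n")


def read_model(path) -> tuple[list[str], np.ndarray, np.ndarray, dict]:
    """Read a model file back: (panel, coefficients, ses, metadata)."""
    meta: dict = {}
    panel: list[str] = []
    coefs: list[float] = []
    ses: list[float] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, value = line[1:].strip().split("\t")
                meta[key] = value
            elif line.startswith("probe_id") or not line:
                continue
            else:
                probe, coef, se = line.split("\t")
                panel.append(probe)
                coefs.append(float(coef))
                ses.append(float(se))
    return panel, np.array(coefs), np.array(ses), meta


def model_from_file(path) -> RiskModel:
    """Rebuild a scoring-capable RiskModel from a persisted model file."""
    panel, coefs, ses, meta = read_model(path)
    fit = CoxFit(
        names=panel,
        coef=coefs,
        se=ses,
        loglik=float("nan"),
        loglik_null=float("nan"),
        ties=meta.get("ties", "efron"),
        n=int(meta.get("n", 0)),
        n_events=int(meta.get("events", 0)),
        converged=True,
        score_norm=float("nan"),
    )
    return RiskModel(panel=panel, cox=fit, scores=pd.Series(dtype=float))
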