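"""Stage 1 of the cascade: tumour/normal differential methylation (paired Δβ).

β values are methylation ratios in [0, 1] held as a probes × samples pandas
DataFrame (missing entries as NaN). The screen removes any probe with a
missing value, computes per-patient Δβ = β_tumour − β_normal over the paired
cohort, tests the difference with a two-sided paired t test, and keeps
hypermethylated probes (mean Δβ strictly above the threshold, default 0.2).
No multiple-testing correction is applied at this stage; downstream reports
flag that explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_MIN_MEAN_DELTA = 0.2


@dataclass(frozen=True)
class PairedCohort:
    """(tumour sample, matched normal sample) links derived from the clinic table."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        tumors = [t for t, _ in self.pairs]
        if len(set(tumors)) != len(tumors):
            raise ValueError("each tumour sample may appear in at most one pair")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def tumor_ids(self) -> list[str]:
        return [t for t, _ in self.pairs]

    @property
    def normal_ids(self) -> list[str]:
        return [n for _, n in self.pairs]


def paired_cohort_from_clinical(clinical: pd.DataFrame) -> PairedCohort:
    """Derive tumour/normal pairs by patient_id from a clinical table.

    Expects columns ``sample_id``, ``patient_id`` and ``tissue`` (values
    ``tumor``/``normal``). Patients lacking either tissue are skipped.
    """
    pairs = []
    for patient_id, group in clinical.groupby("patient_id", sort=True):
        tumors = group.loc[group["tissue"] == "tumor", "sample_id"]
        normals = group.loc[group["tissue"] == "normal", "sample_id"]
        if len(tumors) >= 1 and len(normals) >= 1:
            pairs.append((tumors.iloc[0], normals.iloc[0]))
    return PairedCohort(tuple(pairs))


def drop_missing_probes(beta: pd.DataFrame) -> pd.DataFrame:
    """Remove every probe (row) with at least one missing β value."""
    kept = beta.dropna(axis=0, how="any")
    if kept.empty and not beta.empty:
        log.warning("all %d probes had missing values; empty matrix remains", len(beta))
    return kept


@dataclass
class DeltaBetaResult:
    """Per-probe paired Δβ evidence.

    ``delta`` is a probes × pairs DataFrame of per-patient Δβ (columns are the
    tumour sample ids of the pairs); ``stats`` has one row per probe with
    ``mean_delta_beta``, ``t_statistic`` and ``t_p`` (NaN where the paired t
    test is undefined: fewer than two pairs or zero variance).
    """

    delta: pd.DataFrame
    stats: pd.DataFrame


def paired_delta_beta(beta: pd.DataFrame, cohort: PairedCohort) -> DeltaBetaResult:
    """Per-probe, per-pair Δβ = β_tumour − β_normal plus a two-sided paired t test."""
    if len(cohort) == 0:
        raise ValueError("paired cohort is empty")
    missing = [s for s in cohort.tumor_ids + cohort.normal_ids if s not in beta.columns]
    if missing:
        raise KeyError(f"samples absent from the beta matrix: {missing[:5]}")

    tumor = beta[cohort.tumor_ids].to_numpy(dtype=float)
    normal = beta[cohort.normal_ids].to_numpy(dtype=float)
    delta = tumor - normal
    # guard: pairs with a missing member do not contribute (cannot occur after
    # drop_missing_probes, but Δβ is defined for partially observed rows too)
    mean_delta = np.nanmean(delta, axis=1)

    n_obs = np.sum(~np.isnan(delta), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # ddof on single-pair rows
        sd = np.nanstd(delta, axis=1, ddof=1)
        t_stat = mean_delta / (sd / np.sqrt(n_obs))
    t_stat = np.where((n_obs >= 2) & (sd > 0), t_stat, np.nan)
    t_p = np.where(
        np.isnan(t_stat),
        np.nan,
        2.0 * stats.t.sf(np.abs(t_stat), df=np.maximum(n_obs - 1, 1)),
    )

    delta_df = pd.DataFrame(delta, index=beta.index, columns=cohort.tumor_ids)
    stats_df = pd.DataFrame(
        {
            "mean_delta_beta": mean_delta,
            "t_statistic": t_stat,
            "t_p": t_p,
            "n_pairs": n_obs,
        },
        index=beta.index,
    )
    return DeltaBetaResult(delta=delta_df, stats=stats_df)


def filter_hypermethylated(
    result: DeltaBetaResult, min_mean_delta: float = DEFAULT_MIN_MEAN_DELTA
) -> list[str]:
    """Probes whose mean Δβ is strictly greater than the threshold (hypermethylated)."""
    mask = result.stats["mean_delta_beta"] > min_mean_delta
    return list(result.stats.index[mask])
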