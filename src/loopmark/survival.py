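"""Stage 2 of the cascade and shared survival machinery.

Median dichotomisation, the Kaplan-Meier product-limit estimator, the
two-group log-rank test, and the per-probe survival screen. The screen splits
patients at the median of a per-probe methylation summary (tumour β or paired
Δβ), compares the two survival curves with the log-rank test, and by default
additionally requires the high-methylation group to have the worse outcome
(markers are selected for hypermethylation-associated poor survival).

The log-rank statistic is the standard one: at each distinct event time t,
the observed minus hypergeometric-expected events in group A are accumulated,
χ² = (Σ(O−E))² / ΣV with V the hypergeometric variance, and p is the 1-df
chi-square upper tail (no continuity correction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass(frozen=True)
class LogrankResult:
    """Two-group log-rank outcome; ``o_minus_e_a`` carries the direction."""

    chi_square: float
    p_value: float
    n_per_group: tuple[int, int]
    o_minus_e_a: float
    defined: bool = True


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve: S(0) = 1, nonincreasing."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


class DegenerateSplitError(ValueError):
    """All values equal: a median split cannot form two groups."""


def median_dichotomize(values: pd.Series) -> tuple[list[str], list[str]]:
    """Split sample ids into (high, low) at the median; ties go to LOW.

    "High" means strictly above the median, so the rule is deterministic under
    ties. Raises :class:`DegenerateSplitError` on a constant vector.
    """
    values = values.dropna()
    if len(values) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    if values.nunique() == 1:
        raise DegenerateSplitError("degenerate split: all values equal")
    median = float(values.median())
    high = list(values.index[values > median])
    low = list(values.index[values <= median])
    return high, low


def _to_arrays(records: Iterable[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    records = list(records)
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit curve (lifelines under the hood)."""
    if len(records) == 0:
        raise ValueError("need >= 1 record")
    times, events = _to_arrays(records)
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    table = fitter.event_table
    grid = table.index.to_numpy(dtype=float)
    surv = fitter.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk)


def logrank_arrays(
    time_a: np.ndarray,
    event_a: np.ndarray,
    time_b: np.ndarray,
    event_b: np.ndarray,
) -> LogrankResult:
    """Two-group log-rank test on raw time/event arrays."""
    time_a = np.asarray(time_a, dtype=float)
    time_b = np.asarray(time_b, dtype=float)
    event_a = np.asarray(event_a, dtype=int)
    event_b = np.asarray(event_b, dtype=int)
    if time_a.size == 0 or time_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if event_a.sum() + event_b.sum() == 0:
        raise ValueError("need >= 1 observed event overall")

    all_times = np.concatenate([time_a, time_b])
    all_events = np.concatenate([event_a, event_b])
    in_a = np.concatenate([np.ones_like(time_a), np.zeros_like(time_b)]).astype(bool)

    event_times = np.unique(all_times[all_events == 1])
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = all_times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = (all_times == t) & (all_events == 1)
        d = dying.sum()
        d_a = (dying & in_a).sum()
        expected_a = d * n_a / n
        o_minus_e += d_a - expected_a
        if n > 1:
            variance += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)

    n_per_group = (int(time_a.size), int(time_b.size))
    if variance <= 0.0:
        return LogrankResult(
            chi_square=float("nan"),
            p_value=float("nan"),
            n_per_group=n_per_group,
            o_minus_e_a=o_minus_e,
            defined=False,
        )
    chi_square = o_minus_e**2 / variance
    p_value = float(stats.chi2.sf(chi_square, df=1))
    return LogrankResult(
        chi_square=float(chi_square),
        p_value=p_value,
        n_per_group=n_per_group,
        o_minus_e_a=float(o_minus_e),
    )


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank test on record lists."""
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    return logrank_arrays(ta, ea, tb, eb)


def survival_screen(
    values: pd.DataFrame,
    records: Sequence[SurvivalRecord],
    alpha: float = DEFAULT_ALPHA,
    directional: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Per-probe median-split log-rank screen.

    ``values`` is a probes × samples DataFrame of the quantity to split on
    (tumour β or paired Δβ); ``records`` supplies survival for those samples.
    Returns the retained probe ids and a per-probe results table. With
    ``directional=True`` (marker-selection mode) a probe is retained only if
    its HIGH-methylation group has the worse outcome (more deaths than
    expected under the null, O_high − E_high > 0) in addition to p < alpha.
    Probes whose split is degenerate are dropped with a warning.
    """
    by_id = {r.sample_id: r for r in records}
    shared = [s for s in values.columns if s in by_id]
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between values and survival")
    rows = []
    kept: list[str] = []
    for probe_id, row in values[shared].iterrows():
        try:
            high, low = median_dichotomize(row)
        except DegenerateSplitError:
            log.warning("probe %s: degenerate median split, dropped", probe_id)
            rows.append((probe_id, np.nan, np.nan, np.nan, False))
            continue
        result = logrank_test(
            [by_id[s] for s in high], [by_id[s] for s in low]
        )
        high_worse = result.o_minus_e_a > 0
        retain = (
            result.defined
            and result.p_value < alpha
            and (high_worse or not directional)
        )
        if retain:
            kept.append(probe_id)
        rows.append(
            (probe_id, result.chi_square, result.p_value, result.o_minus_e_a, retain)
        )
    table = pd.DataFrame(
        rows, columns=["probe_id", "chi_square", "logrank_p", "o_minus_e_high", "retained"]
    ).set_index("probe_id")
    return kept, table


def records_from_clinical(
    clinical: pd.DataFrame, tissue: str = "tumor"
) -> list[SurvivalRecord]:
    """Survival records for one tissue's samples from the clinical table."""
    subset = clinical[clinical["tissue"] == tissue].dropna(subset=["time", "event"])
    return [
        SurvivalRecord(row["sample_id"], float(row["time"]), int(row["event"]))
        for _, row in subset.iterrows()
    ]
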