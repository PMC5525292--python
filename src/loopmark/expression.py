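"""Stages 3-4 of the cascade: methylation-expression correlation and the
demethylation-response DEG filter.

Stage 3 keeps loop-defined CpG-gene pairs whose methylation is strongly
negatively correlated with target expression (Pearson R strictly below the
threshold, default -0.35), computed over the tumour samples shared between
the β and expression matrices. Stage 4 keeps pairs whose target gene is
up-regulated (fold change strictly above 1.5 by default) after treatment with
a demethylating agent; down-regulated genes can be admitted too via
``two_sided=True``. Fold change is the ratio of replicate means on the linear
scale; matrices declaring a log2 scale are exponentiated first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pairing import CpGGenePair

log = logging.getLogger(__name__)

DEFAULT_MAX_R = -0.35
DEFAULT_MIN_FC = 1.5
VALID_SCALES = ("linear", "log2")


@dataclass(frozen=True)
class CorrelationRecord:
    probe_id: str
    gene_id: str
    pearson_r: float
    n_samples: int


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    fold_change: float
    is_deg: bool


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def correlation_screen(
    pairs: list[CpGGenePair],
    beta: pd.DataFrame,
    expr: pd.DataFrame,
    max_r: float = DEFAULT_MAX_R,
) -> tuple[list[CpGGenePair], list[CorrelationRecord]]:
    """Keep pairs with Pearson r strictly below ``max_r``; r is recorded on each pair.

    Samples are intersected between the two matrices (tumour samples only by
    construction of the inputs); fewer than 3 shared samples is fatal.
    """
    shared = [s for s in beta.columns if s in set(expr.columns)]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} samples shared between beta and expression matrices"
        )
    records: list[CorrelationRecord] = []
    kept: list[CpGGenePair] = []
    for pair in pairs:
        if pair.probe_id not in beta.index or pair.gene_id not in expr.index:
            log.warning(
                "pair (%s, %s) missing from matrices; dropped",
                pair.probe_id,
                pair.gene_id,
            )
            continue
        x = beta.loc[pair.probe_id, shared].to_numpy(dtype=float)
        y = expr.loc[pair.gene_id, shared].to_numpy(dtype=float)
        try:
            r = pearson_r(x, y)
        except ValueError:
            log.warning(
                "pair (%s, %s): correlation undefined (constant vector); dropped",
                pair.probe_id,
                pair.gene_id,
            )
            continue
        records.append(CorrelationRecord(pair.probe_id, pair.gene_id, r, len(shared)))
        if r < max_r:
            pair.pearson_r = r
            kept.append(pair)
    return kept, records


def _linear_means(matrix: pd.DataFrame, scale: str) -> pd.Series:
    if scale not in VALID_SCALES:
        raise ValueError(f"scale must be one of {VALID_SCALES}, got {scale!r}")
    if scale == "log2":
        # exponentiate first, then average: the ratio of arithmetic linear
        # means is invariant to whether the data arrive as log2 or linear
        return np.exp2(matrix).mean(axis=1)
    if (matrix < 0).any().any():
        raise ValueError("negative values in a linear-scale expression matrix")
    return matrix.mean(axis=1)


def foldchange_degs(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    min_fc: float = DEFAULT_MIN_FC,
    treated_scale: str = "log2",
    control_scale: str = "log2",
    two_sided: bool = False,
) -> list[DEGResult]:
    """Per-gene fold change treated/control and the DEG call (FC strictly > min_fc).

    With ``two_sided=True`` a gene with FC < 1/min_fc (down-regulation) is
    also a DEG. Genes with a nonpositive control mean on the linear scale get
    an undefined (NaN) fold change and are never DEGs.
    """
    if not treated.index.equals(control.index):
        common = treated.index.intersection(control.index)
        if len(common) == 0:
            raise ValueError("treated and control matrices share no genes")
        treated, control = treated.loc[common], control.loc[common]
    mean_treated = _linear_means(treated, treated_scale)
    mean_control = _linear_means(control, control_scale)
    results: list[DEGResult] = []
    for gene_id in treated.index:
        c = float(mean_control.loc[gene_id])
        t = float(mean_treated.loc[gene_id])
        if c <= 0:
            log.warning("gene %s: nonpositive control mean, fold change undefined", gene_id)
            results.append(DEGResult(gene_id, float("nan"), False))
            continue
        fc = t / c
        is_deg = fc > min_fc or (two_sided and min_fc > 0 and fc < 1.0 / min_fc)
        results.append(DEGResult(gene_id, fc, bool(is_deg)))
    return results


def demethylation_screen(
    pairs: list[CpGGenePair], degs: list[DEGResult]
) -> list[CpGGenePair]:
    """Keep pairs whose target gene is a DEG; genes absent from the assay drop."""
    deg_by_gene = {d.gene_id: d for d in degs}
    kept: list[CpGGenePair] = []
    n_absent = 0
    for pair in pairs:
        deg = deg_by_gene.get(pair.gene_id)
        if deg is None:
            n_absent += 1
            log.warning(
                "pair (%s, %s): gene absent from the assay matrices; dropped",
                pair.probe_id,
                pair.gene_id,
            )
            continue
        pair.deg_flag = deg.is_deg
        pair.extras["fold_change"] = deg.fold_change
        if deg.is_deg:
            kept.append(pair)
    if n_absent:
        log.info("%d pairs dropped: target gene not on the assay platform", n_absent)
    return kept
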