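"""End-to-end orchestration of the marker-selection cascade.

Stage order follows the discovery scheme literally: missing-value removal,
loop-overlap preselection, the paired-Δβ hypermethylation filter and the
median-split log-rank survival filter on probes, then loop pairing, the
methylation-expression correlation filter and the demethylation-response DEG
filter on pairs. Probe-level filters run before pairing (order affects the
logged counts only, not the final set). Each stage's input/output counts are
recorded; a stage that empties the candidate set terminates the run cleanly
with a stage-attributed message in the report, not a crash.
"""

from __future__ import annotations

import json
import logging
import os
import time as _time
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import io as lio
from .expression import (
    DEFAULT_MAX_R,
    DEFAULT_MIN_FC,
    correlation_screen,
    demethylation_screen,
    foldchange_degs,
)
from .intervals import CpGProbe, GeneAnnotation, IntervalIndex
from .methylation import (
    DEFAULT_MIN_MEAN_DELTA,
    drop_missing_probes,
    filter_hypermethylated,
    paired_cohort_from_clinical,
    paired_delta_beta,
)
from .pairing import ChromatinInteraction, CpGGenePair, pair_cpgs_to_targets
from .riskmodel import RiskModel, evaluate_panel, fit_risk_model, multivariate_cox
from .survival import DEFAULT_ALPHA, records_from_clinical, survival_screen

log = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds and flags of one cascade run (defaults are the published cutoffs)."""

    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    min_mean_delta: float = DEFAULT_MIN_MEAN_DELTA
    survival_alpha: float = DEFAULT_ALPHA
    max_r: float = DEFAULT_MAX_R
    min_fc: float = DEFAULT_MIN_FC
    min_support: int = 1
    directional: bool = True
    deg_two_sided: bool = False
    split_on: str = "tumor_beta"  # or "delta_beta" (paired-cohort mode)
    ties: str = "efron"
    drop_inter_chromosomal: bool = False

    def validate(self) -> None:
        if self.split_on not in ("tumor_beta", "delta_beta"):
            raise ValueError("split_on must be 'tumor_beta' or 'delta_beta'")
        if not 0 <= self.survival_alpha <= 1:
            raise ValueError("survival_alpha must be in [0, 1]")
        if self.min_fc <= 0:
            raise ValueError("min_fc must be positive")


@dataclass
class StageLog:
    stage: str
    n_in: int
    n_out: int
    seconds: float


@dataclass
class MarkerPanel:
    """The final pair list with full per-stage evidence, grouped by locus."""

    pairs: list[CpGGenePair]
    groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return sorted({p.probe_id for p in self.pairs})

    @property
    def pair_keys(self) -> set[tuple[str, str]]:
        return {p.key() for p in self.pairs}


@dataclass
class CascadeResult:
    panel: MarkerPanel
    stages: list[StageLog]
    emptied_at: str | None
    delta_stats: pd.DataFrame | None = None
    survival_table: pd.DataFrame | None = None
    config: PipelineConfig | None = None


def run_cascade(
    probes: list[CpGProbe],
    genes: list[GeneAnnotation],
    interactions: list[ChromatinInteraction],
    beta: pd.DataFrame,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    treated: pd.DataFrame,
    control: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> CascadeResult:
    """Run the four-stage filter cascade in memory and return the marker panel."""
    config = config or PipelineConfig()
    config.validate()
    stages: list[StageLog] = []

    def _log(stage: str, n_in: int, n_out: int, t0: float) -> None:
        entry = StageLog(stage, n_in, n_out, round(_time.perf_counter() - t0, 4))
        stages.append(entry)
        log.info("stage %-22s %6d -> %6d (%.2fs)", stage, n_in, n_out, entry.seconds)

    def _empty(stage: str, **extra) -> CascadeResult:
        log.warning("candidate set emptied at stage %r", stage)
        return CascadeResult(
            panel=MarkerPanel(pairs=[]), stages=stages, emptied_at=stage,
            config=config, **extra,
        )

    # stage 0: missing-value removal
    t0 = _time.perf_counter()
    beta_full = drop_missing_probes(beta)
    _log("drop_missing_probes", len(beta), len(beta_full), t0)
    if beta_full.empty:
        return _empty("drop_missing_probes")

    # stage 1: loop-overlap preselection (probes inside any PET anchor)
    t0 = _time.perf_counter()
    kept_interactions = [
        pet for pet in interactions
        if pet.support >= config.min_support
        and not (config.drop_inter_chromosomal and pet.inter_chromosomal)
    ]
    anchor_index = IntervalIndex.build(
        anchor for pet in kept_interactions for anchor in (pet.anchor1, pet.anchor2)
    )
    probe_by_id = {p.probe_id: p for p in probes}
    loop_probes = [
        pid for pid in beta_full.index
        if pid in probe_by_id and anchor_index.query(probe_by_id[pid].interval())
    ]
    _log("loop_overlap", len(beta_full), len(loop_probes), t0)
    if not loop_probes:
        return _empty("loop_overlap")
    beta_loop = beta_full.loc[loop_probes]

    # stage 2: paired delta-beta hypermethylation filter
    t0 = _time.perf_counter()
    cohort = paired_cohort_from_clinical(clinical)
    delta_result = paired_delta_beta(beta_loop, cohort)
    hyper = filter_hypermethylated(delta_result, config.min_mean_delta)
    _log("delta_beta_filter", len(loop_probes), len(hyper), t0)
    if not hyper:
        return _empty("delta_beta_filter", delta_stats=delta_result.stats)

    # stage 3: survival screen
    t0 = _time.perf_counter()
    records = records_from_clinical(clinical, tissue="tumor")
    if config.split_on == "delta_beta":
        split_values = delta_result.delta.loc[hyper]
    else:
        tumor_ids = [r.sample_id for r in records]
        split_values = beta_loop.loc[hyper, [c for c in beta_loop.columns if c in set(tumor_ids)]]
    surviving, survival_table = survival_screen(
        split_values, records, alpha=config.survival_alpha, directional=config.directional
    )
    _log("survival_filter", len(hyper), len(surviving), t0)
    if not surviving:
        return _empty(
            "survival_filter", delta_stats=delta_result.stats, survival_table=survival_table
        )

    # stage 4: loop pairing of the surviving probes
    t0 = _time.perf_counter()
    surviving_probes = [probe_by_id[pid] for pid in surviving if pid in probe_by_id]
    pairs = pair_cpgs_to_targets(
        kept_interactions,
        surviving_probes,
        genes,
        upstream=config.promoter_upstream,
        downstream=config.promoter_downstream,
        min_support=config.min_support,
        drop_inter_chromosomal=config.drop_inter_chromosomal,
    )
    for pair in pairs:
        pair.delta_beta = float(delta_result.stats.loc[pair.probe_id, "mean_delta_beta"])
        pair.logrank_p = float(survival_table.loc[pair.probe_id, "logrank_p"])
    _log("cpg_target_pairing", len(surviving), len(pairs), t0)
    if not pairs:
        return _empty(
            "cpg_target_pairing", delta_stats=delta_result.stats, survival_table=survival_table
        )

    # stage 5: methylation-expression correlation filter
    t0 = _time.perf_counter()
    tumor_beta = beta_full[[c for c in beta_full.columns if c in set(expression.columns)]]
    corr_pairs, _records = correlation_screen(pairs, tumor_beta, expression, max_r=config.max_r)
    _log("correlation_filter", len(pairs), len(corr_pairs), t0)
    if not corr_pairs:
        return _empty(
            "correlation_filter", delta_stats=delta_result.stats, survival_table=survival_table
        )

    # stage 6: demethylation-response DEG filter
    t0 = _time.perf_counter()
    degs = foldchange_degs(
        treated, control, min_fc=config.min_fc,
        treated_scale="log2", control_scale="log2",
        two_sided=config.deg_two_sided,
    )
    final_pairs = demethylation_screen(corr_pairs, degs)
    _log("deg_filter", len(corr_pairs), len(final_pairs), t0)
    if not final_pairs:
        return _empty(
            "deg_filter", delta_stats=delta_result.stats, survival_table=survival_table
        )

    panel = MarkerPanel(pairs=final_pairs)
    panel.groups = group_panel(panel, kept_interactions, probe_by_id)
    return CascadeResult(
        panel=panel,
        stages=stages,
        emptied_at=None,
        delta_stats=delta_result.stats,
        survival_table=survival_table,
        config=config,
    )


def group_panel(
    panel: MarkerPanel,
    interactions: list[ChromatinInteraction],
    probe_by_id: dict[str, CpGProbe],
) -> dict[str, list[str]]:
    """Group panel CpGs by shared genomic locus.

    Two CpGs belong to one group when they share a supporting-PET anchor that
    overlaps their own positions (connected components over probe-anchor
    containment). Group ids are deterministic: ``grp1``, ``grp2``, ... ordered
    by the leftmost probe position in the group.
    """
    if not panel.pairs:
        return {}
    pet_by_id = {pet.pet_id: pet for pet in interactions}
    probe_ids = panel.probe_ids
    anchors_of: dict[str, set[tuple[str, int, int]]] = {}
    for pair in panel.pairs:
        probe = probe_by_id[pair.probe_id]
        for pet_id in pair.pet_ids:
            pet = pet_by_id.get(pet_id)
            if pet is None:
                continue
            for anchor in (pet.anchor1, pet.anchor2):
                if anchor.chrom == probe.chrom and anchor.start <= probe.pos < anchor.end:
                    anchors_of.setdefault(pair.probe_id, set()).add(
                        (anchor.chrom, anchor.start, anchor.end)
                    )
    # union-find over shared anchors
    parent = {pid: pid for pid in probe_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    anchor_owner: dict[tuple[str, int, int], str] = {}
    for pid in probe_ids:
        for anchor in sorted(anchors_of.get(pid, ())):
            if anchor in anchor_owner:
                ra, rb = find(anchor_owner[anchor]), find(pid)
                if ra != rb:
                    parent[rb] = ra
            else:
                anchor_owner[anchor] = pid
    components: dict[str, list[str]] = {}
    for pid in probe_ids:
        components.setdefault(find(pid), []).append(pid)
    ordered = sorted(
        components.values(), key=lambda ids: min(probe_by_id[p].pos for p in ids)
    )
    return {f"grp{i + 1}": sorted(ids) for i, ids in enumerate(ordered)}


def write_report(
    result: CascadeResult,
    outdir,
    seed: int | None = None,
    risk_model: RiskModel | None = None,
    evaluation=None,
    multivariate: pd.DataFrame | None = None,
) -> str:
    """Persist a machine-readable (JSON) plus human-readable (text) report."""
    os.makedirs(outdir, exist_ok=True)
    payload = {
        "version": __version__,
        "seed": seed,
        "config": asdict(result.config) if result.config else None,
        "stage_order": [s.stage for s in result.stages],
        "stages": [asdict(s) for s in result.stages],
        "emptied_at": result.emptied_at,
        "n_final_pairs": len(result.panel.pairs),
        "groups": result.panel.groups,
        "warnings": [
            "no multiple-testing correction applied at the delta-beta or survival stages (raw p-values)",
        ],
    }
    if evaluation is not None:
        payload["panel_logrank_p"] = evaluation.logrank.p_value
        payload["panel_logrank_chi_square"] = evaluation.logrank.chi_square
        payload["high_risk_group_is_worse"] = evaluation.high_is_worse
    if multivariate is not None:
        payload["multivariate"] = json.loads(multivariate.to_json(orient="index"))
    json_path = os.path.join(outdir, "report.json")
    with open(json_path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)

    text_path = os.path.join(outdir, "report.txt")
    with open(text_path, "w") as handle:
        handle.write("loopmark cascade report\n=======================\n\n")
        if result.config:
            handle.write("thresholds:\n")
            for key, value in asdict(result.config).items():
                handle.write(f"  {key}: {value}\n")
        handle.write("\nstage counts:\n")
        for s in result.stages:
            handle.write(f"  {s.stage:<22} {s.n_in:>7} -> {s.n_out:>7}\n")
        if result.emptied_at:
            handle.write(f"\ncandidate set emptied at stage: {result.emptied_at}\n")
        handle.write(f"\nfinal pairs: {len(result.panel.pairs)}\n")
        for pair in result.panel.pairs:
            handle.write(
                f"  {pair.probe_id} -> {pair.gene_id} "
                f"(dBeta={pair.delta_beta:.3f}, logrank_p={pair.logrank_p:.3g}, "
                f"r={pair.pearson_r:.3f}, FC={pair.extras.get('fold_change', float('nan')):.2f})\n"
            )
        if result.panel.groups:
            handle.write("\nlocus groups:\n")
            for gid, members in result.panel.groups.items():
                handle.write(f"  {gid}: {', '.join(members)}\n")
        if evaluation is not None:
            handle.write(
                f"\npanel risk-score evaluation: chi2={evaluation.logrank.chi_square:.3f}, "
                f"p={evaluation.logrank.p_value:.3g}, high RS worse={evaluation.high_is_worse}\n"
            )
        if multivariate is not None:
            handle.write("\nmultivariate Cox (HR, 95% CI, p):\n")
            handle.write(multivariate.to_string())
            handle.write("\n")
        handle.write(
            "\nnote: raw p-values; no multiple-testing correction at screening stages\n"
        )
    return json_path


def run_pipeline(
    fixture_dir,
    outdir,
    config: PipelineConfig | None = None,
    with_risk_model: bool = True,
    seed: int | None = None,
) -> CascadeResult:
    """File-level entry point: read a fixture directory, run the cascade,
    fit/evaluate the risk panel, and persist all intermediate artifacts."""
    bundle = lio.read_fixtures(fixture_dir)
    config = config or PipelineConfig()
    result = run_cascade(
        probes=bundle.probes,
        genes=bundle.genes,
        interactions=bundle.interactions,
        beta=bundle.beta,
        expression=bundle.expression,
        clinical=bundle.clinical,
        treated=bundle.treated,
        control=bundle.control,
        config=config,
    )
    os.makedirs(outdir, exist_ok=True)
    lio.write_pairs(result.panel.pairs, os.path.join(outdir, "panel.tsv"))
    if result.delta_stats is not None:
        result.delta_stats.to_csv(os.path.join(outdir, "delta_beta.tsv"), sep="\t")
    if result.survival_table is not None:
        result.survival_table.to_csv(os.path.join(outdir, "survival_screen.tsv"), sep="\t")

    risk_model = evaluation = None
    if with_risk_model and result.panel.pairs:
        from .riskmodel import write_model
        from .survival import records_from_clinical

        records = records_from_clinical(bundle.clinical, tissue="tumor")
        beta_full = drop_missing_probes(bundle.beta)
        risk_model = fit_risk_model(
            beta_full, result.panel.probe_ids, records, ties=config.ties
        )
        evaluation = evaluate_panel(risk_model.scores, records)
        write_model(risk_model, os.path.join(outdir, "model.tsv"))
    write_report(result, outdir, seed=seed, risk_model=risk_model, evaluation=evaluation)
    return result
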