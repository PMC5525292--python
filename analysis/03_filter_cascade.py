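#!/usr/bin/env python
"""Run the four-stage marker filter cascade on the discovery cohort.

Stages: missing-probe removal -> loop-overlap preselection -> paired
tumour/normal delta-beta > 0.2 -> median-split log-rank p < 0.05 (high
methylation worse) -> loop pairing -> Pearson R < -0.35 against target
expression -> fold change > 1.5 after simulated demethylation. Writes the
final panel, per-stage tables and the run report under results/cascade/.
"""

import os

from loopmark.pipeline import PipelineConfig, run_pipeline

HERE = os.path.dirname(__file__)
RESULTS = os.path.join(HERE, "..", "results")

result = run_pipeline(
    os.path.join(HERE, "..", "scratch", "cohorts", "discovery"),
    os.path.join(RESULTS, "cascade"),
    config=PipelineConfig(),
    seed=101,
)

print("stage counts:")
for s in result.stages:
    print(f"  {s.stage:<22} {s.n_in:>6} -> {s.n_out:>6}")
print(f"\nfinal panel: {len(result.panel.pairs)} CpG-gene pairs")
for pair in result.panel.pairs:
    print(
        f"  {pair.probe_id} -> {pair.gene_id}: "
        f"mean dBeta {pair.delta_beta:.3f}, log-rank p {pair.logrank_p:.2e}, "
        f"R {pair.pearson_r:.3f}, FC {pair.extras['fold_change']:.2f}"
    )
print(f"locus groups: {result.panel.groups}")
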