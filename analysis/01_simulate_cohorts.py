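#!/usr/bin/env python
"""Generate the discovery and validation cohorts used by the downstream steps.

Writes two seeded synthetic cohorts (fixtures in every external file format)
under scratch/cohorts/ (bulky, regenerable at will). The discovery cohort is used for marker selection and
model fitting; the validation cohort only ever sees frozen coefficients.
"""

import os

from loopmark.io import write_fixtures
from loopmark.simulate import GeneratorConfig, generate

OUT = os.path.join(os.path.dirname(__file__), "..", "scratch", "cohorts")

# both cohorts sample patients from the same underlying biology: identical
# genome geometry and planted modules (structure_seed), independent patients
for name, seed in (("discovery", 101), ("validation", 202)):
    bundle = generate(GeneratorConfig(seed=seed, structure_seed=101))
    outdir = os.path.join(OUT, name)
    write_fixtures(bundle, outdir)
    tumors = bundle.clinical[bundle.clinical["tissue"] == "tumor"]
    print(
        f"{name}: seed {seed} -> {outdir}\n"
        f"  {len(bundle.probes)} probes, {len(bundle.genes)} genes, "
        f"{len(bundle.interactions)} PETs, {len(tumors)} tumours "
        f"({bundle.config.n_paired_normals} with paired normals), "
        f"{len(bundle.truth)} planted CpG-gene modules, "
        f"censoring {1 - tumors['event'].mean():.2f}"
    )
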