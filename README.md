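# loopmark

Discovery of DNA-methylation markers that regulate **distant** genes through
chromatin loops, and their combination into a prognostic risk-score panel.

Most methylation markers are promoter CpGs scored against the nearest gene.
`loopmark` implements the loop-aware alternative: RNA-Pol-II ChIA-PET
interactions define which distal CpGs physically contact which gene
promoters ("CpGs that overlap the anchor opposite a promoter-anchored end"),
and a candidate CpG→gene pair becomes a marker only if it passes a
four-stage evidence cascade:

1. paired tumour/normal hypermethylation: mean Δβ > 0.2
   (Δβ = β_tumour − β_normal per patient);
2. survival association: median-split log-rank p < 0.05, with the
   high-methylation group faring worse;
3. methylation–expression coupling over the loop: Pearson R < −0.35;
4. demethylation response: target-gene fold change > 1.5 after a
   5-aza-C-style treatment.

Surviving CpGs are combined by a Cox proportional-hazards model into a
per-patient risk score RS = Σᵢ βᵢᶜᵒˣ·βᵢᵐᵉᵗʰ, evaluated by median split +
log-rank within each cohort, validated on independent cohorts with frozen
coefficients, and compared against clinical covariates in a multivariate
Cox model (HR, 95% CI, Wald p, reference-coded subtype factor).

Because the real inputs of such a study are controlled-access or bulky
(tumour methylomes, RNA-seq, ChIA-PET), the package ships a first-class
**synthetic cohort generator** that plants long-range CpG–gene modules with
known Δβ, ρ, and hazard effects and emits every input format the pipeline
reads, plus the ground truth. All statistical claims in the test suite are
made against this generator. See `docs/methods.md` for the model, its
assumptions, and what the synthetic results do and do not show.

## Worked example

The numbered scripts under `analysis/` run the full study on two seeded
synthetic cohorts (discovery seed 101, validation seed 202, shared planted
biology):

```
python analysis/01_simulate_cohorts.py   # fixtures under scratch/cohorts/
python analysis/02_pair_loops.py
python analysis/03_filter_cascade.py
python analysis/04_risk_model.py
python analysis/05_calibration.py        # 25-run recovery summary
```

`03_filter_cascade.py` prints the per-stage candidate counts and the final
panel (abridged):

```
stage counts:
  drop_missing_probes      1000 ->   1000
  loop_overlap             1000 ->     89
  delta_beta_filter          89 ->     10
  survival_filter            10 ->     10
  cpg_target_pairing         10 ->     10
  correlation_filter         10 ->     10
  deg_filter                 10 ->     10

final panel: 10 CpG-gene pairs
  cg000134 -> G0031: mean dBeta 0.293, log-rank p 1.28e-06, R -0.584, FC 2.54
  ...
```

Reading: of 1,000 probes, 89 sit inside a ChIA-PET anchor; 10 are
hypermethylated in tumours (mean Δβ > 0.2); all 10 pass the survival,
correlation and demethylation filters — exactly the 10 planted modules, with
no false pair. `04_risk_model.py` then fits the panel Cox model and
evaluates the risk score:

```
panel of 10 CpGs; Cox fit on 200 tumours (142 events), ties: efron
discovery:  log-rank chi2 15.64, p 7.64e-05, high RS worse: True
validation (frozen coefficients): log-rank chi2 22.48, p 2.13e-06, high RS worse: True
```

so patients above the median risk score die significantly faster in both
cohorts, and in the multivariate table only the risk score (HR 1.85,
p = 0.0009) — not the null-effect clinical covariates — predicts survival.

The same steps are scriptable through the CLI
(`loopmark simulate | pair | screen-methylation | screen-survival |
link-expression | screen-deg | fit-risk | evaluate | multivariate |
run-all`), e.g.:

```
loopmark simulate --seed 101 --out scratch/cohort
loopmark run-all --fixtures scratch/cohort --out scratch/run
```

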