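# Methods

## The problem and the procedure

Most DNA-methylation cancer markers are chosen from promoter CpGs acting on
the nearest gene. `loopmark` implements the complementary, loop-aware
strategy: candidate markers are *distal* CpGs whose physical contact with a
target-gene promoter is evidenced by RNA-Pol-II ChIA-PET interactions, and a
marker is accepted only if four independent lines of evidence line up. The
pipeline takes BEDPE interactions, an HM450k-style probe manifest, gene
annotation (one TSS per gene), a β-value matrix, an expression matrix,
clinical/survival data and a demethylating-agent (5-aza-C-style) assay, and
runs:

1. **Missing-probe removal.** Any probe with a missing β value in the cohort
   is dropped globally, before every other stage.
2. **Loop overlap.** A promoter is the strand-aware window from 2,000 bp
   upstream to 500 bp downstream of the TSS. Probes are 1-bp intervals
   ([pos, pos+1)); all coordinates are 0-based half-open, overlap means ≥1
   shared bp. Only probes inside some PET anchor continue.
3. **Paired Δβ filter.** Δβ = β_tumour − β_normal per patient over the
   matched-pair cohort; probes with mean Δβ strictly > 0.2
   (hypermethylation) survive. A two-sided paired t test is reported but is
   not a filter. No multiple-testing correction is applied at any screening
   stage (raw p-values); reports state this explicitly.
4. **Survival filter.** Patients are split at the median of a per-probe
   summary (tumour β over the full cohort by default, or paired Δβ); ties go
   to the low group so the split is deterministic. The two-group log-rank
   test (χ² = (Σ(O−E))²/ΣV, hypergeometric variance, 1-df asymptotic upper
   tail, no continuity correction) must give p < 0.05, and by default the
   high-methylation group must have the worse outcome (O_high − E_high > 0),
   matching the hypermethylation-bad marker model. The directionality
   requirement can be disabled for pure significance testing.
5. **Pairing.** Each surviving probe is paired with every gene whose
   promoter overlaps the *opposite* anchor of a PET containing the probe.
   Probes lying inside a promoter are deliberately not excluded: a
   promoter-promoter loop makes each promoter's CpGs candidate regulators of
   the *other* gene, and same-anchor co-location alone never creates a pair.
   Pairs are deduplicated over PETs with all supporting PET ids kept.
6. **Correlation filter.** Pearson r between probe β and target expression
   over the tumour samples shared by both matrices must be strictly below
   −0.35.
7. **Demethylation filter.** The target gene must be up-regulated after
   demethylating treatment: fold change strictly > 1.5, where FC is the
   ratio of arithmetic replicate means on the linear scale (log2 matrices
   are exponentiated entry-wise first, which makes FC independent of the
   declared scale). A two-sided |FC| mode exists behind a flag. Genes absent
   from the assay platform drop their pairs, with a count in the report.

Final CpGs are grouped into loci (connected components of probes sharing a
containing PET anchor) and combined into a **risk-score panel**: a Cox
proportional-hazards model fitted on the continuous β values,
RS_s = Σ_i coef_i·β_{i,s}. Evaluation median-splits RS within the evaluated
cohort and applies the log-rank test. For an independent cohort the
discovery coefficients are **frozen** (no refit) by default — refitting on
the validation cohort would make "independent validation" circular; an
explicit refit mode exists. The multivariate analysis enters dichotomised RS
(high vs. low) as a binary covariate jointly with clinical indicators and
reference-coded dummies of one categorical subtype factor, on complete cases
only, and reports HR, Wald 95% CI (exp(coef ± 1.96·SE)) and two-sided p per
covariate with an explicit Reference row.

## Numerical choices

* **Cox solver.** Newton-Raphson on the partial likelihood, covariates
  centred for conditioning, step-halving with a relative tolerance, score
  convergence |U|∞ < 1e−9 (guaranteed < 1e−6 at acceptance), SEs from the
  inverse observed information. Both Breslow and Efron tie corrections are
  provided (default Efron — dichotomised covariates induce heavy ties); they
  coincide exactly on tie-free data. Monotone likelihood (complete
  separation) is detected two ways: coefficients diverging during iteration,
  and a converged coefficient exceeding 10 in standardised-covariate units.
  Both raise an explicit diagnostic rather than returning a silent result.
  An in-package solver is used because the panel interface needs both tie
  corrections and cheap refits inside simulations; lifelines serves as the
  independent cross-check in the test suite, never as the implementation.
* **Log-rank.** Implemented directly (it is re-evaluated thousands of times
  in null calibrations); cross-checked against lifelines and against a
  10,000-permutation reference in the tests. χ² = 0 ⇒ p = 1; zero total
  variance returns an explicitly flagged undefined result.
* **Kaplan-Meier.** Delegated to lifelines' product-limit estimator.
* **Degenerate inputs.** Constant vectors make the median split, Pearson r
  and the paired t statistic undefined; all three are flagged or raised, not
  silently imputed. Strict inequalities are used at every threshold (a value
  exactly at 0.2 / −0.35 / 1.5 does not pass), and thresholds are monotone:
  raising one never admits a new candidate.

## The synthetic cohort generator

The generator emulates the statistical structure of a tumour/normal
multi-omic study on one synthetic 20-Mb chromosome, with every quantity a
pure function of the seed. Defaults (the study conditions): 300 genes,
1,000 probes, 400 PETs (2-kb anchors), 200 tumours of which 90 have matched
normals, 10 planted CpG-gene modules, hypermethylation shift δ = 0.35,
methylation-expression correlation ρ = −0.6, baseline hazard λ = 0.02
events/month with log-hazard γ = 1.5 per unit mean planted β, 30% censoring,
and a 1.2-log2 demethylation response with 3 replicates at sd 0.3.

Design choices that matter:

* **Loop witness.** Every planted pair gets its own PET with one anchor on
  the probe and the opposite anchor on the promoter, so pairing sensitivity
  is exactly 1 before statistical filtering; the ~390 random PETs create the
  null candidate background.
* **Per-patient severity.** The planted hypermethylation shift is
  δ_i = 2δ·s_i with s_i ~ Beta(0.4, 0.4) shared by all planted probes of a
  patient: one epigenetically silenced locus per tumour, bimodal across
  patients the way β values at silenced promoters are, and the reason a
  single probe's median split is informative about a hazard that depends on
  the *mean* planted β. With an exchangeable per-probe shift, one probe
  would carry only 1/10 of the hazard signal and the survival screen would
  be near powerless at the stated γ and n.
* **Expression coupling.** Planted-gene expression is linear in the probe's
  standardised tumour β with Gaussian noise, scaled so the *Pearson*
  correlation is ρ in expectation (a rank-based copula would attenuate
  Pearson r by ~10% under the bimodal β marginal), then mapped onto a
  nonnegative RPKM-like scale (mean 20–100, sd 10).
* **Survival.** Exponential event times (memoryless, closed-form) with
  independent exponential censoring whose rate is solved by bisection so the
  *expected* censoring fraction equals the configuration under the
  heterogeneous per-patient hazards.
* **Structure vs. patients.** Two RNG streams: `structure_seed` fixes the
  genome geometry, planted modules and per-feature baselines; `seed` draws
  the patients. Two cohorts with equal structure seeds and different seeds
  model discovery and validation sampling from one underlying biology, which
  is what makes frozen-coefficient validation meaningful.
* Clinical covariates (ER/PR/HER2, stage, age, histology, a 4-level PAM50
  factor) are generated with **no** survival effect, so the multivariate
  analysis has a known answer: RS significant, everything else covering
  HR = 1.

What the generator does **not** emulate: HM450k type-I/II probe chemistry,
purity/copy-number confounding, batch effects, realistic genome-wide loop
topology, correlated null probes, or non-proportional hazards. Passing tests
therefore demonstrate correctness of the procedure under its own model
assumptions, not performance on real tumours.

## Problem sizes and calibration

Simulation-based checks use: 1,000-interval instances for index/oracle
equivalence; 1,000 replicates (n = 200, 30% censoring) for log-rank type-I
error; 200 replicates (n = 500) for Cox recovery of a planted log-HR of 1.0;
500–4,000 replicates per filter for null calibration against independently
computed nominal levels; and 50 seeded end-to-end runs at generator defaults
for planted-module recovery, where the target operating point (≥8/10
recovered, ≤2 false pairs, in ≥80% of runs) was confirmed by Monte-Carlo
calibration before being frozen as a regression threshold. The analysis
drivers use 25-run summaries; `scripts/acceptance.py` recomputes the
headline quantities from scratch at 20 end-to-end runs per seed.

## Known limitations

* One TSS per gene_id; multi-transcript promoter models are out of scope.
* No anchor merging or loop-significance modelling: every PET is taken at
  face value (support threshold configurable, default 1).
* Raw p-values at the screening stages, by design of the procedure; the
  report flags the absence of multiple-testing correction.
* Wald CIs only; no profile likelihood, no proportional-hazards diagnostics.
* The survival screen's two modes (tumour-β split over all patients, paired
  Δβ split over the matched cohort) can select different probes at the same
  α; both are exposed and the tumour-β mode is the default.
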