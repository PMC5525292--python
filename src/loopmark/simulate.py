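"""Seeded synthetic multi-omic cohorts with planted long-range CpG-gene modules.

The generator emulates the statistical structure the marker-discovery cascade
assumes, on one synthetic chromosome:

* geometry — genes and CpG probes placed uniformly; every planted (probe,
  gene) pair is witnessed by an emitted PET whose one anchor covers the probe
  and whose opposite anchor covers the gene's promoter (loop-witness
  invariant); the remaining PETs have random anchors and supply the null
  candidate background;
* methylation — normal-tissue β per probe ~ Beta(μ_p·κ, (1−μ_p)·κ); at
  planted probes the tumour β is a fresh normal-level draw plus a per-patient
  hypermethylation shift δ_i = 2δ·s_i with severity s_i ~ Beta(0.4, 0.4)
  (mean shift δ, strongly bimodal across patients, shared by all planted
  probes of a patient — one epigenetically silenced locus per tumour, the way
  co-methylated promoter CpGs behave); elsewhere tumour and normal draws are
  exchangeable;
* expression — the planted gene's expression is linearly coupled to its
  probe's standardised tumour β with correlation ρ (Gaussian noise), mapped
  onto a nonnegative RPKM-like scale; other genes are independent;
* survival — time ~ Exponential(λ·exp(γ·mean planted tumour β)), with
  independent exponential censoring whose rate is solved so the expected
  censoring fraction matches the configuration;
* demethylation assay — log2-scale replicates; planted target genes shift up
  by a configured log2 effect under treatment.

Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .intervals import CpGProbe, GeneAnnotation, GenomicInterval, promoter_of
from .pairing import ChromatinInteraction

CHROM = "chr1"
CHROM_LENGTH = 20_000_000
SEVERITY_A = 0.4  # Beta(a, a) severity factor: bimodal silenced/unsilenced tumours


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    structure_seed: int | None = None  # shared genome/planted-module structure;
                                       # defaults to `seed`. Give two cohorts the
                                       # same structure_seed and different seeds
                                       # to model discovery/validation sampling
                                       # from one underlying biology.
    n_genes: int = 300
    n_probes: int = 1000
    n_pets: int = 400
    n_patients: int = 200
    n_paired_normals: int = 90
    n_planted_pairs: int = 10
    beta_mean_low: float = 0.1      # per-probe baseline methylation mean, lower bound
    beta_mean_high: float = 0.5     # upper bound
    beta_concentration: float = 30.0  # Beta(μκ, (1-μ)κ) concentration κ
    delta: float = 0.35             # mean tumour-normal shift at planted probes
    rho: float = -0.6               # methylation-expression correlation at planted pairs
    baseline_hazard: float = 0.02   # λ, events per month at β = 0
    gamma: float = 1.5              # log-hazard per unit mean planted β
    censoring: float = 0.3          # expected censored fraction
    demeth_log2_shift: float = 1.2  # treated-vs-control log2 shift at planted genes
    n_assay_replicates: int = 3
    assay_noise_sd: float = 0.3     # log2-scale assay noise
    missing_rate: float = 0.0       # fraction of β entries set missing
    anchor_width: int = 2000
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    expr_mean_low: float = 20.0
    expr_mean_high: float = 100.0
    expr_sd: float = 10.0

    def validate(self) -> None:
        counts = (
            self.n_genes, self.n_probes, self.n_pets, self.n_patients,
            self.n_paired_normals, self.n_planted_pairs, self.n_assay_replicates,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not (0 <= self.delta < 1):
            raise ValueError("delta must be in [0, 1)")
        if not (-1 < self.rho <= 0):
            raise ValueError("rho must be in (-1, 0]")
        if not (0 <= self.censoring < 1):
            raise ValueError("censoring must be in [0, 1)")
        if self.n_planted_pairs > min(self.n_pets, self.n_probes, self.n_genes):
            raise ValueError(
                "infeasible geometry: n_planted_pairs exceeds available PETs/probes/genes"
            )
        if self.n_paired_normals > self.n_patients:
            raise ValueError("n_paired_normals cannot exceed n_patients")


@dataclass
class SyntheticBundle:
    """Everything one cohort run produces, plus the planted ground truth."""

    config: GeneratorConfig
    genes: list[GeneAnnotation]
    probes: list[CpGProbe]
    interactions: list[ChromatinInteraction]
    beta: pd.DataFrame          # probes x (tumour + normal samples)
    expression: pd.DataFrame    # genes x tumour samples, linear scale
    clinical: pd.DataFrame
    treated: pd.DataFrame       # genes x replicates, log2 scale
    control: pd.DataFrame
    truth: pd.DataFrame         # planted (probe_id, gene_id, pet_id, delta, rho, gamma)

    @property
    def tumor_samples(self) -> list[str]:
        return list(
            self.clinical.loc[self.clinical["tissue"] == "tumor", "sample_id"]
        )

    @property
    def normal_samples(self) -> list[str]:
        return list(
            self.clinical.loc[self.clinical["tissue"] == "normal", "sample_id"]
        )


def _censoring_rate(rates: np.ndarray, fraction: float) -> float:
    """Solve mean_i λc/(λc + r_i) = fraction for λc by bisection."""
    if fraction <= 0:
        return 0.0
    lo, hi = 1e-12, float(rates.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if np.mean(mid / (mid + rates)) < fraction:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate a full synthetic cohort; a pure function of the config seeds."""
    config.validate()
    structure_seed = config.seed if config.structure_seed is None else config.structure_seed
    geom = np.random.default_rng([7, structure_seed])   # genome + planted modules
    rng = np.random.default_rng([13, config.seed])      # patient-level sampling
    pad = 50_000

    # --- geometry -----------------------------------------------------------
    gene_tss = np.sort(geom.integers(pad, CHROM_LENGTH - pad, size=config.n_genes))
    strands = geom.choice(["+", "-"], config.n_genes)
    genes = [
        GeneAnnotation(f"G{i + 1:04d}", CHROM, strands[i], int(gene_tss[i]))
        for i in range(config.n_genes)
    ]
    probe_pos = np.sort(geom.integers(pad, CHROM_LENGTH - pad, size=config.n_probes))
    probes = [
        CpGProbe(f"cg{i + 1:06d}", CHROM, int(probe_pos[i]))
        for i in range(config.n_probes)
    ]

    planted_probe_idx = geom.choice(config.n_probes, config.n_planted_pairs, replace=False)
    planted_gene_idx = geom.choice(config.n_genes, config.n_planted_pairs, replace=False)
    half = config.anchor_width // 2

    interactions: list[ChromatinInteraction] = []
    truth_rows = []
    for k in range(config.n_planted_pairs):
        probe = probes[planted_probe_idx[k]]
        gene = genes[planted_gene_idx[k]]
        promoter = promoter_of(gene, config.promoter_upstream, config.promoter_downstream)
        center = (promoter.start + promoter.end) // 2
        pet_id = f"PET{k + 1:05d}"
        interactions.append(
            ChromatinInteraction(
                pet_id=pet_id,
                anchor1=GenomicInterval(
                    CHROM, max(0, probe.pos - half), probe.pos - half + config.anchor_width
                ),
                anchor2=GenomicInterval(
                    CHROM, max(0, center - half), center - half + config.anchor_width
                ),
                support=int(geom.integers(2, 6)),
            )
        )
        truth_rows.append(
            {
                "probe_id": probe.probe_id,
                "gene_id": gene.gene_id,
                "pet_id": pet_id,
                "delta": config.delta,
                "rho": config.rho,
                "gamma": config.gamma,
            }
        )
    for k in range(config.n_planted_pairs, config.n_pets):
        starts = geom.integers(0, CHROM_LENGTH - config.anchor_width, size=2)
        interactions.append(
            ChromatinInteraction(
                pet_id=f"PET{k + 1:05d}",
                anchor1=GenomicInterval(CHROM, int(starts[0]), int(starts[0]) + config.anchor_width),
                anchor2=GenomicInterval(CHROM, int(starts[1]), int(starts[1]) + config.anchor_width),
                support=int(geom.integers(1, 6)),
            )
        )
    truth = pd.DataFrame(
        truth_rows, columns=["probe_id", "gene_id", "pet_id", "delta", "rho", "gamma"]
    )

    # --- samples ------------------------------------------------------------
    patient_ids = [f"P{i + 1:04d}" for i in range(config.n_patients)]
    tumor_ids = [f"{p}-T" for p in patient_ids]
    normal_ids = [f"{p}-N" for p in patient_ids[: config.n_paired_normals]]

    # --- methylation --------------------------------------------------------
    mu = geom.uniform(config.beta_mean_low, config.beta_mean_high, config.n_probes)
    kappa = config.beta_concentration
    a, b = mu * kappa, (1.0 - mu) * kappa
    tumor_beta = rng.beta(a[:, None], b[:, None], size=(config.n_probes, config.n_patients))
    normal_beta = rng.beta(
        a[:, None], b[:, None], size=(config.n_probes, config.n_paired_normals)
    )
    severity = rng.beta(SEVERITY_A, SEVERITY_A, size=config.n_patients)
    shift = 2.0 * config.delta * severity  # per-patient shift, mean delta
    tumor_beta[planted_probe_idx, :] = np.clip(
        tumor_beta[planted_probe_idx, :] + shift[None, :], 0.0, 1.0
    )
    beta = pd.DataFrame(
        np.hstack([tumor_beta, normal_beta]),
        index=pd.Index([p.probe_id for p in probes], name="probe_id"),
        columns=tumor_ids + normal_ids,
    )
    if config.missing_rate > 0:
        mask = rng.random(beta.shape) < config.missing_rate
        beta = beta.mask(mask)

    # --- survival -----------------------------------------------------------
    mean_planted = tumor_beta[planted_probe_idx, :].mean(axis=0)
    rates = config.baseline_hazard * np.exp(config.gamma * mean_planted)
    event_time = rng.exponential(1.0 / rates)
    lam_c = _censoring_rate(rates, config.censoring)
    if lam_c > 0:
        censor_time = rng.exponential(1.0 / lam_c, size=config.n_patients)
    else:
        censor_time = np.full(config.n_patients, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    # --- clinical covariates (all null effects) ------------------------------
    covariates = pd.DataFrame(
        {
            "er": rng.binomial(1, 0.7, config.n_patients),
            "pr": rng.binomial(1, 0.6, config.n_patients),
            "her2": rng.binomial(1, 0.2, config.n_patients),
            "stage34": rng.binomial(1, 0.3, config.n_patients),
            "age_over_55": rng.binomial(1, 0.5, config.n_patients),
            "ductal": rng.binomial(1, 0.8, config.n_patients),
            "pam50": rng.choice(
                ["LuminalA", "LuminalB", "HER2", "Basal"],
                size=config.n_patients,
                p=[0.5, 0.2, 0.15, 0.15],
            ),
        }
    )
    rows = []
    for i, patient in enumerate(patient_ids):
        base = {
            "patient_id": patient,
            "time": float(observed[i]),
            "event": int(event[i]),
            **covariates.iloc[i].to_dict(),
        }
        rows.append({"sample_id": tumor_ids[i], "tissue": "tumor", **base})
        if i < config.n_paired_normals:
            rows.append({"sample_id": normal_ids[i], "tissue": "normal", **base})
    clinical = pd.DataFrame(rows)
    clinical = clinical[
        ["sample_id", "patient_id", "tissue", "time", "event",
         "er", "pr", "her2", "stage34", "age_over_55", "ductal", "pam50"]
    ]

    # --- expression (tumour samples, linear RPKM-like scale) ------------------
    expr_mu = geom.uniform(config.expr_mean_low, config.expr_mean_high, config.n_genes)
    noise = rng.standard_normal((config.n_genes, config.n_patients))
    expr = expr_mu[:, None] + config.expr_sd * noise
    rho = config.rho
    for k in range(config.n_planted_pairs):
        bvec = tumor_beta[planted_probe_idx[k], :]
        z = (bvec - bvec.mean()) / bvec.std()
        g = planted_gene_idx[k]
        expr[g, :] = expr_mu[g] + config.expr_sd * (
            rho * z + np.sqrt(1.0 - rho**2) * noise[g, :]
        )
    expr = np.clip(expr, 0.0, None)
    expression = pd.DataFrame(
        expr,
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=tumor_ids,
    )

    # --- demethylation assay (log2 scale) ------------------------------------
    base = geom.uniform(4.0, 9.0, config.n_genes)
    reps = config.n_assay_replicates
    control = base[:, None] + rng.normal(0.0, config.assay_noise_sd, (config.n_genes, reps))
    shift_vec = np.zeros(config.n_genes)
    shift_vec[planted_gene_idx] = config.demeth_log2_shift
    treated = (
        base[:, None]
        + shift_vec[:, None]
        + rng.normal(0.0, config.assay_noise_sd, (config.n_genes, reps))
    )
    gene_index = pd.Index([g.gene_id for g in genes], name="gene_id")
    rep_cols = [f"rep{j + 1}" for j in range(reps)]
    treated_df = pd.DataFrame(treated, index=gene_index, columns=rep_cols)
    control_df = pd.DataFrame(control, index=gene_index, columns=rep_cols)

    return SyntheticBundle(
        config=config,
        genes=genes,
        probes=probes,
        interactions=interactions,
        beta=beta,
        expression=expression,
        clinical=clinical,
        treated=treated_df,
        control=control_df,
        truth=truth,
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)


def config_from_dict(data: dict) -> GeneratorConfig:
    fields_ = {f for f in GeneratorConfig.__dataclass_fields__}
    unknown = set(data) - fields_
    if unknown:
        raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
    return GeneratorConfig(**data)
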