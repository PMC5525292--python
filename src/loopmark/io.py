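"""Tab-separated readers and writers for every external interface.

All matrices are TSV with a header row of sample ids and the feature id as
the first column; missing values are written as ``NA``. Floats are written
with ``repr`` semantics (pandas' default), so every writer/reader pair
round-trips exactly. Assay matrices carry their scale (``linear``/``log2``)
as a leading ``# scale`` comment line.
"""

from __future__ import annotations

import os

import pandas as pd
import yaml

from .intervals import CpGProbe, GeneAnnotation, GenomicInterval
from .pairing import ChromatinInteraction, CpGGenePair
from .simulate import GeneratorConfig, SyntheticBundle, config_from_dict, config_to_dict


# --- annotation tables ------------------------------------------------------

def write_genes(genes: list[GeneAnnotation], path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            handle.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def read_genes(path, one_based: bool = False) -> list[GeneAnnotation]:
    """Read a (gene_id, chrom, strand, tss) table; ``one_based`` converts
    1-based TSS columns to the internal 0-based convention at ingest."""
    table = pd.read_csv(path, sep="\t")
    offset = 1 if one_based else 0
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), str(r.strand), int(r.tss) - offset)
        for r in table.itertuples()
    ]


def write_probes(probes: list[CpGProbe], path) -> None:
    with open(path, "w") as handle:
        handle.write("probe_id\tchrom\tpos\n")
        for p in probes:
            handle.write(f"{p.probe_id}\t{p.chrom}\t{p.pos}\n")


def read_probes(path, one_based: bool = False) -> list[CpGProbe]:
    table = pd.read_csv(path, sep="\t")
    if table["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in manifest")
    offset = 1 if one_based else 0
    return [
        CpGProbe(str(r.probe_id), str(r.chrom), int(r.pos) - offset)
        for r in table.itertuples()
    ]


def write_bedpe(interactions: list[ChromatinInteraction], path) -> None:
    with open(path, "w") as handle:
        for pet in interactions:
            a, b = pet.anchor1, pet.anchor2
            handle.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
                f"\t{pet.pet_id}\t{pet.support}\n"
            )


# --- matrices ---------------------------------------------------------------

def write_matrix(matrix: pd.DataFrame, path, scale: str | None = None) -> None:
    with open(path, "w") as handle:
        if scale is not None:
            handle.write(f"# scale\t{scale}\n")
        matrix.to_csv(handle, sep="\t", na_rep="NA")


def read_matrix(path) -> tuple[pd.DataFrame, str | None]:
    """Read a feature × sample TSV; returns (matrix, declared scale or None)."""
    scale = None
    with open(path) as handle:
        first = handle.readline()
        if first.startswith("# scale"):
            scale = first.rstrip("\n").split("\t")[1]
        else:
            handle.seek(0)
        matrix = pd.read_csv(handle, sep="\t", index_col=0, na_values="NA")
    return matrix, scale


def read_beta(path) -> pd.DataFrame:
    beta, _ = read_matrix(path)
    observed = beta.to_numpy()
    bad = ((observed < 0) | (observed > 1)) & ~pd.isna(observed)
    if bad.any():
        raise ValueError("beta values outside [0, 1]")
    return beta


# --- clinical ---------------------------------------------------------------

def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


# --- pairs table ------------------------------------------------------------

def write_pairs(pairs: list[CpGGenePair], path) -> None:
    """Stable-order pairs table with per-stage evidence columns."""
    with open(path, "w") as handle:
        handle.write(
            "probe_id\tgene_id\tn_pets\tpet_ids\tdelta_beta\tlogrank_p\tpearson_r\tdeg_flag\n"
        )
        for pair in sorted(pairs, key=lambda p: p.key()):
            fields = [
                pair.probe_id,
                pair.gene_id,
                str(len(pair.pet_ids)),
                ",".join(pair.pet_ids),
                "NA" if pair.delta_beta is None else repr(pair.delta_beta),
                "NA" if pair.logrank_p is None else repr(pair.logrank_p),
                "NA" if pair.pearson_r is None else repr(pair.pearson_r),
                "NA" if pair.deg_flag is None else str(int(pair.deg_flag)),
            ]
            handle.write("\t".join(fields) + "\n")


def read_pairs(path) -> list[CpGGenePair]:
    table = pd.read_csv(path, sep="\t", na_values="NA")
    pairs = []
    for r in table.itertuples():
        pairs.append(
            CpGGenePair(
                probe_id=str(r.probe_id),
                gene_id=str(r.gene_id),
                pet_ids=tuple(str(r.pet_ids).split(",")),
                delta_beta=None if pd.isna(r.delta_beta) else float(r.delta_beta),
                logrank_p=None if pd.isna(r.logrank_p) else float(r.logrank_p),
                pearson_r=None if pd.isna(r.pearson_r) else float(r.pearson_r),
                deg_flag=None if pd.isna(r.deg_flag) else bool(int(r.deg_flag)),
            )
        )
    return pairs


# --- fixture bundles --------------------------------------------------------

FIXTURE_FILES = {
    "genes": "genes.tsv",
    "probes": "probes.tsv",
    "interactions": "interactions.bedpe",
    "beta": "beta.tsv",
    "expression": "expression.tsv",
    "clinical": "clinical.tsv",
    "treated": "assay_treated.tsv",
    "control": "assay_control.tsv",
    "truth": "ground_truth.tsv",
    "config": "config.yaml",
}


def write_fixtures(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Emit every external-interface file for one synthetic cohort."""
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in FIXTURE_FILES.items()}
    write_genes(bundle.genes, paths["genes"])
    write_probes(bundle.probes, paths["probes"])
    write_bedpe(bundle.interactions, paths["interactions"])
    write_matrix(bundle.beta, paths["beta"])
    write_matrix(bundle.expression, paths["expression"], scale="linear")
    write_clinical(bundle.clinical, paths["clinical"])
    write_matrix(bundle.treated, paths["treated"], scale="log2")
    write_matrix(bundle.control, paths["control"], scale="log2")
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as handle:
        yaml.safe_dump(config_to_dict(bundle.config), handle, sort_keys=True)
    return paths


def read_fixtures(outdir) -> SyntheticBundle:
    """Re-read a fixture directory into an in-memory bundle (exact round trip)."""
    from .pairing import read_bedpe

    paths = {k: os.path.join(outdir, v) for k, v in FIXTURE_FILES.items()}
    with open(paths["config"]) as handle:
        config = config_from_dict(yaml.safe_load(handle))
    beta = read_beta(paths["beta"])
    expression, _ = read_matrix(paths["expression"])
    treated, treated_scale = read_matrix(paths["treated"])
    control, control_scale = read_matrix(paths["control"])
    if treated_scale != "log2" or control_scale != "log2":
        raise ValueError("assay matrices must declare the log2 scale")
    return SyntheticBundle(
        config=config,
        genes=read_genes(paths["genes"]),
        probes=read_probes(paths["probes"]),
        interactions=read_bedpe(paths["interactions"]),
        beta=beta,
        expression=expression,
        clinical=read_clinical(paths["clinical"]),
        treated=treated,
        control=control,
        truth=pd.read_csv(paths["truth"], sep="\t"),
    )
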