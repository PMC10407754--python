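"""End-to-end orchestration: simulate/ingest through divergence and annotation.

Stage order mirrors the analysis: peptide tables are aggregated to proteins
and filtered to >=2 unique peptides per species; per-species mated-vs-virgin
contrasts give per-database ejaculate candidates; the per-species tables are
merged by orthogroup into the combined cross-species matrix, normalized once
(TMM + log2), contrasted mated-vs-virgin per species and classified into
ejaculate / FRT / virgin-biased / excluded; the ejaculate and FRT sets are
then compared between species pairs, clustered, and related to secretion
signals, gene families, evolutionary rates, GO terms, mRNA abundance and
overall sample structure (PCA).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import diffabund, divergence, evo
from . import io as qio
from . import orthology, simulate
from .io import CHANNELS, design_channels

log = logging.getLogger("reproteome")

DEFAULT_CONFIG = {
    "lfc_threshold": 1.0,
    "q_threshold": 0.05,
    "min_unique": 2,
    "pseudocount": 0.5,
    "min_genes": 15,
    "k_ejaculate": 7,
    "k_frt": 4,
    "resampling_draws": 99_999,
    "pca_top": 500,
    "seed": 1,
}

RATE_COMPARISONS = [
    ("ejaculate_secreted", "ejaculate_nonsecreted"),
    ("ejaculate_secreted", "genome"),
    ("ejaculate_nonsecreted", "genome"),
    ("frt_secreted", "frt_nonsecreted"),
    ("frt_secreted", "genome"),
    ("frt_step_secreted", "frt_secreted"),
    ("frt_step_secreted", "ejaculate_secreted"),
    ("frt_step_secreted", "genome"),
]


@dataclass
class PipelineResult:
    config: dict
    design: pd.DataFrame
    per_species: dict = field(default_factory=dict)
    combined: pd.DataFrame | None = None
    unassigned: pd.DataFrame | None = None
    norm: diffabund.NormalizedMatrix | None = None
    contrasts: dict = field(default_factory=dict)
    classification: pd.DataFrame | None = None
    sig_fraction: pd.DataFrame | None = None
    divergence: dict = field(default_factory=dict)
    clusters: dict = field(default_factory=dict)
    fisher: dict = field(default_factory=dict)
    resampling: divergence.ResamplingResult | None = None
    rate_summary: pd.DataFrame | None = None
    rate_tests: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    pca: evo.PCAResult | None = None
    mrna_correlations: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    return cfg


def _species_candidates(
    table: pd.DataFrame, design: pd.DataFrame, species: str, cfg: dict
) -> tuple[pd.DataFrame, pd.Series]:
    """Mated-vs-virgin contrast within one species' own database table."""
    matrix = table.set_index("protein_id")[CHANNELS]
    norm = diffabund.normalize_log2(matrix, pseudocount=cfg["pseudocount"])
    res = diffabund.fit_group_contrast(
        norm, design, (species, "mated"), (species, "virgin")
    )
    calls = cls.call_differential(res, cfg["lfc_threshold"], cfg["q_threshold"])
    return res, calls


def run_pipeline(
    dataset: simulate.SyntheticDataset | None = None,
    config: dict | None = None,
    out_dir: str | Path | None = None,
    inputs: dict | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic dataset or on tables read from disk.

    Parameters
    ----------
    dataset
        In-memory synthetic bundle; generated from ``config['simulate']``
        parameters (seeded by ``config['seed']``) when omitted.
    inputs
        Alternatively, paths: ``peptides`` (species -> TSV), ``design``,
        ``orthomap``, ``annotations``, ``omega``, ``go``, ``mrna``,
        ``exclusion``.
    out_dir
        If given, all stage outputs are written beneath it.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    seed = int(cfg["seed"])

    if dataset is None and inputs is None:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", seed)
        dataset = simulate.generate_dataset(simulate.SimulationParams(**sim_kwargs))

    if dataset is not None:
        design = dataset.design
        peptide_tables = dataset.peptide_tables
        orthomap = dataset.orthomap
        annotations = dataset.annotations.set_index("protein_id")
        omega = dataset.truth.omega
        go = dataset.truth.go
        mrna = dataset.truth.mrna
        exclusion = list(dataset.truth.exclusion_row_keys)
    else:
        design = qio.read_design(inputs["design"])
        peptide_tables = {
            sp: qio.read_peptide_table(p) for sp, p in inputs["peptides"].items()
        }
        orthomap = orthology.read_orthomap(inputs["orthomap"])
        annotations = pd.read_csv(inputs["annotations"], sep="\t").set_index(
            "protein_id"
        )
        omega = pd.read_csv(inputs["omega"], sep="\t")
        go = pd.read_csv(inputs["go"], sep="\t")
        mrna = pd.read_csv(inputs["mrna"], sep="\t") if inputs.get("mrna") else None
        exclusion = (
            [l for l in Path(inputs["exclusion"]).read_text().splitlines() if l]
            if inputs.get("exclusion")
            else []
        )

    result = PipelineResult(config=cfg, design=design)
    summary: dict = {"per_species": {}, "combined": {}}

    # ---- per-species: aggregate, filter, own-database candidates ----------
    filtered_tables = {}
    for sp, peptides in peptide_tables.items():
        agg = qio.aggregate_to_protein(peptides)
        filt = qio.filter_min_unique(agg, cfg["min_unique"])
        log.info(
            "%s: %d peptides -> %d proteins -> %d with >=%d unique peptides",
            sp, len(peptides), len(agg), len(filt), cfg["min_unique"],
        )
        res, calls = _species_candidates(filt, design, sp, cfg)
        filtered_tables[sp] = filt
        result.per_species[sp] = {
            "aggregated": agg, "filtered": filt, "contrast": res, "calls": calls,
        }
        summary["per_species"][sp] = {
            "total_proteins": int(len(agg)),
            "two_unique_peptides": int(len(filt)),
            "ejaculate_candidates": int((calls == "up").sum()),
        }

    # ---- combined orthogroup table ---------------------------------------
    combined, unassigned = orthology.merge_by_orthogroup(filtered_tables, orthomap)
    result.combined, result.unassigned = combined, unassigned
    log.info(
        "combined table: %d rows, %d orthogroups, %d unassigned proteins",
        len(combined), combined["orthogroup"].nunique(), len(unassigned),
    )

    matrix = combined.set_index("row_key")[CHANNELS]
    norm = diffabund.normalize_log2(matrix, pseudocount=cfg["pseudocount"])
    result.norm = norm

    species_list = sorted(peptide_tables)
    calls_by_species = {}
    for sp in species_list:
        res = diffabund.fit_group_contrast(
            norm, design, (sp, "mated"), (sp, "virgin")
        )
        result.contrasts[f"{sp}_mated_vs_virgin"] = res
        calls_by_species[sp] = cls.call_differential(
            res, cfg["lfc_threshold"], cfg["q_threshold"]
        )

    row_ann = _row_annotations(combined, annotations)
    classification = cls.classify_ejaculate(calls_by_species, exclusion, row_ann)
    result.classification = classification
    result.sig_fraction = cls.signal_peptide_fraction(classification, row_ann)

    ej_rows = classification.index[classification["class"] == "ejaculate"]
    frt_rows = cls.frt_set(classification)
    summary["combined"] = {
        "total_rows": int(len(combined)),
        "orthogroups": int(combined["orthogroup"].nunique()),
        "two_unique_peptides": int(len(combined)),
        "ejaculate_candidates": int(len(ej_rows)),
        "ejaculate_orthogroups": int(
            combined.set_index("row_key").loc[ej_rows, "orthogroup"].nunique()
        ),
        "ejaculate_shared_all_species": int(
            classification.loc[ej_rows, "shared_all_species"].sum()
        ),
        "virgin_biased": int((classification["class"] == "virgin-biased").sum()),
        "excluded": int((classification["class"] == "excluded").sum()),
        "frt_proteins": int(len(frt_rows)),
        "frt_orthogroups": int(
            combined.set_index("row_key").loc[frt_rows, "orthogroup"].nunique()
        ),
    }

    # ---- cross-species divergence ----------------------------------------
    fam_flags = combined.set_index("row_key")["is_family_member"]
    sig_flags = row_ann["has_signal_peptide"]
    div_counts: dict = {"ejaculate": {}, "frt": {}}
    for set_name, rows, status in (
        ("ejaculate", ej_rows, "mated"),
        ("frt", frt_rows, "virgin"),
    ):
        if len(rows) == 0:
            continue
        for a, b in simulate.SPECIES_PAIRS:
            pair = f"{a}_vs_{b}"
            res = divergence.pairwise_divergence(
                norm, design, rows, a, b, status,
                cfg["lfc_threshold"], cfg["q_threshold"],
            )
            result.divergence[f"{set_name}_{pair}"] = res
            div_counts[set_name][pair] = int((res["call"] != "ns").sum())
            divergent = res.index[res["call"] != "ns"]
            result.fisher[f"{set_name}_{pair}_signal_peptide"] = (
                divergence.fisher_association(divergent, sig_flags, rows)
            )
    summary["divergence"] = div_counts

    for set_name, rows, status, k in (
        ("ejaculate", ej_rows, "mated", cfg["k_ejaculate"]),
        ("frt", frt_rows, "virgin", cfg["k_frt"]),
    ):
        if len(rows) < k:
            continue
        centered = divergence.replicate_average_center(
            norm.log2.loc[rows], design, [(sp, status) for sp in species_list]
        )
        result.clusters[set_name] = divergence.kmeans_cluster(centered, k, seed=seed)

    if len(ej_rows):
        result.resampling = divergence.family_resampling_test(
            ej_rows, classification.index, fam_flags,
            b=cfg["resampling_draws"], seed=seed,
        )
        ej_fam = fam_flags.loc[ej_rows]
        fam_div = _family_divergent_fraction(result, ej_fam)
        summary["gene_families"] = {
            "ejaculate_family_members": int(ej_fam.sum()),
            "family_members_divergent_fraction": fam_div,
            "resampling_p_upper_mc": result.resampling.p_upper_mc,
            "resampling_p_lower_mc": result.resampling.p_lower_mc,
        }

    # ---- evolutionary rates, GO, PCA, mRNA -------------------------------
    key_of_row = combined.set_index("row_key")["protein_id"]
    groups = _rate_groups(classification, row_ann, key_of_row, omega)
    result.rate_summary, result.rate_tests = evo.compare_rate_groups(
        omega, groups, RATE_COMPARISONS, alternative="two-sided"
    )

    fg = key_of_row.loc[ej_rows].unique()
    bg = key_of_row.unique()
    result.enrichment = evo.go_enrichment(fg, bg, go, min_genes=cfg["min_genes"])

    result.pca = evo.pca_top_variable(norm.log2, n_top=cfg["pca_top"])
    summary["pca_variance_pct"] = [round(float(v), 2) for v in
                                   result.pca.variance_pct[:3]]

    if mrna is not None:
        result.mrna_correlations = _mrna_correlations(
            norm, design, combined, classification, row_ann, mrna
        )

    result.summary = summary
    if out_dir is not None:
        write_outputs(result, Path(out_dir))
    return result


def _row_annotations(combined: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-protein annotation columns reindexed onto combined row keys."""
    idx = combined.set_index("row_key")["protein_id"]
    ann = annotations.reindex(idx.to_numpy())
    ann.index = idx.index
    for col in ("has_signal_peptide", "is_step"):
        if col in ann.columns:
            ann[col] = ann[col].fillna(False).astype(bool)
    return ann


def _rate_groups(classification, row_ann, key_of_row, omega) -> dict:
    sig = row_ann["has_signal_peptide"]
    step = row_ann.get("is_step", pd.Series(False, index=row_ann.index))
    ej = classification["class"] == "ejaculate"
    frt = classification["class"].isin(["FRT", "virgin-biased"])
    rows = classification.index

    def keys(mask):
        return key_of_row.loc[rows[mask]].unique()

    groups = {
        "ejaculate_secreted": keys(ej & sig),
        "ejaculate_nonsecreted": keys(ej & ~sig),
        "frt_secreted": keys(frt & sig & ~step),
        "frt_nonsecreted": keys(frt & ~sig),
        "frt_step_secreted": keys(frt & sig & step),
        "genome": omega["key"].unique(),
    }
    return {k: v for k, v in groups.items() if len(v)}


def _family_divergent_fraction(result: PipelineResult, ej_fam: pd.Series) -> float:
    """Fraction of ejaculate gene-family members divergent in >=1 species pair."""
    members = ej_fam.index[ej_fam]
    if len(members) == 0:
        return float("nan")
    divergent = pd.Series(False, index=members)
    for name, res in result.divergence.items():
        if name.startswith("ejaculate_"):
            divergent |= res.loc[members, "call"] != "ns"
    return float(divergent.mean())


def _mrna_correlations(norm, design, combined, classification, row_ann, mrna):
    """Pearson r between tissue mRNA and mated-sample protein abundance,
    within secreted ejaculate proteins, per species x tissue."""
    pid_of_row = combined.set_index("row_key")["protein_id"]
    sp_of_row = combined.set_index("row_key")["species"]
    sec_ej = (classification["class"] == "ejaculate") & row_ann["has_signal_peptide"]
    rows = []
    for sp in sorted(design["species"].unique()):
        ch = design_channels(design, sp, "mated")
        mask = sec_ej & (sp_of_row == sp)
        keys = classification.index[mask]
        if len(keys) < 3:
            continue
        prot_log2 = norm.log2.loc[keys, ch].mean(axis=1)
        pids = pid_of_row.loc[keys]
        for tissue, sub in mrna[mrna["species"] == sp].groupby("tissue"):
            m = sub.set_index("protein_id")["mrna_log2"].reindex(pids.to_numpy())
            ok = m.notna().to_numpy()
            if ok.sum() < 3:
                continue
            r, p = evo.pearson_r(m.to_numpy()[ok], prot_log2.to_numpy()[ok])
            rows.append(
                {"species": sp, "tissue": tissue, "n": int(ok.sum()),
                 "r": r, "p": p}
            )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if result.combined is not None:
        result.combined.to_csv(out / "combined_table.tsv", sep="\t", index=False)
    if result.norm is not None:
        result.norm.log2.to_csv(out / "normalized_log2.tsv", sep="\t")
    for name, res in {**result.contrasts, **result.divergence}.items():
        res.to_csv(out / f"contrast_{name}.tsv", sep="\t")
    if result.classification is not None:
        result.classification.to_csv(out / "classification.tsv", sep="\t")
    for name, cl in result.clusters.items():
        cl.labels.to_frame().to_csv(out / f"clusters_{name}.tsv", sep="\t")
    if result.resampling is not None:
        r = result.resampling
        payload = {
            "N": r.pool_size, "K": r.annotated_in_pool, "n": r.sample_size,
            "k_obs": r.observed, "B": r.draws, "seed": r.seed,
            "p_upper_mc": r.p_upper_mc, "p_lower_mc": r.p_lower_mc,
            "p_upper_hypergeom": r.p_upper_hypergeom,
            "p_lower_hypergeom": r.p_lower_hypergeom,
        }
        (out / "resampling.json").write_text(json.dumps(payload, indent=2))
    if result.rate_summary is not None:
        result.rate_summary.to_csv(out / "rates.tsv", sep="\t", index=False)
        result.rate_tests.to_csv(out / "rate_tests.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if result.pca is not None:
        payload = {
            "variance_pct": [float(v) for v in result.pca.variance_pct],
            "scores": {
                ch: [float(v) for v in row]
                for ch, row in result.pca.scores.iterrows()
            },
        }
        (out / "pca.json").write_text(json.dumps(payload, indent=2))
    if result.mrna_correlations is not None:
        result.mrna_correlations.to_csv(
            out / "mrna_correlations.tsv", sep="\t", index=False
        )
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )
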