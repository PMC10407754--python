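"""Synthetic multiplexed-proteomics data with planted ground truth.

Emulates a 16-channel isobaric-label (TMT) experiment on the lower female
reproductive tract of three related fly species, sampled virgin and
immediately after conspecific mating:

* three species sharing ~95% single-copy 1:1:1 orthogroups and ~5%
  one-to-many gene families;
* a planted subset of *ejaculate* orthogroups whose proteins appear at
  elevated abundance only in mated channels of the species whose males
  transfer them, on top of a lower-than-average baseline (transferred
  proteins are diluted in whole-tract lysate);
* planted between-species abundance divergence for a fraction of
  orthogroups;
* a small set of female postmating-response proteins that are also
  mated-biased (the confound the curated exclusion list removes);
* annotations with the study's structure: signal-peptide probability higher
  for ejaculate (0.52) than FRT (0.41) proteins, serine-type endopeptidase
  flags among secreted FRT proteins, dN/dS (omega) distributions elevated
  for secreted ejaculate proteins and female endopeptidases, GO term sets
  with a few ejaculate-enriched terms, and male-tissue mRNA abundances
  weakly correlated with secreted ejaculate protein abundance.

The abundance model is log2-normal: per-orthogroup baselines, per-protein
and per-peptide offsets drawn once (shared across channels), independent
per-channel log2 noise. Peptide reporter intensity is
``2^(channel log2 abundance + peptide offset + noise)``; protein abundance
downstream is the plain sum over peptides. Everything is driven by one seed;
a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CHANNELS, DESIGN_COLUMNS

SPECIES = ("americana", "novamexicana", "virilis")
SPECIES_PREFIX = {"americana": "AME", "novamexicana": "NOV", "virilis": "VIR"}
SPECIES_PAIRS = (
    ("americana", "novamexicana"),
    ("americana", "virilis"),
    ("novamexicana", "virilis"),
)
TISSUES = ("accessory_gland", "ejaculatory_bulb", "carcass")

#: omega ~ Gamma(shape, scale); means chosen so that secreted ejaculate
#: proteins and secreted female endopeptidases evolve fastest, secreted FRT
#: proteins faster than the remaining FRT set but below the genome average.
DEFAULT_OMEGA_PARAMS = {
    "ejaculate_secreted": (2.0, 0.14),      # mean 0.28
    "ejaculate_nonsecreted": (2.0, 0.09),   # mean 0.18
    "frt_step_secreted": (2.0, 0.135),      # mean 0.27
    "frt_secreted": (2.0, 0.07),            # mean 0.14
    "frt_nonsecreted": (2.0, 0.05),         # mean 0.10
    "background": (2.0, 0.09),              # mean 0.18 ~ genome average
}


def default_design() -> pd.DataFrame:
    """The 16-plex layout: 3 mated replicates per species; virgin replicates
    3 (virilis) / 2 / 2."""
    rows = []
    ch = iter(CHANNELS)
    for sp in SPECIES:
        for rep in range(1, 4):
            rows.append((next(ch), sp, "mated", rep))
    virgin_reps = {"americana": 2, "novamexicana": 2, "virilis": 3}
    for sp in SPECIES:
        for rep in range(1, virgin_reps[sp] + 1):
            rows.append((next(ch), sp, "virgin", rep))
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_orthogroups: int = 2000
    frac_multicopy: float = 0.05
    frac_ejaculate: float = 0.10
    ejaculate_log2_shift: float = 3.0
    # male-derived proteins sit near the virgin-sample detection floor, so
    # even after the mated-channel transfer shift they stay below the
    # typical female reproductive tract protein
    ejaculate_baseline_offset: float = -5.0
    transfer_prob: float = 0.75          # per species, conditioned on >=1
    frac_species_divergent: float = 0.35
    divergent_log2_effect: float = 2.0
    peptides_per_protein_lambda: float = 3.0   # n_pep = max(2, 1 + Pois(lambda))
    frac_single_peptide: float = 0.05          # forced to exactly 1 unique peptide
    shared_peptide_rate: float = 0.01
    dropout_rate: float = 0.0
    channel_noise_sd: float = 0.5
    peptide_offset_sd: float = 1.0
    protein_offset_sd: float = 0.5             # family members differ a little
    baseline_log2_mean: float = 18.0
    baseline_log2_sd: float = 2.0
    sig_peptide_prob_by_class: dict = field(
        default_factory=lambda: {"ejaculate": 0.52, "frt": 0.41}
    )
    step_prob: float = 0.08                    # STEP flag among secreted FRT
    omega_params_by_class: dict = field(
        default_factory=lambda: dict(DEFAULT_OMEGA_PARAMS)
    )
    n_background_genes: int = 4000             # genome outside the proteome
    n_postmating_response: int = 12
    pmr_log2_shift: float = 2.0
    mrna_protein_r_target: float = 0.45
    mrna_r_other: float = 0.10
    n_go_terms: int = 40
    n_ejaculate_go_terms: int = 5
    go_base_prob: float = 0.03
    go_ejaculate_prob: float = 0.25
    seed: int = 1

    def validate(self) -> None:
        fracs = {
            "frac_multicopy": self.frac_multicopy,
            "frac_ejaculate": self.frac_ejaculate,
            "frac_species_divergent": self.frac_species_divergent,
            "frac_single_peptide": self.frac_single_peptide,
            "shared_peptide_rate": self.shared_peptide_rate,
            "dropout_rate": self.dropout_rate,
            "transfer_prob": self.transfer_prob,
            "mrna_protein_r_target": self.mrna_protein_r_target,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("channel_noise_sd", "peptide_offset_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")
        for cls, p in self.sig_peptide_prob_by_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"sig_peptide_prob_by_class[{cls}] not in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    proteins: pd.DataFrame      # per protein: species, orthogroup, flags, offsets
    orthogroups: pd.DataFrame   # per orthogroup: baseline, planted effects
    pair_effects: pd.DataFrame  # orthogroup x species pair: true log2 effect
    omega: pd.DataFrame         # key, pair, omega (proteome + background genes)
    go: pd.DataFrame            # key, term, branch
    mrna: pd.DataFrame          # protein_id, species, tissue, mrna_log2
    exclusion_row_keys: list    # curated postmating-response proteins


def generate_proteome(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate orthology, annotations and ground truth (no intensities yet).

    Returns ``(orthomap, annotations, truth)``. ``annotations`` is one row
    per protein with the flags the analysis consumes; ``truth`` additionally
    carries planted effect sizes, omega, GO, mRNA and the exclusion list.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_orthogroups
    ogs = np.array([f"OG{i:05d}" for i in range(n)])

    is_ejaculate = rng.random(n) < params.frac_ejaculate
    non_ej = np.where(~is_ejaculate)[0]
    n_pmr = min(params.n_postmating_response, non_ej.size)
    pmr_idx = rng.choice(non_ej, size=n_pmr, replace=False)
    is_pmr = np.zeros(n, dtype=bool)
    is_pmr[pmr_idx] = True

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)
    baseline = baseline + np.where(is_ejaculate, params.ejaculate_baseline_offset, 0.0)

    # which species' males transfer each ejaculate orthogroup (>=1 each)
    transfer = np.zeros((n, len(SPECIES)), dtype=bool)
    tdraw = rng.random((n, len(SPECIES))) < params.transfer_prob
    forced = rng.integers(0, len(SPECIES), size=n)
    for j in range(len(SPECIES)):
        transfer[:, j] = tdraw[:, j]
    none = ~transfer.any(axis=1)
    transfer[none, forced[none]] = True
    transfer &= is_ejaculate[:, None]

    # planted between-species divergence: one species shifted up or down
    divergent = rng.random(n) < params.frac_species_divergent
    div_species = rng.integers(0, len(SPECIES), size=n)
    div_sign = rng.choice([-1.0, 1.0], size=n)
    offsets = np.zeros((n, len(SPECIES)))
    offsets[np.arange(n), div_species] = np.where(
        divergent, div_sign * params.divergent_log2_effect, 0.0
    )

    # gene families: one extra copy in one species
    multicopy = rng.random(n) < params.frac_multicopy
    extra_species = rng.integers(0, len(SPECIES), size=n)

    # annotations shared by orthologs: secretion signal, endopeptidase flag
    sig_prob = np.where(
        is_ejaculate,
        params.sig_peptide_prob_by_class["ejaculate"],
        params.sig_peptide_prob_by_class["frt"],
    )
    has_sig = rng.random(n) < sig_prob
    is_step = (~is_ejaculate) & has_sig & (rng.random(n) < params.step_prob)

    og_df = pd.DataFrame(
        {
            "orthogroup": ogs,
            "baseline_log2": baseline,
            "is_ejaculate": is_ejaculate,
            "is_pmr": is_pmr,
            "is_family": multicopy,
            "has_signal_peptide": has_sig,
            "is_step": is_step,
            **{f"transfer_{sp}": transfer[:, j] for j, sp in enumerate(SPECIES)},
            **{f"offset_{sp}": offsets[:, j] for j, sp in enumerate(SPECIES)},
        }
    ).set_index("orthogroup")

    # true between-species effects: virgin channels see only the divergence
    # offsets; mated channels additionally see differential ejaculate transfer
    pair_rows = []
    for a, b in SPECIES_PAIRS:
        eff = (og_df[f"offset_{a}"] - og_df[f"offset_{b}"]).to_numpy()
        transfer_diff = (
            og_df[f"transfer_{a}"].astype(float) - og_df[f"transfer_{b}"].astype(float)
        ).to_numpy()
        eff_mated = eff + params.ejaculate_log2_shift * transfer_diff
        pair_rows.append(
            pd.DataFrame(
                {
                    "orthogroup": ogs,
                    "pair": f"{a}_vs_{b}",
                    "true_log2_effect": eff,
                    "is_divergent": eff != 0,
                    "true_log2_effect_mated": eff_mated,
                    "is_divergent_mated": eff_mated != 0,
                }
            )
        )
    pair_effects = pd.concat(pair_rows, ignore_index=True)

    # per-species protein members
    prot_rows = []
    for i, og in enumerate(ogs):
        for j, sp in enumerate(SPECIES):
            copies = 2 if (multicopy[i] and extra_species[i] == j) else 1
            for c in range(copies):
                suffix = "" if c == 0 else chr(ord("a") + c)
                prot_rows.append((f"{SPECIES_PREFIX[sp]}_{og}{suffix}", sp, og, i))
    proteins = pd.DataFrame(
        prot_rows, columns=["protein_id", "species", "orthogroup", "_og_idx"]
    )
    og_idx = proteins["_og_idx"].to_numpy()
    proteins["is_ejaculate"] = is_ejaculate[og_idx]
    proteins["is_pmr"] = is_pmr[og_idx]
    proteins["is_family"] = multicopy[og_idx]
    proteins["has_signal_peptide"] = has_sig[og_idx]
    proteins["is_step"] = is_step[og_idx]
    proteins["protein_offset"] = np.where(
        proteins.duplicated(["orthogroup", "species"], keep=False),
        rng.normal(0.0, params.protein_offset_sd, len(proteins)),
        0.0,
    )
    npep = np.maximum(
        2, 1 + rng.poisson(params.peptides_per_protein_lambda, len(proteins))
    )
    single = rng.random(len(proteins)) < params.frac_single_peptide
    proteins["n_peptides"] = np.where(single, 1, npep)

    orthomap = proteins[["protein_id", "species", "orthogroup"]].copy()
    annotations = proteins.drop(columns=["_og_idx", "protein_offset", "n_peptides"])

    omega = _generate_omega(params, proteins, rng)
    go = _generate_go(params, og_df, proteins, rng)
    mrna = _generate_mrna(params, og_df, proteins, rng)

    pmr_mask = proteins["is_pmr"].to_numpy()
    exclusion = (
        proteins.loc[pmr_mask, "orthogroup"]
        + ":"
        + proteins.loc[pmr_mask, "protein_id"]
    ).tolist()

    truth = SyntheticTruth(
        proteins=proteins.drop(columns="_og_idx").set_index("protein_id"),
        orthogroups=og_df,
        pair_effects=pair_effects,
        omega=omega,
        go=go,
        mrna=mrna,
        exclusion_row_keys=sorted(exclusion),
    )
    return orthomap, annotations, truth


def _omega_class(row) -> str:
    if row["is_ejaculate"]:
        return "ejaculate_secreted" if row["has_signal_peptide"] else "ejaculate_nonsecreted"
    if row["is_step"]:
        return "frt_step_secreted"
    return "frt_secreted" if row["has_signal_peptide"] else "frt_nonsecreted"


def _generate_omega(params, proteins, rng) -> pd.DataFrame:
    """Pairwise dN/dS per protein plus a genome background gene set."""
    classes = proteins.apply(_omega_class, axis=1).to_numpy()
    rows = []
    for a, b in SPECIES_PAIRS:
        pair = f"{a}_vs_{b}"
        for key_arr, cls_arr in (
            (proteins["protein_id"].to_numpy(), classes),
            (
                np.array([f"BG{i:05d}" for i in range(params.n_background_genes)]),
                np.repeat("background", params.n_background_genes),
            ),
        ):
            shapes = np.array(
                [params.omega_params_by_class[c][0] for c in cls_arr]
            )
            scales = np.array(
                [params.omega_params_by_class[c][1] for c in cls_arr]
            )
            om = rng.gamma(shapes, scales)
            rows.append(
                pd.DataFrame({"key": key_arr, "pair": pair, "omega": om,
                              "class": cls_arr})
            )
    return pd.concat(rows, ignore_index=True)


def _generate_go(params, og_df, proteins, rng) -> pd.DataFrame:
    """GO annotations per protein; term sets shared by orthologs.

    One term encodes the serine-type endopeptidase flag exactly; a few terms
    are planted at elevated frequency among ejaculate orthogroups.
    """
    n = len(og_df)
    branches = ("BP", "CC", "MF")
    term_rows = []
    is_ej = og_df["is_ejaculate"].to_numpy()
    for t in range(params.n_go_terms):
        term = f"GO:{t + 1:07d}"
        branch = branches[t % 3]
        if t < params.n_ejaculate_go_terms:
            prob = np.where(is_ej, params.go_ejaculate_prob, params.go_base_prob)
        else:
            prob = np.full(n, params.go_base_prob * rng.uniform(0.5, 3.0))
        member = rng.random(n) < prob
        for og in og_df.index[member]:
            term_rows.append((og, term, branch))
    step_ogs = og_df.index[og_df["is_step"]]
    for og in step_ogs:
        term_rows.append((og, "GO:0004252", "MF"))  # serine-type endopeptidase
    og_terms = pd.DataFrame(term_rows, columns=["orthogroup", "term", "branch"])
    merged = proteins[["protein_id", "orthogroup"]].merge(og_terms, on="orthogroup")
    return (
        merged.rename(columns={"protein_id": "key"})[["key", "term", "branch"]]
        .sort_values(["key", "term"], ignore_index=True)
    )


def _generate_mrna(params, og_df, proteins, rng) -> pd.DataFrame:
    """Male-tissue mRNA log2 abundances, coupled to protein abundance.

    For secreted ejaculate proteins the accessory-gland and ejaculatory-bulb
    mRNA is generated as a linear function of true mated-state protein log2
    abundance with noise variance solved from the target correlation; all
    other protein x tissue combinations get a weak coupling.
    """
    rows = []
    for sp in SPECIES:
        sub = proteins[proteins["species"] == sp]
        base = og_df.loc[sub["orthogroup"], "baseline_log2"].to_numpy()
        off = og_df.loc[sub["orthogroup"], f"offset_{sp}"].to_numpy()
        transfer = og_df.loc[sub["orthogroup"], f"transfer_{sp}"].to_numpy()
        true_log2 = (
            base
            + off
            + sub["protein_offset"].to_numpy()
            + np.where(transfer, params.ejaculate_log2_shift, 0.0)
        )
        sec_ej = (sub["is_ejaculate"] & sub["has_signal_peptide"]).to_numpy()
        for tissue in TISSUES:
            r = (
                params.mrna_protein_r_target
                if tissue in ("accessory_gland", "ejaculatory_bulb")
                else params.mrna_r_other
            )
            target_r = np.where(sec_ej, r, params.mrna_r_other)
            sd_p = true_log2.std()
            noise_sd = sd_p * np.sqrt(1.0 / np.maximum(target_r, 1e-6) ** 2 - 1.0)
            mrna = true_log2 + rng.normal(0.0, 1.0, len(sub)) * noise_sd
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": sub["protein_id"].to_numpy(),
                        "species": sp,
                        "tissue": tissue,
                        "mrna_log2": mrna,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_experiment(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    params: SimulationParams,
) -> dict[str, pd.DataFrame]:
    """Peptide-level reporter-intensity tables, one per species database.

    All 16 channels appear in every table (one multiplexed run searched
    against each species' proteome). The log2 abundance of a protein in a
    channel is its orthogroup baseline plus the channel species' divergence
    offset, plus the ejaculate shift in mated channels of transferring
    species, plus the postmating-response shift in any mated channel for
    planted female-response proteins.
    """
    params.validate()
    unknown = set(design["species"]) - set(SPECIES)
    if unknown:
        raise ValueError(f"design references unknown species: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed + 1)

    ch_species = design.set_index("channel")["species"].reindex(CHANNELS)
    ch_status = design.set_index("channel")["status"].reindex(CHANNELS)
    if ch_species.isna().any():
        raise ValueError("design must cover all 16 channels")

    og = truth.orthogroups
    tables = {}
    for sp in SPECIES:
        sub = truth.proteins[truth.proteins["species"] == sp]
        ogs = sub["orthogroup"].to_numpy()
        base = og.loc[ogs, "baseline_log2"].to_numpy()

        mu = np.empty((len(sub), len(CHANNELS)))
        for c, ch in enumerate(CHANNELS):
            c_sp, c_status = ch_species[ch], ch_status[ch]
            val = base + og.loc[ogs, f"offset_{c_sp}"].to_numpy()
            if c_status == "mated":
                val = val + np.where(
                    og.loc[ogs, f"transfer_{c_sp}"].to_numpy(),
                    params.ejaculate_log2_shift,
                    0.0,
                )
                val = val + np.where(
                    og.loc[ogs, "is_pmr"].to_numpy(), params.pmr_log2_shift, 0.0
                )
            mu[:, c] = val
        mu += sub["protein_offset"].to_numpy()[:, None]

        npep = sub["n_peptides"].to_numpy()
        total_pep = int(npep.sum())
        pep_offsets = rng.normal(0.0, params.peptide_offset_sd, total_pep)
        prot_idx = np.repeat(np.arange(len(sub)), npep)
        noise = rng.normal(0.0, params.channel_noise_sd, (total_pep, len(CHANNELS)))
        log2_int = mu[prot_idx] + pep_offsets[:, None] + noise
        intensities = 2.0**log2_int
        if params.dropout_rate > 0:
            drop = rng.random(intensities.shape) < params.dropout_rate
            intensities[drop] = 0.0

        pep_num = np.concatenate([np.arange(k) for k in npep])
        prot_ids = sub.index.to_numpy()
        table = pd.DataFrame(intensities, columns=CHANNELS)
        table.insert(
            0,
            "peptide",
            [f"PEP_{prot_ids[i]}_{j}" for i, j in zip(prot_idx, pep_num)],
        )
        table.insert(1, "protein_id", prot_ids[prot_idx])
        table.insert(2, "is_unique", True)

        table = _add_shared_peptides(table, prot_ids, params, rng, sp)
        tables[sp] = table
    return tables


def _add_shared_peptides(table, prot_ids, params, rng, species):
    """Append a few non-unique peptides each assigned to two proteins."""
    if params.shared_peptide_rate <= 0 or len(prot_ids) < 2:
        return table
    n_shared = rng.binomial(len(prot_ids), params.shared_peptide_rate)
    if n_shared == 0:
        return table
    rows = []
    for s in range(n_shared):
        i, j = rng.choice(len(prot_ids), size=2, replace=False)
        vals = table.loc[table["protein_id"] == prot_ids[i], CHANNELS].iloc[0]
        for owner in (prot_ids[i], prot_ids[j]):
            rows.append(
                {
                    "peptide": f"SHPEP_{species}_{s}",
                    "protein_id": owner,
                    "is_unique": False,
                    **vals.to_dict(),
                }
            )
    return pd.concat([table, pd.DataFrame(rows)], ignore_index=True)


@dataclass
class SyntheticDataset:
    params: SimulationParams
    design: pd.DataFrame
    orthomap: pd.DataFrame
    annotations: pd.DataFrame
    truth: SyntheticTruth
    peptide_tables: dict[str, pd.DataFrame]


def generate_dataset(
    params: SimulationParams | None = None, design: pd.DataFrame | None = None
) -> SyntheticDataset:
    """One-call generation of the full synthetic study."""
    params = params or SimulationParams()
    design = design if design is not None else default_design()
    orthomap, annotations, truth = generate_proteome(params)
    tables = simulate_experiment(truth, design, params)
    return SyntheticDataset(params, design, orthomap, annotations, truth, tables)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write all tables in the documented TSV dialects plus a manifest."""
    from pathlib import Path

    from . import io as qio
    from .orthology import write_orthomap

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    qio.write_design(ds.design, out / "design.tsv")
    write_orthomap(ds.orthomap, out / "orthomap.tsv")
    for sp, table in ds.peptide_tables.items():
        qio.write_peptide_table(table, out / f"peptides_{sp}.tsv")
    ds.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    ds.truth.proteins.to_csv(out / "truth_proteins.tsv", sep="\t")
    ds.truth.pair_effects.to_csv(out / "truth_pair_effects.tsv", sep="\t", index=False)
    ds.truth.omega.to_csv(out / "omega.tsv", sep="\t", index=False)
    ds.truth.go.to_csv(out / "go_annotations.tsv", sep="\t", index=False)
    ds.truth.mrna.to_csv(out / "mrna.tsv", sep="\t", index=False)
    (out / "exclusion_list.txt").write_text(
        "\n".join(ds.truth.exclusion_row_keys) + "\n"
    )
    manifest = {"seed": ds.params.seed, "params": asdict(ds.params)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
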