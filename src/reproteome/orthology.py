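"""Orthogroup-keyed merging of per-species protein quantitation tables.

Cross-species comparison requires a common key. An orthology map assigns
each protein to at most one orthogroup; merging the per-species tables on
orthogroups yields one combined matrix in which 1:1:1 orthogroups contribute
one row per species member and one-to-many orthogroups (gene families)
contribute a row per duplicate, analysed separately downstream. Raw summed
intensities are merged as-is: all channels come from a single multiplexed
run, so normalization is applied once on the combined matrix.

Row keys of the combined table are ``"<orthogroup>:<protein_id>"``.
"""

from __future__ import annotations

import pandas as pd

from .io import CHANNELS

ORTHOMAP_COLUMNS = ["protein_id", "species", "orthogroup"]


def read_orthomap(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ORTHOMAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df[ORTHOMAP_COLUMNS].copy()
    if df.duplicated(["protein_id", "species"]).any():
        raise ValueError(f"{path}: protein mapped to more than one orthogroup")
    return df


def write_orthomap(df: pd.DataFrame, path) -> None:
    df[ORTHOMAP_COLUMNS].to_csv(path, sep="\t", index=False)


def orthogroup_copy_counts(orthomap: pd.DataFrame) -> pd.DataFrame:
    """Per-(orthogroup, species) member counts."""
    return (
        orthomap.groupby(["orthogroup", "species"], sort=True)
        .size()
        .rename("n_copies")
        .reset_index()
    )


def family_membership(orthomap: pd.DataFrame) -> pd.Series:
    """Boolean per-protein flag: orthogroup has >1 member in at least one species.

    Such orthogroups represent gene families (one-to-many or many-to-one
    orthology); all their member proteins are flagged.
    """
    counts = orthogroup_copy_counts(orthomap)
    family_ogs = set(counts.loc[counts["n_copies"] > 1, "orthogroup"])
    flag = orthomap["orthogroup"].isin(family_ogs)
    flag.index = orthomap["protein_id"].to_numpy()
    flag.name = "is_family_member"
    return flag


def merge_by_orthogroup(
    tables: dict[str, pd.DataFrame], orthomap: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge filtered per-species protein tables into one combined table.

    Parameters
    ----------
    tables
        ``species -> proteins.tsv``-shaped DataFrame (already aggregated and
        peptide-filtered).
    orthomap
        protein_id / species / orthogroup assignments.

    Returns
    -------
    combined, unassigned
        ``combined`` has one row per (orthogroup, member protein) with
        columns ``row_key``, ``orthogroup``, ``protein_id``, ``species``,
        ``n_unique_peptides``, ``is_family_member``, ch01..ch16.
        ``unassigned`` lists proteins with no orthogroup, kept aside for
        within-species contrasts only.
    """
    fam = family_membership(orthomap)
    parts, missing = [], []
    for species, table in tables.items():
        if table["protein_id"].duplicated().any():
            dups = table.loc[table["protein_id"].duplicated(), "protein_id"].tolist()
            raise ValueError(f"{species}: duplicate protein IDs {dups[:5]}")
        om = orthomap[orthomap["species"] == species].set_index("protein_id")[
            "orthogroup"
        ]
        table = table.copy()
        table["species"] = species
        table["orthogroup"] = table["protein_id"].map(om)
        unmapped = table["orthogroup"].isna()
        missing.append(table[unmapped].drop(columns="orthogroup"))
        mapped = table[~unmapped].copy()
        mapped["is_family_member"] = mapped["protein_id"].map(fam).astype(bool)
        parts.append(mapped)

    combined = pd.concat(parts, ignore_index=True)
    combined["row_key"] = combined["orthogroup"] + ":" + combined["protein_id"]
    cols = [
        "row_key",
        "orthogroup",
        "protein_id",
        "species",
        "n_unique_peptides",
        "is_family_member",
        *CHANNELS,
    ]
    combined = combined[cols].sort_values("row_key", ignore_index=True)
    unassigned = pd.concat(missing, ignore_index=True)
    return combined, unassigned


def split_by_species(combined: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Invert :func:`merge_by_orthogroup` back to per-species protein tables."""
    out = {}
    for species, part in combined.groupby("species"):
        out[species] = (
            part[["protein_id", "n_unique_peptides", *CHANNELS]]
            .sort_values("protein_id", ignore_index=True)
        )
    return out
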