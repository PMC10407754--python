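"""Reading, writing and aggregation of isobaric-label quantitation tables.

The pipeline starts from per-peptide summed reporter-ion intensities: one row
per peptide x assigned protein, with one intensity column per TMT channel.
Protein abundances are the summed intensities of all associated peptides;
identification confidence is enforced downstream by requiring a minimum
number of unique peptides per protein.

File dialects (tab-separated, exact headers):

* ``peptides.tsv`` — ``peptide``, ``protein_id``, ``is_unique``,
  ``ch01`` .. ``ch16`` (nonnegative floats).
* ``design.tsv`` — ``channel``, ``species``, ``status`` (``virgin`` |
  ``mated``), ``replicate``.
* ``proteins.tsv`` — ``protein_id``, ``n_unique_peptides``, ``ch01`` ..
  ``ch16``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_CHANNELS = 16
CHANNELS = [f"ch{i:02d}" for i in range(1, N_CHANNELS + 1)]

PEPTIDE_COLUMNS = ["peptide", "protein_id", "is_unique", *CHANNELS]
DESIGN_COLUMNS = ["channel", "species", "status", "replicate"]
PROTEIN_COLUMNS = ["protein_id", "n_unique_peptides", *CHANNELS]

VALID_STATUSES = frozenset({"virgin", "mated"})


class FormatError(ValueError):
    """A table file does not conform to the documented dialect."""


class ValidationError(ValueError):
    """A table parses but violates a value constraint (e.g. negative intensity)."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide-level quantitation table.

    Returns a DataFrame with :data:`PEPTIDE_COLUMNS`; ``is_unique`` is
    boolean, intensities are floats. Malformed rows raise with 1-based line
    numbers (header is line 1).
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PEPTIDE_COLUMNS, path)
    df = df[PEPTIDE_COLUMNS].copy()

    bad = df["protein_id"].isna() | (df["protein_id"].astype(str).str.len() == 0)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValidationError(f"{path}: empty protein_id at line(s) {lines[:10]}")

    intens = df[CHANNELS].to_numpy(dtype=float)
    neg = np.where((intens < 0).any(axis=1))[0]
    if neg.size:
        lines = (neg + 2).tolist()
        raise ValidationError(f"{path}: negative intensity at line(s) {lines[:10]}")
    if not np.isfinite(intens).all():
        raise ValidationError(f"{path}: non-finite intensity values")

    df["is_unique"] = df["is_unique"].astype(bool)
    df[CHANNELS] = intens
    return df


def write_peptide_table(df: pd.DataFrame, path) -> None:
    df[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    """Read the sample design table mapping channels to (species, status, replicate)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, DESIGN_COLUMNS, path)
    df = df[DESIGN_COLUMNS].copy()
    return validate_design(df)


def write_design(df: pd.DataFrame, path) -> None:
    df[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    if design["channel"].duplicated().any():
        dups = design.loc[design["channel"].duplicated(), "channel"].tolist()
        raise ValidationError(f"duplicate channel label(s): {dups}")
    bad = set(design["status"]) - VALID_STATUSES
    if bad:
        raise ValidationError(f"unknown mating status value(s): {sorted(bad)}")
    return design


def design_channels(design: pd.DataFrame, species: str | None = None,
                    status: str | None = None) -> list[str]:
    """Channel labels matching a (species, status) selection."""
    mask = pd.Series(True, index=design.index)
    if species is not None:
        mask &= design["species"] == species
    if status is not None:
        mask &= design["status"] == status
    return design.loc[mask, "channel"].tolist()


def aggregate_to_protein(peptides: pd.DataFrame) -> pd.DataFrame:
    """Sum peptide reporter intensities into per-protein channel totals.

    Every assigned peptide contributes its intensity to its protein's sums;
    ``n_unique_peptides`` counts distinct peptide sequences flagged unique.
    Shared (non-unique) peptides therefore add intensity but never count
    toward identification support.
    """
    sums = peptides.groupby("protein_id", sort=True)[CHANNELS].sum()
    uniq = (
        peptides[peptides["is_unique"]]
        .groupby("protein_id")["peptide"]
        .nunique()
        .reindex(sums.index, fill_value=0)
        .astype(int)
    )
    out = sums.reset_index()
    out.insert(1, "n_unique_peptides", uniq.to_numpy())
    return out[PROTEIN_COLUMNS]


def filter_min_unique(proteins: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Retain proteins identified by at least ``k`` unique peptides.

    The default ``k=2`` is the conventional two-unique-peptide
    identification filter. Idempotent.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return proteins[proteins["n_unique_peptides"] >= k].reset_index(drop=True)


def read_protein_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PROTEIN_COLUMNS, path)
    return df[PROTEIN_COLUMNS]


def write_protein_table(df: pd.DataFrame, path) -> None:
    df[PROTEIN_COLUMNS].to_csv(path, sep="\t", index=False)
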