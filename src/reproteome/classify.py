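"""Classification of transferred ejaculate proteins and the FRT proteome.

A protein is called an ejaculate (transferred male) protein when it is
significantly more abundant in mated than in virgin lower-reproductive-tract
samples in at least one species — mating lasts minutes and the female
postmating response emerges hours later, so mated-biased abundance shortly
after copulation indicates male origin. Known female postmating-response
proteins are removed from the ejaculate list via a curated exclusion list.
Everything else quantified constitutes the female reproductive tract (FRT)
proteome; virgin-biased proteins are recorded separately but analysed with
the FRT set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

CLASSES = ("ejaculate", "FRT", "virgin-biased", "excluded")


def call_differential(
    result: pd.DataFrame, lfc_threshold: float = 1.0, q_threshold: float = 0.05
) -> pd.Series:
    """Per-row call in {up, down, ns} at |log2FC| and FDR thresholds.

    Defaults are the conventional |log2FC| > 1, BH q < 0.05.
    """
    if lfc_threshold <= 0 or q_threshold <= 0:
        raise ValueError("thresholds must be positive")
    sig = result["q"] < q_threshold
    call = np.where(
        sig & (result["log2fc"] > lfc_threshold),
        "up",
        np.where(sig & (result["log2fc"] < -lfc_threshold), "down", "ns"),
    )
    return pd.Series(call, index=result.index, name="call")


def classify_ejaculate(
    calls_by_species: dict[str, pd.Series],
    exclusion_list: list[str] | set[str] = (),
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Combine per-species mated-vs-virgin calls into a protein classification.

    Parameters
    ----------
    calls_by_species
        species -> per-row-key call Series ({up, down, ns}) from the
        mated-vs-virgin contrast of that species, all on the same index
        (the combined orthogroup table).
    exclusion_list
        Row keys of curated female postmating-response proteins; those that
        would be classified as ejaculate are moved to class ``excluded``.
    annotations
        Optional per-row-key table with a ``has_signal_peptide`` column.

    Returns
    -------
    DataFrame indexed by row key with ``class``, per-species ``up_<species>``
    flags, ``n_species_up``, ``shared_all_species`` and (if annotated)
    ``has_signal_peptide``. Classes are mutually exclusive and exhaustive.
    """
    species = sorted(calls_by_species)
    idx = calls_by_species[species[0]].index
    for sp in species[1:]:
        if not calls_by_species[sp].index.equals(idx):
            raise ValueError("per-species call indexes differ")

    out = pd.DataFrame(index=idx)
    for sp in species:
        out[f"up_{sp}"] = (calls_by_species[sp] == "up").to_numpy()
        out[f"down_{sp}"] = (calls_by_species[sp] == "down").to_numpy()
    up_any = out[[f"up_{sp}" for sp in species]].any(axis=1)
    down_any = out[[f"down_{sp}" for sp in species]].any(axis=1)
    out["n_species_up"] = out[[f"up_{sp}" for sp in species]].sum(axis=1)
    out["shared_all_species"] = out["n_species_up"] == len(species)

    excl = set(exclusion_list)
    missing = excl - set(idx)
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} exclusion-list ID(s) absent from the table",
            stacklevel=2,
        )
    on_excl = pd.Series([k in excl for k in idx], index=idx)

    cls = np.where(
        up_any & on_excl,
        "excluded",
        np.where(up_any, "ejaculate", np.where(down_any, "virgin-biased", "FRT")),
    )
    out.insert(0, "class", cls)

    if annotations is not None and "has_signal_peptide" in annotations.columns:
        out["has_signal_peptide"] = (
            annotations["has_signal_peptide"].reindex(idx).fillna(False).astype(bool)
        )
    return out


def frt_set(classification: pd.DataFrame) -> pd.Index:
    """Row keys analysed as the FRT proteome: FRT plus virgin-biased."""
    return classification.index[
        classification["class"].isin(["FRT", "virgin-biased"])
    ]


def signal_peptide_fraction(
    classification: pd.DataFrame, annotations: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of proteins carrying a predicted signal peptide, per class.

    Includes a Clopper-Pearson binomial confidence interval.
    """
    if "has_signal_peptide" in classification.columns:
        flags = classification["has_signal_peptide"]
    else:
        flags = (
            annotations["has_signal_peptide"]
            .reindex(classification.index)
            .fillna(False)
            .astype(bool)
        )
    rows = []
    for cls, grp in classification.groupby("class"):
        k = int(flags.loc[grp.index].sum())
        n = len(grp)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
        rows.append(
            {"class": cls, "n": n, "n_signal": k, "fraction": k / n if n else np.nan,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows).set_index("class")
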