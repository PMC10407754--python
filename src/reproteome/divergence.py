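"""Cross-species divergence in protein abundance.

Within the ejaculate set, species are contrasted on mated channels (the
transferred ejaculate is only present after mating); within the FRT set, on
virgin channels (so the male contribution cannot masquerade as female
divergence). Abundance profiles are summarised by replicate-averaged,
median-centred log2 values and grouped by k-means; association of divergence
with annotation flags uses Fisher's exact test; and whether gene-family
members are over- or under-represented in a protein set is tested with a
Monte-Carlo draw-without-replacement null, cross-checked against the
closed-form hypergeometric tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from . import diffabund
from .classify import call_differential
from .io import design_channels


def pairwise_divergence(
    norm: diffabund.NormalizedMatrix,
    design: pd.DataFrame,
    subset: pd.Index | list[str],
    species_a: str,
    species_b: str,
    status: str,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential abundance between two species on one mating status.

    Restricted to ``subset`` row keys; BH adjustment is applied within this
    contrast only. Returns the moderated-model columns plus ``call``.
    """
    subset = pd.Index(subset)
    if subset.empty:
        raise ValueError("empty row subset")
    ch_a = design_channels(design, species_a, status)
    ch_b = design_channels(design, species_b, status)
    if not ch_a or not ch_b:
        missing = species_a if not ch_a else species_b
        raise ValueError(f"no {status} channels for species {missing}")
    sub = diffabund.NormalizedMatrix(
        log2=norm.log2.loc[subset],
        factors=norm.factors,
        channel_totals=norm.channel_totals,
        pseudocount=norm.pseudocount,
    )
    res = diffabund.fit_moderated(sub, design, (ch_a, ch_b))
    res["call"] = call_differential(res, lfc_threshold, q_threshold)
    return res


def replicate_average_center(
    norm_log2: pd.DataFrame,
    design: pd.DataFrame,
    groups: list[tuple[str, str | None]],
) -> pd.DataFrame:
    """Median-centred log2 abundances averaged across biological replicates.

    ``groups`` is a list of (species, status) pairs (status ``None`` pools
    both statuses). Per row: arithmetic mean of log2 values within each
    group, then the per-row median across groups is subtracted.
    """
    cols = {}
    for species, status in groups:
        ch = design_channels(design, species, status)
        if not ch:
            raise ValueError(f"empty group ({species}, {status})")
        label = species if status is None else f"{species}_{status}"
        cols[label] = norm_log2[ch].mean(axis=1)
    means = pd.DataFrame(cols)
    return means.sub(means.median(axis=1), axis=0)


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series       # 1..k per row
    centroids: np.ndarray   # k x n_groups, log2 units
    wss: float              # within-cluster sum of squares
    seed: int


def kmeans_cluster(
    centered: pd.DataFrame, k: int, seed: int = 1, n_restarts: int = 100
) -> ClusterResult:
    """Best-of-restarts k-means (squared Euclidean, k-means++ seeding)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(centered):
        raise ValueError(f"k={k} exceeds row count {len(centered)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(centered.to_numpy())
    return ClusterResult(
        k=k,
        labels=pd.Series(labels + 1, index=centered.index, name="cluster"),
        centroids=km.cluster_centers_,
        wss=float(km.inertia_),
        seed=seed,
    )


def fisher_association(
    set_members: set | pd.Index,
    annotation_flag: pd.Series,
    universe: pd.Index | list[str],
) -> dict:
    """2x2 Fisher's exact test: set membership vs. a boolean annotation.

    Tests, within ``universe``, whether flagged proteins are over- or
    under-represented in ``set_members`` (two-sided).
    """
    universe = pd.Index(universe)
    if universe.empty:
        raise ValueError("empty universe")
    members = set(set_members)
    if not members <= set(universe):
        raise ValueError("set is not contained in the universe")
    flag = annotation_flag.reindex(universe).fillna(False).astype(bool)
    in_set = universe.isin(members)
    a = int((in_set & flag).sum())
    b = int((in_set & ~flag).sum())
    c = int((~in_set & flag).sum())
    d = int((~in_set & ~flag).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return {"table": [[a, b], [c, d]], "odds_ratio": odds, "p": float(p)}


@dataclass
class ResamplingResult:
    """Monte-Carlo and closed-form tails for a draw-without-replacement null."""

    pool_size: int              # N
    annotated_in_pool: int      # K
    sample_size: int            # n
    observed: int               # k_obs
    draws: int                  # B
    p_upper_mc: float           # (1 + #{draws >= k_obs}) / (B + 1)
    p_lower_mc: float
    p_upper_hypergeom: float    # P(X >= k_obs)
    p_lower_hypergeom: float    # P(X <= k_obs)
    seed: int
    expected: float = field(init=False)

    def __post_init__(self):
        self.expected = self.sample_size * self.annotated_in_pool / self.pool_size


def family_resampling_test(
    sample_keys,
    pool_keys,
    family_flags: pd.Series,
    b: int = 99_999,
    seed: int = 1,
    chunk: int = 2000,
) -> ResamplingResult:
    """Is the annotated count in a sample extreme under random draws from the pool?

    Draws ``b`` samples of ``len(sample_keys)`` keys without replacement from
    the pool (random-key order statistics, chunked) and reports both
    Monte-Carlo tail probabilities with the add-one estimator, alongside the
    exact hypergeometric tails. Both tails are reported because "at least as
    many" and "at most as many" answer different questions and overlap at
    the observed count (so p_upper + p_lower >= 1).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    pool = pd.Index(pool_keys)
    sample = pd.Index(sample_keys)
    if len(sample) > len(pool):
        raise ValueError("sample larger than pool")
    if not set(sample) <= set(pool):
        raise ValueError("sample is not a subset of the pool")

    flags = family_flags.reindex(pool).fillna(False).astype(bool).to_numpy()
    n, n_pool = len(sample), len(pool)
    k_obs = int(family_flags.reindex(sample).fillna(False).astype(bool).sum())
    big_k = int(flags.sum())

    rng = np.random.default_rng(seed)
    n_ge = n_le = 0
    remaining = b
    while remaining > 0:
        m = min(chunk, remaining)
        keys = rng.random((m, n_pool))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        counts = flags[idx].sum(axis=1)
        n_ge += int((counts >= k_obs).sum())
        n_le += int((counts <= k_obs).sum())
        remaining -= m

    return ResamplingResult(
        pool_size=n_pool,
        annotated_in_pool=big_k,
        sample_size=n,
        observed=k_obs,
        draws=b,
        p_upper_mc=(1 + n_ge) / (b + 1),
        p_lower_mc=(1 + n_le) / (b + 1),
        p_upper_hypergeom=float(stats.hypergeom.sf(k_obs - 1, n_pool, big_k, n)),
        p_lower_hypergeom=float(stats.hypergeom.cdf(k_obs, n_pool, big_k, n)),
        seed=seed,
    )
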