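"""Evolutionary-rate comparisons, GO enrichment, mRNA-protein correlation, PCA.

dN/dS (omega) distributions are compared between protein classes — e.g.
secreted ejaculate proteins vs. the rest of the ejaculate, secreted FRT
proteins vs. serine-type endopeptidases, each vs. the genome average — with
Mann-Whitney U tests, since omega is bounded below and strongly skewed.
GO term enrichment uses one-sided Fisher (hypergeometric) tests with a
minimum annotated-term size, BH-adjusted across tested terms. Sample
structure is summarised by PCA of the most variable proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import bh_adjust


def mannwhitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U statistic (for x) and p-value.

    Exact p by enumeration when n1 + n2 <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    small = x.size + y.size <= 12
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_rate_groups(
    omega: pd.DataFrame,
    groups: dict[str, pd.Index | list[str]],
    comparisons: list[tuple[str, str]] | None = None,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species-pair group summaries and Mann-Whitney comparisons of omega.

    Parameters
    ----------
    omega
        Long table with columns ``key``, ``pair``, ``omega`` (missing rows
        allowed: proteins without an estimated rate are simply absent).
    groups
        group name -> protein/orthogroup keys. A group with no omega values
        for a pair is skipped with a warning.
    comparisons
        (group_a, group_b) pairs to test; all unordered pairs by default.

    Returns
    -------
    summary
        pair x group: n, mean omega, SE.
    tests
        pair x comparison: n_a, n_b, U, p.
    """
    if comparisons is None:
        comparisons = list(combinations(groups, 2))

    summaries, tests = [], []
    for pair, sub in omega.groupby("pair"):
        by_key = sub.set_index("key")["omega"]
        values = {}
        for name, keys in groups.items():
            v = by_key.reindex(pd.Index(keys).unique()).dropna().to_numpy()
            if v.size == 0:
                import warnings

                warnings.warn(f"group {name!r} has no omega values for {pair}",
                              stacklevel=2)
                continue
            values[name] = v
            summaries.append(
                {"pair": pair, "group": name, "n": v.size,
                 "mean_omega": float(v.mean()),
                 "se_omega": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1
                 else np.nan}
            )
        for a, b in comparisons:
            if a not in values or b not in values:
                continue
            u, p = mannwhitney_u(values[a], values[b], alternative=alternative)
            tests.append({"pair": pair, "group_a": a, "group_b": b,
                          "n_a": values[a].size, "n_b": values[b].size,
                          "U": u, "p": p})
    return pd.DataFrame(summaries), pd.DataFrame(tests)


def go_enrichment(
    foreground,
    background,
    go_annotations: pd.DataFrame,
    min_genes: int = 15,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric) GO term enrichment.

    ``go_annotations`` is a long table with columns ``key``, ``term`` and
    optionally ``branch`` (BP|CC|MF). Only terms annotating at least
    ``min_genes`` background keys are tested; p-values are BH-adjusted
    across the tested terms. Returns one row per tested term, sorted by p,
    with a ``significant`` flag at ``q < q_threshold``.
    """
    fg = pd.Index(foreground).unique()
    bg = pd.Index(background).unique()
    if not set(fg) <= set(bg):
        raise ValueError("foreground is not a subset of the background")
    if fg.empty:
        return pd.DataFrame(
            columns=["term", "branch", "n_background", "n_foreground",
                     "expected", "p", "q", "significant"]
        )

    ann = go_annotations[go_annotations["key"].isin(bg)]
    has_branch = "branch" in ann.columns
    n_bg, n_fg = len(bg), len(fg)
    fg_set = set(fg)

    rows = []
    for term, grp in ann.groupby("term"):
        keys = grp["key"].unique()
        k_bg = len(keys)
        if k_bg < min_genes:
            continue
        k_fg = sum(k in fg_set for k in keys)
        # P(X >= k_fg) drawing n_fg from n_bg with k_bg annotated
        p = float(stats.hypergeom.sf(k_fg - 1, n_bg, k_bg, n_fg))
        rows.append(
            {"term": term,
             "branch": grp["branch"].iloc[0] if has_branch else "",
             "n_background": k_bg, "n_foreground": k_fg,
             "expected": n_fg * k_bg / n_bg, "p": p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "branch", "n_background", "n_foreground",
                     "expected", "p", "q", "significant"]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out.sort_values("p", ignore_index=True)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # samples x components
    variance_pct: np.ndarray        # % of variance per component
    selected: pd.Index              # proteins used


def pca_top_variable(norm_log2: pd.DataFrame, n_top: int = 500) -> PCAResult:
    """PCA of samples on the most variable proteins.

    Rows (proteins) are ranked by variance across channels; the top ``n_top``
    are kept (all, with a warning, if fewer exist). Samples are projected on
    the principal axes of the selected sub-matrix after per-protein mean
    centering; no variance scaling.
    """
    if norm_log2.shape[1] < 2:
        raise ValueError("need at least two samples")
    variances = norm_log2.var(axis=1)
    if len(norm_log2) < n_top:
        import warnings

        warnings.warn(
            f"only {len(norm_log2)} proteins available; using all", stacklevel=2
        )
        n_top = len(norm_log2)
    selected = variances.sort_values(ascending=False).index[:n_top]
    x = norm_log2.loc[selected].to_numpy().T          # samples x proteins
    x = x - x.mean(axis=0, keepdims=True)             # center each protein
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    ncomp = min(x.shape[0] - 1, x.shape[1])           # rank after centering
    scores, var = scores[:, :ncomp], var[:ncomp]
    pct = 100.0 * var / var.sum()
    cols = [f"PC{i + 1}" for i in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=norm_log2.columns, columns=cols),
        variance_pct=pct,
        selected=selected,
    )
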