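"""Normalization and moderated differential-abundance statistics.

The quantitative backbone of every contrast in the pipeline:

1. **TMM scaling factors** — between-channel normalization by the trimmed
   mean of M-values. For each channel a scaling factor is computed from
   log2 abundance ratios (M) against a reference channel, double-trimmed
   (30% on M, 5% on average log abundance A) and precision-weighted, then
   the factor vector is rescaled to geometric mean 1.
2. **log2 normalization** — intensities are divided by the effective
   library size (channel total x TMM factor), scaled to a common constant,
   offset by a pseudocount and logged.
3. **Moderated two-group linear model** — per protein, the two-group
   difference of means with an empirical-Bayes variance: the residual
   variance s^2 (pooled, d degrees of freedom) is shrunk toward a prior
   s0^2 carrying d0 prior degrees of freedom,

       s~^2 = (d0 s0^2 + d s^2) / (d0 + d),

   with (d0, s0^2) estimated by method of moments on log s^2 using
   digamma/trigamma matching. The moderated t = log2FC / (s~ sqrt(1/nA+1/nB))
   is referred to a t distribution on d0 + d degrees of freedom. Borrowing
   strength across proteins is what makes n = 2 replicate groups usable.
4. **Benjamini-Hochberg** step-up adjustment, applied per contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import design_channels

SCALE_CONSTANT = 1e6  # normalized abundances are on a counts-per-million-like scale


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def choose_reference_channel(matrix: pd.DataFrame) -> str:
    """Reference = channel whose total intensity is closest to the mean total."""
    totals = matrix.sum(axis=0)
    return (totals - totals.mean()).abs().idxmin()


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    # rows with a zero in either channel carry no usable log-ratio
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.abs(m).max() < 1e-6:
        return 1.0

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(
    matrix: pd.DataFrame,
    reference_channel: str | None = None,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per channel.

    ``matrix`` is proteins x channels of nonnegative raw intensities.
    Factors are precision-weighted trimmed means of M-values against the
    reference channel, rescaled to geometric mean 1.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM needs at least two channels")
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative intensities")
    totals = x.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero channel(s): {list(matrix.columns[zero])}")
    if reference_channel is None:
        reference_channel = choose_reference_channel(matrix)
    r = matrix.columns.get_loc(reference_channel)

    f = np.array(
        [
            _tmm_pair(x[:, k], x[:, r], totals[k], totals[r], trim_m, trim_a)
            for k in range(x.shape[1])
        ]
    )
    f /= np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=matrix.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """log2 normalized abundances plus the scaling used to produce them."""

    log2: pd.DataFrame           # proteins x channels
    factors: pd.Series           # TMM factor per channel (geometric mean 1)
    channel_totals: pd.Series
    pseudocount: float

    @property
    def channels(self) -> list[str]:
        return list(self.log2.columns)


def normalize_log2(
    matrix: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> NormalizedMatrix:
    """log2((x + pseudocount) / (channel_total * factor) * scale_constant)."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be > 0, got {pseudocount}")
    if factors is None:
        factors = tmm_factors(matrix)
    totals = matrix.sum(axis=0)
    eff = totals * factors.reindex(matrix.columns)
    log2 = np.log2((matrix + pseudocount) / eff * SCALE_CONSTANT)
    return NormalizedMatrix(
        log2=log2, factors=factors, channel_totals=totals, pseudocount=pseudocount
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes moderated two-group model
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    # starting value: trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior on variances.

    Matches the first two moments of log s^2 (for s^2 > 0) through the
    digamma/trigamma identities for log chi-square variables. Returns
    ``(d0, s0_squared)``; ``d0`` may be ``inf`` when the observed spread of
    log s^2 is no larger than sampling noise alone (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.median(s2)) if s2.size else 1.0
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2.0)
    if e_var < 1e-12:
        # degenerate: all residual variances identical; the common variance
        # is that value itself (no sampling-spread correction applies)
        return np.inf, float(np.exp(np.mean(np.log(s2))))
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    contrast: tuple[list[str], list[str]],
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group contrast on a normalized matrix.

    ``contrast`` is ``(channels_A, channels_B)``; log2FC = mean(A) - mean(B),
    so positive values mean higher abundance in group A.

    Returns a DataFrame indexed like ``norm.log2`` with columns ``log2fc``,
    ``t_mod``, ``df_resid``, ``d0``, ``s0_sq``, ``p``, ``q``. q-values are BH
    within this contrast.
    """
    ch_a, ch_b = contrast
    for name, ch in (("A", ch_a), ("B", ch_b)):
        if len(ch) < 2:
            raise ValueError(
                f"group {name} has {len(ch)} channel(s); need >=2 for a variance"
            )
        absent = set(ch) - set(norm.channels)
        if absent:
            raise ValueError(f"group {name}: unknown channel(s) {sorted(absent)}")

    xa = norm.log2[ch_a].to_numpy()
    xb = norm.log2[ch_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    df_resid = na + nb - 2

    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    log2fc = mean_a - mean_b
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + (
        (xb - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = d0_override
        _, s0_sq = estimate_prior(s2, df_resid)
    else:
        d0, s0_sq = estimate_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = float(d0 + df_resid)
    # zero-variance rows fall back to the prior variance alone
    s2_post = np.where(s2 == 0, s0_sq if np.isfinite(s0_sq) else s2_post, s2_post)

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_mod": t_mod,
            "df_resid": float(df_resid),
            "d0": d0,
            "s0_sq": s0_sq,
            "p": p,
            "q": bh_adjust(p),
        },
        index=norm.log2.index,
    )


def fit_group_contrast(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    group_a: tuple[str, str],
    group_b: tuple[str, str],
    **kwargs,
) -> pd.DataFrame:
    """Contrast two (species, status) groups of the design table."""
    ch_a = design_channels(design, *group_a)
    ch_b = design_channels(design, *group_b)
    return fit_moderated(norm, design, (ch_a, ch_b), **kwargs)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
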