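# Methods

## Statistical model

### Normalization

Channels of a multiplexed isobaric-label run differ in total signal for
technical reasons. We compute trimmed-mean-of-M-values (TMM) scaling
factors: for channel *k* against a reference channel *r* (the channel whose
total is closest to the mean total), per-protein log-ratios
M = log2((x_k/N_k)/(x_r/N_r)) and average abundances
A = ½·log2((x_k/N_k)(x_r/N_r)) are formed over proteins with nonzero signal
in both channels; rows in the outer 30 % of the M ranks or outer 5 % of the
A ranks are trimmed, the rest averaged with inverse asymptotic-variance
(delta-method binomial) weights, and the factor is 2 to that mean. Factors
are rescaled to geometric mean 1. Normalized abundance is
`log2((x + c) / (N_k · f_k) · 10⁶)` with pseudocount c = 0.5 (configurable);
intensities are continuous, not rounded. We use a single scaling of the
combined cross-species matrix because all 16 channels come from one
co-labeled run — there is no batch structure to remove.

### Moderated two-group model

Each contrast (mated vs. virgin within a species; species A vs. B within a
mating status) is a per-protein two-group comparison of normalized log2
abundances. With group sizes n_A, n_B (d = n_A + n_B − 2 residual df,
supporting the design's n = 2 virgin groups), the pooled residual variance
s² is shrunk toward a prior:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)
    t   = (mean_A − mean_B) / (s̃·√(1/n_A + 1/n_B)),  t ~ t(d₀ + d)

The prior (d₀, s₀²) is estimated by method of moments on log s² using the
log-chi-square identities: the mean of log s² − ψ(d/2) + log(d/2) and its
variance in excess of ψ′(d/2) determine s₀² and d₀ through digamma/trigamma
matching (trigamma inverted by Newton iteration). Degenerate cases: rows
with s² = 0 are excluded from moment estimation and assigned s̃² = s₀²; if
the spread of log s² does not exceed its sampling component, d₀ = ∞
(complete shrinkage, normal reference distribution); if all s² are exactly
equal, the common variance is taken as-is so moderation reduces to the
ordinary pooled t. p-values are two-sided; Benjamini–Hochberg adjustment is
applied separately within each contrast family, matching how per-contrast
candidate counts are reported.

We implement one coherent path — TMM scaling, log2 transform, moderated
linear model — without observation-level precision weights: reporter-ion
intensities are not counts, and this path covers every contrast the
pipeline reports. Calls use log2FC > |1| and q < 0.05 (both strict).

### Classification

Ejaculate = mated-biased call in at least one species (union rule: a
protein transferred by only one species' males is still ejaculate-derived),
minus the curated exclusion list of known female postmating-response
proteins (moved to class `excluded` only when they would otherwise be
called ejaculate). Virgin-biased proteins are reported separately but
retained within the FRT set for divergence analyses; the four classes
partition the quantified rows exactly.

### Divergence and context analyses

Species-pair contrasts use mated channels for the ejaculate set (the
transferred ejaculate exists only after mating) and virgin channels for the
FRT set (so male material cannot masquerade as female divergence). Profile
heatmaps/clusters use per-group replicate means of normalized log2 values,
median-centred per row; k-means uses squared-Euclidean k-means++ with 100
restarts and a fixed seed (k = 7 ejaculate, k = 4 FRT; k is fixed by
design, no model selection). Gene-family representation in the ejaculate
set is tested by drawing B = 99,999 samples of the same size without
replacement from the pool of all quantified rows; both tail probabilities
(1 + #extreme)/(B + 1) are reported with the closed-form hypergeometric
tails alongside, because "at least" and "at most" answer different
questions and overlap at the observed count. ω (dN/dS) group comparisons
use Mann–Whitney U (exact by enumeration for n₁+n₂ ≤ 12 without ties,
otherwise normal approximation with tie and continuity corrections), since
ω is bounded and skewed. GO enrichment is a one-sided hypergeometric test
per pre-propagated term with ≥ 15 annotated background genes, BH-adjusted
across tested terms; no DAG traversal. PCA takes the 500 most variable
proteins, mean-centres each protein and decomposes sample covariance by
SVD; no unit-variance scaling (scaling would equalize the contribution of
low-variance proteins, which is exactly what the top-variance selection
avoids).

## Synthetic data generator

The generator emulates the study conditions and provides the ground truth
the recovery tests score against.

Design: 16 channels — 3 mated replicates × 3 species, 3 virgin *D. virilis*,
2 virgin each for the other two species.

Abundance model: per-orthogroup log2-normal baselines
(mean 18, SD 2 on the log2-intensity scale); per-peptide multiplicative
offsets N(0, 1) drawn once and shared across channels (mimicking
peptide-specific ionization efficiency without modeling ratio compression);
independent per-peptide-per-channel noise N(0, 0.5). Peptide counts are
max(2, 1 + Poisson(3)) with a 5 % fraction forced to exactly one unique
peptide to exercise the ≥ 2-peptide filter, plus ~1 % shared (non-unique)
peptides assigned to two proteins. No missingness by default (isobaric
multiplexing is near-complete); an optional dropout rate supports
robustness tests.

Planted structure, with defaults:

| quantity | default | rationale |
|---|---|---|
| orthogroups | 2000 | desk-scale stand-in for the ~2100-orthogroup combined database |
| gene-family fraction | 0.05 | ~95 % of orthogroups are 1:1:1 |
| ejaculate fraction | 0.10 | ~200 ejaculate orthogroups among ~2000 |
| mated-channel shift | +3 log2 | strong transfer signal, the classifier's acceptance surface |
| ejaculate baseline offset | −5 log2 | male-derived proteins sit near the virgin-sample floor, so even after the +3 shift their measured abundance stays below the typical FRT protein — reproducing the observed direction that ejaculate proteins are the less abundant class |
| transfer probability/species | 0.75 (≥ 1 forced) | each species' males transfer a species-specific subset, yielding both shared and species-unique ejaculate proteins |
| divergent fraction | 0.35 | between the ejaculate (~60 %) and FRT (~20–35 %) divergence rates |
| divergence effect | ±2 log2 on one species | recovery condition for species contrasts |
| signal-peptide probability | 0.52 ejaculate / 0.41 FRT | the two classes' secretion-signal rates |
| postmating-response proteins | 12, +2 log2 when mated | the confound the exclusion list removes |
| mRNA–protein target r | 0.45 (secretory tissues) | middle of the 0.25–0.6 range; other tissues/classes r ≈ 0.1 |

ω values are Gamma(2, ·) per species pair with class means: secreted
ejaculate 0.28, non-secreted ejaculate 0.18, secreted FRT serine-type
endopeptidase 0.27, other secreted FRT 0.14, non-secreted FRT 0.10, and a
4,000-gene genome background at 0.18 — reproducing the orderings the rate
comparisons probe (secreted ejaculate and female endopeptidases fastest;
FRT below genome average). GO terms are drawn per orthogroup (shared by
orthologs): one term encodes the endopeptidase flag exactly, five terms are
planted at elevated frequency among ejaculate orthogroups, the rest are
background. mRNA abundances are linear in true protein log2 abundance with
noise variance solved from the target correlation.

Within-group variance of protein abundances is not reported by any upstream
source at the peptide level; the SDs above are this package's declared
defaults, chosen to be realistic for MS3 reporter-ion data, and live in
`SimulationParams`, not asserted as properties of any real dataset.

What the generator does **not** emulate: spectra, isotopic impurity,
co-isolation interference/ratio compression, retention-time effects,
peptide-level missingness structure, or correlated noise between channels.
Passing recovery tests therefore demonstrates that the statistical pipeline
is correct and calibrated under its own assumptions — not that those
assumptions hold for any particular instrument run.

## Numerical choices

- Pseudocount 0.5 before log2; TMM trims 30 % (M) / 5 % (A); reference
  channel = total closest to the mean total.
- Trigamma inversion by Newton with starting value 0.5 + 1/y, tolerance
  1e-10.
- p-values clipped to the smallest positive float to keep downstream logs
  finite; BH capped at 1.
- k-means ties and restarts resolved by fixed seed (default 1);
  Monte-Carlo resampling uses random-key order statistics in chunks of
  2,000 draws — genuine without-replacement sampling, kept independent of
  the closed-form hypergeometric check.
- Determinism: every stochastic component takes a named seed; fixed seeds
  give byte-identical outputs (tested).

## Problem sizes

Default analyses run at 2,000 orthogroups (~5,800 combined rows); the
null-calibration study uses 200 independent no-effect datasets at the same
scale, and the resampling test its full B = 99,999 draws. These sizes give
each statistical check comfortable resolution (e.g. Monte-Carlo SE of the
null false-discovery rate ≈ 0.015) while the whole suite plus acceptance
script completes in a few minutes on one CPU.

## Known limitations

- The ejaculate/FRT split inherits the operational definition: female
  proteins induced within minutes of mating (beyond the curated exclusion
  list) would be misclassified as ejaculate.
- One-to-many orthogroups are analysed one row per member; cross-species
  comparisons for such rows compare a single protein's profile across
  channels and cannot apportion signal between co-orthologs.
- The moderated model assumes equal group variances per protein; strong
  heteroscedasticity between species would call for per-group variances.
- GO enrichment treats terms as flat pre-propagated sets; parent/child
  dependence between terms is not modeled.
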