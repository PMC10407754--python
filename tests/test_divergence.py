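"""Cross-species divergence: contrasts, centering, clustering, association,
and the gene-family resampling null."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reproteome import diffabund, divergence
from reproteome.io import CHANNELS
from reproteome.simulate import SPECIES_PAIRS


class TestPairwiseDivergence:
    def test_calls_antisymmetric_in_species_order(self, small_pipeline):
        res = small_pipeline
        cl = res.classification
        rows = cl.index[cl["class"] == "ejaculate"]
        a, b = "americana", "virilis"
        fwd = divergence.pairwise_divergence(
            res.norm, res.design, rows, a, b, "mated"
        )
        rev = divergence.pairwise_divergence(
            res.norm, res.design, rows, b, a, "mated"
        )
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], rtol=1e-10)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-10)
        assert ((fwd["call"] == "up") == (rev["call"] == "down")).all()
        assert (fwd["call"] != "ns").sum() == (rev["call"] != "ns").sum()

    def test_identical_profiles_give_zero_calls(self):
        rng = np.random.default_rng(0)
        base = rng.normal(20, 2, 300)
        channels = CHANNELS[:8]
        # two species, four channels each, identical distribution
        x = base[:, None] + rng.normal(0, 0.3, (300, 8))
        norm = diffabund.NormalizedMatrix(
            log2=pd.DataFrame(x, columns=channels,
                              index=[f"r{i}" for i in range(300)]),
            factors=pd.Series(1.0, index=channels),
            channel_totals=pd.Series(1.0, index=channels),
            pseudocount=0.5,
        )
        design = pd.DataFrame(
            {"channel": channels, "species": ["a"] * 4 + ["b"] * 4,
             "status": "mated", "replicate": list(range(1, 5)) * 2}
        )
        res = divergence.pairwise_divergence(
            norm, design, norm.log2.index, "a", "b", "mated"
        )
        assert (res["call"] == "ns").mean() > 0.99

    def test_missing_status_channels_error(self, small_pipeline):
        res = small_pipeline
        rows = res.classification.index[:10]
        bad_design = res.design[res.design["status"] == "mated"]
        with pytest.raises(ValueError, match="no virgin channels"):
            divergence.pairwise_divergence(
                res.norm, bad_design, rows, "americana", "virilis", "virgin"
            )


class TestReplicateAverageCenter:
    design = pd.DataFrame(
        {"channel": CHANNELS[:6], "species": ["a", "a", "b", "b", "c", "c"],
         "status": "mated", "replicate": [1, 2] * 3}
    )

    def test_group_means_then_median_centering(self):
        x = pd.DataFrame(
            [[0, 2, 2, 2, 3, 3]], columns=CHANNELS[:6], dtype=float
        )
        out = divergence.replicate_average_center(
            x, self.design, [(s, "mated") for s in "abc"]
        )
        np.testing.assert_allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_single_group_is_all_zero(self):
        x = pd.DataFrame([[1.0, 5.0]], columns=CHANNELS[:2])
        design = self.design.iloc[:2]
        out = divergence.replicate_average_center(x, design, [("a", "mated")])
        np.testing.assert_allclose(out.to_numpy(), 0.0)

    def test_matches_formula_oracle_on_random_matrix(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(0, 1, (40, 6)), columns=CHANNELS[:6])
        out = divergence.replicate_average_center(
            x, self.design, [(s, "mated") for s in "abc"]
        )
        means = np.stack(
            [x[CHANNELS[i:i + 2]].mean(axis=1) for i in (0, 2, 4)], axis=1
        )
        expected = means - np.median(means, axis=1, keepdims=True)
        np.testing.assert_allclose(out.to_numpy(), expected, rtol=1e-12)

    def test_empty_group_rejected(self):
        x = pd.DataFrame([[1.0, 2.0]], columns=CHANNELS[:2])
        with pytest.raises(ValueError, match="empty group"):
            divergence.replicate_average_center(
                x, self.design.iloc[:2], [("zz", "mated")]
            )


class TestKMeans:
    def test_separated_duplicated_rows_get_pure_clusters(self):
        base = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        x = pd.DataFrame(np.repeat(base, 5, axis=0))
        res = divergence.kmeans_cluster(x, k=3, seed=0)
        assert res.wss == pytest.approx(0.0, abs=1e-12)
        labels = res.labels.to_numpy().reshape(3, 5)
        assert all(len(set(row)) == 1 for row in labels)
        assert len({row[0] for row in labels}) == 3

    def test_beats_random_labelings(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(0, 1, (120, 4)))
        res = divergence.kmeans_cluster(x, k=5, seed=1)
        arr = x.to_numpy()
        for _ in range(100):
            labels = rng.integers(0, 5, 120)
            wss = sum(
                ((arr[labels == j] - arr[labels == j].mean(axis=0)) ** 2).sum()
                for j in range(5)
                if (labels == j).any()
            )
            assert res.wss <= wss + 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.normal(0, 1, (60, 3)))
        r1 = divergence.kmeans_cluster(x, k=4, seed=9)
        r2 = divergence.kmeans_cluster(x, k=4, seed=9)
        assert (r1.labels == r2.labels).all()
        assert r1.wss == r2.wss

    def test_invalid_k_rejected(self):
        x = pd.DataFrame(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            divergence.kmeans_cluster(x, k=0)
        with pytest.raises(ValueError):
            divergence.kmeans_cluster(x, k=6)


def enumerate_fisher_two_sided(table):
    """Exact two-sided p by enumerating all tables with the same margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = stats.hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(total, 1.0)


class TestFisherAssociation:
    def _run(self, a, b, c, d):
        universe = pd.Index([f"x{i}" for i in range(a + b + c + d)])
        members = set(universe[: a + b])
        flag = pd.Series(
            [True] * a + [False] * b + [True] * c + [False] * d, index=universe
        )
        return divergence.fisher_association(members, flag, universe)

    def test_balanced_table_p_one(self):
        assert self._run(5, 5, 5, 5)["p"] == pytest.approx(1.0)

    def test_perfect_association_exact_value(self):
        out = self._run(10, 0, 0, 10)
        assert out["p"] == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_symmetry_under_flag_inversion(self):
        out1 = self._run(8, 2, 4, 10)
        out2 = self._run(2, 8, 10, 4)  # inverted annotation flag
        assert out1["p"] == pytest.approx(out2["p"], rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 12, 4)
        if a + b == 0 or c + d == 0:
            a, d = a + 1, d + 1
        out = self._run(int(a), int(b), int(c), int(d))
        expected = enumerate_fisher_two_sided([[a, b], [c, d]])
        assert out["p"] == pytest.approx(expected, abs=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty universe"):
            divergence.fisher_association(set(), pd.Series(dtype=bool), [])


class TestFamilyResampling:
    def _flags(self, n_pool, n_flagged, prefix="k"):
        keys = [f"{prefix}{i}" for i in range(n_pool)]
        flags = pd.Series([i < n_flagged for i in range(n_pool)], index=keys)
        return keys, flags

    def test_sample_equals_pool_both_tails_one(self):
        keys, flags = self._flags(20, 7)
        res = divergence.family_resampling_test(keys, keys, flags, b=99, seed=0)
        assert res.p_upper_mc == 1.0 and res.p_lower_mc == 1.0
        assert res.p_upper_hypergeom == pytest.approx(1.0)
        assert res.p_lower_hypergeom == pytest.approx(1.0)

    def test_zero_observed_lower_tail_one(self):
        keys, flags = self._flags(30, 10)
        sample = [k for k in keys if not flags[k]][:5]
        res = divergence.family_resampling_test(sample, keys, flags, b=99, seed=0)
        assert res.observed == 0
        # every draw contains at least as many flagged keys as the observed 0
        assert res.p_upper_mc == 1.0
        assert res.p_upper_hypergeom == pytest.approx(1.0)

    def test_monte_carlo_matches_hypergeometric_tails(self):
        # N=50, K=20, n=10 against the closed form, 3 sigma of B=99,999 draws
        keys, flags = self._flags(50, 20)
        rng = np.random.default_rng(17)
        sample = list(rng.choice(keys, size=10, replace=False))
        res = divergence.family_resampling_test(
            sample, keys, flags, b=99_999, seed=23
        )
        for mc, exact in [
            (res.p_upper_mc, res.p_upper_hypergeom),
            (res.p_lower_mc, res.p_lower_hypergeom),
        ]:
            se = math.sqrt(exact * (1 - exact) / res.draws)
            assert abs(mc - exact) <= 3 * se + 2 / res.draws

    def test_tails_overlap_at_observed(self):
        keys, flags = self._flags(40, 15)
        sample = keys[5:17]
        res = divergence.family_resampling_test(sample, keys, flags, b=999, seed=3)
        assert res.p_upper_mc + res.p_lower_mc >= 1.0
        assert res.p_upper_hypergeom + res.p_lower_hypergeom >= 1.0

    def test_sample_larger_than_pool_rejected(self):
        keys, flags = self._flags(5, 2)
        with pytest.raises(ValueError, match="larger than pool"):
            divergence.family_resampling_test(keys + ["extra"], keys, flags)

    def test_deterministic_given_seed(self):
        keys, flags = self._flags(30, 12)
        r1 = divergence.family_resampling_test(keys[:8], keys, flags, b=499, seed=5)
        r2 = divergence.family_resampling_test(keys[:8], keys, flags, b=499, seed=5)
        assert r1.p_upper_mc == r2.p_upper_mc and r1.p_lower_mc == r2.p_lower_mc


def test_planted_family_divergence_recovered(small_pipeline, small_dataset):
    """When family ejaculate proteins carry planted between-species effects,
    nearly all are called differentially abundant in at least one pair."""
    res = small_pipeline
    cl = res.classification
    comb = res.combined.set_index("row_key")
    fam_ej = cl.index[(cl["class"] == "ejaculate")
                      & comb.loc[cl.index, "is_family_member"]]
    if len(fam_ej) == 0:
        pytest.skip("no family ejaculate rows at this scale")
    pe = small_dataset.truth.pair_effects
    divergent_any = pd.Series(False, index=fam_ej)
    truly_divergent = pd.Series(False, index=fam_ej)
    for a, b in SPECIES_PAIRS:
        pair = f"{a}_vs_{b}"
        dres = res.divergence[f"ejaculate_{pair}"]
        divergent_any |= dres.loc[fam_ej, "call"] != "ns"
        truth_pair = pe[pe["pair"] == pair].set_index("orthogroup")
        ogs = comb.loc[fam_ej, "orthogroup"]
        truly_divergent |= pd.Series(
            truth_pair["is_divergent_mated"].reindex(ogs).to_numpy(), index=fam_ej
        )
    # every truly divergent family member is recovered
    assert divergent_any[truly_divergent].mean() >= 0.9
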