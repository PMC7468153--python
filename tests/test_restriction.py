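"""Randomization null for geographic restriction: enumeration oracles,
calibration, classification boundaries, determinism."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakebiogeo import geometry, restriction, synth
from lakebiogeo.errors import ValidationError


@pytest.fixture(scope="module")
def tiny_matrix():
    # four lakes on the equator at 0, 1, 3, 7 degrees (all pair distances distinct)
    return geometry.distance_matrix(["a", "b", "c", "d"], [0, 0, 0, 0], [0, 1, 3, 7])


class TestNullDistribution:
    def test_full_pool_draw_has_zero_variance(self, tiny_matrix):
        null = restriction.null_distribution(4, ["a", "b", "c", "d"], tiny_matrix, R=50, seed=0)
        pool_mean = geometry.mean_pairwise_distance(["a", "b", "c", "d"], tiny_matrix)
        np.testing.assert_allclose(null.draws, pool_mean)

    def test_pairs_from_three_lakes_enumerate(self, tiny_matrix):
        # C(3,2) = 3 possible subsets; draws take only those values, each ~1/3
        pool = ["a", "b", "c"]
        values = {
            round(geometry.mean_pairwise_distance(list(p), tiny_matrix), 6)
            for p in itertools.combinations(pool, 2)
        }
        null = restriction.null_distribution(2, pool, tiny_matrix, R=3000, seed=1)
        seen = np.round(null.draws, 6)
        assert set(seen) <= values
        freqs = pd.Series(seen).value_counts(normalize=True)
        assert np.allclose(freqs, 1 / 3, atol=0.05)

    def test_unbiasedness(self, small_matrix):
        # every unordered pair is equally likely across subsets, so the mean
        # of draws approaches the pool's overall mean pairwise distance
        pool = list(small_matrix.lake_ids)
        overall = geometry.mean_pairwise_distance(pool, small_matrix)
        null = restriction.null_distribution(8, pool, small_matrix, R=3000, seed=2)
        se = null.draws.std() / np.sqrt(len(null.draws))
        assert abs(null.draws.mean() - overall) < 4 * se

    @pytest.mark.parametrize("n", [1, 5])
    def test_invalid_occupancy_rejected(self, tiny_matrix, n):
        with pytest.raises(ValidationError):
            restriction.null_distribution(n, ["a", "b", "c", "d"], tiny_matrix, R=10)


class TestQuantileAndFlags:
    def test_extremes_and_ties(self):
        draws = np.array([10.0, 20.0, 30.0])
        assert restriction.restriction_quantile(5.0, draws) == 1.0
        assert restriction.restriction_quantile(50.0, draws) == 0.0
        assert restriction.restriction_quantile(10.0, np.array([10.0, 10.0])) == 0.0

    def test_restricted_threshold(self):
        assert restriction.classify_restricted(1.0)
        assert not restriction.classify_restricted(0.0)
        assert not restriction.classify_restricted(0.5)  # strictly greater

    @pytest.mark.parametrize(
        "q,area,expected",
        [
            (0.95, 500_000, True),
            (0.95, 1_200_000, False),
            (0.89, 100, False),
            (0.90, 1_000_000, True),  # both boundaries inclusive
        ],
    )
    def test_endemic_criteria(self, q, area, expected):
        assert restriction.classify_endemic(q, area) is expected


class TestCohortTTest:
    def test_all_zero_differences(self):
        res = restriction.cohort_paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.t_statistic, res.p_value) == (0.0, 1.0)

    def test_zero_variance_nonzero_mean(self):
        res = restriction.cohort_paired_ttest([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == -np.inf and 0 < res.p_value < 1e-300

    def test_hand_computed_example(self):
        # d = (-2, -1, -3): mean -2, sd 1 -> t = -2*sqrt(3) = -3.464
        res = restriction.cohort_paired_ttest([0.0, 0.0, 0.0], [2.0, 1.0, 3.0])
        assert res.t_statistic == pytest.approx(-3.4641016, rel=1e-6)
        assert res.p_value == pytest.approx(2 * stats.t.cdf(-2 * np.sqrt(3), df=2), rel=1e-9)
        assert res.p_value == pytest.approx(0.0742, abs=2e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            restriction.cohort_paired_ttest([1.0], [1.0, 2.0])


class TestRunBiogeography:
    def test_only_singletons_gives_no_results(self, small_world, small_matrix):
        df = small_world.table.df.drop_duplicates("v9_id")
        from lakebiogeo.occurrence import OccurrenceTable

        singles = OccurrenceTable(df.reset_index(drop=True))
        res, cohort, n_single = restriction.run_biogeography(
            singles, small_world.lakes, small_matrix, R=10, seed=0
        )
        assert len(res) == 0 and cohort is None
        assert n_single == df["v9_id"].nunique()

    def test_planted_endemics_flagged(self, small_world, small_matrix):
        res, _, _ = restriction.run_biogeography(
            small_world.table, small_world.lakes, small_matrix, R=500, seed=5
        )
        kinds = {t: v["kind"] for t, v in small_world.truth.taxa.items()}
        res = res.assign(kind=res["taxon_id"].map(kinds))
        endemics = res[res["kind"] == "endemic"]
        assert len(endemics) >= 5
        assert endemics["endemic"].mean() >= 0.9

    def test_seed_reproducibility(self, small_world, small_matrix):
        args = (small_world.table, small_world.lakes, small_matrix)
        r1, _, _ = restriction.run_biogeography(*args, R=100, seed=9)
        r2, _, _ = restriction.run_biogeography(*args, R=100, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_taxon_substreams_order_independent(self, tiny_matrix):
        # the same taxon id gets the same null regardless of what else runs
        n1 = restriction.null_distribution(
            2, ["a", "b", "c", "d"], tiny_matrix, R=20, taxon_id="X", seed=3
        )
        n2 = restriction.null_distribution(
            2, ["a", "b", "c", "d"], tiny_matrix, R=20, taxon_id="X", seed=3
        )
        np.testing.assert_array_equal(n1.draws, n2.draws)

    def test_unknown_lake_rejected(self, small_world, small_matrix):
        bad = small_world.table.df.copy()
        bad.loc[bad.index[0], "lake_id"] = "NOT_A_LAKE"
        from lakebiogeo.occurrence import OccurrenceTable

        lakes = small_world.lakes
        with pytest.raises(ValidationError):
            restriction.run_biogeography(OccurrenceTable(bad), lakes, small_matrix, R=10)


class TestCalibration:
    def test_uniform_taxa_give_uniform_q(self, small_matrix, rng):
        """Type-I behaviour: q of randomly placed taxa is ~ Uniform(0,1)."""
        pool = list(small_matrix.lake_ids)
        qs = []
        for _ in range(150):
            n = int(rng.integers(3, 15))
            ids = list(rng.choice(pool, size=n, replace=False))
            obs = geometry.mean_pairwise_distance(ids, small_matrix)
            null = restriction.null_distribution(
                n, pool, small_matrix, R=200, rng=np.random.default_rng(rng.integers(2**31))
            )
            qs.append(restriction.restriction_quantile(obs, null))
        qs = np.array(qs)
        # KS against uniform; generous alpha, derandomised rng
        assert stats.kstest(qs, "uniform").pvalue > 0.01
        assert abs((qs > 0.5).mean() - 0.5) < 0.15
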