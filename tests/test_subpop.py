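"""Kruskal-Wallis/Dunn oracles, parent-conditioned swarm restriction,
environmental differentiation recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lakebiogeo import geometry, subpop, synth
from lakebiogeo.errors import ValidationError
from lakebiogeo.occurrence import OccurrenceTable

from conftest import toy_lakes


def exact_kw_p(groups):
    """Exact permutation p-value for the Kruskal-Wallis H (tiny n only)."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])

    def H_of(perm):
        parts, start = [], 0
        for s in sizes:
            parts.append(perm[start : start + s])
            start += s
        try:
            return stats.kruskal(*parts).statistic
        except ValueError:
            return 0.0

    obs = H_of(pooled)
    count = total = 0
    for perm in itertools.permutations(pooled):
        total += 1
        if H_of(np.array(perm)) >= obs - 1e-9:
            count += 1
    return count / total


class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1..6, rank sums 6 and 15: H = 12/(6*7) * (36/3 + 225/3) - 21
        H, p = subpop.kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert H == pytest.approx(3.857142857, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(3.857142857, 1), rel=1e-9)
        assert p == pytest.approx(0.0495, abs=1e-4)

    def test_identical_values(self):
        H, p = subpop.kruskal_wallis([[2, 2], [2, 2, 2]])
        assert (H, p) == (0.0, 1.0)

    def test_matches_exact_permutation_oracle(self, rng):
        groups = [list(rng.normal(size=3)), list(rng.normal(size=3))]
        _, p_chi2 = subpop.kruskal_wallis(groups)
        p_exact = exact_kw_p(groups)
        # chi-square approximation vs exact permutation on n=6: same scale
        assert abs(p_chi2 - p_exact) < 0.12

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            subpop.kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_two_group_z_squared_equals_tie_corrected_H(self, rng):
        for _ in range(5):
            a = rng.integers(0, 6, size=6).astype(float)  # ties likely
            b = rng.integers(0, 6, size=8).astype(float)
            if np.all(np.concatenate([a, b]) == a[0]):
                continue
            H, _ = subpop.kruskal_wallis([a, b])
            d = subpop.dunn_posthoc([a, b], adjust=None)
            assert d["z"].iloc[0] ** 2 == pytest.approx(H, rel=1e-9)

    def test_label_swap_flips_sign(self):
        d1 = subpop.dunn_posthoc([[1, 2, 3], [4, 5, 6]], adjust=None)
        d2 = subpop.dunn_posthoc([[4, 5, 6], [1, 2, 3]], adjust=None)
        assert d1["z"].iloc[0] == pytest.approx(-d2["z"].iloc[0])
        assert d1["p"].iloc[0] == pytest.approx(d2["p"].iloc[0])

    def test_pairwise_table_size(self):
        groups = [[1, 2], [3, 4], [5, 6], [7, 8]]
        d = subpop.dunn_posthoc(groups)
        assert len(d) == 6  # C(4,2)

    @pytest.mark.parametrize("method", ["bh", "bonferroni", "holm"])
    def test_adjusted_p_never_below_raw(self, rng, method):
        groups = [list(rng.normal(size=5)) for _ in range(4)]
        d = subpop.dunn_posthoc(groups, adjust=method)
        assert np.all(d["p_adj"] >= d["p"] - 1e-12)


class TestSwarmRestriction:
    def _fixture(self):
        # parent V9 spans 6 lakes: a tight western triple and a far eastern triple
        coords = [("W1", 50.0, 5.0), ("W2", 50.1, 5.1), ("W3", 50.2, 5.0),
                  ("E1", 50.0, 25.0), ("E2", 50.1, 25.1), ("E3", 50.2, 25.0)]
        lakes = toy_lakes([(i, la, lo, 100) for i, la, lo in coords])
        m = geometry.distance_matrix(lakes["lake_id"], lakes["lat"].to_numpy(),
                                     lakes["lon"].to_numpy())
        rows = [("V1", "V1_S1", lk) for lk in ["W1", "W2", "W3"]]   # corner swarm
        rows += [("V1", "V1_S2", lk) for lk in ["E1", "E2", "E3"]]
        rows += [("V1", "V1_S3", lk) for lk in lakes["lake_id"]]    # fills the range
        df = pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id"])
        df["reads"] = 10
        return OccurrenceTable(df), m

    def test_corner_swarm_strongly_restricted(self):
        table, m = self._fixture()
        res = subpop.swarm_restriction(table, m, R=500, seed=0)
        tight = res.set_index("swarm_id").loc["V1_S1"]
        assert tight["q"] >= 0.9 and tight["restricted"]

    def test_range_filling_swarm_untestable(self):
        table, m = self._fixture()
        res = subpop.swarm_restriction(table, m, R=100, seed=0).set_index("swarm_id")
        assert bool(res.loc["V1_S3", "untestable"])
        assert res.loc["V1_S3", "q"] == 0.0

    def test_null_pool_is_parent_range(self):
        table, m = self._fixture()
        res = subpop.swarm_restriction(table, m, R=100, seed=0)
        assert (res["pool_size"] == 6).all()

    def test_uniform_swarm_subsets_give_uniform_q(self, rng):
        # swarms drawn as random subsets of the parent's lakes -> q ~ U(0,1)
        coords = [(f"L{i}", 45 + rng.uniform(0, 8), rng.uniform(0, 20), 100)
                  for i in range(30)]
        lakes = toy_lakes(coords)
        m = geometry.distance_matrix(lakes["lake_id"], lakes["lat"].to_numpy(),
                                     lakes["lon"].to_numpy())
        rows = [("V1", "V1_S000", lk) for lk in lakes["lake_id"]]  # parent everywhere
        for s in range(120):
            for lk in rng.choice(lakes["lake_id"], size=4, replace=False):
                rows.append(("V1", f"V1_S{s + 1:03d}", lk))
        df = pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id"])
        df = df.drop_duplicates(["swarm_id", "lake_id"])
        df["reads"] = 5
        res = subpop.swarm_restriction(OccurrenceTable(df), m, R=300, seed=2)
        qs = res.loc[~res["untestable"], "q"].to_numpy()
        assert stats.kstest(qs, "uniform").pvalue > 0.01


class TestEnvDifferentiation:
    def _world(self, rng, split_param="pH"):
        coords = []
        for i in range(20):
            coords.append((f"L{i:02d}", 45 + rng.uniform(0, 8), rng.uniform(0, 20), 100.0))
        lakes = toy_lakes(coords)
        lakes["pH"] = np.where(np.arange(20) < 10, 5.5, 8.5) + rng.normal(0, 0.1, 20)
        lakes["temperature_C"] = rng.normal(15, 3, 20)
        lakes["conductivity_uScm"] = rng.lognormal(5, 0.5, 20)
        acid = list(lakes["lake_id"][:10])
        alkaline = list(lakes["lake_id"][10:])
        rows = [("V1", "V1_S1", lk) for lk in acid] + [("V1", "V1_S2", lk) for lk in alkaline]
        df = pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id"])
        df["reads"] = 10
        return OccurrenceTable(df), lakes

    def test_ph_partitioned_swarms_detected_for_ph_only(self, rng):
        table, lakes = self._world(rng)
        res, _ = subpop.env_differentiation(
            table, lakes, parameters=("pH", "temperature_C"), adjust=None
        )
        res = res.set_index("parameter")
        assert res.loc["pH", "significant"]
        assert res.loc["pH", "p"] < 0.001
        assert res.loc["temperature_C", "p"] > res.loc["pH", "p"]

    def test_identical_lake_sets_not_differentiated(self):
        lakes = toy_lakes([(f"L{i}", 46 + i, 10, 100) for i in range(4)])
        rows = [("V1", "V1_S1", lk) for lk in lakes["lake_id"]]
        rows += [("V1", "V1_S2", lk) for lk in lakes["lake_id"]]
        df = pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id"])
        df["reads"] = 10
        res, _ = subpop.env_differentiation(OccurrenceTable(df), lakes,
                                            parameters=("pH",), adjust=None)
        assert (res["p"] == 1.0).all()

    def test_single_swarm_v9_excluded(self):
        lakes = toy_lakes([(f"L{i}", 46 + i, 10, 100) for i in range(4)])
        rows = [("V1", "V1_S1", lk) for lk in lakes["lake_id"]]
        df = pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id"])
        df["reads"] = 10
        res, _ = subpop.env_differentiation(OccurrenceTable(df), lakes, parameters=("pH",))
        assert len(res) == 0

    def test_rank_based_monotone_invariance(self, rng):
        table, lakes = self._world(rng)
        res1, _ = subpop.env_differentiation(table, lakes, parameters=("pH",), adjust=None)
        lakes2 = lakes.copy()
        lakes2["pH"] = np.exp(lakes2["pH"])  # strictly monotone transform
        res2, _ = subpop.env_differentiation(table, lakes2, parameters=("pH",), adjust=None)
        assert res1["H"].iloc[0] == pytest.approx(res2["H"].iloc[0], rel=1e-12)

    def test_shuffled_labels_calibrate_to_alpha(self, rng):
        """Random swarm membership -> raw significant fraction ~ alpha."""
        n_groups, alpha = 400, 0.05
        lakes = toy_lakes([(f"L{i:02d}", 45 + rng.uniform(0, 8), rng.uniform(0, 20), 100.0)
                           for i in range(24)])
        lakes["pH"] = rng.normal(7.5, 0.8, 24)
        rows = []
        for g in range(n_groups):
            perm = rng.permutation(24)
            for k, blk in enumerate(np.array_split(perm, 3)):
                for i in blk:
                    rows.append((f"V{g:03d}", f"V{g:03d}_S{k}", f"L{i:02d}"))
        df = pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id"])
        df["reads"] = 5
        res, _ = subpop.env_differentiation(
            OccurrenceTable(df), lakes, parameters=("pH",), adjust=None, collect_dunn=False
        )
        frac = (res["p"] < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / n_groups)
        assert abs(frac - alpha) < 3 * se + 0.01
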