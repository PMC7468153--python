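"""Calibration, power and oracle-agreement experiments.

Each function builds its own synthetic inputs from a seed, runs the relevant
pipeline stage through the public package API, and returns a small dict of
measured quantities. They back the validation analyses (type-I calibration
of the restriction null, planted-endemism recovery, mountain-exclusivity
detection, environmental-differentiation calibration/power, amplicon
round-trip fidelity) and the closed-form/brute-force oracle comparisons for
the numerical primitives.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from . import altitude as alt_mod
from . import amplicon, restriction, richness, subpop, synth
from .geometry import EARTH_RADIUS_KM, distance_matrix, haversine_km
from .occurrence import OccurrenceTable


def _matrix_of(lakes):
    return distance_matrix(lakes["lake_id"], lakes["lat"].to_numpy(), lakes["lon"].to_numpy())


def _uniform_taxon_table(lakes, n_taxa, occupancies, rng, prefix="U"):
    rows = []
    width = len(str(n_taxa))
    for i in range(n_taxa):
        n = int(occupancies[i])
        tid = f"{prefix}{i + 1:0{width}d}"
        for lk in rng.choice(lakes["lake_id"].to_numpy(), size=n, replace=False):
            rows.append((tid, f"{tid}_S1", lk, 10))
    return OccurrenceTable(pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id", "reads"]))


# ---------------------------------------------------------------------------
# restriction null: type-I calibration and endemism recovery


def null_calibration(
    n_taxa: int = 500, n_lakes: int = 200, occ_range=(3, 20), R: int = 1000, seed: int = 0
) -> dict:
    """Type-I behaviour of the restriction screen on randomly placed taxa.

    Taxa are placed uniformly over the lakes, so q should be ~ Uniform(0,1):
    ~10% reach the endemism quantile (q >= 0.9) and ~50% fall below the null
    median (q > 0.5).
    """
    rng = np.random.default_rng(seed)
    cfg = synth.WorldConfig(n_lakes=n_lakes, n_mountain=min(27, n_lakes // 8), seed=seed)
    lakes = synth.generate_lakes(cfg, rng)
    occs = rng.integers(occ_range[0], occ_range[1] + 1, size=n_taxa)
    table = _uniform_taxon_table(lakes, n_taxa, occs, rng)
    m = _matrix_of(lakes)
    res, _, _ = restriction.run_biogeography(table, lakes, m, level="v9", R=R, seed=seed)
    q = res["q"].to_numpy()
    return {
        "n_taxa": int(len(q)),
        "frac_q_ge_090": float((q >= 0.9).mean()),
        "frac_restricted": float((q > 0.5).mean()),
        "q_values": q,
    }


def endemism_recovery(
    n_endemic: int = 100, n_cosmopolitan: int = 100, R: int = 1000, seed: int = 0
) -> dict:
    """Power/specificity of the endemism classifier on planted taxa.

    Endemics: radius 150 km, occupancy 5-8 (all occupied lakes inside a
    10^6 km^2 box by construction). Cosmopolitans: occupancy 5-15 placed
    uniformly. Measures the planted-endemic recovery rate and the
    cosmopolitan false-flag rate.
    """
    rng = np.random.default_rng(seed)
    cfg = synth.WorldConfig(seed=seed)
    lakes = synth.generate_lakes(cfg, rng)
    blueprints = []
    for i in range(n_endemic):
        blueprints.append(
            synth.TaxonBlueprint(
                taxon_id=f"E{i + 1:03d}", kind="endemic",
                occupancy=int(rng.integers(5, 9)), taxon_group="Chrysophyceae",
                n_swarms=1, swarm_structure="none", radius_km=cfg.endemic_radius_km,
            )
        )
    for i in range(n_cosmopolitan):
        blueprints.append(
            synth.TaxonBlueprint(
                taxon_id=f"C{i + 1:03d}", kind="cosmopolitan",
                occupancy=int(rng.integers(5, 16)), taxon_group="Chrysophyceae",
                n_swarms=1, swarm_structure="none",
            )
        )
    v9_table, truth = synth.generate_occurrences(lakes, blueprints, cfg, rng)
    v9_table["swarm_id"] = v9_table["v9_id"] + "_S1"
    table = OccurrenceTable(
        v9_table[["v9_id", "swarm_id", "lake_id", "reads"]].reset_index(drop=True)
    )
    m = _matrix_of(lakes)
    res, _, _ = restriction.run_biogeography(table, lakes, m, level="v9", R=R, seed=seed)
    res = res.set_index("taxon_id")
    endemic_ids = [b.taxon_id for b in blueprints if b.kind == "endemic"]
    cosmo_ids = [b.taxon_id for b in blueprints if b.kind == "cosmopolitan"]
    return {
        "n_endemic": len(endemic_ids),
        "n_cosmopolitan": len(cosmo_ids),
        "endemic_recovery": float(res.loc[endemic_ids, "endemic"].mean()),
        "cosmopolitan_false_rate": float(res.loc[cosmo_ids, "endemic"].mean()),
    }


# ---------------------------------------------------------------------------
# geometry / rarefaction / clustering / rank-test oracles


def haversine_oracle(n_pairs: int = 1000, seed: int = 0) -> dict:
    """Agreement with the spherical-law-of-cosines closed form."""
    rng = np.random.default_rng(seed)
    lat1, lat2 = rng.uniform(-80, 80, (2, n_pairs))
    lon1, lon2 = rng.uniform(-179, 179, (2, n_pairs))
    d = haversine_km(lat1, lon1, lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    oracle = EARTH_RADIUS_KM * np.arccos(np.clip(c, -1.0, 1.0))
    ok = (d > 1.0) & (d < np.pi * EARTH_RADIUS_KM - 100)
    max_rel = float(np.max(np.abs(d[ok] - oracle[ok]) / oracle[ok]))
    quarter = haversine_km(0, 0, 0, 90)
    quarter_rel = abs(quarter - np.pi / 2 * EARTH_RADIUS_KM) / (np.pi / 2 * EARTH_RADIUS_KM)
    return {"n_pairs": int(ok.sum()), "max_rel_err": max_rel,
            "quarter_circle_rel_err": float(quarter_rel)}


def rarefaction_oracle(L: int = 10, T: int = 50, n_iter: int = 10_000, seed: int = 0) -> dict:
    """Analytic rarefaction vs Monte-Carlo subsampling; log-model recovery."""
    rng = np.random.default_rng(seed)
    presence = rng.random((T, L)) < 0.3
    presence[:, 0] |= ~presence.any(axis=1)
    occ = presence.sum(axis=1)
    max_z = 0.0
    for n in range(2, L):
        analytic = richness.rarefaction_expected_richness(occ, L, n)
        mc = richness.monte_carlo_rarefaction(presence, n, n_iter, rng)
        se = max(mc.std() / np.sqrt(n_iter), 1e-12)
        max_z = max(max_z, abs(analytic - mc.mean()) / se)
    ns = np.arange(1, 11)
    fit = richness.fit_log_model(ns, 3.0 * np.log(ns + 1) + 1.0)
    coef_err = max(abs(fit.a - 3.0), abs(fit.b - 1.0))
    return {"max_abs_z": float(max_z), "fit_coef_abs_err": float(coef_err)}


def _dp_levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


def _brute_components(variants, d):
    variants = sorted(set(variants))
    parent = list(range(len(variants)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(variants)):
        for j in range(i + 1, len(variants)):
            if _dp_levenshtein(variants[i], variants[j]) <= d:
                parent[find(i)] = find(j)
    comps = {}
    for i, v in enumerate(variants):
        comps.setdefault(find(i), []).append(v)
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def clustering_oracle(n_fixtures: int = 50, seed: int = 0) -> dict:
    """swarm_cluster(d=1) vs a dynamic-programming union-find oracle."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_fixtures):
        n = int(rng.integers(10, 101))
        # short alphabet-3 sequences make distance-1 links common
        variants = ["".join(rng.choice(list("ACG"), size=int(rng.integers(3, 31))))
                    for _ in range(n)]
        if amplicon.swarm_cluster(variants, d=1) == _brute_components(variants, 1):
            agree += 1
    return {"n_fixtures": n_fixtures, "agreement": agree / n_fixtures}


def ranktest_oracles(seed: int = 0) -> dict:
    """Small-sample rank-test oracles.

    * rank-sum on {1,2,3} vs {4,5,6}: exact two-sided p = 2/20 = 0.1;
    * Kruskal-Wallis chi-square p vs exact permutation p at n <= 8;
    * two-group Dunn z^2 equals the tie-corrected H.
    """
    _, p_ranksum = alt_mod.ranksum_test([1, 2, 3], [4, 5, 6])
    rng = np.random.default_rng(seed)
    kw_max_gap = 0.0
    for _ in range(5):
        groups = [list(rng.normal(size=4)), list(rng.normal(size=4))]
        _, p_chi2 = subpop.kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        obs = stats.kruskal(*groups).statistic
        count = total = 0
        for comb in itertools.combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(comb)] = True
            h = stats.kruskal(pooled[mask], pooled[~mask]).statistic
            total += 1
            count += h >= obs - 1e-9
        kw_max_gap = max(kw_max_gap, abs(p_chi2 - count / total))
    dunn_max_gap = 0.0
    for _ in range(5):
        a = rng.integers(0, 5, size=6).astype(float)
        b = rng.integers(0, 5, size=7).astype(float)
        if np.all(np.concatenate([a, b]) == a[0]):
            continue
        H, _ = subpop.kruskal_wallis([a, b])
        z = subpop.dunn_posthoc([a, b], adjust=None)["z"].iloc[0]
        dunn_max_gap = max(dunn_max_gap, abs(z * z - H))
    return {
        "ranksum_p_123_456": float(p_ranksum),
        "kw_chi2_vs_exact_max_gap": float(kw_max_gap),
        "dunn_z2_vs_H_max_gap": float(dunn_max_gap),
    }


# ---------------------------------------------------------------------------
# altitude exclusivity detection / coverage


def _exclusivity_world(seed, n_planted, planted_kind):
    rng = np.random.default_rng(seed)
    cfg = synth.WorldConfig(n_lakes=200, n_mountain=27, seed=seed)
    lakes = synth.generate_lakes(cfg, rng)
    blueprints = []
    for i in range(n_planted):
        blueprints.append(
            synth.TaxonBlueprint(
                taxon_id=f"P{i + 1:03d}", kind=planted_kind,
                occupancy=int(rng.integers(2, 11)), taxon_group="Chrysophyceae",
                n_swarms=1, swarm_structure="none",
            )
        )
    for i in range(300):
        blueprints.append(
            synth.TaxonBlueprint(
                taxon_id=f"B{i + 1:03d}", kind="cosmopolitan",
                occupancy=int(rng.integers(2, 15)), taxon_group="Fungi",
                n_swarms=1, swarm_structure="none",
            )
        )
    v9_table, _ = synth.generate_occurrences(lakes, blueprints, cfg, rng)
    v9_table["swarm_id"] = v9_table["v9_id"] + "_S1"
    table = OccurrenceTable(
        v9_table[["v9_id", "swarm_id", "lake_id", "reads"]].reset_index(drop=True)
    )
    return lakes, table


def mountain_exclusivity_experiment(
    n_replicates: int = 100, n_planted: int = 30, planted: bool = True,
    n_perm: int = 100, seed: int = 0
) -> dict:
    """Detection (planted mountain-exclusive taxa) or null coverage.

    Planted mode: a replicate detects the effect when every per-draw
    mountain fraction exceeds every size-matched lowland draw fraction.
    Null mode (planted=False: the same taxa are cosmopolitan): the first
    per-draw mountain fraction is exchangeable with the 100 lowland draw
    fractions, so it falls in their central 95% band ~95% of the time.
    """
    detected = 0
    inside = 0
    for r in range(n_replicates):
        kind = "mountain_exclusive" if planted else "cosmopolitan"
        lakes, table = _exclusivity_world(seed * 100_003 + r, n_planted, kind)
        split = alt_mod.split_by_altitude(lakes)
        res = alt_mod.exclusivity_resampling(table, split, "v9", n_perm=n_perm,
                                             seed=seed * 7919 + r)
        mtn, low = res["mountain_fractions"], res["lowland_fractions"]
        if mtn.min() > low.max():
            detected += 1
        lo, hi = np.percentile(low, [2.5, 97.5])
        if lo <= mtn[0] <= hi:
            inside += 1
    return {
        "n_replicates": n_replicates,
        "detection_rate": detected / n_replicates,
        "null_coverage": inside / n_replicates,
    }


# ---------------------------------------------------------------------------
# environmental differentiation calibration / power


def env_calibration(
    n_groups: int = 400, n_lakes: int = 24, k_swarms: int = 3,
    alpha: float = 0.05, seed: int = 0
) -> dict:
    """Significant fraction under randomly shuffled swarm membership.

    With membership independent of the environment each group's test is a
    valid null test, so the raw-alpha significant fraction is ~ alpha.
    """
    rng = np.random.default_rng(seed)
    lakes = synth.generate_lakes(
        synth.WorldConfig(n_lakes=n_lakes, n_mountain=max(1, n_lakes // 8), seed=seed), rng
    )
    rows = []
    for g in range(n_groups):
        perm = rng.permutation(n_lakes)
        for k, blk in enumerate(np.array_split(perm, k_swarms)):
            for i in blk:
                rows.append((f"V{g:04d}", f"V{g:04d}_S{k}", lakes["lake_id"].iloc[i], 5))
    table = OccurrenceTable(pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id", "reads"]))
    res, _ = subpop.env_differentiation(
        table, lakes, parameters=("pH",), adjust=None, collect_dunn=False
    )
    frac = float((res["p"] < alpha).mean())
    return {"n_groups": int(len(res)), "alpha": alpha, "significant_fraction": frac}


def env_power(
    n_groups: int = 100, occupancy: int = 16, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Power for pH-partitioned swarms; specificity for temperature.

    Each parent occupies ``occupancy`` random lakes split into two swarms at
    the median pH of its lakes; pH should separate, temperature should not.
    """
    rng = np.random.default_rng(seed)
    lakes = synth.generate_lakes(synth.WorldConfig(n_lakes=200, seed=seed), rng)
    rows = []
    for g in range(n_groups):
        take = rng.choice(len(lakes), size=occupancy, replace=False)
        sub = lakes.iloc[take]
        order = np.argsort(sub["pH"].to_numpy(), kind="stable")
        for k, blk in enumerate(np.array_split(order, 2)):
            for i in blk:
                rows.append((f"V{g:04d}", f"V{g:04d}_S{k}", sub["lake_id"].iloc[i], 5))
    table = OccurrenceTable(pd.DataFrame(rows, columns=["v9_id", "swarm_id", "lake_id", "reads"]))
    res, _ = subpop.env_differentiation(
        table, lakes, parameters=("pH", "temperature_C"), adjust=None, collect_dunn=False
    )
    res = res.set_index("parameter", append=False)
    ph = res[res.index == "pH"]
    temp = res[res.index == "temperature_C"]
    return {
        "n_groups": n_groups,
        "ph_power": float((ph["p"] < alpha).mean()),
        "temperature_significant_fraction": float((temp["p"] < alpha).mean()),
    }


# ---------------------------------------------------------------------------
# amplicon round trip


def roundtrip_experiment(n_taxa: int = 300, seed: int = 0) -> dict:
    """Presence-level identity through the full amplicon processing chain,
    plus verified removal of spiked noise records."""
    world = synth.generate_world(synth.WorldConfig(n_taxa=n_taxa, seed=seed))
    clean, info_clean = synth.generate_amplicons(world.table, seed=seed)
    table_clean, _ = amplicon.process_amplicons(clean)
    clean_ok = synth.presence_equivalent(world.table, table_clean, info_clean)

    noisy, info = synth.generate_amplicons(
        world.table, seed=seed, n_subthreshold_spikes=50, n_crosspair_spikes=50
    )
    table_noisy, _ = amplicon.process_amplicons(noisy)
    noisy_ok = synth.presence_equivalent(world.table, table_noisy, info)
    spiked_its = {s[1] for s in info.spikes_subthreshold}
    # sub-threshold spike variants must not survive the per-lake filter
    derep = amplicon.pair_filter(amplicon.dereplicate(noisy))
    kept = amplicon.filter_low_abundance(derep)
    survived_sub = len(set(kept["its_seq"]) & spiked_its)
    # minority pairings must not survive the pair filter
    cross = {(v, i) for v, i, _ in info.spikes_crosspair}
    survived_cross = len(set(zip(derep["v9_seq"], derep["its_seq"])) & cross)
    n_sub = len(info.spikes_subthreshold)
    n_cross = len(info.spikes_crosspair)
    return {
        "clean_roundtrip_identity": bool(clean_ok),
        "noisy_roundtrip_identity": bool(noisy_ok),
        "subthreshold_removed_fraction": 1.0 - survived_sub / max(1, n_sub),
        "crosspair_removed_fraction": 1.0 - survived_cross / max(1, n_cross),
        "n_spikes": n_sub + n_cross,
    }
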