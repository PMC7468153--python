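"""Occupancy-conditioned randomization test for geographic restriction.

For a taxon occupying n lakes, the observed mean pairwise great-circle
distance among those lakes is compared with a null distribution obtained by
drawing R (default 1,000) random n-lake subsets of a reference pool without
replacement. The empirical quantile

    q = (# draws with observed < draw) / R

measures how much tighter the taxon's range is than an equal-occupancy
random range. Classification:

* geographically restricted:  q > 0.5 (observed below the null median;
  threshold configurable);
* putatively endemic: q >= 0.9 AND all occupied lakes fall inside a
  lat/lon-aligned rectangle of area <= 1,000,000 km^2.

A cohort-level paired t-test compares, across taxa, each observed mean with
the mean of its null draws.

Reproducibility: one master seed; each taxon gets an independent substream
derived from (master seed, CRC32 of the taxon id), so per-taxon results do
not depend on iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .geometry import (
    DistanceMatrix,
    bounding_box_area_km2,
    geometric_center,
    mean_pairwise_from_indices,
)
from .occurrence import OccurrenceTable

DEFAULT_DRAWS = 1000
DEFAULT_RESTRICTED_Q = 0.5
DEFAULT_ENDEMIC_Q = 0.9
DEFAULT_MAX_AREA_KM2 = 1_000_000.0

# cap on R*n*n gather size per chunk, keeps peak memory modest
_CHUNK_ELEMS = 20_000_000


@dataclass(frozen=True)
class NullDistribution:
    taxon_id: str
    n: int
    draws: np.ndarray  # R mean pairwise distances, km
    seed: int


@dataclass(frozen=True)
class CohortTest:
    n_taxa: int
    t_statistic: float
    p_value: float
    mean_difference_km: float


def taxon_rng(master_seed: int, taxon_id: str) -> np.random.Generator:
    """Independent, order-insensitive substream for one taxon."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(str(taxon_id).encode())])
    )


def _subset_mean_distances(
    values: np.ndarray, pool_idx: np.ndarray, n: int, R: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean pairwise distance of R random n-subsets of pool_idx (vectorized)."""
    P = len(pool_idx)
    out = np.empty(R, dtype=float)
    chunk = max(1, int(_CHUNK_ELEMS // max(1, n * n)))
    done = 0
    denom = n * (n - 1)
    while done < R:
        r = min(chunk, R - done)
        keys = rng.random((r, P))
        take = np.argpartition(keys, n - 1, axis=1)[:, :n]
        sub = pool_idx[take]  # (r, n)
        d = values[sub[:, :, None], sub[:, None, :]]
        out[done : done + r] = d.sum(axis=(1, 2)) / denom
        done += r
    return out


def null_distribution(
    n: int,
    pool_ids,
    m: DistanceMatrix,
    R: int = DEFAULT_DRAWS,
    rng: np.random.Generator | None = None,
    taxon_id: str = "",
    seed: int = 0,
) -> NullDistribution:
    """R draws of n lakes without replacement from the reference pool."""
    pool_idx = m.indices(pool_ids)
    if n < 2:
        raise ValidationError("null distribution requires occupancy >= 2")
    if n > len(pool_idx):
        raise ValidationError(
            f"occupancy {n} exceeds reference pool size {len(pool_idx)}"
        )
    if rng is None:
        rng = taxon_rng(seed, taxon_id)
    draws = _subset_mean_distances(m.values, pool_idx, n, R, rng)
    return NullDistribution(taxon_id=taxon_id, n=n, draws=draws, seed=seed)


def restriction_quantile(observed_mean_km: float, null: NullDistribution | np.ndarray) -> float:
    """Fraction of null draws strictly above the observed mean distance.

    Ties count as not-smaller (conservative; distances are continuous so
    ties have probability ~0 on real data).
    """
    draws = null.draws if isinstance(null, NullDistribution) else np.asarray(null)
    return float(np.mean(observed_mean_km < draws))


def classify_restricted(q: float, threshold: float = DEFAULT_RESTRICTED_Q) -> bool:
    return q > threshold


def classify_endemic(
    q: float,
    bbox_area_km2: float,
    q_threshold: float = DEFAULT_ENDEMIC_Q,
    max_area_km2: float = DEFAULT_MAX_AREA_KM2,
) -> bool:
    return (q >= q_threshold) and (bbox_area_km2 <= max_area_km2)


def cohort_paired_ttest(observed, expected) -> CohortTest:
    """Paired t-test of per-taxon observed vs null-mean distances.

    Degenerate branches: all differences zero -> t=0, p=1; zero variance
    with nonzero mean -> infinite t, p reported at the float tiny limit.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.ndim != 1:
        raise ValidationError("observed/expected must be equal-length 1-D vectors")
    n = len(observed)
    if n < 2:
        raise ValidationError("paired t-test requires at least two taxa")
    d = observed - expected
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return CohortTest(n, 0.0, 1.0, 0.0)
        t = np.inf if d.mean() > 0 else -np.inf
        return CohortTest(n, float(t), float(np.finfo(float).tiny), float(d.mean()))
    res = stats.ttest_rel(observed, expected)
    return CohortTest(n, float(res.statistic), float(res.pvalue), float(d.mean()))


def run_biogeography(
    table: OccurrenceTable,
    lakes: pd.DataFrame,
    m: DistanceMatrix,
    level: str = "v9",
    R: int = DEFAULT_DRAWS,
    seed: int = 0,
    restricted_q: float = DEFAULT_RESTRICTED_Q,
    endemic_q: float = DEFAULT_ENDEMIC_Q,
    max_area_km2: float = DEFAULT_MAX_AREA_KM2,
    reference_pool: dict | None = None,
) -> tuple[pd.DataFrame, CohortTest | None, int]:
    """Geographic-restriction screen over all taxa of one resolution level.

    Taxa occupying a single lake are counted as singletons and excluded from
    testing. The reference pool defaults to all lakes in the metadata; for
    the swarm level pass ``reference_pool`` mapping taxon -> parent pool
    (see :mod:`lakebiogeo.subpop`).

    Returns (per-taxon results frame, cohort paired t-test or None,
    singleton count).
    """
    lake_pos = lakes.set_index("lake_id")
    unknown = set(table.df["lake_id"].unique()) - set(lake_pos.index)
    if unknown:
        raise ValidationError(f"occurrence table references unknown lakes: {sorted(unknown)[:5]}")
    presence = table.presence_sets(level)
    all_lakes = list(lake_pos.index)
    rows = []
    n_singletons = 0
    for taxon in sorted(presence):
        occ_lakes = sorted(presence[taxon])
        n = len(occ_lakes)
        if n < 2:
            n_singletons += 1
            continue
        pool = sorted(reference_pool[taxon]) if reference_pool is not None else all_lakes
        idx = m.indices(occ_lakes)
        observed = mean_pairwise_from_indices(m.values, idx)
        null = null_distribution(n, pool, m, R=R, taxon_id=taxon, seed=seed)
        q = restriction_quantile(observed, null)
        lats = lake_pos.loc[occ_lakes, "lat"].to_numpy()
        lons = lake_pos.loc[occ_lakes, "lon"].to_numpy()
        bbox = bounding_box_area_km2(lats, lons)
        center = geometric_center(lats, lons)
        rows.append(
            {
                "taxon_id": taxon,
                "level": level,
                "occupancy": n,
                "observed_km": observed,
                "null_mean_km": float(null.draws.mean()),
                "q": q,
                "restricted": classify_restricted(q, restricted_q),
                "endemic": classify_endemic(q, bbox.area_km2, endemic_q, max_area_km2),
                "bbox_km2": bbox.area_km2,
                "center_lat": center[0],
                "center_lon": center[1],
            }
        )
    results = pd.DataFrame(
        rows,
        columns=[
            "taxon_id", "level", "occupancy", "observed_km", "null_mean_km",
            "q", "restricted", "endemic", "bbox_km2", "center_lat", "center_lon",
        ],
    )
    cohort = None
    if len(results) >= 2:
        cohort = cohort_paired_ttest(
            results["observed_km"].to_numpy(), results["null_mean_km"].to_numpy()
        )
    return results, cohort, n_singletons
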