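"""High-mountain (> 1,500 m) versus lowland comparisons.

Mountain lakes are azonal habitats: their richness and the exclusivity of
their taxa are compared against equally sized random subsets of lowland
lakes. Because the lowland pool is much larger, exclusivity is resampled:
each permutation draws |mountain| lowland lakes and computes, for both the
mountain set and the drawn lowland set, the fraction of taxa found in the
focal set but absent from the reference (the lowland lakes outside the
draw). Recomputing the mountain fraction against each draw's complement
keeps the two fractions comparable draw by draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .occurrence import OccurrenceTable

DEFAULT_ALTITUDE_THRESHOLD_M = 1500.0
DEFAULT_N_PERM = 100


@dataclass(frozen=True)
class AltitudeSplit:
    mountain: tuple
    lowland: tuple
    threshold_m: float


def split_by_altitude(
    lakes: pd.DataFrame, threshold_m: float = DEFAULT_ALTITUDE_THRESHOLD_M
) -> AltitudeSplit:
    """Partition lakes at the altitude threshold; strictly above -> mountain."""
    if "altitude_m" not in lakes.columns:
        raise ValidationError("lake metadata lacks an altitude_m column")
    missing = lakes.loc[lakes["altitude_m"].isna(), "lake_id"].tolist()
    if missing:
        raise ValidationError(f"lakes with missing altitude: {missing[:10]}")
    is_mtn = lakes["altitude_m"] > threshold_m
    return AltitudeSplit(
        mountain=tuple(sorted(lakes.loc[is_mtn, "lake_id"])),
        lowland=tuple(sorted(lakes.loc[~is_mtn, "lake_id"])),
        threshold_m=threshold_m,
    )


def per_lake_richness(table: OccurrenceTable, level: str) -> pd.Series:
    """Distinct taxa per lake at the requested resolution ('v9' or 'swarm')."""
    col = "v9_id" if level == "v9" else "swarm_id"
    if level not in ("v9", "swarm"):
        raise ValidationError(f"unknown level {level!r}")
    return table.df.groupby("lake_id")[col].nunique().sort_index()


def swarms_per_v9_per_lake(table: OccurrenceTable) -> pd.Series:
    """Mean number of ITS-SWARMs per V9-group in each lake (microdiversity)."""
    per = table.df.groupby(["lake_id", "v9_id"])["swarm_id"].nunique()
    return per.groupby("lake_id").mean().sort_index()


def ranksum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Exact enumeration when both samples are small and untied; otherwise the
    tie-corrected normal approximation. Returns (U statistic of the first
    sample, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("rank-sum test requires two nonempty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def exclusive_fraction(presence: np.ndarray, focal: np.ndarray, reference: np.ndarray):
    """(n_exclusive, fraction) of taxa present in focal, absent from reference.

    ``presence`` is boolean taxa x lakes; focal/reference are column indices.
    The fraction is n_exclusive / richness(focal); presence-based, so
    duplicated read counts are irrelevant.
    """
    in_focal = presence[:, focal].any(axis=1)
    in_ref = presence[:, reference].any(axis=1)
    richness = int(in_focal.sum())
    if richness == 0:
        return 0, 0.0
    n_excl = int((in_focal & ~in_ref).sum())
    return n_excl, n_excl / richness


def exclusivity_resampling(
    table: OccurrenceTable,
    split: AltitudeSplit,
    level: str = "v9",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """Mountain vs size-matched lowland exclusivity, resampled n_perm times.

    Per draw: sample |mountain| lowland lakes without replacement; the
    reference is the remaining lowland lakes; record the exclusive fraction
    of (i) the mountain set and (ii) the drawn lowland set against that
    reference. Returns both distributions, a rank-sum comparison, and the
    absolute exclusive counts against the full opposite altitude class.
    """
    if len(split.mountain) == 0:
        raise DegenerateDataError("no mountain lakes; altitude contrast undefined")
    if len(split.mountain) > len(split.lowland):
        raise ValidationError("more mountain than lowland lakes; cannot size-match draws")
    lake_ids = sorted(set(split.mountain) | set(split.lowland))
    taxa, lake_ids, pres = table.presence_matrix(level, lake_ids)
    pos = {l: i for i, l in enumerate(lake_ids)}
    mtn = np.array([pos[l] for l in split.mountain], dtype=np.intp)
    low = np.array([pos[l] for l in split.lowland], dtype=np.intp)
    k = len(mtn)
    rng = np.random.default_rng(seed)
    mountain_fracs = np.empty(n_perm)
    lowland_fracs = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(low, size=k, replace=False)
        ref = np.setdiff1d(low, draw)
        _, mountain_fracs[i] = exclusive_fraction(pres, mtn, ref)
        _, lowland_fracs[i] = exclusive_fraction(pres, draw, ref)
    stat, p = ranksum_test(mountain_fracs, lowland_fracs)
    n_excl_mtn, frac_mtn = exclusive_fraction(pres, mtn, low)
    n_excl_low, frac_low = exclusive_fraction(pres, low, mtn)
    return {
        "level": level,
        "n_perm": n_perm,
        "mountain_fractions": mountain_fracs,
        "lowland_fractions": lowland_fracs,
        "ranksum_U": stat,
        "ranksum_p": p,
        "n_exclusive_mountain": n_excl_mtn,
        "fraction_exclusive_mountain": frac_mtn,
        "n_exclusive_lowland": n_excl_low,
        "fraction_exclusive_lowland": frac_low,
        "reference_size": len(low) - k,
    }


def altitude_richness_test(
    table: OccurrenceTable, split: AltitudeSplit, level: str = "v9"
) -> dict:
    """Rank-sum comparison of per-lake richness, mountain vs lowland."""
    rich = per_lake_richness(table, level)
    rich = rich.reindex(sorted(set(split.mountain) | set(split.lowland)), fill_value=0)
    a = rich.loc[list(split.mountain)].to_numpy()
    b = rich.loc[list(split.lowland)].to_numpy()
    if len(a) == 0:
        raise DegenerateDataError("no mountain lakes; altitude contrast undefined")
    stat, p = ranksum_test(a, b)
    return {
        "level": level,
        "median_mountain": float(np.median(a)),
        "median_lowland": float(np.median(b)),
        "ranksum_U": stat,
        "ranksum_p": p,
    }


def microdiversity_test(table: OccurrenceTable, split: AltitudeSplit) -> dict:
    """Rank-sum test of ITS-SWARMs per V9-group per lake across altitude."""
    micro = swarms_per_v9_per_lake(table)
    a = micro.reindex(list(split.mountain)).dropna().to_numpy()
    b = micro.reindex(list(split.lowland)).dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("microdiversity contrast needs taxa in both classes")
    stat, p = ranksum_test(a, b)
    return {
        "median_mountain": float(np.median(a)),
        "median_lowland": float(np.median(b)),
        "ranksum_U": stat,
        "ranksum_p": p,
    }
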