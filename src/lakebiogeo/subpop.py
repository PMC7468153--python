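"""ITS-SWARM (subpopulation) analyses.

Two questions are asked of the swarms nested inside each V9-group:

1. Geographic restriction *within* the parent's range: the same
   randomization machinery as the V9-level screen, but the reference pool
   for each swarm is the set of lakes occupied by its parent V9-group. A
   swarm that fills its parent's whole range (or whose parent occupies
   fewer than three lakes) has a degenerate null and is flagged untestable.

2. Ecophysiological differentiation: for every V9-group with at least two
   swarms, the per-lake environmental values (pH, conductivity,
   temperature, altitude) of each swarm's occupied lakes are compared by a
   Kruskal-Wallis test followed by Dunn's post hoc z tests. A lake occupied
   by several swarms of the same V9 contributes its value once per swarm.
   P-values are Benjamini-Hochberg adjusted across V9-groups within each
   parameter (the correction is configurable, including none).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .geometry import DistanceMatrix, mean_pairwise_from_indices
from .occurrence import OccurrenceTable
from .restriction import (
    DEFAULT_DRAWS,
    DEFAULT_RESTRICTED_Q,
    null_distribution,
    restriction_quantile,
)

DEFAULT_PARAMETERS = ("pH", "conductivity_uScm", "temperature_C", "altitude_m")


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H across k >= 2 groups.

    Returns (H, p) with p from the chi-square(k-1) approximation; all
    values identical -> (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("Kruskal-Wallis groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def dunn_posthoc(groups, labels=None, adjust: str | None = "bh") -> pd.DataFrame:
    """Dunn's pairwise post hoc z tests after a Kruskal-Wallis comparison.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)] with
    tie term T = sum(t^3 - t) / (12 (N - 1)). Two-sided normal p-values,
    optionally adjusted ('bh', 'bonferroni', 'holm' or None) across the
    C(k,2) pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValidationError("Dunn's test groups must be nonempty")
    k = len(groups)
    if labels is None:
        labels = list(range(k))
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(ranks[start : start + n_i].mean())
        start += n_i
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(k), 2):
        denom = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / denom if denom > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if denom > 0 else 1.0
        rows.append({"group_i": labels[i], "group_j": labels[j], "z": z, "p": p})
    out = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), adjust)
    return out


def adjust_pvalues(p: np.ndarray, method: str | None) -> np.ndarray:
    if method is None or method == "none" or len(p) == 0:
        return np.asarray(p, dtype=float)
    name = {"bh": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}.get(method)
    if name is None:
        raise ValidationError(f"unknown p adjustment {method!r}")
    return multipletests(p, method=name)[1]


def swarm_restriction(
    table: OccurrenceTable,
    m: DistanceMatrix,
    R: int = DEFAULT_DRAWS,
    seed: int = 0,
    restricted_q: float = DEFAULT_RESTRICTED_Q,
) -> pd.DataFrame:
    """Parent-conditioned geographic restriction for every multi-lake swarm.

    The null pool is the parent V9-group's lake set ("all lakes in which the
    respective V9-group occurred"). Swarms with occupancy 1 are excluded;
    swarms with a parent pool < 3 lakes or occupancy equal to the pool size
    are reported with ``untestable=True`` (zero-variance null, q = 0).
    """
    v9_lakes = table.presence_sets("v9")
    swarm_lakes = table.presence_sets("swarm")
    parent_of = table.swarm_parent()
    rows = []
    for swarm in sorted(swarm_lakes):
        occ = sorted(swarm_lakes[swarm])
        n = len(occ)
        if n < 2:
            continue
        parent = parent_of[swarm]
        pool = sorted(v9_lakes[parent])
        if not set(occ) <= set(pool):
            raise ValidationError(f"swarm {swarm} occupies lakes outside parent {parent}")
        idx = m.indices(occ)
        observed = mean_pairwise_from_indices(m.values, idx)
        untestable = len(pool) < 3 or n == len(pool)
        if untestable:
            q = 0.0
            null_mean = observed if n == len(pool) else np.nan
        else:
            null = null_distribution(n, pool, m, R=R, taxon_id=swarm, seed=seed)
            q = restriction_quantile(observed, null)
            null_mean = float(null.draws.mean())
        rows.append(
            {
                "swarm_id": swarm,
                "parent_v9": parent,
                "occupancy": n,
                "pool_size": len(pool),
                "observed_km": observed,
                "null_mean_km": null_mean,
                "q": q,
                "restricted": (not untestable) and q > restricted_q,
                "untestable": untestable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["swarm_id", "parent_v9", "occupancy", "pool_size", "observed_km",
                 "null_mean_km", "q", "restricted", "untestable"],
    )


def env_differentiation(
    table: OccurrenceTable,
    lakes: pd.DataFrame,
    parameters=DEFAULT_PARAMETERS,
    min_swarm_lakes: int = 2,
    alpha: float = 0.05,
    adjust: str | None = "bh",
    collect_dunn: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis + Dunn screen for environmental differentiation of
    swarms within each V9-group.

    Only V9-groups with >= 2 swarms each occupying >= ``min_swarm_lakes``
    lakes enter a parameter's test; lakes lacking a value for a parameter
    are dropped from that parameter only. Per parameter, p-values are
    adjusted across V9-groups (``adjust``: 'bh' default, or None for raw
    alpha). Returns (per-group results, pairwise Dunn table).
    """
    meta = lakes.set_index("lake_id")
    for par in parameters:
        if par not in meta.columns:
            raise ValidationError(f"lake metadata lacks parameter column {par!r}")
    swarm_lakes = table.presence_sets("swarm")
    parent_of = table.swarm_parent()
    by_parent: dict = {}
    for s, lk in swarm_lakes.items():
        by_parent.setdefault(parent_of[s], []).append((s, sorted(lk)))

    results = []
    dunn_rows = []
    for v9 in sorted(by_parent):
        swarms = sorted(by_parent[v9])
        if len(swarms) < 2:
            continue
        for par in parameters:
            vals = meta[par]
            groups, labels = [], []
            for s, lk in swarms:
                g = vals.reindex(lk).dropna().to_numpy()
                if len(g) >= min_swarm_lakes:
                    groups.append(g)
                    labels.append(s)
            if len(groups) < 2:
                continue
            H, p = kruskal_wallis(groups)
            results.append(
                {"v9_id": v9, "parameter": par, "k_swarms": len(groups),
                 "n_values": int(sum(len(g) for g in groups)), "H": H, "p": p}
            )
            if collect_dunn:
                d = dunn_posthoc(groups, labels=labels, adjust=adjust)
                d.insert(0, "parameter", par)
                d.insert(0, "v9_id", v9)
                dunn_rows.append(d)
    res = pd.DataFrame(results, columns=["v9_id", "parameter", "k_swarms", "n_values", "H", "p"])
    if len(res):
        res["p_adj"] = np.nan
        for par in parameters:
            mask = res["parameter"] == par
            if mask.any():
                res.loc[mask, "p_adj"] = adjust_pvalues(res.loc[mask, "p"].to_numpy(), adjust)
        res["significant"] = res["p_adj"] < alpha
    else:
        res["p_adj"] = pd.Series(dtype=float)
        res["significant"] = pd.Series(dtype=bool)
    dunn = (
        pd.concat(dunn_rows, ignore_index=True)
        if dunn_rows
        else pd.DataFrame(columns=["v9_id", "parameter", "group_i", "group_j", "z", "p", "p_adj"])
    )
    return res, dunn
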