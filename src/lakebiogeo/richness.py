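"""Gridded regional richness with rarefaction interpolation to one lake.

Lakes are binned into 2.5 deg x 2.5 deg cells (half-open, origin at
(0, 0) by default so cells align with multiples of 2.5 deg). Within each
cell and taxonomic group, the expected richness of a random n-lake subset
is computed analytically (hypergeometric form):

    S_exp(n) = sum_i [ 1 - C(L - L_i, n) / C(L, n) ]

with L lakes in the cell and taxon i occupying L_i of them. The curve
(n, S_exp(n)) for n = 1..L is then fitted with

    S = a * log(n + 1) + b        (natural log by default)

and the value at n = 1, N_interpolated = a*log(2) + b, is the cell's
lake-density-corrected richness. Cells holding a single lake use the raw
richness of that lake. Groups with fewer than ``min_group_size`` (default
50) V9-groups overall are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ValidationError
from .occurrence import OccurrenceTable

DEFAULT_GRID_SIZE = 2.5
DEFAULT_MIN_GROUP_SIZE = 50


def assign_grid(lats, lons, origin=(0.0, 0.0), size: float = DEFAULT_GRID_SIZE):
    """(lat_index, lon_index) of the half-open cell containing each point."""
    if size <= 0:
        raise ValidationError("grid size must be positive")
    lat = np.asarray(lats, dtype=float)
    lon = np.asarray(lons, dtype=float)
    lat_idx = np.floor((lat - origin[0]) / size).astype(int)
    lon_idx = np.floor((lon - origin[1]) / size).astype(int)
    return lat_idx, lon_idx


def rarefaction_expected_richness(occupancy: np.ndarray, L: int, n: int) -> float:
    """Expected richness of a uniform random n-lake subset of an L-lake cell.

    ``occupancy`` holds L_i, the number of cell lakes occupied by taxon i.
    Exact analytic expectation; no resampling.
    """
    if not (1 <= n <= L):
        raise ValidationError(f"subsample size {n} outside [1, {L}]")
    Li = np.asarray(occupancy, dtype=float)
    if np.any(Li < 1) or np.any(Li > L):
        raise ValidationError("taxon occupancies must lie in [1, L]")
    # C(L - Li, n) / C(L, n), zero when L - Li < n
    rest = L - Li
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(rest + 1) - gammaln(n + 1) - gammaln(rest - n + 1)
            - (gammaln(L + 1) - gammaln(n + 1) - gammaln(L - n + 1))
        )
    miss = np.where(rest >= n, np.exp(log_ratio), 0.0)
    return float(np.sum(1.0 - miss))


def rarefaction_curve(occupancy: np.ndarray, L: int) -> pd.DataFrame:
    """The full analytic rarefaction curve for n = 1..L."""
    pts = [(n, rarefaction_expected_richness(occupancy, L, n)) for n in range(1, L + 1)]
    return pd.DataFrame(pts, columns=["n_lakes", "expected_richness"])


def monte_carlo_rarefaction(
    presence: np.ndarray, n: int, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Richness of ``n_iter`` random n-lake subsets (cross-check of the
    analytic expectation). ``presence`` is a boolean taxa x lakes matrix."""
    T, L = presence.shape
    out = np.empty(n_iter)
    for k in range(n_iter):
        cols = rng.choice(L, size=n, replace=False)
        out[k] = presence[:, cols].any(axis=1).sum()
    return out


@dataclass(frozen=True)
class LogModelFit:
    a: float
    b: float
    n_points: int
    rss: float
    N_interpolated: float


def fit_log_model(n_values, richness, base: str = "e") -> LogModelFit:
    """Least-squares fit of S = a*log(n+1) + b; returns the value at n=1.

    ``base`` 'e' (default) or '10'.
    """
    n_values = np.asarray(n_values, dtype=float)
    richness = np.asarray(richness, dtype=float)
    if n_values.ndim != 1 or n_values.shape != richness.shape:
        raise ValidationError("n_values and richness must be equal-length vectors")
    if len(np.unique(n_values)) < 2:
        raise ValidationError("log-model fit needs >= 2 distinct n values")
    logf = np.log10 if base == "10" else np.log
    x = logf(n_values + 1.0)
    a, b = np.polyfit(x, richness, 1)
    pred = a * x + b
    rss = float(np.sum((richness - pred) ** 2))
    return LogModelFit(float(a), float(b), len(n_values), rss, float(a * logf(2.0) + b))


def interpolated_richness(
    presence: np.ndarray, base: str = "e", mode: str = "analytic",
    rng: np.random.Generator | None = None, mc_iter: int = 200,
) -> float:
    """Per-lake interpolated richness of one cell (taxa x lakes presence).

    L = 1 -> raw richness of the single lake; L >= 2 -> value at one lake of
    the fitted log curve. ``mode='monte_carlo'`` fits to resampled rather
    than analytic rarefaction points (cross-validation mode).
    """
    T, L = presence.shape
    if L < 1:
        raise ValidationError("cell must contain at least one lake")
    present = presence.any(axis=1)
    presence = presence[present]
    if L == 1:
        return float(presence.any(axis=1).sum())
    occ = presence.sum(axis=1)
    if mode == "monte_carlo":
        rng = rng or np.random.default_rng(0)
        pts = [
            (n, float(monte_carlo_rarefaction(presence, n, mc_iter, rng).mean()))
            for n in range(1, L + 1)
        ]
        curve = pd.DataFrame(pts, columns=["n_lakes", "expected_richness"])
    else:
        curve = rarefaction_curve(occ, L)
    fit = fit_log_model(curve["n_lakes"], curve["expected_richness"], base=base)
    return fit.N_interpolated


def richness_grid(
    table: OccurrenceTable,
    lakes: pd.DataFrame,
    taxon_groups: pd.Series | None = None,
    origin=(0.0, 0.0),
    size: float = DEFAULT_GRID_SIZE,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
    base: str = "e",
) -> pd.DataFrame:
    """Per-cell, per-group interpolated V9 richness.

    ``taxon_groups`` maps v9_id -> group label; defaults to the table's own
    annotation column. Groups with fewer than ``min_group_size`` V9-groups
    are skipped (too sparse for regional comparison).
    """
    if taxon_groups is None:
        taxon_groups = table.taxon_groups()
    if taxon_groups is None:
        raise ValidationError("richness_grid requires taxon_group annotations")
    meta = lakes.set_index("lake_id")
    lat_idx, lon_idx = assign_grid(meta["lat"].to_numpy(), meta["lon"].to_numpy(), origin, size)
    cell_of = pd.Series(list(zip(lat_idx, lon_idx)), index=meta.index)

    df = table.df[["v9_id", "lake_id"]].drop_duplicates()
    df = df[df["v9_id"].isin(taxon_groups.index)]
    df = df.assign(taxon_group=df["v9_id"].map(taxon_groups), cell=df["lake_id"].map(cell_of))

    group_sizes = df.groupby("taxon_group")["v9_id"].nunique()
    keep_groups = set(group_sizes.index[group_sizes >= min_group_size])

    rows = []
    for (group, cell), sub in df.groupby(["taxon_group", "cell"], sort=True):
        if group not in keep_groups:
            continue
        cell_lakes = sorted(meta.index[cell_of == cell])
        taxa = sorted(sub["v9_id"].unique())
        t_idx = {t: i for i, t in enumerate(taxa)}
        l_idx = {l: i for i, l in enumerate(cell_lakes)}
        pres = np.zeros((len(taxa), len(cell_lakes)), dtype=bool)
        pres[sub["v9_id"].map(t_idx).to_numpy(), sub["lake_id"].map(l_idx).to_numpy()] = True
        L = len(cell_lakes)
        if L == 1:
            a = b = np.nan
            value = float(pres.any(axis=1).sum())
        else:
            curve = rarefaction_curve(pres.sum(axis=1), L)
            fit = fit_log_model(curve["n_lakes"], curve["expected_richness"], base=base)
            a, b, value = fit.a, fit.b, fit.N_interpolated
        rows.append(
            {
                "taxon_group": group,
                "lat_index": cell[0],
                "lon_index": cell[1],
                "n_lakes": L,
                "a": a,
                "b": b,
                "interpolated_richness": value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["taxon_group", "lat_index", "lon_index", "n_lakes", "a", "b",
                 "interpolated_richness"],
    )
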