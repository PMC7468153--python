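"""The central data container: a long-format (V9-group, ITS-SWARM, lake) table.

Two phylogenetic resolutions are carried side by side: V9-groups (identical
first-150-bp 18S V9 prefix; the species-level proxy) and ITS-SWARMs (d=1
single-linkage clusters of ITS1 variants within one V9-group; the
subpopulation proxy). All downstream statistics are presence/absence based;
read counts are kept for filtering and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

COLUMNS = ("v9_id", "swarm_id", "lake_id", "reads")


@dataclass
class OccurrenceTable:
    """Long-format occurrence table keyed by (v9_id, swarm_id, lake_id).

    ``df`` may carry an optional ``taxon_group`` column (per-V9 taxonomic
    annotation, e.g. Chrysophyceae) used by the per-group richness analyses.
    """

    df: pd.DataFrame
    _swarm_parent: dict = field(init=False, repr=False, default=None)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"occurrence table missing columns: {missing}")
        if len(self.df) and (self.df["reads"] < 1).any():
            raise ValidationError("occurrence table contains read counts < 1")
        # a swarm must belong to exactly one parent V9-group
        if len(self.df):
            parents = self.df.groupby("swarm_id", sort=False)["v9_id"].nunique()
            bad = parents[parents > 1]
            if len(bad):
                raise ValidationError(
                    f"swarms with multiple parent V9-groups: {list(bad.index[:5])}"
                )
        dup = self.df.duplicated(subset=["v9_id", "swarm_id", "lake_id"])
        if dup.any():
            raise ValidationError("duplicate (v9_id, swarm_id, lake_id) rows")

    # -- presence views -----------------------------------------------------

    def lakes(self) -> list:
        return sorted(self.df["lake_id"].unique())

    def taxa(self, level: str) -> list:
        return sorted(self.df[_level_col(level)].unique())

    def presence_sets(self, level: str) -> dict:
        """taxon id -> frozenset of occupied lakes, at 'v9' or 'swarm' level."""
        col = _level_col(level)
        return {
            t: frozenset(g)
            for t, g in self.df.groupby(col, sort=True)["lake_id"].unique().items()
        }

    def presence_matrix(self, level: str, lake_ids=None):
        """(taxa list, lake list, boolean taxa x lakes matrix)."""
        col = _level_col(level)
        taxa = self.taxa(level)
        if lake_ids is None:
            lake_ids = self.lakes()
        lake_ids = list(lake_ids)
        t_idx = {t: i for i, t in enumerate(taxa)}
        l_idx = {l: i for i, l in enumerate(lake_ids)}
        mat = np.zeros((len(taxa), len(lake_ids)), dtype=bool)
        sub = self.df[self.df["lake_id"].isin(l_idx)]
        mat[
            sub[col].map(t_idx).to_numpy(),
            sub["lake_id"].map(l_idx).to_numpy(),
        ] = True
        return taxa, lake_ids, mat

    def occupancy(self, level: str) -> pd.Series:
        """Number of occupied lakes per taxon."""
        col = _level_col(level)
        return self.df.groupby(col)["lake_id"].nunique().sort_index()

    def swarm_parent(self) -> dict:
        """swarm_id -> parent v9_id."""
        if self._swarm_parent is None:
            self._swarm_parent = (
                self.df.drop_duplicates("swarm_id").set_index("swarm_id")["v9_id"].to_dict()
            )
        return self._swarm_parent

    def taxon_groups(self) -> pd.Series | None:
        """v9_id -> taxon_group annotation, if the table carries one."""
        if "taxon_group" not in self.df.columns:
            return None
        return self.df.drop_duplicates("v9_id").set_index("v9_id")["taxon_group"]

    def restrict_lakes(self, keep_ids) -> "OccurrenceTable":
        keep = set(keep_ids)
        return OccurrenceTable(self.df[self.df["lake_id"].isin(keep)].reset_index(drop=True))

    def total_reads(self) -> int:
        return int(self.df["reads"].sum())


def _level_col(level: str) -> str:
    if level == "v9":
        return "v9_id"
    if level == "swarm":
        return "swarm_id"
    raise ValidationError(f"unknown level {level!r} (expected 'v9' or 'swarm')")
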