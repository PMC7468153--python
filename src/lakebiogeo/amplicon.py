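"""From paired V9-ITS1 amplicons to the (V9-group x ITS-SWARM x lake) table.

The processing chain mirrors the standard paired-marker protist workflow:

1. exact dereplication per lake (100% identity, length-sensitive);
2. pair filtering: each ITS1 sequence keeps only its most abundant V9
   partner (minority pairings are treated as erroneous chimeric pairings);
3. V9 clustering by identical first-150-bp prefix -> V9-groups;
4. sample filter: lakes with fewer reads than ``min_sample_fraction`` x the
   median per-lake total are dropped;
5. per-lake low-abundance filter: ITS variants below
   ``min_variant_fraction`` of that lake's total are dropped in that lake;
6. SWARM-style clustering of the surviving ITS variants of each V9-group:
   connected components under Levenshtein distance <= d (d=1 default).

Only the single-linkage growth rule of SWARM is implemented; the fastidious
phase and abundance-based chain breaking are not (documented divergence).
Records are plain pandas DataFrames with columns
``v9_seq, its_seq, lake_id, count``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .occurrence import OccurrenceTable

RECORD_COLUMNS = ("v9_seq", "its_seq", "lake_id", "count")

#: taxon annotations excluded from all analyses when annotations are given
DEFAULT_EXCLUDED_GROUPS = frozenset({"Metazoa", "Embryophyta"})


@dataclass
class ProcessingConfig:
    min_sample_fraction: float = 0.15
    min_variant_fraction: float = 1e-5
    swarm_d: int = 1
    v9_prefix_len: int = 150


@dataclass
class ProcessingReport:
    """Per-stage attrition counts, logged for provenance."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, n_records: int, n_reads: int, **extra):
        self.stages.append({"stage": stage, "records": n_records, "reads": n_reads, **extra})

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"amplicon records missing columns: {missing}")
    if len(records) and (records["count"] < 1).any():
        raise ValidationError("amplicon counts must be >= 1")
    if len(records):
        seqs = pd.concat([records["v9_seq"], records["its_seq"]])
        if seqs.str.len().eq(0).any():
            raise ValidationError("empty sequences in amplicon records")
        if not seqs.str.fullmatch("[ACGTN]+").all():
            raise ValidationError("sequences must be over the alphabet {A,C,G,T,N}")
    return records


def dereplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Merge identical (v9_seq, its_seq, lake_id) records, summing reads.

    Length variants are distinct sequences; read totals are conserved.
    """
    _check_records(records)
    if len(records) == 0:
        return records.reset_index(drop=True)
    out = (
        records.groupby(["v9_seq", "its_seq", "lake_id"], sort=True, as_index=False)["count"]
        .sum()
    )
    return out[list(RECORD_COLUMNS)]


def pair_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each ITS sequence, only its most abundant V9 partner.

    Abundance is the total read count of the (v9, its) pairing across lakes;
    ties break to the lexicographically smallest V9 sequence. Afterwards the
    ITS -> V9 mapping is a function, while one V9 may retain many ITS
    variants.
    """
    if len(records) == 0:
        return records.reset_index(drop=True)
    totals = records.groupby(["its_seq", "v9_seq"], sort=True)["count"].sum().reset_index()
    # sort so the winner (max count, then smallest v9_seq) is first per its_seq
    totals = totals.sort_values(
        ["its_seq", "count", "v9_seq"], ascending=[True, False, True], kind="mergesort"
    )
    winners = totals.drop_duplicates("its_seq").set_index("its_seq")["v9_seq"]
    keep = records["v9_seq"] == records["its_seq"].map(winners)
    return records[keep].reset_index(drop=True)


def cluster_v9(records: pd.DataFrame, prefix_len: int = 150) -> pd.Series:
    """Assign V9-group ids by identical ``prefix_len``-bp V9 prefix.

    Sequences shorter than the prefix length are grouped by their full
    sequence. Ids are assigned in lexicographic prefix order, so they are
    independent of record order. Returns a Series aligned to ``records``.
    """
    prefixes = records["v9_seq"].str.slice(0, prefix_len)
    uniq = sorted(prefixes.unique())
    width = max(5, len(str(len(uniq))))
    ids = {p: f"V9_{i + 1:0{width}d}" for i, p in enumerate(uniq)}
    return prefixes.map(ids)


def filter_samples(per_lake_totals: pd.Series, fraction: float = 0.15) -> list:
    """Lakes retained under the median-based sequencing-depth filter.

    A lake is dropped when its read total is strictly below
    ``fraction x median(total)``; the threshold is computed from the data at
    hand, not hard-coded.
    """
    if len(per_lake_totals) == 0:
        raise DegenerateDataError("no lakes to filter")
    cutoff = fraction * float(per_lake_totals.median())
    kept = sorted(per_lake_totals.index[per_lake_totals >= cutoff])
    if not kept:
        raise DegenerateDataError("sample filter removed every lake")
    return kept


def filter_low_abundance(records: pd.DataFrame, min_fraction: float = 1e-5) -> pd.DataFrame:
    """Drop, per lake, ITS variants below ``min_fraction`` of the lake total.

    The removal is per lake: a variant may survive in a deeply covered lake
    and be dropped from another. Equality with the threshold is kept
    (strictly-less-than is removed).
    """
    if len(records) == 0:
        return records.reset_index(drop=True)
    totals = records.groupby("lake_id")["count"].transform("sum")
    keep = records["count"] >= min_fraction * totals
    return records[keep].reset_index(drop=True)


def _levenshtein_le(a: str, b: str, d: int) -> bool:
    if abs(len(a) - len(b)) > d:
        return False
    return edlib.align(a, b, task="distance", k=d)["editDistance"] != -1


def swarm_cluster(variants, d: int = 1) -> list:
    """Cluster ITS variants of one V9-group: components at edit distance <= d.

    Single-linkage agglomeration (the core SWARM growth rule): two variants
    belong to the same swarm iff they are connected by a chain of variants
    with consecutive Levenshtein distances <= d. Returns a list of sorted
    variant lists; clusters ordered by their smallest member.
    """
    if d < 0:
        raise ValidationError("swarm clustering distance d must be >= 0")
    variants = sorted(set(variants))
    n = len(variants)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) != find(j) and _levenshtein_le(variants[i], variants[j], d):
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(variants[i])
    return sorted((sorted(c) for c in comps.values()), key=lambda c: c[0])


def build_occurrence_table(
    records: pd.DataFrame,
    v9_ids: pd.Series,
    config: ProcessingConfig,
    annotations: dict | None = None,
    excluded_groups=DEFAULT_EXCLUDED_GROUPS,
) -> OccurrenceTable:
    """Cluster ITS variants per V9-group and aggregate to the long table.

    ``annotations`` optionally maps v9_id -> taxon_group; groups named in
    ``excluded_groups`` (metazoans, higher plants) are dropped entirely.
    """
    if len(records) == 0:
        return OccurrenceTable(pd.DataFrame(columns=["v9_id", "swarm_id", "lake_id", "reads"]))
    work = records.assign(v9_id=v9_ids.values)
    rows = []
    for v9_id, grp in work.groupby("v9_id", sort=True):
        group_label = annotations.get(v9_id) if annotations else None
        if group_label is not None and group_label in excluded_groups:
            continue
        swarms = swarm_cluster(grp["its_seq"].unique(), d=config.swarm_d)
        member_of = {v: k for k, sw in enumerate(swarms) for v in sw}
        width = max(3, len(str(len(swarms))))
        sid = grp["its_seq"].map(lambda v: f"{v9_id}_S{member_of[v] + 1:0{width}d}")
        agg = (
            grp.assign(swarm_id=sid)
            .groupby(["swarm_id", "lake_id"], sort=True)["count"]
            .sum()
            .reset_index()
        )
        agg.insert(0, "v9_id", v9_id)
        if group_label is not None:
            agg["taxon_group"] = group_label
        rows.append(agg)
    if not rows:
        return OccurrenceTable(pd.DataFrame(columns=["v9_id", "swarm_id", "lake_id", "reads"]))
    out = pd.concat(rows, ignore_index=True).rename(columns={"count": "reads"})
    return OccurrenceTable(out)


def process_amplicons(
    records: pd.DataFrame,
    config: ProcessingConfig | None = None,
    annotations_by_prefix: dict | None = None,
) -> tuple[OccurrenceTable, ProcessingReport]:
    """Run the full chain from raw paired amplicons to an OccurrenceTable.

    ``annotations_by_prefix`` maps a V9 prefix (first ``v9_prefix_len``
    bases) to a taxon_group label; BLAST-style taxonomy itself is out of
    scope and labels are taken as input.
    """
    config = config or ProcessingConfig()
    report = ProcessingReport()
    report.add("input", len(records), int(records["count"].sum()) if len(records) else 0)

    rec = dereplicate(records)
    report.add("dereplicate", len(rec), int(rec["count"].sum()) if len(rec) else 0)

    rec = pair_filter(rec)
    report.add("pair_filter", len(rec), int(rec["count"].sum()) if len(rec) else 0)

    if len(rec) == 0:
        return build_occurrence_table(rec, pd.Series(dtype=object), config), report

    totals = rec.groupby("lake_id")["count"].sum()
    kept_lakes = filter_samples(totals, fraction=config.min_sample_fraction)
    rec = rec[rec["lake_id"].isin(set(kept_lakes))].reset_index(drop=True)
    report.add("filter_samples", len(rec), int(rec["count"].sum()), lakes_kept=len(kept_lakes))

    rec = filter_low_abundance(rec, min_fraction=config.min_variant_fraction)
    report.add("filter_low_abundance", len(rec), int(rec["count"].sum()) if len(rec) else 0)

    v9_ids = cluster_v9(rec, prefix_len=config.v9_prefix_len)
    annotations = None
    if annotations_by_prefix is not None:
        prefix_of = rec["v9_seq"].str.slice(0, config.v9_prefix_len)
        annotations = {
            vid: annotations_by_prefix.get(pref)
            for vid, pref in zip(v9_ids, prefix_of)
        }
    table = build_occurrence_table(rec, v9_ids, config, annotations=annotations)
    table.df.attrs["v9_prefix_map"] = dict(
        zip(v9_ids, rec["v9_seq"].str.slice(0, config.v9_prefix_len))
    )
    report.add(
        "occurrence_table",
        len(table.df),
        table.total_reads(),
        v9_groups=table.df["v9_id"].nunique() if len(table.df) else 0,
        its_swarms=table.df["swarm_id"].nunique() if len(table.df) else 0,
    )
    return table, report
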