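"""Readers, writers, run configuration and the end-to-end pipeline driver.

All tabular artifacts are tab-separated text. Paired amplicons travel as
FASTA with a size-annotation header dialect:

    >seq00001;lake=L001;size=123;v9len=157
    <V9 sequence immediately followed by the ITS1 sequence>

``v9len`` marks the split point between the V9 and ITS1 parts of the merged
amplicon.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import altitude as alt_mod
from . import restriction, richness, subpop
from .errors import ValidationError
from .geometry import distance_matrix
from .occurrence import COLUMNS, OccurrenceTable

LAKE_COLUMNS = ("lake_id", "lat", "lon", "altitude_m", "pH", "conductivity_uScm",
                "temperature_C")


def read_lakes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"lake table {path} missing columns: {missing}")
    dup = df["lake_id"][df["lake_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate lake ids: {sorted(set(dup))[:5]}")
    bad_lat = df.index[(df["lat"].abs() > 90) | ~np.isfinite(df["lat"])].tolist()
    bad_lon = df.index[(df["lon"].abs() > 180) | ~np.isfinite(df["lon"])].tolist()
    if bad_lat or bad_lon:
        lines = sorted(set(bad_lat + bad_lon))
        raise ValidationError(f"out-of-range coordinates at data lines {lines[:10]}")
    return df


def write_lakes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path, lakes: pd.DataFrame | None = None) -> OccurrenceTable:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        df = pd.DataFrame(columns=list(COLUMNS))
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"occurrence table {path} missing columns: {missing}")
    if lakes is not None:
        unknown = sorted(set(df["lake_id"]) - set(lakes["lake_id"]))
        if unknown:
            raise ValidationError(f"occurrence table references unknown lakes: {unknown[:10]}")
    return OccurrenceTable(df)


def write_table(table: OccurrenceTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> dict:
    """TSV v9_id -> taxon_group."""
    df = pd.read_csv(path, sep="\t")
    for col in ("v9_id", "taxon_group"):
        if col not in df.columns:
            raise ValidationError(f"annotation table missing column {col!r}")
    return dict(zip(df["v9_id"], df["taxon_group"]))


def write_amplicon_fasta(records: pd.DataFrame, path) -> None:
    out = []
    for i, r in enumerate(records.itertuples(index=False)):
        header = f"seq{i + 1:07d};lake={r.lake_id};size={int(r.count)};v9len={len(r.v9_seq)}"
        out.append(SeqRecord(Seq(r.v9_seq + r.its_seq), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_amplicon_fasta(path) -> pd.DataFrame:
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(kv.split("=", 1) for kv in rec.id.split(";")[1:] if "=" in kv)
        try:
            lake, size, v9len = fields["lake"], int(fields["size"]), int(fields["v9len"])
        except KeyError as e:
            raise ValidationError(f"FASTA header {rec.id!r} lacks field {e.args[0]!r}") from None
        seq = str(rec.seq).upper()
        rows.append((seq[:v9len], seq[v9len:], lake, size))
    return pd.DataFrame(rows, columns=["v9_seq", "its_seq", "lake_id", "count"])


# ---------------------------------------------------------------------------
# run configuration and orchestration


@dataclass
class RunConfig:
    """Every tunable threshold of the pipeline, serialized for provenance."""

    draws: int = 1000
    endemic_q: float = 0.9
    max_area_km2: float = 1_000_000.0
    restricted_q: float = 0.5
    grid_size_deg: float = 2.5
    altitude_threshold_m: float = 1500.0
    n_perm: int = 100
    min_group_size: int = 50
    min_sample_fraction: float = 0.15
    min_variant_fraction: float = 1e-5
    swarm_d: int = 1
    v9_prefix_len: int = 150
    seed: int = 0
    env_parameters: tuple = subpop.DEFAULT_PARAMETERS
    stages: tuple = ("biogeo_v9", "biogeo_swarm", "grid", "altitude", "subpop")
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        clean = {k: v for k, v in (data or {}).items() if k in known}
        for key in ("env_parameters", "stages"):
            if key in clean and clean[key] is not None:
                clean[key] = tuple(clean[key])
        return cls(**clean)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    table: OccurrenceTable,
    lakes: pd.DataFrame,
    out_dir,
    config: RunConfig | None = None,
) -> dict:
    """Run the configured stages on one dataset and write all artifacts.

    Outputs (TSV/JSON) land in ``out_dir`` together with ``config.yaml``
    and a ``manifest.json`` carrying the SHA-256 of every artifact: a rerun
    from the same inputs, config and seed reproduces the manifest
    byte-for-byte.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    m = distance_matrix(lakes["lake_id"], lakes["lat"].to_numpy(), lakes["lon"].to_numpy())
    summary: dict = {"stages": {}}

    if "biogeo_v9" in cfg.stages:
        res, cohort, n_single = restriction.run_biogeography(
            table, lakes, m, level="v9", R=cfg.draws, seed=cfg.seed,
            restricted_q=cfg.restricted_q, endemic_q=cfg.endemic_q,
            max_area_km2=cfg.max_area_km2,
        )
        res.to_csv(out / "restriction_v9.tsv", sep="\t", index=False)
        summary["stages"]["biogeo_v9"] = {
            "taxa_tested": int(len(res)),
            "singletons": int(n_single),
            "n_restricted": int(res["restricted"].sum()) if len(res) else 0,
            "n_endemic": int(res["endemic"].sum()) if len(res) else 0,
            "cohort_t": None if cohort is None else dataclasses.asdict(cohort),
        }

    if "biogeo_swarm" in cfg.stages:
        sres = subpop.swarm_restriction(
            table, m, R=cfg.draws, seed=cfg.seed, restricted_q=cfg.restricted_q
        )
        sres.to_csv(out / "restriction_swarm.tsv", sep="\t", index=False)
        occ = table.occupancy("swarm")
        summary["stages"]["biogeo_swarm"] = {
            "swarms_total": int(len(occ)),
            "swarms_singleton": int((occ == 1).sum()),
            "swarms_tested": int((~sres["untestable"]).sum()) if len(sres) else 0,
            "n_restricted": int(sres["restricted"].sum()) if len(sres) else 0,
        }

    if "grid" in cfg.stages:
        grid = richness.richness_grid(
            table, lakes, size=cfg.grid_size_deg, min_group_size=cfg.min_group_size
        ) if table.taxon_groups() is not None else pd.DataFrame()
        grid.to_csv(out / "grid_richness.tsv", sep="\t", index=False)
        summary["stages"]["grid"] = {
            "cells": int(len(grid)),
            "groups": int(grid["taxon_group"].nunique()) if len(grid) else 0,
        }

    if "altitude" in cfg.stages:
        split = alt_mod.split_by_altitude(lakes, cfg.altitude_threshold_m)
        if len(split.mountain) == 0:
            summary["stages"]["altitude"] = {"skipped": "no mountain lakes"}
        else:
            alt_summary = {"n_mountain": len(split.mountain), "n_lowland": len(split.lowland)}
            per_draw = {}
            for level in ("v9", "swarm"):
                rich_test = alt_mod.altitude_richness_test(table, split, level)
                excl = alt_mod.exclusivity_resampling(
                    table, split, level, n_perm=cfg.n_perm, seed=cfg.seed
                )
                per_draw[f"mountain_{level}"] = excl.pop("mountain_fractions")
                per_draw[f"lowland_{level}"] = excl.pop("lowland_fractions")
                alt_summary[level] = {"richness": rich_test, "exclusivity": excl}
            alt_summary["microdiversity"] = alt_mod.microdiversity_test(table, split)
            pd.DataFrame(per_draw).to_csv(out / "altitude_draws.tsv", sep="\t", index=False)
            summary["stages"]["altitude"] = alt_summary

    if "subpop" in cfg.stages:
        env, dunn = subpop.env_differentiation(table, lakes, parameters=cfg.env_parameters)
        env.to_csv(out / "env_differentiation.tsv", sep="\t", index=False)
        dunn.to_csv(out / "env_dunn.tsv", sep="\t", index=False)
        sig = (
            env[env["significant"]].groupby("parameter")["v9_id"].nunique().to_dict()
            if len(env) else {}
        )
        summary["stages"]["subpop"] = {
            "v9_tested": int(env["v9_id"].nunique()) if len(env) else 0,
            "significant_per_parameter": {k: int(v) for k, v in sig.items()},
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    artifacts = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": cfg.seed,
        "files": {p.name: _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return summary
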