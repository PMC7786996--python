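"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions: beta matrices are TSV with probe rows and a header of sample
ids; sample sheets are CSV keyed by ``sample_id``; site tables are 6-column
TSV (chrom, pos 1-based, strand, count_methylated, count_total, beta);
regions are BED (0-based half-open) converted once, at read time, to the
internal 1-based inclusive convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("evtwin")

REQUIRED_SHEET_COLUMNS = ("sample_id", "individual_id", "family_id")


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples beta TSV; rows with missing or out-of-range
    values are dropped (and counted in the log), never imputed."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"empty beta matrix: {path}")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate probe ids in {path}")
    if pd.Index(df.columns).duplicated().any():
        raise ValueError(f"duplicate sample ids in {path}")
    vals = df.apply(pd.to_numeric, errors="coerce")
    ok = vals.notna().all(axis=1) & ((vals >= 0) & (vals <= 1)).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        log.info("read_beta_matrix: dropped %d rows with missing/out-of-range values", dropped)
    out = vals.loc[ok]
    out.index.name = "probe_id"
    out.attrs["rows_dropped"] = dropped
    return out


def write_beta_matrix(beta: pd.DataFrame, path):
    beta.to_csv(path, sep="\t", float_format="%.6f", index_label="probe_id")


def read_sample_sheet(path, require_twins: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in REQUIRED_SHEET_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"sample sheet is missing required column: {col}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicated sample_id values: {dup}")
    if require_twins:
        sizes = df.groupby("family_id")["individual_id"].nunique()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValueError(f"families without exactly 2 individuals: {dict(bad)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path):
    sheet.to_csv(path, index=False)


def read_probe_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "probe_id" not in df.columns:
        raise ValueError("manifest must have a probe_id column")
    if df["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in manifest")
    if "flags" not in df.columns:
        df["flags"] = ""
    return df


def write_probe_manifest(manifest: pd.DataFrame, path):
    manifest.to_csv(path, sep="\t", index=False)


@dataclass
class RegionSet:
    """Per-chromosome sorted, merged intervals, 1-based inclusive."""

    intervals: dict = field(default_factory=dict)

    def __len__(self):
        return sum(len(v) for v in self.intervals.values())


def read_regions(path) -> RegionSet:
    """Read BED3+ (0-based half-open) into merged 1-based inclusive
    intervals; a line ``chr1 0 10`` covers 1-based positions 1..10."""
    raw = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed BED line (need 3 fields)")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start0, end0 = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start0 >= end0:
                raise ValueError(f"{path}:{lineno}: start >= end")
            raw.setdefault(chrom, []).append((start0 + 1, end0))
    merged = {}
    for chrom, ivs in raw.items():
        ivs.sort()
        out = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=int)
    return RegionSet(intervals=merged)


def read_wgbs_table(path, dialect: str = "onebased") -> pd.DataFrame:
    """Read a 6-column site TSV; ``dialect='bedmethyl'`` marks 0-based
    positions, shifted to 1-based on read."""
    df = pd.read_csv(
        path, sep="\t",
        names=["chrom", "pos", "strand", "count_methylated", "count_total", "beta"],
        header=None, comment="#",
    )
    if df.iloc[0]["chrom"] == "chrom":  # tolerate a header row
        df = df.iloc[1:].reset_index(drop=True)
        df["pos"] = df["pos"].astype(int)
        for c in ("count_methylated", "count_total"):
            df[c] = df[c].astype(int)
        df["beta"] = df["beta"].astype(float)
    if dialect == "bedmethyl":
        df["pos"] = df["pos"] + 1
    elif dialect != "onebased":
        raise ValueError(f"unknown dialect: {dialect!r}")
    if (df["count_methylated"] > df["count_total"]).any():
        raise ValueError("count_methylated exceeds count_total")
    return df


def write_wgbs_table(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def read_icc(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "icc"} <= set(df.columns):
        raise ValueError("ICC file needs columns probe_id, icc")
    return df


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "scheme", "label"} <= set(df.columns):
        raise ValueError("annotation file needs columns probe_id, scheme, label")
    return df


def read_fasta(path) -> dict:
    """FASTA keyed by record id (sequence windows around probes)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(path, command: str, config: dict, seeds: dict, inputs=(), stage_counts=None):
    """Record everything needed to reproduce a CLI run."""
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "stage_counts": stage_counts or {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
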