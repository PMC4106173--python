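"""Readers and writers for the tabular genotype/cross/phenotype formats.

All files are plain tab-separated text with a header line, optionally
preceded by ``# key=value`` metadata comment lines; every file written by
this package embeds the run seed and a configuration hash so outputs are
traceable.  Hybrid identifiers are canonicalized as "parentA×parentB"
with the lexicographically smaller parent first (a plain "x" separator is
accepted on input).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import check_phenotypes
from .panel import CrossSet, LinePanel, hybrid_id, split_hybrid_id


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a TSV with ``# key=value`` metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by `write_table`; returns (frame, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    return df, meta


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def write_genotypes(panel: LinePanel, path, meta: dict | None = None) -> None:
    """Long-format genotype table: line, group, marker, allele."""
    rows = []
    for line in panel.lines:
        group = int(panel.groups[line])
        for marker in panel.markers:
            allele = panel.genotypes.at[line, marker]
            if pd.isna(allele):
                continue
            rows.append((line, group, marker, allele))
    df = pd.DataFrame(rows, columns=["line", "group", "marker", "allele"])
    write_table(df, path, meta)


def read_genotypes(path) -> LinePanel:
    """Read a genotype table, long (line/group/marker/allele) or wide.

    Wide format: one row per line with a ``group`` column and one column
    per marker; empty cells mark missing genotypes.  Conflicting duplicate
    (line, marker) entries are rejected with their row numbers.
    """
    df, _ = read_table(path)
    if df.empty:
        raise ValueError(f"{path}: empty genotype file")
    cols = set(df.columns)
    if {"line", "marker", "allele"} <= cols:
        n_alleles = df.groupby(["line", "marker"])["allele"].nunique()
        conflicts = n_alleles[n_alleles > 1]
        if len(conflicts):
            key = conflicts.index[0]
            rows = list(
                df.index[(df["line"] == key[0]) & (df["marker"] == key[1])] + 2
            )
            raise ValueError(
                f"{path}: conflicting alleles for line {key[0]!r} marker "
                f"{key[1]!r} at file lines {rows}"
            )
        df = df.drop_duplicates(subset=["line", "marker"])
        if "group" not in cols:
            raise ValueError(f"{path}: long genotype format requires a 'group' column")
        groups = (
            df.drop_duplicates("line").set_index("line")["group"].astype(int)
        )
        wide = df.pivot(index="line", columns="marker", values="allele")
        wide = wide.reindex(sorted(wide.index))
        wide = wide[sorted(wide.columns)]
        return LinePanel(wide, groups.reindex(wide.index))
    if "line" in cols and "group" in cols:
        wide = df.set_index("line")
        groups = wide.pop("group").astype(int)
        return LinePanel(wide, groups)
    raise ValueError(
        f"{path}: unrecognized genotype columns {sorted(cols)[:6]}; expected "
        "long (line, group, marker, allele) or wide (line, group, <markers...>)"
    )


# --------------------------------------------------------------------------
# crosses
# --------------------------------------------------------------------------

def write_crosses(crosses: CrossSet, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(list(crosses), columns=["parent1", "parent2"])
    write_table(df, path, meta)


def read_crosses(path) -> CrossSet:
    df, _ = read_table(path)
    if not {"parent1", "parent2"} <= set(df.columns):
        raise ValueError(f"{path}: cross list requires columns parent1, parent2")
    return CrossSet([(a, b) for a, b in zip(df["parent1"], df["parent2"])])


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(check_phenotypes(pheno), path, meta)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a plot-level phenotype table.

    Expects columns hybrid (parent1×parent2), environment, replicate,
    block, yield.  A missing/empty block column defaults to one block per
    replicate; duplicated plot rows are rejected with their location.
    """
    df, _ = read_table(path)
    if "yield" not in df.columns or "hybrid" not in df.columns:
        raise ValueError(f"{path}: phenotype table requires hybrid and yield columns")
    if "environment" not in df.columns:
        raise ValueError(f"{path}: phenotype table requires an environment column")
    if "replicate" not in df.columns:
        df["replicate"] = "R1"
    if "block" not in df.columns or df["block"].isna().all():
        df["block"] = "B1"
    df["block"] = df["block"].fillna("B1")
    try:
        df["yield"] = pd.to_numeric(df["yield"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric yield value ({exc})") from exc
    # canonicalize hybrid keys, accepting a plain "x" separator
    df["hybrid"] = [hybrid_id(*split_hybrid_id(h)) for h in df["hybrid"]]
    plot_dup = df.duplicated(subset=["hybrid", "environment", "replicate"], keep=False)
    if plot_dup.any():
        where = list(df.index[plot_dup][:5] + 2)
        raise ValueError(f"{path}: duplicated plot rows near lines {where}")
    return check_phenotypes(df)


# --------------------------------------------------------------------------
# truth records
# --------------------------------------------------------------------------

def write_truth(record, path, meta: dict | None = None) -> None:
    """Serialize a simulation TruthRecord to JSON (for recovery checks)."""
    def ser(series):
        if series is None:
            return None
        return {str(k): float(v) for k, v in series.items()}

    payload = {
        "mode": record.mode,
        "seed": record.seed,
        "variances": {
            k: float(v) for k, v in vars(record.variances).items()
        },
        "gca": ser(record.gca),
        "sca": ser(record.sca),
        "additive_effects": ser(record.additive_effects),
        "dominance_effects": ser(record.dominance_effects),
        "hybrid_values": ser(record.hybrid_values),
        "meta": {k: str(v) for k, v in (meta or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
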