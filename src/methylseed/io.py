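"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions:

* β / M matrices: TSV, probes as rows (index column ``probe_id``), samples as
  columns.
* Sample metadata: CSV with a ``sample_id`` column and a ``group`` column
  (values ``control`` / ``case``).  An optional second header line starting
  with ``#types`` declares each factor as ``categorical`` or ``continuous``;
  without it, types are inferred from dtypes.
* Gene sets: GMT (name, description, then member genes, tab-separated).
* Genomic intervals: BED, 0-based half-open, ``chrom  start  end  name``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix (first column = probe IDs)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FMT)


def read_metadata(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a metadata CSV, returning (table indexed by sample_id, factor types).

    The optional ``#types`` line maps column names to ``categorical`` or
    ``continuous``; missing declarations are inferred (numeric dtype ->
    continuous, anything else -> categorical).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        second = fh.readline()
    declared: dict[str, str] = {}
    skiprows: list[int] = []
    if second.startswith("#types"):
        cols = header.rstrip("\n").split(",")
        types = second.rstrip("\n").split(",")
        declared = {c: t for c, t in zip(cols, types[0 : len(cols)]) if t in ("categorical", "continuous")}
        skiprows = [1]
    meta = pd.read_csv(path, skiprows=skiprows).set_index("sample_id")
    ftypes: dict[str, str] = {}
    for col in meta.columns:
        if col == "group":
            continue
        if col in declared:
            ftypes[col] = declared[col]
        else:
            ftypes[col] = "continuous" if pd.api.types.is_numeric_dtype(meta[col]) else "categorical"
    return meta, ftypes


def write_metadata(meta: pd.DataFrame, ftypes: dict[str, str], path: str | Path) -> None:
    cols = ["sample_id"] + list(meta.columns)
    types = [""] + [ftypes.get(c, "") for c in meta.columns]
    lines = [",".join(cols), "#types" + ",".join([""] + types[1:])]
    body = meta.reset_index().rename(columns={meta.index.name or "index": "sample_id"})
    lines += body.astype(str).apply(lambda r: ",".join(r), axis=1).tolist()
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="probe_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED into (chrom, start, end, name), 0-based half-open."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        name = parts[3] if len(parts) > 3 else ""
        rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals.columns else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_probe_list(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
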