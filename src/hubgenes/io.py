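"""Plain-text readers/writers for the formats the pipeline exchanges.

Everything is TSV, GMT or JSON so that inputs and results stay
human-readable and diffable. Matrices carry row/column labels; GMT is
the standard gene-set format (term, description, tab-separated gene
symbols, one term per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

REGION_COLUMNS = ["region_id", "x", "y", "z"]


def read_region_table(path) -> pd.DataFrame:
    """Read a region table TSV (region_id, x, y, z[, class, block])."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region table {path} lacks columns {missing}")
    return df


def write_region_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Square or rectangular labelled matrix TSV (first column = row ids)."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t")


def read_time_series(paths, tr_seconds: float, region_ids=None):
    """Read one regions x timepoints TSV per subject into a TimeSeriesSet."""
    from .connectivity import TimeSeriesSet

    mats, ids = [], None
    for p in paths:
        df = pd.read_csv(p, sep="\t", index_col=0, comment="#")
        if ids is None:
            ids = list(df.index)
        elif list(df.index) != ids:
            raise ValueError(f"{p}: region order differs from first subject")
        mats.append(df.to_numpy(float))
    if region_ids is not None and list(region_ids) != ids:
        raise ValueError("time-series region ids do not match region table")
    return TimeSeriesSet(values=np.stack(mats), tr_seconds=tr_seconds, region_ids=ids)


def write_time_series(ts, directory, prefix="subject") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(ts.values.shape[0]):
        df = pd.DataFrame(ts.values[s], index=ts.region_ids)
        p = directory / f"{prefix}{s:03d}.tsv"
        df.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file into {term: {"description": str, "genes": [..]}}."""
    out: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (needs >=3 fields): {line[:80]!r}")
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"GMT term {term!r} has no genes")
            if len(set(genes)) != len(genes):
                raise ValueError(f"GMT term {term!r} lists duplicate genes")
            out[term] = {"description": desc, "genes": genes}
    if not out:
        raise ValueError(f"GMT file {path} is empty")
    return out


def write_gmt(annotation: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for term, rec in annotation.items():
            fh.write("\t".join([term, rec.get("description", "")] + list(rec["genes"])) + "\n")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
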