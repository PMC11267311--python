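"""Readers and writers for the pipeline's plain-text exchange formats.

MTX triplets live on :class:`~gbotools.matrix.CountMatrix`; SWC on
:class:`~gbotools.morphometry.Skeleton`. This module covers the rest: GMT
gene-set collections, genes-by-columns TSV matrices, trace CSVs with a YAML
metadata sidecar, and YAML configs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import TraceSet


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name] + sorted(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Genes-by-columns TSV with header row and gene IDs in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_points_csv(path: str | Path) -> np.ndarray:
    """Point cloud CSV with x,y,z columns (header optional)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if {"x", "y", "z"} <= set(cols):
        df.columns = cols
        return df[["x", "y", "z"]].to_numpy(dtype=float)
    return pd.read_csv(path, header=None).to_numpy(dtype=float)[:, :3]


def write_points_csv(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_traces(csv_path: str | Path, meta_path: str | Path) -> TraceSet:
    """Trace CSV (column ``time`` then one column per cell) + YAML sidecar.

    The sidecar provides ``stimulus_time`` and optionally a ``groups``
    mapping of cell name -> treatment label.
    """
    df = pd.read_csv(csv_path)
    meta = yaml.safe_load(Path(meta_path).read_text())
    cells = [c for c in df.columns if c != "time"]
    groups = meta.get("groups", {})
    return TraceSet(
        times=df["time"].to_numpy(dtype=float),
        F=df[cells].to_numpy(dtype=float).T,
        stimulus_time=float(meta["stimulus_time"]),
        cells=np.array(cells, dtype=object),
        groups=np.array([groups.get(c, "CONT") for c in cells], dtype=object),
    )


def write_traces(trace_set: TraceSet, csv_path: str | Path, meta_path: str | Path) -> None:
    df = pd.DataFrame({"time": trace_set.times})
    for i, c in enumerate(trace_set.cells):
        df[str(c)] = trace_set.F[i]
    df.to_csv(csv_path, index=False)
    meta = {
        "stimulus_time": float(trace_set.stimulus_time),
        "groups": {str(c): str(g) for c, g in zip(trace_set.cells, trace_set.groups)},
    }
    Path(meta_path).write_text(yaml.safe_dump(meta))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
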