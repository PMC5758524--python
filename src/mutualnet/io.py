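"""Readers and writers: edge lists, adjacency matrices, Pajek, GraphML.

The native tabular format is a delimited edge list with a mandatory header
and columns ``layer, plant, bird[, weight]``; ``#`` lines are comments.
Layer values are matched case-insensitively.  Both tabular formats
round-trip: read -> build -> write -> read reproduces the network exactly.
All exports order species lexicographically so output is deterministic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import LAYER_KINDS, LayerMatrix, MutualismNetwork, build_network, union_graph

__all__ = [
    "EdgeListDialect",
    "EdgeRecord",
    "read_edge_list",
    "read_network",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "write_pajek",
    "write_graphml",
    "write_report",
]


@dataclass
class EdgeListDialect:
    """Column layout of an edge-list file.

    The column-mapping fields allow permissive import of third-party
    tables whose headers differ from the native ``layer/plant/bird/weight``.
    """

    delimiter: str = ","
    comment_prefix: str = "#"
    layer_col: str = "layer"
    plant_col: str = "plant"
    bird_col: str = "bird"
    weight_col: str = "weight"


@dataclass
class EdgeRecord:
    layer: str
    plant: str
    bird: str
    weight: float | None = None
    line_no: int | None = None

    def as_tuple(self):
        if self.weight is None:
            return (self.layer, self.plant, self.bird)
        return (self.layer, self.plant, self.bird, self.weight)


def read_edge_list(path, dialect: EdgeListDialect | None = None) -> list[EdgeRecord]:
    """Parse and validate an edge-list file; errors name the offending line."""
    dialect = dialect or EdgeListDialect()
    path = Path(path)
    records: list[EdgeRecord] = []
    with path.open(newline="") as fh:
        header: list[str] | None = None
        idx: dict[str, int] = {}
        has_weight = False
        for line_no, row in enumerate(csv.reader(fh, delimiter=dialect.delimiter), start=1):
            if not row or (row[0].strip().startswith(dialect.comment_prefix)):
                continue
            if header is None:
                header = [c.strip().casefold() for c in row]
                for col in (dialect.layer_col, dialect.plant_col, dialect.bird_col):
                    if col.casefold() not in header:
                        raise ValueError(f"{path}: missing required column {col!r}")
                    idx[col] = header.index(col.casefold())
                has_weight = dialect.weight_col.casefold() in header
                if has_weight:
                    idx[dialect.weight_col] = header.index(dialect.weight_col.casefold())
                continue
            layer = row[idx[dialect.layer_col]].strip().casefold()
            if layer not in LAYER_KINDS:
                raise ValueError(f"{path}:{line_no}: bad layer value {layer!r}")
            plant = row[idx[dialect.plant_col]].strip()
            bird = row[idx[dialect.bird_col]].strip()
            if not plant or not bird:
                raise ValueError(f"{path}:{line_no}: empty species name")
            weight = None
            if has_weight:
                raw = row[idx[dialect.weight_col]].strip()
                if raw:
                    try:
                        weight = float(raw)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{line_no}: non-numeric weight {raw!r}"
                        ) from None
            records.append(EdgeRecord(layer, plant, bird, weight, line_no))
        if header is None:
            raise ValueError(f"{path}: empty file (header is mandatory)")
    return records


def read_network(path, dialect: EdgeListDialect | None = None) -> MutualismNetwork:
    """Read an edge-list file straight into a network."""
    return build_network([r.as_tuple() for r in read_edge_list(path, dialect)])


def write_edge_list(net: MutualismNetwork, path, dialect: EdgeListDialect | None = None) -> None:
    dialect = dialect or EdgeListDialect()
    path = Path(path)
    any_weight = any(net.layer(k).weight is not None for k in LAYER_KINDS)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=dialect.delimiter)
        head = [dialect.layer_col, dialect.plant_col, dialect.bird_col]
        if any_weight:
            head.append(dialect.weight_col)
        w.writerow(head)
        for kind in LAYER_KINDS:
            lay = net.layer(kind)
            for i, p in enumerate(lay.plants):
                for j, b in enumerate(lay.birds):
                    if not lay.presence[i, j]:
                        continue
                    row = [kind, p, b]
                    if any_weight:
                        row.append(
                            repr(float(lay.weight[i, j])) if lay.weight is not None else ""
                        )
                    w.writerow(row)


def write_adjacency(layer: LayerMatrix, path, weighted: bool = False) -> None:
    """One layer as a plants x birds CSV (header row of bird names)."""
    mat = layer.weight if (weighted and layer.weight is not None) else layer.presence
    pd.DataFrame(mat, index=layer.plants, columns=layer.birds).to_csv(Path(path))


def read_adjacency(path, layer_kind: str) -> LayerMatrix:
    df = pd.read_csv(Path(path), index_col=0)
    values = df.to_numpy()
    presence = (values > 0).astype(np.int8)
    weight = None
    if not np.array_equal(values, presence):
        weight = values.astype(float)
    return LayerMatrix(
        layer_kind, [str(i) for i in df.index], [str(c) for c in df.columns], presence, weight
    )


def write_pajek(net: MutualismNetwork, path) -> None:
    """Union graph in Pajek .net format: all species as vertices, then edges."""
    g = union_graph(net)
    nx.write_pajek(g, Path(path))


def write_graphml(net: MutualismNetwork, path) -> None:
    g = union_graph(net)
    nx.write_graphml(g, Path(path))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_report(report: dict, path) -> None:
    """Flat machine-readable summary (JSON) of metrics, seeds and settings."""
    Path(path).write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")


def write_null_counts(counts, path) -> None:
    """Null distribution as one-column numeric text for external inspection."""
    np.savetxt(Path(path), np.asarray(counts), fmt="%d")
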