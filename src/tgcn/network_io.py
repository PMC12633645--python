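"""Text serialization of temporal networks.

Three interchange forms, all UTF-8 with LF line endings:

* per-snapshot CSV edge lists with the header ``source,target,pvalue`` —
  the dialect Cytoscape's table import consumes.  P-values are printed
  with six decimals; anything below 1e-6 is floored to the string
  ``"0.0"`` (an annotation convention only — the in-memory value keeps
  full precision);
* per-snapshot plain-text adjacency lists (``node: neighbor1 neighbor2``),
  with every node present, isolated ones included;
* a single JSON sidecar (``tgcn.json``) carrying nodes, alpha and full-
  precision per-snapshot edge arrays for lossless programmatic round-trip.

Rows are emitted sorted, so identical networks serialize byte-identically.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Sequence

from .errors import ConfigurationError, FormatError, IntegrityError
from .genes import GeneRecord
from .model import (
    AgeGroup,
    Edge,
    Snapshot,
    TemporalNetwork,
    canonical_pair,
    make_temporal_network,
)

__all__ = [
    "EDGE_LIST_HEADER",
    "P_VALUE_FLOOR",
    "export_adjacency_lists",
    "export_edge_lists",
    "format_p_value",
    "import_edge_lists",
    "read_json",
    "write_json",
]

EDGE_LIST_HEADER = ("source", "target", "pvalue")

#: P-values below this are printed as the literal string "0.0".
P_VALUE_FLOOR = 1e-6

_EDGE_FILE_RE = re.compile(r"snapshot_(\d+)_(\d{2}-\d{2})\.csv$")


def format_p_value(p: float) -> str:
    """Fixed-precision p-value string with the sub-1e-6 floor."""
    return "0.0" if p < P_VALUE_FLOOR else f"{p:.6f}"


def _edge_list_name(snapshot: Snapshot) -> str:
    age = snapshot.time_point
    return f"snapshot_{age.index}_{age.label}.csv"


def _identifier_map(
    tn: TemporalNetwork, id_mode: str, records: Sequence[GeneRecord] | None
) -> dict[str, str]:
    if id_mode == "canonical_id":
        return {node: node for node in tn.nodes}
    if id_mode != "symbol":
        raise ConfigurationError(
            f"id_mode must be 'symbol' or 'canonical_id', got {id_mode!r}"
        )
    if records is None:
        raise ConfigurationError("id_mode='symbol' requires gene records")
    mapping: dict[str, str] = {}
    for rec in records:
        # nodes may be labelled by versioned/unversioned ID or by symbol
        mapping[rec.canonical_id] = rec.symbol
        mapping[rec.canonical_id.split(".", 1)[0]] = rec.symbol
        mapping[rec.symbol] = rec.symbol
    missing = [node for node in tn.nodes if node not in mapping]
    if missing:
        raise ConfigurationError(f"no symbol known for node(s): {missing}")
    return mapping


def export_edge_lists(
    tn: TemporalNetwork,
    out_dir: str | Path,
    id_mode: str = "canonical_id",
    records: Sequence[GeneRecord] | None = None,
) -> list[Path]:
    """Write one ``snapshot_<index>_<agegroup>.csv`` per snapshot.

    Empty snapshots produce a header-only file, keeping the file count
    equal to the number of time points.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    id_map = _identifier_map(tn, id_mode, records)
    paths: list[Path] = []
    for snapshot in tn:
        path = out_dir / _edge_list_name(snapshot)
        rows = []
        for edge in snapshot.edges.values():
            source, target = canonical_pair(id_map[edge.gene_i], id_map[edge.gene_j])
            rows.append((source, target, format_p_value(edge.p)))
        rows.sort(key=lambda row: (row[0], row[1]))
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(",".join(EDGE_LIST_HEADER) + "\n")
            for row in rows:
                handle.write(",".join(row) + "\n")
        paths.append(path)
    return paths


def export_adjacency_lists(tn: TemporalNetwork, out_dir: str | Path) -> list[Path]:
    """Write one ``snapshot_<index>_<agegroup>.adjlist`` per snapshot.

    Line format ``node: neighbor1 neighbor2 ...``; every node appears, and
    the listing is symmetric because the graph is undirected.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for snapshot in tn:
        age = snapshot.time_point
        path = out_dir / f"snapshot_{age.index}_{age.label}.adjlist"
        graph = snapshot.to_graph()
        with open(path, "w", encoding="utf-8", newline="\n") as handle:
            for node in sorted(snapshot.nodes):
                neighbors = sorted(graph.neighbors(node))
                line = f"{node}: {' '.join(neighbors)}" if neighbors else f"{node}:"
                handle.write(line + "\n")
        paths.append(path)
    return paths


def import_edge_lists(
    paths: Sequence[str | Path],
    nodes: Sequence[str],
    alpha: float,
) -> TemporalNetwork:
    """Rebuild a temporal network from exported edge-list files.

    The age group is recovered from the ``snapshot_<index>_<agegroup>.csv``
    filename pattern.  Correlation coefficients are not part of the edge-
    list dialect, so imported edges carry ``r=None``; p-values are exact up
    to the 6-decimal printing precision (and the sub-1e-6 floor).
    """
    node_tuple = tuple(nodes)
    node_set = set(node_tuple)
    snapshots: list[Snapshot] = []
    for raw_path in paths:
        path = Path(raw_path)
        match = _EDGE_FILE_RE.search(path.name)
        if match is None:
            raise FormatError(
                f"cannot recover the age group from filename {path.name!r}; "
                "expected snapshot_<index>_<agegroup>.csv"
            )
        age = AgeGroup.from_label(match.group(2))
        with open(path, "r", encoding="utf-8", newline="") as handle:
            reader = csv.reader(handle)
            try:
                header = next(reader)
            except StopIteration:
                raise FormatError(f"edge-list file {path} is empty") from None
            if tuple(header) != EDGE_LIST_HEADER:
                raise FormatError(
                    f"bad edge-list header {header!r} in {path}; "
                    f"expected {','.join(EDGE_LIST_HEADER)}"
                )
            edges: list[Edge] = []
            for line_no, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 3:
                    raise FormatError(
                        f"malformed row at {path}:{line_no}: {row!r}"
                    )
                source, target, p_text = row
                for endpoint in (source, target):
                    if endpoint not in node_set:
                        raise IntegrityError(
                            f"edge endpoint {endpoint!r} at {path}:{line_no} "
                            "is outside the declared node set"
                        )
                try:
                    p = float(p_text)
                except ValueError:
                    raise FormatError(
                        f"non-numeric p-value {p_text!r} at {path}:{line_no}"
                    ) from None
                gene_i, gene_j = canonical_pair(source, target)
                edges.append(Edge(gene_i, gene_j, p=p))
        snapshots.append(Snapshot(age, node_tuple, edges))
    return make_temporal_network(node_tuple, snapshots, alpha)


def write_json(tn: TemporalNetwork, path: str | Path) -> Path:
    """Write the lossless JSON sidecar (full-precision r and p)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(to_json_dict(tn), handle, indent=2)
        handle.write("\n")
    return path


def to_json_dict(tn: TemporalNetwork) -> dict:
    """Sidecar schema as a plain dict (also the HTTP facade's payload)."""
    return {
        "nodes": list(tn.nodes),
        "alpha": tn.alpha,
        "age_groups": [snap.time_point.label for snap in tn],
        "snapshots": [
            {
                "age_group": snap.time_point.label,
                "edges": [
                    [e.gene_i, e.gene_j, e.r, e.p]
                    for e in sorted(snap.edges.values(), key=lambda e: e.pair)
                ],
            }
            for snap in tn
        ],
    }


def read_json(path: str | Path) -> TemporalNetwork:
    """Rebuild a temporal network from its JSON sidecar."""
    with open(path, "r", encoding="utf-8") as handle:
        payload = json.load(handle)
    return from_json_dict(payload)


def from_json_dict(payload: dict) -> TemporalNetwork:
    try:
        nodes = tuple(payload["nodes"])
        alpha = float(payload["alpha"])
        snapshots = [
            Snapshot(
                AgeGroup.from_label(entry["age_group"]),
                nodes,
                [
                    Edge(gene_i, gene_j, p=p, r=r)
                    for gene_i, gene_j, r, p in entry["edges"]
                ],
            )
            for entry in payload["snapshots"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed temporal-network JSON: {exc}") from exc
    return make_temporal_network(nodes, snapshots, alpha)
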