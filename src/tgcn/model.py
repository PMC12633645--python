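"""Snapshot-based temporal network model.

A temporal gene co-expression network (TGCN) is represented as an ordered
sequence of static graphs ("snapshots"), one per time point, over a single
immutable node set.  Time points are the six decade-wide donor age groups
used by GTEx (20-29 through 70-79 years); the snapshot at age group *a*
contains an edge between two genes exactly when their expression was
significantly correlated within that age group.

The classes here enforce the structural rules of that representation:

* node-set immutability — every snapshot carries the same node set;
* canonical edge orientation — each unordered gene pair is stored once,
  with endpoints in lexicographic order;
* temporal ordering — snapshots are sorted by age-group index.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import networkx as nx

from .errors import GeneLookupError, IntegrityError

__all__ = [
    "AGE_GROUP_LABELS",
    "AgeGroup",
    "Edge",
    "Snapshot",
    "TemporalNetwork",
    "canonical_pair",
    "contact_of",
    "make_temporal_network",
]

#: The six canonical donor age groups, in temporal order (unit: years).
AGE_GROUP_LABELS: tuple[str, ...] = (
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
)

# Tolerance applied when re-validating the "p < alpha" snapshot invariant on
# networks that passed through a 6-decimal text serialization.
_P_SERIALIZATION_TOL = 1e-6


@dataclass(frozen=True)
class AgeGroup:
    """One decade-wide donor age group acting as a time point.

    Parameters
    ----------
    label:
        Hyphenated ASCII label, one of :data:`AGE_GROUP_LABELS`.
    """

    label: str

    def __post_init__(self) -> None:
        if self.label not in AGE_GROUP_LABELS:
            raise IntegrityError(
                f"unknown age-group label {self.label!r}; "
                f"expected one of {AGE_GROUP_LABELS}"
            )

    @property
    def index(self) -> int:
        """Temporal position, 0 (20-29) through 5 (70-79)."""
        return AGE_GROUP_LABELS.index(self.label)

    @classmethod
    def from_label(cls, raw: str) -> "AgeGroup":
        """Build an AgeGroup from a loosely formatted label.

        Accepts en/em dashes, surrounding brackets and stray whitespace,
        e.g. ``"[20–29]"`` normalizes to ``"20-29"``.
        """
        label = (
            raw.strip()
            .strip("[]")
            .replace("–", "-")
            .replace("—", "-")
            .replace(" ", "")
        )
        return cls(label)

    @classmethod
    def is_canonical(cls, raw: str) -> bool:
        """True if ``raw`` normalizes to one of the six canonical labels."""
        try:
            cls.from_label(raw)
        except IntegrityError:
            return False
        return True

    def __lt__(self, other: "AgeGroup") -> bool:
        return self.index < other.index

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered pair in canonical (lexicographic) orientation."""
    if gene_a == gene_b:
        raise IntegrityError(f"self-pair {gene_a!r} is not a valid gene pair")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class Edge:
    """A significant co-expression edge within one snapshot.

    ``r`` is the Pearson correlation coefficient; it may be ``None`` for
    edges reconstructed from an edge-list file, which carries only p-values.
    """

    gene_i: str
    gene_j: str
    p: float
    r: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_i < self.gene_j:
            raise IntegrityError(
                f"edge ({self.gene_i!r}, {self.gene_j!r}) is not in "
                "canonical order (gene_i < gene_j)"
            )
        if not 0.0 <= self.p <= 1.0:
            raise IntegrityError(f"edge p-value {self.p} outside [0, 1]")
        if self.r is not None and not -1.0 <= self.r <= 1.0:
            raise IntegrityError(f"edge correlation {self.r} outside [-1, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_i, self.gene_j)


class Snapshot:
    """The static co-expression network observed at one age group.

    Nodes are canonical gene identifiers; the node set always includes
    isolated genes, because the temporal model keeps the node set fixed
    across time points even when an age group contributes no edges.
    """

    def __init__(
        self,
        time_point: AgeGroup,
        nodes: Sequence[str],
        edges: Iterable[Edge] = (),
    ) -> None:
        if len(set(nodes)) != len(nodes):
            raise IntegrityError("snapshot node list contains duplicates")
        self._time_point = time_point
        self._nodes = tuple(nodes)
        node_set = set(self._nodes)
        edge_map: dict[tuple[str, str], Edge] = {}
        for edge in edges:
            for endpoint in edge.pair:
                if endpoint not in node_set:
                    raise IntegrityError(
                        f"edge endpoint {endpoint!r} not in snapshot node set "
                        f"(age group {time_point.label})"
                    )
            if edge.pair in edge_map:
                raise IntegrityError(
                    f"duplicate edge {edge.pair} in snapshot {time_point.label}"
                )
            edge_map[edge.pair] = edge
        self._edges: Mapping[tuple[str, str], Edge] = MappingProxyType(edge_map)

    @property
    def time_point(self) -> AgeGroup:
        return self._time_point

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> Mapping[tuple[str, str], Edge]:
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def has_edge(self, gene_a: str, gene_b: str) -> bool:
        return canonical_pair(gene_a, gene_b) in self._edges

    def edge(self, gene_a: str, gene_b: str) -> Edge | None:
        return self._edges.get(canonical_pair(gene_a, gene_b))

    def to_graph(self) -> nx.Graph:
        """Export as a networkx Graph with ``p``/``r`` edge attributes."""
        graph = nx.Graph(time_point=self._time_point.label)
        graph.add_nodes_from(self._nodes)
        for edge in self._edges.values():
            graph.add_edge(edge.gene_i, edge.gene_j, p=edge.p, r=edge.r)
        return graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Snapshot({self._time_point.label}, "
            f"{len(self._nodes)} nodes, {self.n_edges} edges)"
        )


class Contact(NamedTuple):
    """Presence of a gene pair at one time point (one row of a contact)."""

    age_group: AgeGroup
    present: bool
    p: float | None


class TemporalNetwork:
    """An ordered snapshot sequence over a fixed gene set.

    Construct through :func:`make_temporal_network`, which validates the
    model invariants and sorts snapshots temporally.
    """

    def __init__(
        self,
        nodes: tuple[str, ...],
        snapshots: tuple[Snapshot, ...],
        alpha: float,
    ) -> None:
        self._nodes = nodes
        self._snapshots = snapshots
        self._alpha = alpha

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def snapshots(self) -> tuple[Snapshot, ...]:
        return self._snapshots

    @property
    def alpha(self) -> float:
        return self._alpha

    @property
    def n_edges(self) -> int:
        """Total edge count over all snapshots."""
        return sum(s.n_edges for s in self._snapshots)

    def snapshot_at(self, label: str) -> Snapshot:
        age = AgeGroup.from_label(label)
        for snap in self._snapshots:
            if snap.time_point == age:
                return snap
        raise GeneLookupError(f"no snapshot for age group {label!r}")

    def contact_of(self, gene_i: str, gene_j: str) -> list[Contact]:
        return contact_of(self, gene_i, gene_j)

    def to_graphs(self) -> list[nx.Graph]:
        """Snapshot sequence as a list of networkx graphs, temporal order."""
        return [snap.to_graph() for snap in self._snapshots]

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self._snapshots)

    def __len__(self) -> int:
        return len(self._snapshots)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"TemporalNetwork({len(self._nodes)} nodes, "
            f"{len(self._snapshots)} snapshots, alpha={self._alpha})"
        )


def make_temporal_network(
    nodes: Sequence[str],
    snapshots: Iterable[Snapshot],
    alpha: float,
) -> TemporalNetwork:
    """Assemble and validate a temporal network from snapshots.

    Snapshots may arrive in any order; they are stored ascending by
    age-group index.  Raises :class:`IntegrityError` when a snapshot's node
    set differs from ``nodes``, when two snapshots share an age group, or
    when a retained edge does not satisfy ``p < alpha`` (up to the
    6-decimal tolerance used by the text exporters).
    """
    snaps = list(snapshots)
    if not snaps:
        raise IntegrityError("a temporal network requires at least one snapshot")
    node_tuple = tuple(nodes)
    if len(set(node_tuple)) != len(node_tuple):
        raise IntegrityError("temporal-network node list contains duplicates")
    node_set = set(node_tuple)

    seen: set[str] = set()
    for snap in snaps:
        label = snap.time_point.label
        if label in seen:
            raise IntegrityError(f"duplicate snapshot for age group {label!r}")
        seen.add(label)
        if set(snap.nodes) != node_set:
            raise IntegrityError(
                f"snapshot {label!r} node set {sorted(snap.nodes)} does not "
                f"match network node set {sorted(node_set)}"
            )
        for edge in snap.edges.values():
            if not edge.p < alpha + _P_SERIALIZATION_TOL:
                raise IntegrityError(
                    f"snapshot {label!r} retains edge {edge.pair} with "
                    f"p={edge.p} >= alpha={alpha}"
                )

    snaps.sort(key=lambda s: s.time_point.index)
    return TemporalNetwork(node_tuple, tuple(snaps), alpha)


def contact_of(
    tn: TemporalNetwork, gene_i: str, gene_j: str
) -> list[Contact]:
    """Time-resolved presence of the unordered pair ``{gene_i, gene_j}``.

    Returns one :class:`Contact` per snapshot in temporal order; argument
    order is irrelevant.  ``p`` is ``None`` where the pair is absent.
    """
    for gene in (gene_i, gene_j):
        if gene not in tn.nodes:
            raise GeneLookupError(f"gene {gene!r} not in temporal network")
    out: list[Contact] = []
    for snap in tn:
        edge = snap.edge(gene_i, gene_j)
        out.append(
            Contact(snap.time_point, edge is not None, None if edge is None else edge.p)
        )
    return out
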