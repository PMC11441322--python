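"""SPOKE-style property graph: typed nodes, attributed edges, filtered neighborhoods.

The graph holds biomedical concepts (Disease, Gene, Protein, Compound, ...)
as nodes and schema-named predicates as directed edges.  Edges carry the
attributes needed for high-quality context retrieval: provenance (the source
databases asserting the edge), optional statistical evidence (p-value and/or
z-score), the clinical phase of treatment associations, and a source type
that distinguishes curated from text-mined assertions.

``neighborhood`` is the retrieval primitive: all edges incident to a node,
in either direction, surviving a quality filter whose defaults keep only
phase >= 3 treatment edges, SwissProt-curated protein neighbors, and
non-text-mined disease-gene associations.
"""

from __future__ import annotations

import csv
import io
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, Iterator, List, Mapping, Optional, Tuple, Union

from ._text import norm_key
from .errors import GraphLoadError, UnknownNodeError
from .verbalize import parse_predicate

NODE_COLUMNS = ("node_id", "node_type", "name", "identifier", "attributes")
EDGE_COLUMNS = (
    "subject_id",
    "predicate",
    "object_id",
    "provenance",
    "evidence",
    "clinical_phase",
    "source_type",
)


@dataclass(frozen=True)
class NodeRecord:
    """One graph node: an identified, typed biomedical concept."""

    node_id: str
    node_type: str
    name: str
    identifier: str = ""
    attributes: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class EdgeRecord:
    """One directed edge with retrieval-relevant attributes.

    ``evidence`` maps ``p_value`` and/or ``z_score`` to floats;
    ``clinical_phase`` is only present on treatment associations;
    ``source_type`` is e.g. ``"curated"`` or ``"textmining"``.
    """

    subject_id: str
    object_id: str
    predicate: str
    provenance: Tuple[str, ...] = ()
    evidence: Optional[Mapping[str, float]] = None
    clinical_phase: Optional[int] = None
    source_type: Optional[str] = None


@dataclass(frozen=True)
class ContextFilter:
    """Edge-quality filter applied when fetching a node neighborhood.

    Defaults reproduce the curation rules used for disease context:
    treatment edges need clinical phase >= 3, protein neighbors must be
    curated, and text-mined disease-gene associations are excluded.
    Setting ``min_clinical_phase=0`` and both booleans to ``False`` yields
    a fully permissive filter.
    """

    min_clinical_phase: int = 3
    require_curated_protein: bool = True
    exclude_textmining_disease_gene: bool = True


#: Filter that keeps every incident edge.
PERMISSIVE_FILTER = ContextFilter(
    min_clinical_phase=0,
    require_curated_protein=False,
    exclude_textmining_disease_gene=False,
)


@dataclass(frozen=True)
class AttributedTriple:
    """A (subject, predicate, object) edge with its attributes resolved to
    node records.  Direction is preserved exactly as stored."""

    subject: NodeRecord
    predicate: str
    object: NodeRecord
    provenance: Tuple[str, ...] = ()
    evidence: Optional[Mapping[str, float]] = None


class PropertyGraph:
    """In-memory property graph with by-type and by-name indexes.

    Validates on construction: unique node ids, non-empty types/names,
    edge endpoints resolving to existing nodes, and predicates that parse
    under the schema with type initials matching the endpoint node types.
    """

    def __init__(self, nodes: Iterable[NodeRecord], edges: Iterable[EdgeRecord]):
        self._nodes: Dict[str, NodeRecord] = {}
        self._by_type: Dict[str, List[str]] = defaultdict(list)
        self._by_type_name: Dict[Tuple[str, str], List[str]] = defaultdict(list)
        for node in nodes:
            if node.node_id in self._nodes:
                raise GraphLoadError(f"duplicate node_id {node.node_id!r}")
            if not node.node_type:
                raise GraphLoadError(f"node {node.node_id!r} has empty node_type")
            if not node.name:
                raise GraphLoadError(f"node {node.node_id!r} has empty name")
            self._nodes[node.node_id] = node
            self._by_type[node.node_type].append(node.node_id)
            self._by_type_name[(node.node_type, norm_key(node.name))].append(
                node.node_id
            )

        self._edges: List[EdgeRecord] = []
        self._incident: Dict[str, List[int]] = defaultdict(list)
        for edge in edges:
            self._validate_edge(edge)
            idx = len(self._edges)
            self._edges.append(edge)
            self._incident[edge.subject_id].append(idx)
            if edge.object_id != edge.subject_id:
                self._incident[edge.object_id].append(idx)

    def _validate_edge(self, edge: EdgeRecord) -> None:
        for endpoint in (edge.subject_id, edge.object_id):
            if endpoint not in self._nodes:
                raise GraphLoadError(
                    f"edge ({edge.subject_id!r}, {edge.predicate!r}, "
                    f"{edge.object_id!r}) references unknown node {endpoint!r}"
                )
        try:
            parts = parse_predicate(edge.predicate)
        except Exception as exc:
            raise GraphLoadError(
                f"edge ({edge.subject_id!r}, {edge.predicate!r}, "
                f"{edge.object_id!r}): {exc}"
            ) from exc
        subject = self._nodes[edge.subject_id]
        obj = self._nodes[edge.object_id]
        if parts.subject_initial != subject.node_type[0].upper():
            raise GraphLoadError(
                f"edge predicate {edge.predicate!r}: subject initial "
                f"{parts.subject_initial!r} does not match node type "
                f"{subject.node_type!r}"
            )
        if parts.object_initial != obj.node_type[0].upper():
            raise GraphLoadError(
                f"edge predicate {edge.predicate!r}: object initial "
                f"{parts.object_initial!r} does not match node type "
                f"{obj.node_type!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> Tuple[NodeRecord, ...]:
        return tuple(self._nodes.values())

    @property
    def edges(self) -> Tuple[EdgeRecord, ...]:
        return tuple(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, node_id: str) -> NodeRecord:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"unknown node id {node_id!r}") from None

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def nodes_of_type(self, node_type: str) -> List[NodeRecord]:
        return [self._nodes[i] for i in self._by_type.get(node_type, [])]

    def incident_edges(self, node_id: str) -> List[EdgeRecord]:
        if node_id not in self._nodes:
            raise UnknownNodeError(f"unknown node id {node_id!r}")
        return [self._edges[i] for i in self._incident.get(node_id, [])]

    def triple(self, edge: EdgeRecord) -> AttributedTriple:
        return AttributedTriple(
            subject=self._nodes[edge.subject_id],
            predicate=edge.predicate,
            object=self._nodes[edge.object_id],
            provenance=edge.provenance,
            evidence=edge.evidence,
        )

    def _name_lookup(self, node_type: str, name: str) -> List[str]:
        return self._by_type_name.get((node_type, norm_key(name)), [])


def find_nodes_by_name(
    graph: PropertyGraph, node_type: str, name: str
) -> List[NodeRecord]:
    """Case-insensitive exact-name lookup, in deterministic id order.

    Unknown node types simply yield an empty list.
    """
    ids = sorted(graph._name_lookup(node_type, name))
    return [graph.node(i) for i in ids]


def _neighbor(graph: PropertyGraph, edge: EdgeRecord, node_id: str) -> NodeRecord:
    other = edge.object_id if edge.subject_id == node_id else edge.subject_id
    return graph.node(other)


def _survives(
    graph: PropertyGraph,
    edge: EdgeRecord,
    node_id: str,
    context_filter: ContextFilter,
) -> bool:
    if (
        edge.clinical_phase is not None
        and edge.clinical_phase < context_filter.min_clinical_phase
    ):
        return False
    neighbor = _neighbor(graph, edge, node_id)
    if (
        context_filter.require_curated_protein
        and neighbor.node_type.casefold() == "protein"
        and not neighbor.attributes.get("curated", False)
    ):
        return False
    if context_filter.exclude_textmining_disease_gene:
        types = {
            graph.node(edge.subject_id).node_type.casefold(),
            graph.node(edge.object_id).node_type.casefold(),
        }
        if types == {"disease", "gene"} and edge.source_type == "textmining":
            return False
    return True


def neighborhood(
    graph: PropertyGraph,
    node_id: str,
    context_filter: Optional[ContextFilter] = None,
) -> List[AttributedTriple]:
    """Filtered one-hop neighborhood of a node as attributed triples.

    Incident edges in both directions are returned without reorientation
    (the stored subject/object roles are what verbalization needs), ordered
    deterministically by predicate and then neighbor id.
    """
    if context_filter is None:
        context_filter = ContextFilter()
    if not graph.has_node(node_id):
        raise UnknownNodeError(f"unknown node id {node_id!r}")
    keep = [
        edge
        for edge in graph.incident_edges(node_id)
        if _survives(graph, edge, node_id, context_filter)
    ]
    keep.sort(
        key=lambda e: (
            e.predicate,
            e.object_id if e.subject_id == node_id else e.subject_id,
        )
    )
    return [graph.triple(e) for e in keep]


# -- loading and serialization --------------------------------------------


def _iter_rows(source: Any, columns: Tuple[str, ...]) -> Iterator[Dict[str, str]]:
    """Yield dict rows from a TSV (with header) or JSONL path/stream."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from _iter_rows(handle, columns)
        return
    if isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        lines = [line.rstrip("\n") for line in source]
    else:
        lines = [str(line).rstrip("\n") for line in source]
    lines = [line for line in lines if line.strip()]
    if not lines:
        return
    if lines[0].lstrip().startswith("{"):
        for line in lines:
            obj = json.loads(line)
            yield {col: obj.get(col, "") for col in columns}
    else:
        reader = csv.DictReader(lines, delimiter="\t")
        missing = set(columns) - set(reader.fieldnames or ())
        if missing:
            raise GraphLoadError(
                f"missing columns {sorted(missing)} in tabular source"
            )
        for row in reader:
            yield {col: row.get(col) or "" for col in columns}


def _parse_json_field(value: Any, default: Any) -> Any:
    if value is None or value == "":
        return default
    if isinstance(value, str):
        return json.loads(value)
    return value


def load_graph(nodes_source: Any, edges_source: Any) -> PropertyGraph:
    """Load and validate a property graph from node/edge tables.

    Each source may be a path, an open text stream, or an iterable of
    lines, in either TSV (with a header row) or JSONL form.  Column
    schemas are ``NODE_COLUMNS`` and ``EDGE_COLUMNS``; ``attributes``,
    ``provenance`` and ``evidence`` are JSON-encoded in tabular form.

    Raises :class:`GraphLoadError` naming the offending id for duplicate
    nodes, dangling edge endpoints, or malformed predicates.
    """
    nodes = []
    for row in _iter_rows(nodes_source, NODE_COLUMNS):
        try:
            attributes = _parse_json_field(row["attributes"], {})
        except json.JSONDecodeError as exc:
            raise GraphLoadError(
                f"node {row['node_id']!r}: bad attributes JSON: {exc}"
            ) from exc
        nodes.append(
            NodeRecord(
                node_id=row["node_id"],
                node_type=row["node_type"],
                name=row["name"],
                identifier=row["identifier"],
                attributes=attributes,
            )
        )

    edges = []
    for row in _iter_rows(edges_source, EDGE_COLUMNS):
        try:
            provenance = tuple(_parse_json_field(row["provenance"], []))
            evidence = _parse_json_field(row["evidence"], None)
        except json.JSONDecodeError as exc:
            raise GraphLoadError(
                f"edge ({row['subject_id']!r}, {row['predicate']!r}, "
                f"{row['object_id']!r}): bad JSON field: {exc}"
            ) from exc
        phase = row["clinical_phase"]
        clinical_phase = None if phase in (None, "") else int(phase)
        source_type = row["source_type"] or None
        edges.append(
            EdgeRecord(
                subject_id=row["subject_id"],
                object_id=row["object_id"],
                predicate=row["predicate"],
                provenance=provenance,
                evidence=evidence,
                clinical_phase=clinical_phase,
                source_type=source_type,
            )
        )

    return PropertyGraph(nodes, edges)


def save_graph(
    graph: PropertyGraph,
    nodes_path: Union[str, Path],
    edges_path: Union[str, Path],
) -> None:
    """Write a graph back to the TSV form accepted by :func:`load_graph`."""
    with open(nodes_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(NODE_COLUMNS)
        for node in graph.nodes:
            writer.writerow(
                [
                    node.node_id,
                    node.node_type,
                    node.name,
                    node.identifier,
                    json.dumps(dict(node.attributes), sort_keys=True),
                ]
            )
    with open(edges_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EDGE_COLUMNS)
        for edge in graph.edges:
            writer.writerow(
                [
                    edge.subject_id,
                    edge.predicate,
                    edge.object_id,
                    json.dumps(list(edge.provenance)),
                    "" if edge.evidence is None else json.dumps(dict(edge.evidence)),
                    "" if edge.clinical_phase is None else edge.clinical_phase,
                    edge.source_type or "",
                ]
            )
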