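"""Optional thin client for a SPOKE-style neighborhood REST endpoint.

All retrieval logic in this package is backend-agnostic; this adapter
only translates the JSON a ``/api/v1/neighborhood/`` style endpoint
returns into :class:`~kgrag.graph_store.AttributedTriple` objects.  The
attribute names such services use for provenance and evidence vary, so
the mapping is configuration (``field_map``) rather than hard-coded.

Network access is never required by the rest of the package; the pure
translation function :func:`triples_from_response` is unit-testable
offline.
"""

from __future__ import annotations

import json
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping

from .graph_store import AttributedTriple, NodeRecord

#: Default JSON field names; override per deployment.
DEFAULT_FIELD_MAP: Dict[str, str] = {
    "nodes": "nodes",
    "edges": "edges",
    "node_id": "id",
    "node_type": "type",
    "node_name": "name",
    "subject_id": "source",
    "object_id": "target",
    "predicate": "type",
    "provenance": "sources",
    "evidence": "evidence",
}


def triples_from_response(
    payload: Mapping[str, Any],
    field_map: Mapping[str, str] = DEFAULT_FIELD_MAP,
) -> List[AttributedTriple]:
    """Convert a neighborhood JSON payload into attributed triples."""
    fm = {**DEFAULT_FIELD_MAP, **dict(field_map)}
    nodes: Dict[str, NodeRecord] = {}
    for item in payload.get(fm["nodes"], []):
        node = NodeRecord(
            node_id=str(item[fm["node_id"]]),
            node_type=str(item[fm["node_type"]]),
            name=str(item.get(fm["node_name"], item[fm["node_id"]])),
        )
        nodes[node.node_id] = node
    triples = []
    for item in payload.get(fm["edges"], []):
        provenance = item.get(fm["provenance"]) or []
        if isinstance(provenance, str):
            provenance = [provenance]
        triples.append(
            AttributedTriple(
                subject=nodes[str(item[fm["subject_id"]])],
                predicate=str(item[fm["predicate"]]),
                object=nodes[str(item[fm["object_id"]])],
                provenance=tuple(provenance),
                evidence=item.get(fm["evidence"]),
            )
        )
    return triples


@dataclass
class SpokeRestClient:
    """Minimal HTTP client for a neighborhood endpoint."""

    base_url: str
    endpoint: str = "/api/v1/neighborhood/"
    timeout: float = 30.0
    field_map: Mapping[str, str] = field(default_factory=lambda: DEFAULT_FIELD_MAP)

    def neighborhood(self, node_type: str, attribute: str, value: str):
        """Fetch and translate the neighborhood of one node."""
        url = (
            self.base_url.rstrip("/")
            + self.endpoint
            + "/".join(
                urllib.parse.quote(part) for part in (node_type, attribute, value)
            )
        )
        with urllib.request.urlopen(url, timeout=self.timeout) as response:
            payload = json.loads(response.read().decode("utf-8"))
        return triples_from_response(payload, self.field_map)
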