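"""Embeddings, vector search, and disease entity linking.

Entity recognition is a two-step process: a pluggable extractor pulls
disease mentions out of the question text (in production an LLM prompted
to return JSON; in tests a dictionary matcher), and each mention is then
linked to a graph node by cosine similarity against a precomputed index
of disease-name embeddings.  When extraction fails, the top five index
entries most similar to the whole question are used instead.

The bundled :class:`ReferenceTrigramEmbedder` is a deterministic sentence
embedder: case-folded character trigrams hashed into a fixed 256-dimensional
signed-count vector, L2-normalized.  It requires no model download, is
exactly reproducible across processes, and is case-insensitive by
construction — the property the lowercase-perturbation robustness analysis
relies on.  Production sentence-transformer models plug in behind the same
``Embedder`` contract.
"""

from __future__ import annotations

import abc
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._text import norm_key
from .errors import EmptyIndexError, ExtractionTransportError


class Embedder(abc.ABC):
    """Maps batches of texts to fixed-dimension unit vectors.

    Implementations must be deterministic for fixed inputs within one
    process; the reference embedder is additionally case-insensitive.
    """

    name: str
    dimension: int

    @abc.abstractmethod
    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """Return an array of shape ``(len(texts), dimension)``.

        Rows have unit L2 norm except for texts with no features (the
        empty string), which embed to the zero vector; cosine similarity
        against a zero vector is defined as 0.
        """


def _stable_hash(gram: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(gram.encode("utf-8"), digest_size=8).digest(), "big"
    )


class ReferenceTrigramEmbedder(Embedder):
    """Deterministic character-trigram hashing embedder.

    Text is NFC-normalized, case-folded, padded with ``##`` boundaries,
    and decomposed into its character-trigram multiset.  Each trigram is
    hashed (BLAKE2b, stable across platforms) to a bucket in a
    256-dimensional vector with a hash-derived sign, and the result is
    L2-normalized so cosine similarity is a plain dot product.
    """

    def __init__(self, dimension: int = 256, name: str = "ref-trigram-256"):
        self.dimension = dimension
        self.name = name

    def _vector(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension, dtype=np.float64)
        key = norm_key(text)
        if not key:
            return vec
        padded = f"##{key}##"
        for i in range(len(padded) - 2):
            h = _stable_hash(padded[i : i + 3])
            sign = 1.0 if (h >> 8) & 1 else -1.0
            vec[h % self.dimension] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        if len(texts) == 0:
            return np.zeros((0, self.dimension), dtype=np.float64)
        return np.stack([self._vector(t) for t in texts])


_DEFAULT_EMBEDDER = ReferenceTrigramEmbedder()


def reference_embed(texts: Sequence[str]) -> np.ndarray:
    """Embed with the shared default :class:`ReferenceTrigramEmbedder`."""
    return _DEFAULT_EMBEDDER.embed(texts)


@dataclass(frozen=True)
class EntityMatch:
    """One linked entity: a query string resolved to a graph node."""

    query_text: str
    node_id: str
    similarity: float
    rank: int


class VectorIndex:
    """Exact-scan cosine index over (id, text, payload) entries.

    Entries are embedded at build time with a stamped embedder; queries
    embed with the same embedder and score by dot product (all vectors are
    unit-normalized).  Ties break by entry id ascending.
    """

    def __init__(
        self,
        entry_ids: List[str],
        texts: List[str],
        payloads: List[str],
        matrix: np.ndarray,
        embedder: Embedder,
    ):
        if matrix.shape != (len(entry_ids), embedder.dimension):
            raise ValueError("vector matrix shape disagrees with entries/embedder")
        self.entry_ids = entry_ids
        self.texts = texts
        self.payloads = payloads
        self.matrix = matrix
        self.embedder = embedder

    def __len__(self) -> int:
        return len(self.entry_ids)


def build_index(
    items: Iterable[Tuple[str, str, str]], embedder: Optional[Embedder] = None
) -> VectorIndex:
    """Embed ``(entry_id, text, payload)`` items into a :class:`VectorIndex`.

    Raises ``ValueError`` on duplicate entry ids.
    """
    if embedder is None:
        embedder = ReferenceTrigramEmbedder()
    entry_ids: List[str] = []
    texts: List[str] = []
    payloads: List[str] = []
    seen = set()
    for entry_id, text, payload in items:
        if entry_id in seen:
            raise ValueError(f"duplicate entry id {entry_id!r}")
        seen.add(entry_id)
        entry_ids.append(entry_id)
        texts.append(text)
        payloads.append(str(payload))
    matrix = embedder.embed(texts)
    return VectorIndex(entry_ids, texts, payloads, matrix, embedder)


def query_index(index: VectorIndex, text: str, k: int) -> List[EntityMatch]:
    """Top-k entries by cosine similarity to ``text``.

    Returns fewer than ``k`` matches if the index is smaller; ties break
    by entry id ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(index) == 0:
        return []
    query_vec = index.embedder.embed([text])[0]
    sims = index.matrix @ query_vec
    order = sorted(range(len(index)), key=lambda i: (-sims[i], index.entry_ids[i]))
    return [
        EntityMatch(
            query_text=text,
            node_id=index.payloads[i],
            similarity=float(sims[i]),
            rank=rank,
        )
        for rank, i in enumerate(order[:k], start=1)
    ]


def save_index(index: VectorIndex, prefix: Union[str, Path]) -> None:
    """Persist an index as a JSONL entry sidecar plus a text vector matrix."""
    prefix = str(prefix)
    with open(f"{prefix}.entries.jsonl", "w", encoding="utf-8") as handle:
        meta = {"embedder": index.embedder.name, "dimension": index.embedder.dimension}
        handle.write(json.dumps(meta) + "\n")
        for entry_id, text, payload in zip(
            index.entry_ids, index.texts, index.payloads
        ):
            handle.write(
                json.dumps({"entry_id": entry_id, "text": text, "payload": payload})
                + "\n"
            )
    np.savetxt(f"{prefix}.vectors.tsv", index.matrix, delimiter="\t")


def load_index(prefix: Union[str, Path], embedder: Embedder) -> VectorIndex:
    """Load a persisted index; the embedder must match the saved stamp."""
    prefix = str(prefix)
    with open(f"{prefix}.entries.jsonl", "r", encoding="utf-8") as handle:
        lines = [line for line in handle if line.strip()]
    meta = json.loads(lines[0])
    if meta["embedder"] != embedder.name or meta["dimension"] != embedder.dimension:
        raise ValueError(
            f"index was built with embedder {meta['embedder']!r} "
            f"(dim {meta['dimension']}), got {embedder.name!r} "
            f"(dim {embedder.dimension})"
        )
    entries = [json.loads(line) for line in lines[1:]]
    matrix = np.loadtxt(f"{prefix}.vectors.tsv", delimiter="\t", ndmin=2)
    if len(entries) == 0:
        matrix = np.zeros((0, embedder.dimension))
    return VectorIndex(
        [e["entry_id"] for e in entries],
        [e["text"] for e in entries],
        [e["payload"] for e in entries],
        matrix,
        embedder,
    )


@dataclass(frozen=True)
class ExtractedEntities:
    """Result of disease-mention extraction from a question."""

    diseases: Tuple[str, ...]
    raw_response: str
    succeeded: bool


class DictionaryExtractor:
    """Deterministic extractor: case-insensitive scan for known disease names.

    Emits the same JSON payload shape an LLM extractor is instructed to
    return, so both run behind the same extraction contract.  Matches are
    reported in order of first appearance; overlapping matches at the same
    position prefer the longer name.
    """

    def __init__(self, names: Iterable[str]):
        seen = set()
        self.names: List[str] = []
        for name in names:
            key = norm_key(name)
            if key and key not in seen:
                seen.add(key)
                self.names.append(name)

    def __call__(self, prompt: str) -> str:
        haystack = norm_key(prompt)
        hits = []
        for name in self.names:
            pos = haystack.find(norm_key(name))
            if pos >= 0:
                hits.append((pos, -len(name), name))
        hits.sort()
        return json.dumps({"diseases": [name for _, _, name in hits]})


def extract_disease_entities(
    prompt: str, extractor: Callable[[str], str]
) -> ExtractedEntities:
    """Run the pluggable extractor and parse its JSON payload.

    The extractor returns raw text expected to be JSON with a list of
    disease strings (either a bare list or under a ``diseases`` key).
    Malformed output yields ``succeeded=False`` with no diseases; a raised
    exception from the extractor itself (transport failure) is re-raised
    as :class:`ExtractionTransportError` — a failure mode distinct from
    "no entities found".
    """
    try:
        raw = extractor(prompt)
    except Exception as exc:
        raise ExtractionTransportError(f"extractor failed: {exc}") from exc

    diseases: Optional[List[str]] = None
    try:
        payload: Any = json.loads(raw)
    except (json.JSONDecodeError, TypeError):
        payload = None
    if isinstance(payload, list):
        diseases = payload
    elif isinstance(payload, dict):
        for key, value in payload.items():
            if key.casefold() in {"diseases", "disease", "entities"}:
                diseases = value
                break
    if not isinstance(diseases, list) or not all(
        isinstance(d, str) for d in diseases
    ):
        return ExtractedEntities((), str(raw), False)
    return ExtractedEntities(tuple(diseases), str(raw), True)


def link_entities(
    entities: ExtractedEntities,
    prompt: str,
    disease_index: VectorIndex,
    fallback_k: int = 5,
) -> List[EntityMatch]:
    """Map extracted disease mentions to graph nodes.

    Each extracted mention is linked to its single most similar indexed
    disease name (argmax, no similarity floor), deduplicated by node id.
    If extraction failed or found nothing, the whole prompt text is
    queried instead and the top ``fallback_k`` disease concepts are
    returned.
    """
    if len(disease_index) == 0:
        raise EmptyIndexError("cannot link entities against an empty index")
    if entities.succeeded and entities.diseases:
        matches: List[EntityMatch] = []
        seen = set()
        for mention in entities.diseases:
            best = query_index(disease_index, mention, 1)[0]
            if best.node_id not in seen:
                seen.add(best.node_id)
                matches.append(
                    EntityMatch(
                        query_text=mention,
                        node_id=best.node_id,
                        similarity=best.similarity,
                        rank=len(matches) + 1,
                    )
                )
        return matches
    return query_index(disease_index, prompt, fallback_k)


def build_disease_index(
    graph: Any,
    embedder: Optional[Embedder] = None,
    node_types: Tuple[str, ...] = ("Disease",),
) -> VectorIndex:
    """Index the names of all nodes of the given types (default: diseases).

    Entry id, payload and text are the node id, node id and display name,
    so a query resolves directly to graph nodes.
    """
    wanted = {t.casefold() for t in node_types}
    items = sorted(
        (node.node_id, node.name, node.node_id)
        for node in graph.nodes
        if node.node_type.casefold() in wanted
    )
    return build_index(items, embedder)
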