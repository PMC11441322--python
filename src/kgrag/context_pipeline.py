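"""Prompt-aware context: retrieve, verbalize, prune, and budget.

Given the disease nodes linked from a question, the pipeline fetches
their filtered one-hop neighborhoods, verbalizes each surviving triple,
and keeps only the sentences semantically pertinent to the question:
within each linked node's group, a sentence survives when its cosine
similarity to the question is strictly greater than the group's 75th
percentile (linear interpolation between order statistics) AND at least
0.5.  Survivors from all groups are pooled, ranked by similarity, and
truncated to the context volume — the cap on how many graph associations
may flow into the prompt (default 150; 100 is the convention for
True/False runs).

Similarities are always computed on the bare association sentence;
provenance and evidence clauses are re-attached later, at prompt
assembly, so they never influence pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import KGRAGError
from .graph_store import (
    AttributedTriple,
    ContextFilter,
    NodeRecord,
    PropertyGraph,
    neighborhood,
)
from .semantic_index import (
    DictionaryExtractor,
    Embedder,
    EntityMatch,
    ReferenceTrigramEmbedder,
    VectorIndex,
    extract_disease_entities,
    link_entities,
)
from .verbalize import ContextSentence, verbalize_triple

#: Context-volume convention for True/False question runs.
TF_CONTEXT_VOLUME = 100


@dataclass(frozen=True)
class PruningConfig:
    """Percentile + floor pruning rule and context-volume budget.

    ``percentile=None`` disables the percentile rule (with
    ``min_similarity=0.0`` this keeps every sentence, i.e. pruning off
    while the volume cap still applies).
    """

    percentile: Optional[float] = 75.0
    min_similarity: float = 0.5
    context_volume: int = 150

    def __post_init__(self) -> None:
        if self.percentile is not None and not 0.0 <= self.percentile <= 100.0:
            raise ValueError("percentile must lie in [0, 100]")
        if self.context_volume < 0:
            raise ValueError("context_volume must be non-negative")


#: Pruning disabled: keep everything, subject only to the volume cap.
NO_PRUNING = PruningConfig(percentile=None, min_similarity=0.0)


@dataclass(frozen=True)
class RetrievedSentence:
    """A verbalized neighborhood triple tagged with the linked node it
    came from (the group key for percentile pruning)."""

    sentence: ContextSentence
    entity_node_id: str


@dataclass(frozen=True)
class ScoredContext:
    """A retrieved sentence with its question-similarity score."""

    sentence: ContextSentence
    similarity: float
    entity_node_id: str


def retrieve_context(
    graph: PropertyGraph,
    matches: Sequence[EntityMatch],
    context_filter: Optional[ContextFilter] = None,
) -> List[RetrievedSentence]:
    """Verbalized filtered neighborhoods of all matched nodes, in match
    order then deterministic neighborhood order.

    Sentences are verbalized without provenance/evidence clauses: this is
    the pruning-facing text.
    """
    retrieved: List[RetrievedSentence] = []
    for match in matches:
        for triple in neighborhood(graph, match.node_id, context_filter):
            retrieved.append(
                RetrievedSentence(
                    sentence=verbalize_triple(triple),
                    entity_node_id=match.node_id,
                )
            )
    return retrieved


def prune_context(
    prompt: str,
    contexts: Sequence[RetrievedSentence],
    embedder: Optional[Embedder] = None,
    config: Optional[PruningConfig] = None,
) -> List[ScoredContext]:
    """Keep the question-pertinent subset of the retrieved context.

    Per entity group: similarity strictly greater than the group's
    ``percentile`` threshold and at least ``min_similarity``.  Survivors
    are pooled across groups, sorted by similarity descending (ties by
    sentence text ascending), and truncated to ``context_volume``.
    """
    if embedder is None:
        embedder = ReferenceTrigramEmbedder()
    if config is None:
        config = PruningConfig()
    if not contexts:
        return []

    texts = [ctx.sentence.text for ctx in contexts]
    vectors = embedder.embed([prompt] + texts)
    prompt_vec = vectors[0]
    sims = vectors[1:] @ prompt_vec

    groups: dict = {}
    for idx, ctx in enumerate(contexts):
        groups.setdefault(ctx.entity_node_id, []).append(idx)

    kept: List[ScoredContext] = []
    for entity_id, idxs in groups.items():
        group_sims = sims[idxs]
        if config.percentile is not None:
            threshold = float(np.percentile(group_sims, config.percentile))
        else:
            threshold = -np.inf
        for idx in idxs:
            sim = float(sims[idx])
            if sim > threshold and sim >= config.min_similarity:
                kept.append(
                    ScoredContext(
                        sentence=contexts[idx].sentence,
                        similarity=sim,
                        entity_node_id=entity_id,
                    )
                )

    kept.sort(key=lambda sc: (-sc.similarity, sc.sentence.text))
    return kept[: config.context_volume]


def triple_neighbor(triple: AttributedTriple, entity_node_id: str) -> NodeRecord:
    """The endpoint of a triple that is not the linked entity node."""
    if triple.subject.node_id == entity_node_id:
        return triple.object
    return triple.subject


def semantic_retriever(
    graph: PropertyGraph,
    disease_index: VectorIndex,
    embedder: Optional[Embedder] = None,
    extractor: Optional[Callable[[str], str]] = None,
    context_filter: Optional[ContextFilter] = None,
    pruning: Optional[PruningConfig] = None,
    predicates: Optional[Iterable[str]] = None,
    fallback_k: int = 5,
) -> Callable[[str], Set[str]]:
    """Build a question -> retrieved-neighbor-names function.

    This is the retrieval half of the pipeline (extract, link, fetch,
    verbalize, prune), used by the benchmark harness to score retrieval
    questions: the returned set contains the names of the neighbor nodes
    of every context sentence that survived pruning, optionally restricted
    to the given predicates.  Pruning defaults to off so the function
    measures retrieval rather than pruning.
    """
    if embedder is None:
        embedder = disease_index.embedder
    if extractor is None:
        extractor = DictionaryExtractor(
            node.name for node in graph.nodes if node.node_type.casefold() == "disease"
        )
    if pruning is None:
        pruning = NO_PRUNING
    predicate_set = set(predicates) if predicates is not None else None

    def retrieve(question: str) -> Set[str]:
        entities = extract_disease_entities(question, extractor)
        matches = link_entities(entities, question, disease_index, fallback_k)
        retrieved = retrieve_context(graph, matches, context_filter)
        if predicate_set is not None:
            retrieved = [
                ctx
                for ctx in retrieved
                if ctx.sentence.source_triple.predicate in predicate_set
            ]
        scored = prune_context(question, retrieved, embedder, pruning)
        return {
            triple_neighbor(sc.sentence.source_triple, sc.entity_node_id).name
            for sc in scored
        }

    return retrieve


def sweep_context_volume(
    questions: Sequence,
    graph: PropertyGraph,
    disease_index: VectorIndex,
    volumes: Sequence[int],
    embedder: Optional[Embedder] = None,
    extractor: Optional[Callable[[str], str]] = None,
    context_filter: Optional[ContextFilter] = None,
    pruning: Optional[PruningConfig] = None,
    predicates: Optional[Iterable[str]] = ("ASSOCIATES_DaG",),
) -> pd.DataFrame:
    """Mean retrieval Jaccard as a function of the context volume.

    For each volume, runs the retrieval pipeline on every retrieval
    question and scores the retrieved association set against the
    question's ground-truth set with Jaccard similarity.  Returns a
    DataFrame with columns ``volume``, ``mean_jaccard``, ``n_questions``.
    """
    from .benchmark import jaccard  # local import to avoid a module cycle

    questions = [q for q in questions if q.kind == "retrieval"]
    if not questions:
        raise KGRAGError("sweep_context_volume needs at least one retrieval question")
    if pruning is None:
        pruning = NO_PRUNING

    rows = []
    for volume in volumes:
        config = replace(pruning, context_volume=int(volume))
        retrieve = semantic_retriever(
            graph,
            disease_index,
            embedder=embedder,
            extractor=extractor,
            context_filter=context_filter,
            pruning=config,
            predicates=predicates,
        )
        scores = [jaccard(retrieve(q.text), set(q.truth_set)) for q in questions]
        rows.append(
            {
                "volume": int(volume),
                "mean_jaccard": float(np.mean(scores)),
                "n_questions": len(questions),
            }
        )
    return pd.DataFrame(rows)
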