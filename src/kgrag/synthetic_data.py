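"""Synthetic SPOKE-like graphs and matched benchmark question sets.

The generator emulates the structural features the retrieval pipeline
cares about — typed nodes with unique display names, schema-compliant
predicates, per-edge provenance, p-value/z-score evidence, clinical
phases on treatment associations, a text-mined fraction of disease-gene
edges, and a curated fraction of protein nodes — without claiming any
biological realism of the specific associations.

Question sets are derived from the generated graph so ground truth is
correct by construction: True assertions verbalize edges that survive
the default context filter, False assertions rewire to nodes with no
edge at all, MCQ distractors are same-type nodes unlinked to the
disease, and retrieval truth sets are exactly the filtered association
names.  Everything is reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .benchmark import MCQ_N_OPTIONS, QuestionRecord
from .errors import InfeasibleSpecError, KGRAGError
from .graph_store import (
    AttributedTriple,
    ContextFilter,
    EdgeRecord,
    NodeRecord,
    PropertyGraph,
    neighborhood,
)
from .verbalize import verbalize_triple

#: Real concept names seeded into generated graphs so worked examples and
#: golden fixtures resolve against generator output too.
DEFAULT_DISEASE_NAMES = (
    "hypertension",
    "Bardet-Biedl syndrome",
    "liver benign neoplasm",
    "multiple sclerosis",
    "type 2 diabetes mellitus",
)
DEFAULT_GENE_NAMES = ("VHL", "PNPLA3", "HLA-B")

_DAG_SOURCES = ("GWAS Catalog", "DisGeNET")
_DAG_TEXTMINING_SOURCES = ("SemMedDB",)
_CTD_SOURCES = ("ChEMBL", "DrugCentral")
_DAP_SOURCES = ("SwissProt",)


@dataclass(frozen=True)
class GraphSpec:
    """Shape and attribute distributions of a generated graph.

    Edge densities are mean associations per disease for each relation
    type.  ``fraction_textmining`` is the share of disease-gene edges
    tagged as text-mined; ``fraction_curated_proteins`` the share of
    protein nodes flagged curated.  Evidence on disease-gene edges draws
    p-values uniformly on (0, ``p_value_max``] and z-scores from a normal
    with the stated mean/sd.  With ``exact_fractions`` the text-mining and
    curated counts are exact rather than binomial.
    """

    n_diseases: int = 30
    n_genes: int = 120
    n_compounds: int = 40
    n_proteins: int = 30
    assoc_per_disease: int = 6
    treats_per_disease: int = 3
    protein_assoc_per_disease: int = 2
    fraction_textmining: float = 0.3
    fraction_curated_proteins: float = 0.7
    clinical_phase_weights: Tuple[float, ...] = (0.1, 0.1, 0.2, 0.3, 0.3)
    p_value_max: float = 0.05
    z_mean: float = 4.0
    z_sd: float = 1.0
    exact_fractions: bool = False
    disease_names: Tuple[str, ...] = DEFAULT_DISEASE_NAMES
    gene_names: Tuple[str, ...] = DEFAULT_GENE_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_textmining", "fraction_curated_proteins"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InfeasibleSpecError(f"{name} must lie in [0, 1]")
        for name in ("n_diseases", "n_genes", "n_compounds", "n_proteins"):
            if getattr(self, name) < 0:
                raise InfeasibleSpecError(f"{name} must be non-negative")
        if len(self.clinical_phase_weights) != 5 or not np.isclose(
            sum(self.clinical_phase_weights), 1.0
        ):
            raise InfeasibleSpecError(
                "clinical_phase_weights must be 5 probabilities summing to 1"
            )
        if self.n_diseases > 0:
            if self.assoc_per_disease > self.n_genes:
                raise InfeasibleSpecError(
                    "assoc_per_disease exceeds the gene pool"
                )
            if self.treats_per_disease > self.n_compounds:
                raise InfeasibleSpecError(
                    "treats_per_disease exceeds the compound pool"
                )
            if self.protein_assoc_per_disease > self.n_proteins:
                raise InfeasibleSpecError(
                    "protein_assoc_per_disease exceeds the protein pool"
                )

    @property
    def expected_n_nodes(self) -> int:
        return self.n_diseases + self.n_genes + self.n_compounds + self.n_proteins

    @property
    def expected_n_edges(self) -> int:
        return self.n_diseases * (
            self.assoc_per_disease
            + self.treats_per_disease
            + self.protein_assoc_per_disease
        )


def _names(prefix: str, count: int, real: Sequence[str]) -> List[str]:
    names = list(real[:count])
    i = 0
    while len(names) < count:
        candidate = f"{prefix}_{i:04d}"
        if candidate not in names:
            names.append(candidate)
        i += 1
    return names


def _flags(rng: np.random.Generator, count: int, fraction: float, exact: bool):
    if count == 0:
        return np.zeros(0, dtype=bool)
    if exact:
        flags = np.zeros(count, dtype=bool)
        chosen = rng.choice(count, size=round(fraction * count), replace=False)
        flags[chosen] = True
        return flags
    return rng.random(count) < fraction


def generate_graph(spec: Optional[GraphSpec] = None) -> PropertyGraph:
    """Generate a validated property graph according to ``spec``.

    Byte-identical output for identical specs: node naming is integer
    based and all sampling flows through one seeded generator.
    """
    if spec is None:
        spec = GraphSpec()
    rng = np.random.default_rng(spec.seed)

    disease_names = _names("Disease", spec.n_diseases, spec.disease_names)
    gene_names = _names("Gene", spec.n_genes, spec.gene_names)
    compound_names = _names("Compound", spec.n_compounds, ())
    protein_names = _names("Protein", spec.n_proteins, ())

    curated = _flags(
        rng, spec.n_proteins, spec.fraction_curated_proteins, spec.exact_fractions
    )

    nodes: List[NodeRecord] = []
    for i, name in enumerate(disease_names):
        nodes.append(
            NodeRecord(f"D{i:04d}", "Disease", name, identifier=f"MONDO:{i:07d}")
        )
    for i, name in enumerate(gene_names):
        nodes.append(NodeRecord(f"G{i:04d}", "Gene", name, identifier=f"NCBI:{i:05d}"))
    for i, name in enumerate(compound_names):
        nodes.append(
            NodeRecord(f"C{i:04d}", "Compound", name, identifier=f"CHEMBL:{i:06d}")
        )
    for i, name in enumerate(protein_names):
        nodes.append(
            NodeRecord(
                f"P{i:04d}",
                "Protein",
                name,
                identifier=f"UNIPROT:{i:05d}",
                attributes={"curated": bool(curated[i])},
            )
        )

    edges: List[EdgeRecord] = []

    # Disease-Gene associations with evidence and a text-mined fraction.
    dag_pairs: List[Tuple[int, int]] = []
    for d in range(spec.n_diseases):
        genes = rng.choice(spec.n_genes, size=spec.assoc_per_disease, replace=False)
        dag_pairs.extend((d, int(g)) for g in sorted(genes))
    textmining = _flags(
        rng, len(dag_pairs), spec.fraction_textmining, spec.exact_fractions
    )
    for (d, g), mined in zip(dag_pairs, textmining):
        if mined:
            provenance = _DAG_TEXTMINING_SOURCES
        else:
            n_sources = int(rng.integers(1, len(_DAG_SOURCES) + 1))
            picks = rng.choice(len(_DAG_SOURCES), size=n_sources, replace=False)
            provenance = tuple(_DAG_SOURCES[p] for p in sorted(picks))
        evidence = {
            "p_value": float(spec.p_value_max * (1.0 - rng.random())),
            "z_score": float(rng.normal(spec.z_mean, spec.z_sd)),
        }
        edges.append(
            EdgeRecord(
                subject_id=f"D{d:04d}",
                object_id=f"G{g:04d}",
                predicate="ASSOCIATES_DaG",
                provenance=provenance,
                evidence=evidence,
                source_type="textmining" if mined else "curated",
            )
        )

    # Compound-treats-Disease edges with clinical phases.
    for d in range(spec.n_diseases):
        compounds = rng.choice(
            spec.n_compounds, size=spec.treats_per_disease, replace=False
        )
        for c in sorted(compounds):
            phase = int(rng.choice(5, p=spec.clinical_phase_weights))
            source = _CTD_SOURCES[int(rng.integers(len(_CTD_SOURCES)))]
            edges.append(
                EdgeRecord(
                    subject_id=f"C{int(c):04d}",
                    object_id=f"D{d:04d}",
                    predicate="TREATS_CtD",
                    provenance=(source,),
                    clinical_phase=phase,
                    source_type="curated",
                )
            )

    # Disease-Protein associations; the curated flag lives on the node.
    for d in range(spec.n_diseases):
        proteins = rng.choice(
            spec.n_proteins, size=spec.protein_assoc_per_disease, replace=False
        )
        for p in sorted(proteins):
            edges.append(
                EdgeRecord(
                    subject_id=f"D{d:04d}",
                    object_id=f"P{int(p):04d}",
                    predicate="ASSOCIATES_DaP",
                    provenance=_DAP_SOURCES,
                    source_type="curated",
                )
            )

    return PropertyGraph(nodes, edges)


@dataclass(frozen=True)
class QuestionSpec:
    """What kind of question set to derive from a graph, and how many.

    MCQ distractors are same-type nodes with no association (of any
    source type) to the question's disease; True/False negatives rewire
    the object to such an unlinked node, so labels are correct by
    construction.
    """

    kind: str = "retrieval"
    n_questions: int = 20
    seed: int = 0


def _association_tables(graph: PropertyGraph):
    """Per-disease filtered gene triples, plus all linked gene ids (any
    source type) for distractor/negative exclusion."""
    filtered: Dict[str, List[AttributedTriple]] = {}
    linked: Dict[str, set] = {}
    diseases = sorted(graph.nodes_of_type("Disease"), key=lambda n: n.node_id)
    for disease in diseases:
        triples = [
            t
            for t in neighborhood(graph, disease.node_id, ContextFilter())
            if t.predicate == "ASSOCIATES_DaG"
        ]
        filtered[disease.node_id] = triples
        linked[disease.node_id] = {
            e.object_id if e.subject_id == disease.node_id else e.subject_id
            for e in graph.incident_edges(disease.node_id)
            if e.predicate == "ASSOCIATES_DaG"
        }
    return diseases, filtered, linked


def _unlinked_genes(graph: PropertyGraph, linked: set) -> List[NodeRecord]:
    return [
        node
        for node in sorted(graph.nodes_of_type("Gene"), key=lambda n: n.node_id)
        if node.node_id not in linked
    ]


def generate_questions(
    graph: PropertyGraph, spec: Optional[QuestionSpec] = None
) -> List[QuestionRecord]:
    """Derive a benchmark question set from a graph.

    True/False sets are balanced: floor(n/2) true assertions verbalized
    from filtered disease-gene edges and the rest false assertions rewired
    to unlinked genes.  MCQ questions pair the true linked gene with four
    unlinked distractors.  Retrieval questions name a disease and carry
    its filtered associated gene names as the truth set.

    Raises :class:`KGRAGError` stating the shortfall when the graph holds
    fewer usable associations than ``n_questions``.
    """
    if spec is None:
        spec = QuestionSpec()
    rng = np.random.default_rng(spec.seed)
    diseases, filtered, linked = _association_tables(graph)
    pairs: List[Tuple[NodeRecord, AttributedTriple]] = [
        (disease, triple)
        for disease in diseases
        for triple in filtered[disease.node_id]
    ]

    records: List[QuestionRecord] = []

    if spec.kind == "tf":
        if len(pairs) < spec.n_questions:
            raise KGRAGError(
                f"need {spec.n_questions} associations for tf questions, "
                f"graph has {len(pairs)} (short by {spec.n_questions - len(pairs)})"
            )
        chosen = rng.choice(len(pairs), size=spec.n_questions, replace=False)
        n_true = spec.n_questions // 2
        for i, idx in enumerate(chosen):
            disease, triple = pairs[int(idx)]
            if i < n_true:
                sentence = verbalize_triple(triple).text
                correct = "True"
            else:
                candidates = _unlinked_genes(graph, linked[disease.node_id])
                if not candidates:
                    raise KGRAGError(
                        f"no unlinked gene available to negate an assertion "
                        f"for {disease.name!r}"
                    )
                gene = candidates[int(rng.integers(len(candidates)))]
                fake = AttributedTriple(
                    subject=triple.subject, predicate=triple.predicate, object=gene
                )
                sentence = verbalize_triple(fake).text
                correct = "False"
            records.append(
                QuestionRecord(
                    question_id=f"tf-{i:04d}",
                    kind="tf",
                    text=f"True or False: {sentence}.",
                    correct=correct,
                )
            )

    elif spec.kind == "mcq":
        if len(pairs) < spec.n_questions:
            raise KGRAGError(
                f"need {spec.n_questions} associations for mcq questions, "
                f"graph has {len(pairs)} (short by {spec.n_questions - len(pairs)})"
            )
        chosen = rng.choice(len(pairs), size=spec.n_questions, replace=False)
        for i, idx in enumerate(chosen):
            disease, triple = pairs[int(idx)]
            correct_gene = (
                triple.object
                if triple.subject.node_id == disease.node_id
                else triple.subject
            )
            candidates = _unlinked_genes(graph, linked[disease.node_id])
            if len(candidates) < MCQ_N_OPTIONS - 1:
                raise KGRAGError(
                    f"need {MCQ_N_OPTIONS - 1} unlinked distractor genes for "
                    f"{disease.name!r}, only {len(candidates)} available"
                )
            picks = rng.choice(
                len(candidates), size=MCQ_N_OPTIONS - 1, replace=False
            )
            options = [correct_gene.name] + [candidates[int(p)].name for p in picks]
            order = rng.permutation(len(options))
            records.append(
                QuestionRecord(
                    question_id=f"mcq-{i:04d}",
                    kind="mcq",
                    text=(
                        "Which of the following genes is associated with "
                        f"{disease.name}?"
                    ),
                    options=tuple(options[int(j)] for j in order),
                    correct=correct_gene.name,
                )
            )

    elif spec.kind == "retrieval":
        usable = [d for d in diseases if filtered[d.node_id]]
        if len(usable) < spec.n_questions:
            raise KGRAGError(
                f"need {spec.n_questions} diseases with filtered associations "
                f"for retrieval questions, graph has {len(usable)} "
                f"(short by {spec.n_questions - len(usable)})"
            )
        chosen = rng.choice(len(usable), size=spec.n_questions, replace=False)
        for i, idx in enumerate(sorted(int(c) for c in chosen)):
            disease = usable[idx]
            truth = frozenset(
                (
                    t.object if t.subject.node_id == disease.node_id else t.subject
                ).name
                for t in filtered[disease.node_id]
            )
            records.append(
                QuestionRecord(
                    question_id=f"retrieval-{i:04d}",
                    kind="retrieval",
                    text=f"What genes are associated with {disease.name}?",
                    truth_set=truth,
                )
            )

    else:
        raise KGRAGError(f"unknown question kind {spec.kind!r}")

    return records
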