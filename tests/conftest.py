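import pytest

from kgrag import (
    AttributedTriple,
    EdgeRecord,
    GraphSpec,
    NodeRecord,
    PropertyGraph,
    ReferenceTrigramEmbedder,
    build_disease_index,
    generate_graph,
)


@pytest.fixture(scope="session")
def embedder():
    return ReferenceTrigramEmbedder()


@pytest.fixture()
def golden_triple():
    """The worked hypertension-VHL association, with node-type strings
    stored exactly as rendered in the expected sentence."""
    hypertension = NodeRecord("D1", "disease", "hypertension")
    vhl = NodeRecord("G1", "Gene", "VHL")
    return AttributedTriple(
        subject=hypertension,
        predicate="ASSOCIATES_DaG",
        object=vhl,
        provenance=("GWAS Catalog",),
        evidence={"p_value": 1.2e-8, "z_score": 4.56},
    )


@pytest.fixture()
def filter_graph():
    """Hand-built graph exercising all three context-filter rules:
    phase-2 vs phase-3 treatment edges, curated vs uncurated protein
    neighbors, text-mined vs curated disease-gene associations."""
    nodes = [
        NodeRecord("D1", "Disease", "hypertension"),
        NodeRecord("C1", "Compound", "drug-early"),
        NodeRecord("C2", "Compound", "drug-approved"),
        NodeRecord("G1", "Gene", "MINED1"),
        NodeRecord("G2", "Gene", "CURATED1"),
        NodeRecord("P1", "Protein", "ProtCurated", attributes={"curated": True}),
        NodeRecord("P2", "Protein", "ProtRaw", attributes={"curated": False}),
        NodeRecord("D2", "Disease", "isolated disease"),
    ]
    edges = [
        EdgeRecord("C1", "D1", "TREATS_CtD", provenance=("ChEMBL",), clinical_phase=2),
        EdgeRecord(
            "C2", "D1", "TREATS_CtD", provenance=("DrugCentral",), clinical_phase=3
        ),
        EdgeRecord(
            "D1",
            "G1",
            "ASSOCIATES_DaG",
            provenance=("SemMedDB",),
            source_type="textmining",
        ),
        EdgeRecord(
            "D1",
            "G2",
            "ASSOCIATES_DaG",
            provenance=("GWAS Catalog", "DisGeNET"),
            evidence={"p_value": 0.003, "z_score": 5.1},
            source_type="curated",
        ),
        EdgeRecord("D1", "P1", "ASSOCIATES_DaP", provenance=("SwissProt",)),
        EdgeRecord("D1", "P2", "ASSOCIATES_DaP", provenance=("SwissProt",)),
    ]
    return PropertyGraph(nodes, edges)


@pytest.fixture(scope="session")
def synth_graph():
    return generate_graph(GraphSpec(seed=7))


@pytest.fixture(scope="session")
def synth_index(synth_graph):
    return build_disease_index(synth_graph)


@pytest.fixture(scope="session")
def big_graph():
    """Larger graph for statistics-heavy checks (500-question sets)."""
    return generate_graph(
        GraphSpec(n_diseases=100, n_genes=300, assoc_per_disease=8, seed=11)
    )


@pytest.fixture(scope="session")
def big_index(big_graph):
    return build_disease_index(big_graph)


@pytest.fixture(scope="session")
def mixedcase_graph():
    """Graph whose node names are all mixed-case generated names, so the
    exact-string baseline has nothing to match in a lower-cased question."""
    return generate_graph(
        GraphSpec(n_diseases=100, n_genes=300, disease_names=(), gene_names=(), seed=13)
    )


@pytest.fixture(scope="session")
def mixedcase_index(mixedcase_graph):
    return build_disease_index(mixedcase_graph)
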