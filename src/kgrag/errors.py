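"""Exception hierarchy shared across the package."""


class KGRAGError(Exception):
    """Base class for all kgrag errors."""


class GraphLoadError(KGRAGError):
    """A node/edge table violates the property-graph schema."""


class UnknownNodeError(KGRAGError):
    """A node id was requested that does not exist in the graph."""


class PredicateSchemaError(KGRAGError):
    """A predicate string does not follow the NAME_SpO suffix schema."""


class ExtractionTransportError(KGRAGError):
    """The entity extractor itself failed (network, crash); distinct from
    an extractor that ran but found nothing."""


class EmptyIndexError(KGRAGError):
    """Entity linking was attempted against an index with no entries."""


class QuestionFormatError(KGRAGError):
    """A benchmark question record violates its schema."""


class InfeasibleSpecError(KGRAGError):
    """A synthetic-data spec asks for more structure than can exist."""
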