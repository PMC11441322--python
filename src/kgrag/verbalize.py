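"""Predicate-schema handling and triple verbalization.

SPOKE-style property graphs name their edge types with an upper-case
predicate name followed by a three-letter suffix encoding the endpoint
types: ``UPPERCASE_NAME_SpO`` where ``S`` is the upper-cased first letter
of the subject node type, ``p`` the lower-cased first letter of the
predicate name, and ``O`` the upper-cased first letter of the object node
type.  ``ASSOCIATES_DaG`` therefore links a Disease to a Gene.

Because the schema carries the grammatical roles, a triple converts to an
English sentence by a fixed rule::

    (S, P, O)  ->  "<subject> <lower-cased predicate name> <object>"

where each endpoint renders as ``"<node_type> <name>"`` with the type
string taken verbatim from the stored record.  Provenance and statistical
evidence, when requested, are appended as parenthetical clauses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Optional

from .errors import PredicateSchemaError

if TYPE_CHECKING:  # pragma: no cover - import only for type checkers
    from .graph_store import AttributedTriple

# Predicate names: upper-case words joined by single underscores.
_NAME_RE = re.compile(r"[A-Z](?:[A-Z_]*[A-Z])?")
# Strict default suffix: subject initial (upper), predicate initial (lower),
# object initial (upper), one letter each.
_SUFFIX_RE = re.compile(r"[A-Z][a-z][A-Z]")
_COMPOSE_NAME_RE = re.compile(r"[A-Za-z](?:[A-Za-z_]*[A-Za-z])?")


@dataclass(frozen=True)
class PredicateParts:
    """A parsed predicate string.

    ``subject_initial`` and ``object_initial`` are single upper-case letters
    under the default grammar; with a custom abbreviation table they may be
    longer type abbreviations.
    """

    predicate_name: str
    subject_initial: str
    predicate_initial: str
    object_initial: str

    @property
    def suffix(self) -> str:
        return self.subject_initial + self.predicate_initial + self.object_initial

    def compose(self) -> str:
        return f"{self.predicate_name}_{self.suffix}"

    @property
    def phrase(self) -> str:
        """The predicate name as sentence text (lower case, spaces)."""
        return self.predicate_name.replace("_", " ").lower()


def parse_predicate(
    predicate: str,
    abbreviations: Optional[Mapping[str, str]] = None,
) -> PredicateParts:
    """Split a schema predicate into its name and type-initial suffix.

    The string is split at its final underscore.  By default the suffix must
    be exactly three letters in Upper-lower-Upper case, and the middle letter
    must equal the lower-cased first letter of the predicate name.

    ``abbreviations`` optionally maps node types to multi-letter type
    abbreviations (e.g. ``{"SideEffect": "SE"}``); when given, suffixes
    built from any pair of those abbreviations are also accepted.

    Raises
    ------
    PredicateSchemaError
        If the suffix is missing, has the wrong case pattern, or its middle
        initial disagrees with the predicate name.
    """
    head, sep, suffix = predicate.rpartition("_")
    if not sep or not head or not suffix:
        raise PredicateSchemaError(
            f"predicate {predicate!r} has no NAME_SpO suffix"
        )
    name = head
    if not _NAME_RE.fullmatch(name):
        raise PredicateSchemaError(
            f"predicate {predicate!r}: name part {name!r} is not upper-case"
        )
    expected_initial = name[0].lower()

    if abbreviations:
        abbrevs = sorted(set(abbreviations.values()), key=len, reverse=True)
        for sub in abbrevs:
            for obj in abbrevs:
                if suffix == f"{sub}{expected_initial}{obj}":
                    return PredicateParts(name, sub, expected_initial, obj)

    if not _SUFFIX_RE.fullmatch(suffix):
        raise PredicateSchemaError(
            f"predicate {predicate!r}: suffix {suffix!r} does not match "
            "the Upper-lower-Upper pattern"
        )
    if suffix[1] != expected_initial:
        raise PredicateSchemaError(
            f"predicate {predicate!r}: suffix initial {suffix[1]!r} does not "
            f"match predicate name initial {expected_initial!r}"
        )
    return PredicateParts(name, suffix[0], suffix[1], suffix[2])


def compose_predicate(
    predicate_name: str,
    subject_type: str,
    object_type: str,
    abbreviations: Optional[Mapping[str, str]] = None,
) -> str:
    """Build a schema predicate string from a name and endpoint types.

    ``parse_predicate(compose_predicate(name, s, o))`` round-trips for any
    valid inputs.
    """
    if not predicate_name or not subject_type or not object_type:
        raise PredicateSchemaError(
            "compose_predicate requires non-empty name and endpoint types"
        )
    if not _COMPOSE_NAME_RE.fullmatch(predicate_name):
        raise PredicateSchemaError(
            f"predicate name {predicate_name!r} must be alphabetic words "
            "joined by underscores"
        )

    def initial(node_type: str) -> str:
        if abbreviations and node_type in abbreviations:
            return abbreviations[node_type]
        return node_type[0].upper()

    return (
        f"{predicate_name.upper()}_"
        f"{initial(subject_type)}{predicate_name[0].lower()}{initial(object_type)}"
    )


@dataclass(frozen=True)
class ContextSentence:
    """A verbalized association, ready for embedding or prompt assembly.

    ``text`` is the full rendered sentence including any provenance or
    evidence clause requested at verbalization time; the optional clause
    strings are kept separately so callers can recover the bare sentence.
    """

    text: str
    source_triple: Optional["AttributedTriple"] = None
    provenance_text: Optional[str] = None
    evidence_text: Optional[str] = None


def _fmt(value: float) -> str:
    return f"{value:.6g}"


def verbalize_triple(
    triple: "AttributedTriple",
    include_provenance: bool = False,
    include_evidence: bool = False,
    abbreviations: Optional[Mapping[str, str]] = None,
) -> ContextSentence:
    """Render an attributed triple as an English context sentence.

    The core sentence is ``"<type> <name> <predicate phrase> <type> <name>"``
    with the node-type strings exactly as stored.  With
    ``include_provenance`` a clause ``" (Provenance: src1, src2)"`` is
    appended listing the edge's sources in stored order; with
    ``include_evidence`` and evidence present, ``" (evidence: p-value = p,
    z-score = z)"`` follows, omitting absent fields.
    """
    parts = parse_predicate(triple.predicate, abbreviations=abbreviations)
    subject = f"{triple.subject.node_type} {triple.subject.name}"
    obj = f"{triple.object.node_type} {triple.object.name}"
    text = f"{subject} {parts.phrase} {obj}"

    provenance_text = None
    if include_provenance and triple.provenance:
        provenance_text = f" (Provenance: {', '.join(triple.provenance)})"
        text += provenance_text

    evidence_text = None
    if include_evidence and triple.evidence:
        clauses = []
        if "p_value" in triple.evidence:
            clauses.append(f"p-value = {_fmt(triple.evidence['p_value'])}")
        if "z_score" in triple.evidence:
            clauses.append(f"z-score = {_fmt(triple.evidence['z_score'])}")
        if clauses:
            evidence_text = f" (evidence: {', '.join(clauses)})"
            text += evidence_text

    return ContextSentence(
        text=text,
        source_triple=triple,
        provenance_text=provenance_text,
        evidence_text=evidence_text,
    )
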