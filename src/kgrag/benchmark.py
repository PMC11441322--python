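"""Benchmark harness: question sets, bootstrap accuracy, Jaccard scoring,
perturbation robustness, and token-usage comparison.

Question sets come in three kinds: True/False assertions, five-option
multiple choice, and retrieval questions carrying a ground-truth set of
associated node names.  Accuracy on TF/MCQ sets is summarized by
bootstrapping: the evaluation set is resampled with replacement (default
150 draws, 1000 iterations) and the accuracy of each resample recorded,
yielding a performance distribution rather than a point estimate.

Retrieval questions are scored by whether a retriever's returned
association set covers the ground truth (subset containment by default;
any-overlap mode available), and the robustness analysis repeats the
scoring after lower-casing the question text — a perturbation that
semantic retrieval shrugs off while exact-string matching collapses.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .errors import KGRAGError, QuestionFormatError
from .graph_store import ContextFilter, PropertyGraph, neighborhood

logger = logging.getLogger(__name__)

KINDS = ("tf", "mcq", "retrieval")
MCQ_N_OPTIONS = 5


@dataclass(frozen=True)
class QuestionRecord:
    """One benchmark item; fields beyond ``text`` depend on ``kind``."""

    question_id: str
    kind: str
    text: str
    options: Optional[Tuple[str, ...]] = None
    correct: Optional[str] = None
    truth_set: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise QuestionFormatError(
                f"question {self.question_id!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "mcq":
            if self.options is None or len(self.options) != MCQ_N_OPTIONS:
                raise QuestionFormatError(
                    f"question {self.question_id!r}: mcq needs exactly "
                    f"{MCQ_N_OPTIONS} options"
                )
            if self.correct not in self.options:
                raise QuestionFormatError(
                    f"question {self.question_id!r}: correct answer not "
                    "among the options"
                )
        if self.kind == "tf" and self.correct not in ("True", "False"):
            raise QuestionFormatError(
                f"question {self.question_id!r}: tf needs correct "
                "'True' or 'False'"
            )
        if self.kind == "retrieval" and not self.truth_set:
            raise QuestionFormatError(
                f"question {self.question_id!r}: retrieval needs a "
                "non-empty truth_set"
            )


def format_question(record: QuestionRecord) -> str:
    """Question text as presented to a system (MCQ options appended)."""
    from .generation import format_options

    if record.kind == "mcq":
        return f"{record.text}\n{format_options(record.options)}"
    return record.text


def _record_from_obj(obj: Mapping[str, Any], kind: Optional[str]) -> QuestionRecord:
    record_kind = obj.get("kind", kind)
    if record_kind is None:
        raise QuestionFormatError("question record has no 'kind'")
    options = obj.get("options")
    truth = obj.get("truth_set")
    return QuestionRecord(
        question_id=str(obj.get("id", obj.get("question_id", ""))),
        kind=record_kind,
        text=obj["text"],
        options=tuple(options) if options else None,
        correct=obj.get("correct"),
        truth_set=frozenset(truth) if truth else None,
    )


def load_questions(source: Any, kind: Optional[str] = None) -> List[QuestionRecord]:
    """Load a question set from a JSON array or CSV stream/path.

    JSON objects carry ``{id, kind, text, options?, correct?, truth_set?}``;
    the CSV form uses the same columns with ``options`` and ``truth_set``
    as ``|``-separated lists.  Records are validated on construction (an
    MCQ row without five options is a load error).
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as handle:
            return load_questions(handle, kind)
    if hasattr(source, "read"):
        content = source.read()
    else:
        content = "\n".join(str(line) for line in source)
    content = content.strip()
    if not content:
        return []
    if content.startswith("["):
        objs = json.loads(content)
        return [_record_from_obj(obj, kind) for obj in objs]
    records = []
    for row in csv.DictReader(io.StringIO(content)):
        obj: Dict[str, Any] = dict(row)
        if obj.get("options"):
            obj["options"] = [o for o in obj["options"].split("|") if o]
        else:
            obj["options"] = None
        if obj.get("truth_set"):
            obj["truth_set"] = [t for t in obj["truth_set"].split("|") if t]
        else:
            obj["truth_set"] = None
        records.append(_record_from_obj(obj, kind))
    return records


def save_questions(records: Sequence[QuestionRecord], path: Any) -> None:
    """Write a question set as a JSON array readable by :func:`load_questions`."""
    objs = []
    for record in records:
        obj: Dict[str, Any] = {
            "id": record.question_id,
            "kind": record.kind,
            "text": record.text,
        }
        if record.options is not None:
            obj["options"] = list(record.options)
        if record.correct is not None:
            obj["correct"] = record.correct
        if record.truth_set is not None:
            obj["truth_set"] = sorted(record.truth_set)
        objs.append(obj)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(objs, handle, indent=1)


def _answer_candidate(record: QuestionRecord, answer: Any) -> Optional[str]:
    """Best-effort extraction of the answered value as a string."""
    parsed = getattr(answer, "parsed", None)
    if parsed is not None:
        return str(parsed)
    text = getattr(answer, "text", None)
    if text is None:
        text = str(answer)
    try:
        payload = json.loads(text)
        if isinstance(payload, dict) and "answer" in payload:
            return str(payload["answer"])
    except (json.JSONDecodeError, TypeError):
        pass
    return text


_LETTERS = "ABCDE"


def _is_correct(record: QuestionRecord, answer: Any) -> bool:
    candidate = _answer_candidate(record, answer)
    if candidate is None:
        logger.warning("question %s: unparseable answer", record.question_id)
        return False
    candidate = candidate.strip().strip('"')
    if record.kind == "tf":
        return candidate.casefold() == record.correct.casefold()
    if record.kind == "mcq":
        if len(candidate) == 1 and candidate.upper() in _LETTERS:
            idx = _LETTERS.index(candidate.upper())
            return idx < len(record.options) and record.options[idx] == record.correct
        for option in record.options:
            if candidate.casefold() == option.casefold():
                return option == record.correct
        logger.warning(
            "question %s: answer %r matches no option", record.question_id, candidate
        )
        return False
    raise QuestionFormatError(
        f"evaluate() scores tf/mcq questions, not {record.kind!r}"
    )


def evaluate(
    questions: Sequence[QuestionRecord],
    system: Callable[[QuestionRecord], Any],
) -> List[bool]:
    """Per-question correctness of a system on a TF/MCQ set.

    MCQ answers may be the option letter (A-E) or the option text,
    case-insensitively, taken from the parsed JSON field when present;
    anything unparseable counts as incorrect and is logged.
    """
    return [_is_correct(record, system(record)) for record in questions]


@dataclass(frozen=True)
class BootstrapSummary:
    """The accuracy distribution over with-replacement resamples."""

    sample_size: int
    iterations: int
    seed: int
    accuracies: Tuple[float, ...]
    mean: float
    std: float


def bootstrap_accuracy(
    correctness: Sequence[bool],
    sample_size: int = 150,
    iterations: int = 1000,
    seed: int = 0,
) -> BootstrapSummary:
    """Bootstrap the accuracy of a correctness vector.

    Each iteration draws ``sample_size`` items with replacement from the
    vector and records their accuracy; a single seeded generator drives
    all draws, so results are bit-reproducible for a fixed seed.
    """
    if len(correctness) == 0:
        raise KGRAGError("bootstrap_accuracy requires a non-empty input")
    values = np.asarray(correctness, dtype=np.float64)
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(values), size=(iterations, sample_size))
    accuracies = values[draws].mean(axis=1)
    return BootstrapSummary(
        sample_size=sample_size,
        iterations=iterations,
        seed=seed,
        accuracies=tuple(float(a) for a in accuracies),
        mean=float(accuracies.mean()),
        std=float(accuracies.std()),
    )


def jaccard(a: Set[str], b: Set[str]) -> float:
    """Jaccard similarity |a∩b| / |a∪b|; both empty counts as 1.0
    (perfect agreement on nothing)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def perturb_lowercase(
    questions: Sequence[QuestionRecord],
    mode: str = "whole_text",
    entity_names: Optional[Sequence[str]] = None,
) -> List[QuestionRecord]:
    """Lower-case question text (whole text, or just named entities).

    Ids, options, answers and truth sets are preserved; the operation is
    idempotent.
    """
    perturbed = []
    for record in questions:
        if mode == "whole_text":
            text = record.text.lower()
        elif mode == "entities":
            if entity_names is None:
                raise KGRAGError("entities mode needs entity_names")
            text = record.text
            for name in entity_names:
                text = text.replace(name, name.lower())
        else:
            raise KGRAGError(f"unknown perturbation mode {mode!r}")
        perturbed.append(replace(record, text=text))
    return perturbed


@dataclass(frozen=True)
class RobustnessReport:
    """Retrieval accuracy before and after question perturbation."""

    system_name: str
    accuracy_original: float
    accuracy_perturbed: float
    outcomes_original: Tuple[bool, ...]
    outcomes_perturbed: Tuple[bool, ...]


def retrieval_accuracy(
    questions: Sequence[QuestionRecord],
    retriever: Callable[[str], Set[str]],
    mode: str = "subset",
    system_name: str = "system",
    perturb_mode: str = "whole_text",
) -> RobustnessReport:
    """Score a retriever on retrieval questions, original and perturbed.

    A question counts correct when its ground-truth association set is a
    subset of the retrieved set (``mode="subset"``) or merely intersects
    it (``mode="overlap"``).  The perturbed pass lower-cases the question
    text first.
    """
    questions = [q for q in questions if q.kind == "retrieval"]
    if not questions:
        raise KGRAGError("retrieval_accuracy needs retrieval questions")
    if mode not in ("subset", "overlap"):
        raise KGRAGError(f"unknown retrieval scoring mode {mode!r}")

    def score(record: QuestionRecord) -> bool:
        retrieved = retriever(record.text)
        truth = set(record.truth_set)
        if mode == "subset":
            return truth <= retrieved
        return bool(truth & retrieved)

    original = tuple(score(q) for q in questions)
    perturbed_qs = perturb_lowercase(questions, mode=perturb_mode)
    perturbed = tuple(score(q) for q in perturbed_qs)
    return RobustnessReport(
        system_name=system_name,
        accuracy_original=float(np.mean(original)),
        accuracy_perturbed=float(np.mean(perturbed)),
        outcomes_original=original,
        outcomes_perturbed=perturbed,
    )


@dataclass(frozen=True)
class TokenUsageReport:
    """Per-system token counts with mean and standard error of the mean."""

    per_question: Mapping[str, Tuple[int, ...]]
    mean: Mapping[str, float]
    sem: Mapping[str, float]


def token_usage_report(
    questions: Sequence[QuestionRecord],
    systems: Mapping[str, Callable[[QuestionRecord], Any]],
) -> TokenUsageReport:
    """Total token usage (prompt + completion) of each system per question.

    SEM is the sample standard deviation over questions divided by the
    square root of the question count.
    """
    if not questions:
        raise KGRAGError("token_usage_report needs at least one question")
    per_question: Dict[str, Tuple[int, ...]] = {}
    mean: Dict[str, float] = {}
    sem: Dict[str, float] = {}
    for name, system in systems.items():
        counts = tuple(int(system(q).token_usage) for q in questions)
        per_question[name] = counts
        mean[name] = float(np.mean(counts))
        if len(counts) > 1:
            sem[name] = float(np.std(counts, ddof=1) / math.sqrt(len(counts)))
        else:
            sem[name] = 0.0
    return TokenUsageReport(per_question=per_question, mean=mean, sem=sem)


def exact_match_retriever(
    graph: PropertyGraph,
    context_filter: Optional[ContextFilter] = None,
    node_type: str = "Disease",
    predicates: Optional[Sequence[str]] = None,
) -> Callable[[str], Set[str]]:
    """Case-sensitive exact-string baseline retriever.

    Scans the question for verbatim (case-sensitive) occurrences of graph
    node names of the given type and returns the neighbor names of every
    matched node's filtered neighborhood.  This deterministic lexical
    baseline plays the role of a full-text/Cypher-style system in the
    robustness comparison: lower-casing the question breaks it whenever
    the graph's names are mixed-case.
    """
    nodes = graph.nodes_of_type(node_type)
    predicate_set = set(predicates) if predicates is not None else None

    def retrieve(question: str) -> Set[str]:
        retrieved: Set[str] = set()
        for node in nodes:
            if node.name in question:
                for triple in neighborhood(graph, node.node_id, context_filter):
                    if (
                        predicate_set is not None
                        and triple.predicate not in predicate_set
                    ):
                        continue
                    other = (
                        triple.object
                        if triple.subject.node_id == node.node_id
                        else triple.subject
                    )
                    retrieved.add(other.name)
        return retrieved

    return retrieve
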