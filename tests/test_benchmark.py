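import io
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgrag import (
    KGRAGError,
    QuestionFormatError,
    QuestionRecord,
    QuestionSpec,
    bootstrap_accuracy,
    evaluate,
    exact_match_retriever,
    generate_questions,
    jaccard,
    load_questions,
    perturb_lowercase,
    retrieval_accuracy,
    save_questions,
    token_usage_report,
)


class TestLoadQuestions:
    def test_empty_stream(self):
        assert load_questions(io.StringIO("")) == []

    def test_generator_output_roundtrips(self, tmp_path, synth_graph):
        records = generate_questions(
            synth_graph, QuestionSpec(kind="mcq", n_questions=20, seed=1)
        )
        save_questions(records, tmp_path / "q.json")
        loaded = load_questions(tmp_path / "q.json")
        assert len(loaded) == 20
        assert loaded == records

    def test_mcq_with_four_options_is_a_load_error(self):
        payload = json.dumps([
            {
                "id": "m1",
                "kind": "mcq",
                "text": "q?",
                "options": ["a", "b", "c", "d"],
                "correct": "a",
            }
        ])
        with pytest.raises(QuestionFormatError, match="5 options"):
            load_questions(io.StringIO(payload))

    def test_retrieval_needs_truth_set(self):
        payload = json.dumps([{"id": "r1", "kind": "retrieval", "text": "q?"}])
        with pytest.raises(QuestionFormatError, match="truth_set"):
            load_questions(io.StringIO(payload))

    def test_csv_form(self):
        csv_text = (
            "id,kind,text,options,correct,truth_set\n"
            "m1,mcq,Which gene?,a|b|c|d|e,c,\n"
        )
        records = load_questions(io.StringIO(csv_text))
        assert records[0].options == ("a", "b", "c", "d", "e")
        assert records[0].correct == "c"


class TestEvaluate:
    def test_empty_question_list(self):
        assert evaluate([], lambda q: "True") == []

    def test_option_letter_and_text_both_accepted(self):
        record = QuestionRecord(
            question_id="m1", kind="mcq", text="q?",
            options=("alpha", "beta", "gamma", "delta", "eps"), correct="beta",
        )
        assert evaluate([record], lambda q: "B") == [True]
        assert evaluate([record], lambda q: "BETA") == [True]
        assert evaluate([record], lambda q: json.dumps({"answer": "beta"})) == [True]
        assert evaluate([record], lambda q: "nonsense") == [False]

    def test_tf_case_insensitive(self):
        record = QuestionRecord(
            question_id="t1", kind="tf", text="True or False: x.", correct="True"
        )
        assert evaluate([record], lambda q: '{"answer": "true"}') == [True]
        assert evaluate([record], lambda q: "False") == [False]

    def test_fixed_option_system_scores_at_chance_on_balanced_mcq(self, big_graph):
        questions = generate_questions(
            big_graph, QuestionSpec(kind="mcq", n_questions=500, seed=23)
        )
        correctness = evaluate(questions, lambda q: q.options[0])
        accuracy = sum(correctness) / len(correctness)
        sigma = math.sqrt(0.2 * 0.8 / 500)
        assert abs(accuracy - 0.2) <= 3 * sigma


class TestBootstrap:
    def test_all_correct_gives_degenerate_distribution(self):
        summary = bootstrap_accuracy([True] * 20, seed=1)
        assert set(summary.accuracies) == {1.0}
        assert summary.std == 0.0

    def test_fixed_seed_reproduces_bitwise(self):
        correctness = [True] * 30 + [False] * 20
        a = bootstrap_accuracy(correctness, seed=99)
        b = bootstrap_accuracy(correctness, seed=99)
        assert a.accuracies == b.accuracies

    def test_mean_near_point_accuracy(self):
        correctness = [True] * 300 + [False] * 200
        summary = bootstrap_accuracy(
            correctness, sample_size=150, iterations=1000, seed=7
        )
        assert abs(summary.mean - 0.6) <= 3 * math.sqrt(0.6 * 0.4 / 150)
        assert len(summary.accuracies) == 1000
        assert summary.mean == pytest.approx(np.mean(summary.accuracies))
        assert summary.std == pytest.approx(np.std(summary.accuracies))

    def test_empty_input_errors(self):
        with pytest.raises(KGRAGError):
            bootstrap_accuracy([])


class TestJaccard:
    def test_formula(self):
        assert jaccard({"x", "y"}, {"y", "z"}) == pytest.approx(1 / 3)

    def test_identical(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_both_empty_by_convention(self):
        assert jaccard(set(), set()) == 1.0

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.frozensets(st.text(min_size=1, max_size=3), max_size=8),
        b=st.frozensets(st.text(min_size=1, max_size=3), max_size=8),
    )
    def test_symmetric_and_bounded(self, a, b):
        score = jaccard(a, b)
        assert score == jaccard(b, a)
        assert 0.0 <= score <= 1.0


class TestPerturbLowercase:
    def test_whole_text_mode(self):
        record = QuestionRecord(
            question_id="t1", kind="tf",
            text="Does VHL associate with Hypertension?", correct="True",
        )
        out = perturb_lowercase([record])
        assert out[0].text == "does vhl associate with hypertension?"
        assert out[0].question_id == "t1"

    def test_idempotent_and_count_preserving(self, synth_graph):
        records = generate_questions(
            synth_graph, QuestionSpec(kind="retrieval", n_questions=10, seed=3)
        )
        once = perturb_lowercase(records)
        twice = perturb_lowercase(once)
        assert once == twice
        assert len(once) == len(records)

    def test_entities_mode_lowercases_only_names(self):
        record = QuestionRecord(
            question_id="t1", kind="tf",
            text="Does VHL associate with Hypertension?", correct="True",
        )
        out = perturb_lowercase([record], mode="entities", entity_names=["VHL"])
        assert out[0].text == "Does vhl associate with Hypertension?"


class TestRetrievalAccuracy:
    def _questions(self, graph, n=10, seed=3):
        return generate_questions(
            graph, QuestionSpec(kind="retrieval", n_questions=n, seed=seed)
        )

    def test_exact_baseline_collapses_under_lowercasing(self, mixedcase_graph):
        questions = self._questions(mixedcase_graph, n=20)
        retriever = exact_match_retriever(
            mixedcase_graph, predicates=("ASSOCIATES_DaG",)
        )
        report = retrieval_accuracy(questions, retriever, system_name="exact")
        assert report.accuracy_original == 1.0
        assert report.accuracy_perturbed == 0.0

    def test_truth_sets_absent_from_graph_score_zero(self, synth_graph):
        questions = [
            QuestionRecord(
                question_id=f"r{i}", kind="retrieval",
                text="What genes are associated with hypertension?",
                truth_set=frozenset({f"NOT_A_NODE_{i}"}),
            )
            for i in range(5)
        ]
        retriever = exact_match_retriever(synth_graph)
        report = retrieval_accuracy(questions, retriever, mode="overlap")
        assert report.accuracy_original == 0.0

    def test_overlap_mode_is_weaker_than_subset(self, synth_graph):
        questions = self._questions(synth_graph)
        truth_plus_noise = [
            QuestionRecord(
                question_id=q.question_id, kind="retrieval", text=q.text,
                truth_set=frozenset(set(q.truth_set) | {"NOT_A_NODE"}),
            )
            for q in questions
        ]
        retriever = exact_match_retriever(synth_graph, predicates=("ASSOCIATES_DaG",))
        subset = retrieval_accuracy(truth_plus_noise, retriever, mode="subset")
        overlap = retrieval_accuracy(truth_plus_noise, retriever, mode="overlap")
        assert subset.accuracy_original == 0.0
        assert overlap.accuracy_original == 1.0

    def test_non_retrieval_questions_rejected(self):
        record = QuestionRecord(
            question_id="t1", kind="tf", text="x", correct="True"
        )
        with pytest.raises(KGRAGError):
            retrieval_accuracy([record], lambda text: set())


class _FixedUsageSystem:
    def __init__(self, counts):
        self._counts = iter(counts)

    def __call__(self, record):
        from types import SimpleNamespace

        return SimpleNamespace(token_usage=next(self._counts))


class TestTokenUsageReport:
    def _questions(self, n):
        return [
            QuestionRecord(question_id=f"t{i}", kind="tf", text="x", correct="True")
            for i in range(n)
        ]

    def test_mean_and_sem_hand_computed(self):
        report = token_usage_report(
            self._questions(3), {"sys": _FixedUsageSystem([10, 20, 30])}
        )
        assert report.mean["sys"] == 20.0
        assert report.sem["sys"] == pytest.approx(5.77, abs=0.01)

    def test_empty_question_set_errors(self):
        with pytest.raises(KGRAGError):
            token_usage_report([], {"sys": _FixedUsageSystem([])})
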