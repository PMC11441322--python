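# Methods

This note records the model implemented by `kgrag`, the parameters that
matter, the numerical choices made where the design was genuinely open,
and what the synthetic study conditions do and do not establish.

## The retrieval model

The pipeline treats grounded question answering as four composable
stages over a property graph *G* with typed nodes and attributed edges.

**Entity recognition** is a two-step contract.  Extraction maps the
question to a list of disease mention strings; the production adapter is
an LLM prompted to return JSON, and the bundled `DictionaryExtractor`
performs a case-insensitive scan over known disease names (first
appearance order, longer name wins at equal positions).  Both return the
same JSON payload shape, so the downstream code cannot tell them apart.
Linking embeds each mention and takes the argmax-cosine disease node
from a precomputed name index; there is deliberately no similarity
floor (configurable, off by default), and duplicate node hits are
deduplicated preserving order.  When extraction fails or finds nothing,
the top 5 nodes most similar to the entire question text are linked
instead.

**Context retrieval** fetches all edges incident to each linked node, in
either direction, without reorienting them — verbalization needs the
stored subject/object roles.  The quality filter has three independent
rules with these defaults:

| parameter | default | meaning |
|---|---|---|
| `min_clinical_phase` | 3 | treatment edges carrying a phase below this are dropped; edges without the attribute are unaffected |
| `require_curated_protein` | true | triples whose *neighbor* is an uncurated Protein node are dropped |
| `exclude_textmining_disease_gene` | true | Disease–Gene edges with `source_type="textmining"` are dropped |

Relaxing any single rule can only grow the result (a tested
monotonicity property).

**Verbalization** exploits the predicate schema
`UPPERCASE_NAME_` + subject initial (upper) + predicate initial (lower)
+ object initial (upper).  The default grammar is strictly one letter
per initial; real deployments with multi-letter type abbreviations can
supply an abbreviation table, under which suffixes built from any pair
of table abbreviations also parse.  The sentence rule is
`"<node_type> <name> <predicate phrase> <node_type> <name>"` with the
node-type string taken verbatim from the stored record (stored case is
rendered case) and underscores in multi-word predicate names becoming
spaces.  Provenance renders as `" (Provenance: s1, s2)"` in stored
order; evidence as `" (evidence: p-value = p, z-score = z)"` with
absent fields omitted and numbers at 6 significant digits.  The content
of these clauses is fixed by what the graph stores; their exact format
is this package's own convention.

**Pruning** embeds the question and every retrieved sentence in the same
space and keeps, per linked-node group, sentences with similarity
strictly greater than the group's 75th-percentile threshold and at
least 0.5.  Numerical choices pinned by the brute-force oracle test:

- the percentile uses linear interpolation between order statistics
  (`numpy.percentile` default);
- "greater than" is strict, so a single-sentence group never survives
  the percentile rule, and sentences tied exactly at the threshold are
  dropped;
- similarity is computed on the bare sentence — provenance/evidence
  clauses are re-attached only at prompt assembly, so they never affect
  pruning;
- the threshold distribution is per linked node, not pooled across
  nodes; the context-volume cap is applied after pooling, globally by
  similarity rank (ties by sentence text ascending).  A per-disease
  split of the volume would also be defensible for multi-disease
  questions; pooled global rank is the implemented reading.

Defaults: percentile 75, floor 0.5, context volume 150 (100 for
True/False runs).  `percentile=None` with floor 0 disables pruning while
keeping the volume cap — the configuration used wherever a test needs
the full filtered neighborhood in the prompt.

**Generation** renders system instruction, context block (pruned order,
one sentence per line), and question, counts tokens with a pluggable
tokenizer (default: each word or punctuation mark is one token), and
calls an `LLMBackend` at temperature 0.  `cited_provenance` on the
answer is computed by intersection: only provenance strings present on
the supplied context edges can ever be attributed.

## The reference embedder

Tests and offline runs use a deterministic stand-in for sentence
transformers: NFC-normalized, case-folded text is padded with `##`
boundaries and decomposed into character trigrams; each trigram is
BLAKE2b-hashed to one of 256 buckets with a hash-derived sign, and the
count vector is L2-normalized (cosine = dot product; the empty string
embeds to the zero vector with similarity 0 by convention).  It is
exactly reproducible across platforms and case-insensitive by
construction, which is what makes the lowercase-robustness property
hold exactly rather than approximately.  It is *not* a semantic model:
similarity reflects shared character n-grams, so synonyms score low and
near-identical sentences score nearly identically.  One visible
consequence: sentences that differ only in an entity name the question
does not mention get *exactly* equal similarities, and a group whose
top scores all tie is wiped out by the strict-greater percentile rule.
Real sentence embedders produce ties with probability zero, so this is
an artifact of the stand-in, not of the rule.

## Mock backends

Three deterministic backends close the loop without a language model:
`ContextEchoBackend` (returns the context block verbatim — used for
provenance-fidelity and token accounting), `MCQLookupBackend` (answers
with the first option whose text occurs in the context; with no match
it picks by a BLAKE2b hash of the prompt, so identical inputs give
identical outputs while a question set scores at the 1-in-5 chance
level), and `TFLookupBackend` (answers True iff the asserted sentence
occurs in the context).  The hash fallback was chosen over a seeded RNG
precisely to keep the backend stateless and repeat-call identical at
temperature 0.

## Synthetic study conditions

The generator emulates the *structure* retrieval depends on: unique
mixed-case names (`Disease_0001`, plus a configurable list of real
names such as `hypertension` and `VHL` seeded in by default), schema
predicates `ASSOCIATES_DaG` / `TREATS_CtD` / `ASSOCIATES_DaP`, per-edge
provenance drawn from named source lists, p-values uniform on
(0, 0.05] and z-scores Normal(4, 1) on disease–gene edges, clinical
phases on treatment edges (weights 0.1/0.1/0.2/0.3/0.3 over phases
0–4), a 30% text-mined fraction of disease–gene edges, and a 70%
curated fraction of protein nodes.  Defaults: 30 diseases, 120 genes,
40 compounds, 30 proteins, with 6/3/2 disease–gene/treatment/protein
associations per disease.  Question sets are derived from the generated
graph, so ground truth is correct by construction: True/False sets are
balanced (negatives rewire to a gene with no edge of any source type to
the disease), MCQ distractors are unlinked same-type nodes, and
retrieval truth sets are exactly the filtered associated gene names.

What passing tests show: the stages compose correctly (a lookup mock
achieves 100% when the true association is retrievable and falls to
chance when the context volume is 0), pruning implements its stated
rule exactly, retrieval is invariant to question case while an
exact-string baseline collapses, and pruning strictly reduces token
usage.  What they do not show: anything about linguistic
generalization, paraphrase robustness, real-model answer quality, or
the biological validity of retrieved facts — those depend on the
production embedders, LLMs and graph content that plug in behind the
contracts.

Problem sizes: the statistics-heavy checks run on a 100-disease /
300-gene graph with 8 associations per disease (≈560 filtered
disease–gene pairs), 500-question MCQ sets for binomial checks, 100
retrieval questions for the robustness comparison, and 300-question
sets bootstrapped at 150 draws × 1000 iterations in the acceptance
script.  The robustness and acceptance runs generate the graph with the
real-name list empty: the property "exact matching scores zero after
lower-casing" requires that no graph name be all-lowercase already,
which the default inclusion of `hypertension` would violate.

## Evaluation conventions

- Bootstrap: one seeded `numpy` generator, independent draws, accuracy
  per iteration; the reported std is the population standard deviation
  of the bootstrap distribution.
- `jaccard(∅, ∅) = 1.0` (perfect agreement on nothing); the case never
  arises in generated sets, whose truth sets are non-empty.
- Retrieval correctness defaults to subset containment of the truth set
  (an any-overlap mode is exposed); the volume sweep restricts retrieval
  to `ASSOCIATES_DaG` sentences so the retrieved set grows within the
  ground-truth universe and mean Jaccard is monotone in the volume.
- MCQ answer parsing accepts the option letter (A–E) or the option
  text, case-insensitively, from a JSON `answer` field or raw text;
  anything else is incorrect and logged.
- Token usage counts prompt plus completion with the same tokenizer.

## Known limitations

- One-hop neighborhoods only; no multi-hop path retrieval.
- Disease-centric by default: only disease names are indexed for entity
  linking, though the node-type list is configurable.
- The strict-greater percentile rule interacts with tied similarity
  scores (see above); under the trigram embedder, questions that do not
  name a specific neighbor may prune an entire uniform-similarity group.
- The exact sentence formats of production SPOKE deployments (REST field
  names, provenance encodings) vary; the REST adapter maps them through
  a configurable field map and is not exercised against a live service.
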