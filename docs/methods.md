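# Methods

This note documents the modelling choices behind `sipnet`, the parameters
that matter, and what the synthetic-data tests do and do not demonstrate.

## Pipeline overview

1. **Corpus reading and sentence segmentation** (`corpus_io`). Abstracts are
   read from TSV (`doc_id`, `title`, `abstract`) or MEDLINE-tagged text
   (`PMID- `, `TI  - `, `AB  - ` with continuation lines). Sentences are
   cut by a deterministic rule: a run of `.?!` followed by whitespace ends a
   sentence when the next non-space character is uppercase or a digit and
   the preceding text does not end in a stop-listed abbreviation
   (`et al.`, `Fig.`, `vs.`, `e.g.`, ...). Offsets are 0-based, half-open,
   in characters, so spans slice the abstract exactly. A rule-based splitter
   was chosen over a learned model purely for reproducibility; segmentation
   conventions are pinned by this package, and texts whose sentence
   boundaries defeat the rules (unusual abbreviations, lowercase sentence
   starts) will be under-split, which can only *strengthen* an evidence type
   (two sentences misread as one can turn a type-4 pair into type 3), never
   invent a pair.

2. **Dictionary tagging** (`entity_tagging`). Mentions are matched exactly
   against lexicon surface forms (canonical symbols and synonyms),
   case-insensitively, anchored at word boundaries defined as
   non-alphanumeric neighbours — gene symbols are case-variant in prose,
   but `TP53` must not match inside `TP533`. Overlapping candidates are
   resolved longest-match-first, then leftmost, then by canonical symbol,
   so multiword disease names beat symbols embedded in them and the result
   is deterministic. Lexicons in which one surface form maps to two
   canonicals are rejected outright rather than disambiguated. Limitations,
   by design: no learned NER, no abbreviation/long-form expansion, no
   species-prefix disambiguation — a mention is tagged only if it literally
   matches the dictionary. An optional species filter restricts the lexicon
   (e.g. to *Homo sapiens*) before tagging.

3. **Evidence typing** (`cooccurrence`). Each document contributes at most
   one evidence per pair — the strongest type found — because the four
   types form a hierarchy, not independent events. "Interaction term
   between the names" is read strictly: the term's span must start at or
   after the end of the earlier mention and end at or before the start of
   the later one, within one sentence. Term matching is case-insensitive
   whole-word against a configurable list; the shipped default
   (`activates`, `activation`, `inhibits`, `inhibition`, `induces`,
   `binds`, `regulates`, `suppresses`, `phosphorylates`, `interacts`) is a
   minimal vocabulary of common interaction verbs/nominals and should be
   replaced with a domain list for real corpora. Negated statements are not
   handled: "A does not bind B" is typed like its affirmative form.
   Cross-document co-occurrence is never counted.

4. **Aggregation and filtering.** Per-pair tallies across the corpus give an
   edge record: counts by type, total supporting documents (the *relevance
   rate*), and a confidence equal to the **maximum** score observed. Max
   rather than mean or sum keeps the aggregate on the four-level weight
   grid {1, 0.75, 0.5, 0.25}, which is what the influence model expects as
   edge probabilities. The default relevance-rate filter removes pairs
   supported by ≤ 5 documents (strictly-greater-than-5 survival). An
   optional confidence cutoff exists (e.g. ≥ 0.90) but defaults to off:
   applied literally it would delete every non-type-1 edge and collapse the
   four-level weighting the influence step depends on, so it is exposed as
   a deliberate, visible choice rather than a default.

5. **Graph.** Undirected, no self-loops, node colors from the lexicon, edge
   weight = record confidence, weights in (0, 1]. Weight 1 is allowed:
   type-1 evidence maps to probability 1, and a zero-weight edge would
   simply not exist.

## Expression-based adjacency

`soft_threshold_adjacency` computes `a_ij = |cor(x_i, x_j)|**beta` from a
genes × samples matrix with Pearson correlation. The unsigned (absolute
value) convention is used because fractional powers of negative numbers are
undefined; `beta` defaults to 1 and must be positive. Zero-variance genes
have undefined correlations and are dropped with a warning; the diagonal is
set to 0. This operation stands alone: nothing in the pipeline fuses it with
the literature graph, and no default `beta` calibration is implied.

## Influence model

**SIP.** The influence of `u` on `v` is the maximum over connecting paths of
the product of edge probabilities, with `sip(u, u) = 1` and 0 for
unreachable pairs. It is computed as one Dijkstra search per source on
costs `-log w` (all nonnegative because `w <= 1`); the probability is then
re-multiplied along the returned path, so reported values are exact products
of edge weights rather than `exp` of summed logs. On the four-level grid
distinct path products are separated by far more than float rounding, so
the search agrees with exhaustive path enumeration to machine precision
(asserted over 200 random graphs in the tests).

**Node and set influence.** The influence of a single node is the sum of its
SIP probabilities over eligible targets — the simplest scalar consistent
with sorting nodes by influence. The combined influence of a seed set on
one target aggregates per-seed SIP values with a noisy-OR
(`1 - prod(1 - sigma)`), treating the seeds' strongest paths as independent
channels; a plain `max` aggregator is available for a conservative reading.
Both aggregators and the influence sum are reconstructions of informally
stated quantities and are configurable rather than asserted as canonical.
Set influence is summed over eligible targets **outside** the seed set
("influence on the other nodes"), so with `s = |V|` the final influence is
0 by construction.

**Greedy selection.** Iteration 1 picks the argmax of node influence; each
later iteration adds the candidate whose inclusion maximizes the combined
influence of the enlarged set on the remaining targets. All ties break
lexicographically by node id, making runs deterministic. Two consequences
of excluding seeds from the target set deserve a note:

* The influence *trace* is not guaranteed monotone in general — when a new
  seed was itself a heavily-influenced target, its removal from the target
  sum can outweigh the gains (a 3-leaf star with two seeds is a minimal
  example). On sparse graphs at the scales exercised here the trace is
  nondecreasing in practice, and the paper-scale test asserts it for that
  instance only, not as a universal law.
* The exclude-seeds objective differs from the noisy-OR coverage objective
  (which counts each seed as a fully-influenced target) by exactly the
  constant |S| whenever all candidates are target-eligible, so the greedy
  *selection order* coincides with the classical monotone-submodular
  coverage greedy and inherits its quality in practice. The (1 − 1/e)
  optimality ratio is asserted empirically against exhaustive subset search
  on all oracle-sized test instances rather than claimed as a theorem for
  the exclude-seeds value.

**Colored queries.** `query_influencers` fixes the target set (e.g. two
disease nodes) and greedily selects k sources of a given color, summing
influence over the fixed targets only; swapping colors answers the reverse
question. `suite_relevance` scores a (gene suite, disease suite) pair as
the sum over diseases of the combined influence of the gene suite — a
reconstruction chosen for consistency with the ranking use-case; the
significance cutoff applied to such scores is left to the caller.

**Oracles.** `brute_force_sip` enumerates all simple paths and
`brute_force_seeds` searches all seed subsets; both refuse graphs above a
cap (default 10 nodes), where exhaustive search is still instant.

## Synthetic data

`generate_corpus` plants typed pair evidence using fixed sentence templates
— one planted evidence per document, so no incidental abstract-level
co-occurrence between unrelated pairs can arise — plus distractor sentences
that never mention a lexicon symbol (some deliberately contain an
interaction term, which must not upgrade any evidence type). The template
for each type realizes exactly that type under the classifier's rules, so
the returned ground-truth edge table is what a correct extractor must
produce, and end-to-end recovery is tested as exact equality with 100%
pair-level precision and recall. `generate_graph` draws a uniform random
simple graph with weights on the confidence grid and colors apportioned by
largest remainder. Seeds are mandatory everywhere; the same seed reproduces
outputs byte for byte.

What this does **not** show: robustness to real prose. Synthetic text has
no tagger errors, no ambiguous symbols, no negations, no paraphrase —
passing the recovery tests demonstrates that the typing/aggregation logic
is internally correct, not that the pipeline's precision on PubMed
abstracts matches any published figure.

## Problem sizes and defaults

| parameter | default | meaning |
|---|---|---|
| `min_count` | 5 | relevance-rate cutoff; pairs with ≤ 5 supporting docs dropped |
| `min_confidence` | off | optional edge-confidence floor (0.90 would keep only type-1 edges) |
| `aggregator` | `noisy_or` | combination of per-seed SIP values on a target |
| `num_seeds` | 2 (CLI) | seed-set size; 2–5 is the exercised range |
| `beta` | 1.0 | soft-threshold exponent for expression adjacency |
| oracle cap | 10 nodes | upper size for brute-force oracles |

The test suite exercises oracle equivalence on 200 random graphs of ≤ 8
nodes, greedy quality for s ∈ {2, 3} against exhaustive search on the same
instances, and whole-graph selection with s = 2..5 on a synthetic
487-node / 1626-edge instance (the scale of the motivating gastrointestinal
cancer network), which completes in a few seconds on one CPU.
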