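"""Synthetic corpora with planted typed co-occurrences, and random colored graphs.

Every stage of the pipeline is testable without any external download:
``generate_corpus`` writes template sentences that realize exactly the
requested evidence type for each planted pair, alongside the edge table a
correct extractor must recover; ``generate_graph`` draws a random simple
undirected graph with weights on the four-level confidence grid and colors
assigned by fractions.

Templates, not free text: the ground truth has to be unambiguous under the
typing rules, so each document carries exactly one planted pair (avoiding
incidental abstract-level co-occurrences between unrelated pairs) plus
distractor sentences that mention no lexicon symbol.  A required random
seed makes every output reproducible byte for byte.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .cooccurrence import CoocGraph, EdgeRecord, SCORE_BY_TYPE
from .corpus_io import Document, InteractionTerms, Lexicon, LexiconEntry, split_sentences
from .errors import ValidationError

__all__ = ["PlantedPair", "CorpusSpec", "GraphSpec",
           "generate_corpus", "generate_graph"]


@dataclass(frozen=True)
class PlantedPair:
    a: str
    b: str
    etype: int
    num_docs: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class CorpusSpec:
    num_docs: int
    gene_symbols: list[str]
    disease_symbols: list[str]
    planted_pairs: list[PlantedPair]
    random_seed: int
    distractor_sentences_per_doc: int = 1
    species: str = "Homo sapiens"

    def validate(self) -> None:
        symbols = self.gene_symbols + self.disease_symbols
        if len(set(symbols)) != len(symbols):
            raise ValidationError("symbols must be unique across colors")
        known = set(symbols)
        for p in self.planted_pairs:
            if p.etype not in SCORE_BY_TYPE:
                raise ValidationError(f"planted etype {p.etype} outside 1..4")
            if p.a == p.b:
                raise ValidationError(f"planted self-pair {p.a!r}")
            if p.a not in known or p.b not in known:
                raise ValidationError(f"planted pair ({p.a},{p.b}) uses unknown symbols")
            if p.num_docs < 1:
                raise ValidationError("each planted pair needs >= 1 supporting doc")
        total = sum(p.num_docs for p in self.planted_pairs)
        if total > self.num_docs:
            raise ValidationError(
                f"{total} planted evidences do not fit in {self.num_docs} documents"
            )


# Each template realizes exactly its type under the classifier's rules:
# the type-1 sentence puts the term strictly between the mentions; the
# type-2 sentence has the term before both; type 3 shares a sentence with
# no term; type 4 separates the mentions into different sentences.
_TEMPLATES = {
    1: ["{a} activates {b}."],
    2: ["Activation of {a} and {b} was detected."],
    3: ["{a} and {b} were quantified together."],
    4: ["{a} was profiled in the discovery cohort.",
        "Independent profiling covered {b} as well."],
}

_SYNTHETIC_TERMS = InteractionTerms(("activates", "activation", "inhibits",
                                     "induces", "binds"))

# Distractors never mention a symbol; some carry an interaction term on
# purpose, which must not upgrade any planted evidence type.
_DISTRACTORS = [
    "The cohort was followed for two years.",
    "Samples were processed with a standard protocol.",
    "Strong activation was reported in unrelated assays.",
    "Statistical review found no batch effects.",
    "The replication arm used an independent platform.",
]


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], Lexicon,
                                               InteractionTerms, list[EdgeRecord]]:
    """Generate (documents, lexicon, interaction terms, planted edge table)."""
    spec.validate()
    rng = random.Random(spec.random_seed)

    entries = [LexiconEntry(sym, (f"syn{sym}",), "gene", spec.species)
               for sym in spec.gene_symbols]
    entries += [LexiconEntry(sym, (f"syn{sym}",), "disease", spec.species)
                for sym in spec.disease_symbols]
    lexicon = Lexicon(entries)

    # one planted evidence per document, in shuffled document slots
    slots = list(range(spec.num_docs))
    rng.shuffle(slots)
    planted_sentences: dict[int, list[str]] = {}
    assigned = 0
    for p in spec.planted_pairs:
        for _ in range(p.num_docs):
            planted_sentences[slots[assigned]] = [
                t.format(a=p.a, b=p.b) for t in _TEMPLATES[p.etype]
            ]
            assigned += 1

    docs: list[Document] = []
    for i in range(spec.num_docs):
        sentences = list(planted_sentences.get(i, []))
        for _ in range(spec.distractor_sentences_per_doc):
            sentences.append(rng.choice(_DISTRACTORS))
        rng.shuffle(sentences)
        if not sentences:
            sentences = [rng.choice(_DISTRACTORS)]
        abstract = " ".join(sentences)
        doc = Document(doc_id=f"SYN{i:05d}", title=f"Synthetic abstract {i}",
                       abstract=abstract, sentences=split_sentences(abstract))
        doc.validate()
        docs.append(doc)

    truth: dict[tuple[str, str], dict[int, int]] = {}
    for p in spec.planted_pairs:
        counts = truth.setdefault(p.pair, {})
        counts[p.etype] = counts.get(p.etype, 0) + p.num_docs
    records = [
        EdgeRecord(pair, sum(counts.values()), dict(sorted(counts.items())),
                   max(SCORE_BY_TYPE[t] for t in counts))
        for pair, counts in sorted(truth.items())
    ]
    return docs, lexicon, _SYNTHETIC_TERMS, records


@dataclass
class GraphSpec:
    num_nodes: int
    num_edges: int
    random_seed: int
    weight_levels: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    color_fractions: dict[str, float] = field(
        default_factory=lambda: {"gene": 1.0})

    def validate(self) -> None:
        max_edges = self.num_nodes * (self.num_nodes - 1) // 2
        if not 0 <= self.num_edges <= max_edges:
            raise ValidationError(
                f"{self.num_edges} edges infeasible for {self.num_nodes} nodes "
                f"(max {max_edges})"
            )
        if not set(self.weight_levels) <= {0.25, 0.5, 0.75, 1.0}:
            raise ValidationError("weight levels must lie on the confidence grid")
        if not self.weight_levels:
            raise ValidationError("need at least one weight level")
        if abs(sum(self.color_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("color fractions must sum to 1")


def _color_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n nodes to colors."""
    floors = {c: int(f * n) for c, f in fractions.items()}
    remainder = n - sum(floors.values())
    by_frac = sorted(fractions, key=lambda c: (-(fractions[c] * n - floors[c]), c))
    for c in by_frac[:remainder]:
        floors[c] += 1
    return floors


def generate_graph(spec: GraphSpec) -> CoocGraph:
    """Random simple undirected colored graph with grid weights."""
    spec.validate()
    rng = random.Random(spec.random_seed)
    counts = _color_counts(spec.color_fractions, spec.num_nodes)
    width = len(str(max(spec.num_nodes - 1, 0)))
    nodes: list[tuple[str, str]] = []
    i = 0
    for color in sorted(counts):
        for _ in range(counts[color]):
            nodes.append((f"{color}{i:0{width}d}", color))
            i += 1
    g = nx.Graph()
    for name, color in nodes:
        g.add_node(name, color=color)
    names = [name for name, _ in nodes]
    all_pairs = list(itertools.combinations(names, 2))
    levels = sorted(spec.weight_levels)
    for u, v in rng.sample(all_pairs, spec.num_edges):
        g.add_edge(u, v, weight=rng.choice(levels))
    cg = CoocGraph(g)
    cg.validate()
    return cg
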