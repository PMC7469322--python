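"""Typed co-occurrence evidence, corpus-level aggregation and graph building.

A pair of tagged entities in one document yields at most one piece of
evidence, the strongest of four hierarchical types:

* type 1 — both entities share a sentence with an interaction term strictly
  between the two mentions (confidence 1.0);
* type 2 — both share a sentence that contains an interaction term anywhere
  (confidence 0.75);
* type 3 — both share a sentence with no interaction term (confidence 0.5);
* type 4 — both occur in the abstract but never in the same sentence
  (confidence 0.25).

Evidence is aggregated per pair across the corpus into edge records (the
number of supporting documents is the pair's relevance rate), filtered, and
turned into an undirected colored graph whose edge weights are the
confidences, interpreted downstream as probabilities of influence.
Negated statements are not treated specially, and co-occurrence across
documents is never counted.

The module also houses the expression-based soft-threshold adjacency
``a_ij = |cor(x_i, x_j)|**beta`` as a standalone operation.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .corpus_io import Document, InteractionTerms, Lexicon
from .entity_tagging import TaggedEntity, distinct_pairs, tag_corpus
from .errors import ValidationError, FormatError

__all__ = [
    "SCORE_BY_TYPE",
    "DEFAULT_INTERACTION_TERMS",
    "CoocEvidence",
    "EdgeRecord",
    "CoocGraph",
    "ExpressionAdjacency",
    "classify_pair_in_document",
    "extract_evidence",
    "aggregate_evidence",
    "filter_edges",
    "build_graph",
    "soft_threshold_adjacency",
    "precision_recall",
    "read_evidence_tsv",
    "write_evidence_tsv",
    "read_expression",
]

#: Fixed confidence score for each evidence type; no other values ever appear.
SCORE_BY_TYPE: dict[int, float] = {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.25}

#: Default interaction vocabulary; fully overrideable by the caller.
DEFAULT_INTERACTION_TERMS = InteractionTerms((
    "activates", "activation", "inhibits", "inhibition", "induces",
    "binds", "regulates", "suppresses", "phosphorylates", "interacts",
))


@dataclass(frozen=True)
class CoocEvidence:
    """One document's strongest evidence for one unordered pair."""

    doc_id: str
    pair: tuple[str, str]
    etype: int
    score: float

    def __post_init__(self) -> None:
        if self.etype not in SCORE_BY_TYPE:
            raise ValidationError(f"evidence type {self.etype} outside 1..4")
        if self.score != SCORE_BY_TYPE[self.etype]:
            raise ValidationError(
                f"score {self.score} does not match type {self.etype}"
            )
        if self.pair[0] >= self.pair[1]:
            object.__setattr__(self, "pair", (self.pair[1], self.pair[0]))


@dataclass
class EdgeRecord:
    """Corpus-level evidence for one pair.

    ``count_total`` is the number of supporting documents (the relevance
    rate); ``confidence`` is the best score seen across documents, so it
    always lands on the four-level grid.
    """

    pair: tuple[str, str]
    count_total: int
    counts_by_type: dict[int, int]
    confidence: float

    def __post_init__(self) -> None:
        if self.pair[0] >= self.pair[1]:
            self.pair = (self.pair[1], self.pair[0])
        if self.count_total != sum(self.counts_by_type.values()):
            raise ValidationError(
                f"edge {self.pair}: count_total != sum of per-type counts"
            )
        if self.confidence not in SCORE_BY_TYPE.values():
            raise ValidationError(
                f"edge {self.pair}: confidence {self.confidence} off the score grid"
            )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _term_spans(text: str, terms: InteractionTerms) -> list[tuple[int, int]]:
    spans = []
    for term in terms.terms:
        pat = re.compile(r"(?<![A-Za-z0-9])" + re.escape(term) + r"(?![A-Za-z0-9])",
                         re.IGNORECASE)
        spans.extend((m.start(), m.end()) for m in pat.finditer(text))
    return spans


def classify_pair_in_document(
    doc: Document,
    entities: Sequence[TaggedEntity],
    pair: tuple[str, str],
    terms: InteractionTerms = DEFAULT_INTERACTION_TERMS,
) -> CoocEvidence | None:
    """Return the strongest evidence type for ``pair`` in ``doc``, or ``None``.

    "Strictly between" for type 1 means the term's span starts at or after
    the end of the earlier mention and ends at or before the start of the
    later one, within the same sentence.
    """
    a, b = sorted(pair)
    if a == b:
        raise ValidationError("pair members must be distinct")
    occ_a: dict[int, list[TaggedEntity]] = {}
    occ_b: dict[int, list[TaggedEntity]] = {}
    for e in entities:
        if e.canonical == a:
            occ_a.setdefault(e.sentence_index, []).append(e)
        elif e.canonical == b:
            occ_b.setdefault(e.sentence_index, []).append(e)
    if not occ_a or not occ_b:
        return None

    best: int | None = None
    for si in sorted(set(occ_a) & set(occ_b)):
        spans = _term_spans(doc.sentences[si].text, terms)
        if spans:
            between = any(
                t_start >= min(ea, eb, key=lambda e: e.start).end
                and t_end <= max(ea, eb, key=lambda e: e.start).start
                for ea in occ_a[si]
                for eb in occ_b[si]
                for t_start, t_end in spans
            )
            etype = 1 if between else 2
        else:
            etype = 3
        best = etype if best is None else min(best, etype)
        if best == 1:
            break
    if best is None:
        best = 4  # both present in the abstract, never in one sentence
    return CoocEvidence(doc.doc_id, (a, b), best, SCORE_BY_TYPE[best])


def extract_evidence(
    docs: Sequence[Document],
    lexicon: Lexicon,
    terms: InteractionTerms = DEFAULT_INTERACTION_TERMS,
) -> list[CoocEvidence]:
    """Tag every document and classify every distinct pair it mentions."""
    tagged = tag_corpus(docs, lexicon)
    evidences: list[CoocEvidence] = []
    for doc in docs:
        entities = tagged[doc.doc_id]
        for pair in distinct_pairs(entities):
            ev = classify_pair_in_document(doc, entities, pair, terms)
            if ev is not None:
                evidences.append(ev)
    return evidences


# ---------------------------------------------------------------------------
# aggregation and filtering
# ---------------------------------------------------------------------------

def aggregate_evidence(evidences: Iterable[CoocEvidence]) -> list[EdgeRecord]:
    """Tally evidence per pair across documents.

    Each document may contribute at most one evidence per pair; the record's
    confidence is the maximum score observed, keeping aggregates on the
    four-level weight grid.
    """
    seen: set[tuple[str, tuple[str, str]]] = set()
    by_pair: dict[tuple[str, str], dict[int, int]] = {}
    for ev in evidences:
        key = (ev.doc_id, ev.pair)
        if key in seen:
            raise ValidationError(
                f"duplicate evidence for pair {ev.pair} in document {ev.doc_id!r}"
            )
        seen.add(key)
        counts = by_pair.setdefault(ev.pair, {})
        counts[ev.etype] = counts.get(ev.etype, 0) + 1
    records = []
    for pair in sorted(by_pair):
        counts = by_pair[pair]
        confidence = max(SCORE_BY_TYPE[t] for t in counts)
        records.append(EdgeRecord(pair, sum(counts.values()), dict(sorted(counts.items())),
                                  confidence))
    return records


def filter_edges(
    records: Iterable[EdgeRecord],
    min_count: int = 5,
    min_confidence: float | None = None,
) -> list[EdgeRecord]:
    """Keep pairs supported by strictly more than ``min_count`` documents
    (pairs with a relevance rate <= ``min_count`` are removed) and, when set,
    with confidence >= ``min_confidence``."""
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    return [
        r for r in records
        if r.count_total > min_count
        and (min_confidence is None or r.confidence >= min_confidence)
    ]


# ---------------------------------------------------------------------------
# graph
# ---------------------------------------------------------------------------

_EDGELIST_COLUMNS = (
    "source", "target", "weight", "count_total",
    "count_type1", "count_type2", "count_type3", "count_type4",
    "color_source", "color_target",
)


@dataclass
class CoocGraph:
    """Undirected colored graph; edge weights in (0, 1] are influence
    probabilities (a zero-influence edge would simply not exist)."""

    graph: nx.Graph

    def validate(self) -> None:
        for n, data in self.graph.nodes(data=True):
            if "color" not in data:
                raise ValidationError(f"node {n!r} has no color")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            w = data.get("weight")
            if w is None or not (0.0 < w <= 1.0):
                raise ValidationError(f"edge ({u!r},{v!r}) weight {w} outside (0,1]")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def color(self, node: str) -> str:
        return self.graph.nodes[node]["color"]

    def nodes_of_color(self, color: str) -> list[str]:
        if color == "all":
            return sorted(self.graph.nodes)
        return sorted(n for n, d in self.graph.nodes(data=True) if d["color"] == color)

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_EDGELIST_COLUMNS)
            for u, v in sorted(map(sorted, self.graph.edges)):
                data = self.graph.edges[u, v]
                rec: EdgeRecord | None = data.get("record")
                counts = rec.counts_by_type if rec else {}
                writer.writerow([
                    u, v, repr(data["weight"]),
                    rec.count_total if rec else 1,
                    *(counts.get(t, 0) for t in (1, 2, 3, 4)),
                    self.color(u), self.color(v),
                ])

    @classmethod
    def read_edgelist(cls, path: str | Path) -> "CoocGraph":
        g = nx.Graph()
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or "source" not in reader.fieldnames:
                raise FormatError(f"{path}: not an edge-list TSV")
            for i, row in enumerate(reader, start=2):
                try:
                    u, v = row["source"], row["target"]
                    weight = float(row["weight"])
                    counts = {t: int(row.get(f"count_type{t}", 0) or 0)
                              for t in (1, 2, 3, 4)}
                    total = int(row.get("count_total", 1) or 1)
                except (KeyError, TypeError, ValueError) as exc:
                    raise FormatError(f"{path}: line {i}: bad edge record") from exc
                record = None
                if sum(counts.values()) == total:
                    record = EdgeRecord((min(u, v), max(u, v)), total, counts,
                                        max((SCORE_BY_TYPE[t] for t, c in counts.items() if c),
                                            default=weight))
                g.add_node(u, color=row.get("color_source", "gene"))
                g.add_node(v, color=row.get("color_target", "gene"))
                g.add_edge(u, v, weight=weight, record=record)
        cg = cls(g)
        cg.validate()
        return cg


def build_graph(records: Sequence[EdgeRecord], lexicon: Lexicon) -> CoocGraph:
    """Build the weighted colored graph; edge weight = record confidence."""
    colors = {e.canonical: e.color for e in lexicon.entries}
    g = nx.Graph()
    for rec in records:
        for node in rec.pair:
            if node not in colors:
                raise ValidationError(f"edge endpoint {node!r} missing from lexicon")
            g.add_node(node, color=colors[node])
        g.add_edge(*rec.pair, weight=rec.confidence, record=rec)
    cg = CoocGraph(g)
    cg.validate()
    return cg


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def precision_recall(
    predicted: Sequence[EdgeRecord],
    truth: Sequence[EdgeRecord],
) -> tuple[float, float]:
    """Pair-level precision and recall of a predicted edge table against a
    reference table.  An empty prediction has precision 1 by convention."""
    pred_pairs = {r.pair for r in predicted}
    true_pairs = {r.pair for r in truth}
    tp = len(pred_pairs & true_pairs)
    precision = tp / len(pred_pairs) if pred_pairs else 1.0
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall


# ---------------------------------------------------------------------------
# expression adjacency
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAdjacency:
    """Soft-threshold connection strengths ``a_ij = |s_ij|**beta`` from a
    genes x samples expression matrix, with ``s`` the Pearson correlation."""

    genes: list[str]
    s: pd.DataFrame
    a: pd.DataFrame
    beta: float
    dropped: list[str] = field(default_factory=list)


def soft_threshold_adjacency(X: pd.DataFrame, beta: float = 1.0) -> ExpressionAdjacency:
    """Compute the soft-threshold adjacency of a genes x samples matrix.

    The unsigned convention ``|s|**beta`` is used because fractional powers
    of negative correlations are undefined.  Zero-variance genes have no
    defined correlation; they are dropped with a warning.  The diagonal is
    excluded (set to 0) since self-adjacency carries no information.
    """
    if beta <= 0:
        raise ValidationError("beta must be positive")
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 samples per gene")
    variances = X.var(axis=1)
    dropped = list(X.index[variances == 0.0])
    if dropped:
        warnings.warn(
            f"excluding zero-variance genes with undefined correlations: {dropped}",
            UserWarning,
            stacklevel=2,
        )
        X = X.drop(index=dropped)
    genes = list(X.index)
    s = np.corrcoef(X.to_numpy(dtype=float))
    s = np.atleast_2d(s)
    a = np.abs(s) ** beta
    np.fill_diagonal(a, 0.0)
    return ExpressionAdjacency(
        genes=genes,
        s=pd.DataFrame(s, index=genes, columns=genes),
        a=pd.DataFrame(a, index=genes, columns=genes),
        beta=beta,
        dropped=dropped,
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples numeric TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# evidence I/O
# ---------------------------------------------------------------------------

def write_evidence_tsv(evidences: Sequence[CoocEvidence], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "geneA", "geneB", "etype", "score"])
        for ev in evidences:
            writer.writerow([ev.doc_id, ev.pair[0], ev.pair[1], ev.etype, ev.score])


def read_evidence_tsv(path: str | Path) -> list[CoocEvidence]:
    evidences = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "etype" not in reader.fieldnames:
            raise FormatError(f"{path}: not an evidence TSV")
        for i, row in enumerate(reader, start=2):
            try:
                evidences.append(CoocEvidence(
                    row["doc_id"], (row["geneA"], row["geneB"]),
                    int(row["etype"]), float(row["score"]),
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}: line {i}: bad evidence record") from exc
    return evidences
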