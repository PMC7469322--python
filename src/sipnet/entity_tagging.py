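"""Dictionary-based recognition of gene/disease mentions in sentences.

Matching is exact against the lexicon's surface forms (canonical symbols and
synonyms), case-insensitive and anchored at word boundaries, where a
boundary means the neighbouring character is not alphanumeric.  When
candidate matches overlap, the longer match wins, then the leftmost, so a
specific multiword disease name beats any symbol embedded inside it.  Every
match is normalized to its canonical symbol.

Abbreviation/long-form expansion is not attempted: a mention is tagged only
if it literally matches a lexicon surface form.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Document, Lexicon

__all__ = ["TaggedEntity", "EntityMatcher", "tag_entities", "tag_corpus",
           "distinct_pairs", "write_tagged_tsv"]


@dataclass(frozen=True)
class TaggedEntity:
    """One normalized mention; offsets are within the sentence, 0-based half-open."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    mention: str
    canonical: str
    color: str


class EntityMatcher:
    """Compiled matcher for a lexicon; build once, tag many documents."""

    def __init__(self, lexicon: Lexicon):
        self._patterns: list[tuple[re.Pattern[str], str, str]] = []
        for surface, (canonical, color) in lexicon.surface_map().items():
            pat = re.compile(
                r"(?<![A-Za-z0-9])" + re.escape(surface) + r"(?![A-Za-z0-9])",
                re.IGNORECASE,
            )
            self._patterns.append((pat, canonical, color))

    def find(self, text: str) -> list[tuple[int, int, str, str]]:
        """Non-overlapping matches in ``text`` as (start, end, canonical, color),
        resolved longest-match-first, then leftmost, then by canonical symbol."""
        candidates: list[tuple[int, int, str, str]] = []
        for pat, canonical, color in self._patterns:
            for m in pat.finditer(text):
                candidates.append((m.start(), m.end(), canonical, color))
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
        chosen: list[tuple[int, int, str, str]] = []
        occupied: list[tuple[int, int]] = []
        for start, end, canonical, color in candidates:
            if any(start < e and s < end for s, e in occupied):
                continue
            occupied.append((start, end))
            chosen.append((start, end, canonical, color))
        chosen.sort(key=lambda c: c[0])
        return chosen


def tag_entities(doc: Document, lexicon: Lexicon,
                 matcher: EntityMatcher | None = None) -> list[TaggedEntity]:
    """Tag all lexicon mentions in ``doc``, sentence by sentence."""
    matcher = matcher or EntityMatcher(lexicon)
    entities: list[TaggedEntity] = []
    for si, sentence in enumerate(doc.sentences):
        for start, end, canonical, color in matcher.find(sentence.text):
            entities.append(TaggedEntity(
                doc_id=doc.doc_id, sentence_index=si, start=start, end=end,
                mention=sentence.text[start:end], canonical=canonical, color=color,
            ))
    return entities


def tag_corpus(docs: Sequence[Document], lexicon: Lexicon) -> dict[str, list[TaggedEntity]]:
    """Tag every document with a shared compiled matcher; doc_id -> entities."""
    matcher = EntityMatcher(lexicon)
    return {d.doc_id: tag_entities(d, lexicon, matcher) for d in docs}


def distinct_pairs(entities: Iterable[TaggedEntity]) -> list[tuple[str, str]]:
    """Unordered pairs of distinct canonicals mentioned in one document.

    Self-pairs are excluded and duplicates collapse; pairs come back sorted
    with each pair's members in lexicographic order.
    """
    canonicals = sorted({e.canonical for e in entities})
    return [(a, b) for i, a in enumerate(canonicals) for b in canonicals[i + 1:]]


def write_tagged_tsv(entities: Sequence[TaggedEntity], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "sentence_index", "start", "end",
                        "mention", "canonical", "color"])
        for e in entities:
            writer.writerow([e.doc_id, e.sentence_index, e.start, e.end,
                             e.mention, e.canonical, e.color])
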