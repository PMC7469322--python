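"""Reading, writing and validating abstract corpora, lexicons and term lists.

The pipeline consumes three kinds of input: a corpus of titled abstracts
(tab-separated or MEDLINE-tagged text), an entity lexicon mapping canonical
gene/disease symbols and their synonyms to a color class and species, and a
flat list of interaction terms.  Abstracts are segmented here into sentences
with stable character offsets, because downstream evidence typing depends on
whether two entities share a sentence or only the abstract.

Offsets are 0-based, half-open and counted in characters, so
``abstract[s.start:s.end] == s.text`` always holds.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError

__all__ = [
    "Sentence",
    "Document",
    "LexiconEntry",
    "Lexicon",
    "InteractionTerms",
    "split_sentences",
    "read_corpus",
    "write_corpus",
    "read_lexicon",
    "write_lexicon",
    "read_interaction_terms",
    "write_interaction_terms",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sentence:
    """A contiguous span of an abstract: ``abstract[start:end] == text``."""

    start: int
    end: int
    text: str


@dataclass
class Document:
    """One titled abstract, segmented into ordered, non-overlapping sentences."""

    doc_id: str
    title: str
    abstract: str
    sentences: list[Sentence] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = -1
        for s in self.sentences:
            if not (0 <= s.start < s.end <= len(self.abstract)):
                raise ValidationError(
                    f"document {self.doc_id!r}: sentence span [{s.start},{s.end}) "
                    f"out of bounds for abstract of length {len(self.abstract)}"
                )
            if s.start < prev_end:
                raise ValidationError(
                    f"document {self.doc_id!r}: overlapping or unordered sentence spans"
                )
            if self.abstract[s.start:s.end] != s.text:
                raise ValidationError(
                    f"document {self.doc_id!r}: sentence text does not match its span"
                )
            prev_end = s.end


@dataclass(frozen=True)
class LexiconEntry:
    canonical: str
    synonyms: tuple[str, ...]
    color: str
    species: str


@dataclass
class Lexicon:
    """Canonical symbols with synonyms, a color class (e.g. gene/disease) and species.

    Surface forms are matched case-insensitively downstream, so validation
    rejects any surface that would map to more than one canonical symbol:
    ambiguous dictionaries are an input error, not something to guess around.
    """

    entries: list[LexiconEntry]

    def __post_init__(self) -> None:
        seen_canonical: set[str] = set()
        for e in self.entries:
            if e.canonical in seen_canonical:
                raise ValidationError(f"duplicate canonical symbol {e.canonical!r}")
            seen_canonical.add(e.canonical)
            if not e.canonical:
                raise ValidationError("empty canonical symbol")
            for syn in e.synonyms:
                if not syn:
                    raise ValidationError(
                        f"entry {e.canonical!r} contains an empty synonym"
                    )
        surface_owner: dict[str, str] = {}
        for e in self.entries:
            for surface in (e.canonical, *e.synonyms):
                key = surface.casefold()
                owner = surface_owner.get(key)
                if owner is not None and owner != e.canonical:
                    raise ValidationError(
                        f"surface form {surface!r} is ambiguous between "
                        f"{owner!r} and {e.canonical!r}"
                    )
                surface_owner[key] = e.canonical

    def surface_map(self) -> dict[str, tuple[str, str]]:
        """Casefolded surface form -> (canonical, color)."""
        out: dict[str, tuple[str, str]] = {}
        for e in self.entries:
            for surface in (e.canonical, *e.synonyms):
                out[surface.casefold()] = (e.canonical, e.color)
        return out

    def color_of(self, canonical: str) -> str:
        for e in self.entries:
            if e.canonical == canonical:
                return e.color
        raise ValidationError(f"symbol {canonical!r} not in lexicon")

    @property
    def canonicals(self) -> list[str]:
        return [e.canonical for e in self.entries]


@dataclass
class InteractionTerms:
    """Lowercase interaction-term vocabulary (e.g. activates, inhibits)."""

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("interaction-term list is empty")
        lowered = tuple(t.lower() for t in self.terms)
        # normalize: lowercase, order-preserving dedup
        seen: set[str] = set()
        unique = tuple(t for t in lowered if not (t in seen or seen.add(t)))
        object.__setattr__(self, "terms", unique)


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

#: Trailing strings that block a sentence break at the following period.
ABBREVIATIONS: tuple[str, ...] = (
    "et al.",
    "Fig.",
    "fig.",
    "Figs.",
    "vs.",
    "e.g.",
    "i.e.",
    "cf.",
    "ca.",
    "approx.",
    "Dr.",
    "St.",
    "No.",
    "resp.",
)

_BOUNDARY = re.compile(r"[.?!]+(?=\s)")


def split_sentences(text: str) -> list[Sentence]:
    """Segment ``text`` into sentences with 0-based half-open character spans.

    The splitter is deliberately rule-based and deterministic: a run of
    ``.?!`` followed by whitespace ends a sentence when the next non-space
    character is an uppercase letter or a digit, unless the text so far ends
    in a known abbreviation (``et al.``, ``Fig.`` ...).  Whitespace between
    sentences is treated as separator and excluded from spans.
    """
    if not text:
        return []
    breakpoints: list[int] = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        prefix = text[:end]
        if any(prefix.endswith(abbr) for abbr in ABBREVIATIONS):
            continue
        rest = text[end:].lstrip()
        if not rest:
            continue
        if not (rest[0].isupper() or rest[0].isdigit()):
            continue
        breakpoints.append(end)

    sentences: list[Sentence] = []
    prev = 0
    for cut in [*breakpoints, len(text)]:
        segment = text[prev:cut]
        lead = len(segment) - len(segment.lstrip())
        trail = len(segment.rstrip())
        if trail > lead:
            start, end = prev + lead, prev + trail
            sentences.append(Sentence(start, end, text[start:end]))
        prev = cut
    return sentences


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------

_CORPUS_COLUMNS = ("doc_id", "title", "abstract")


def _make_document(doc_id: str, title: str, abstract: str) -> Document:
    doc = Document(doc_id=doc_id, title=title, abstract=abstract,
                   sentences=split_sentences(abstract))
    doc.validate()
    return doc


def read_corpus(path: str | Path, format: str = "tsv") -> list[Document]:
    """Read a corpus file; ``format`` is ``"tsv"`` or ``"medline"``."""
    path = Path(path)
    if format == "tsv":
        docs = _read_corpus_tsv(path)
    elif format == "medline":
        docs = _read_corpus_medline(path)
    else:
        raise ValidationError(f"unknown corpus format {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {d.doc_id!r} in {path}")
        seen.add(d.doc_id)
    return docs


def _read_corpus_tsv(path: Path) -> list[Document]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty corpus file")
        missing = set(_CORPUS_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(
                f"{path}: missing corpus columns {sorted(missing)}"
            )
        docs = []
        for i, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in _CORPUS_COLUMNS):
                raise FormatError(f"{path}: line {i}: short record")
            docs.append(_make_document(row["doc_id"], row["title"], row["abstract"]))
    return docs


def _read_corpus_medline(path: Path) -> list[Document]:
    """Parse the MEDLINE text dialect: ``PMID- ``, ``TI  - ``, ``AB  - `` tags,
    6-character field prefixes and space-indented continuation lines."""
    records: list[dict[str, str]] = []
    current: dict[str, str] | None = None
    tag = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                current = None
                tag = None
                continue
            if len(line) >= 6 and line[4:6] == "- ":
                tag = line[:4].strip()
                value = line[6:]
                if tag == "PMID":
                    current = {"PMID": value.strip()}
                    records.append(current)
                elif current is None:
                    raise FormatError(
                        f"{path}: line {lineno}: field {tag!r} before any PMID"
                    )
                else:
                    current[tag] = (current.get(tag, "") + " " + value).strip() \
                        if tag in current else value
            elif line.startswith("      ") and current is not None and tag:
                current[tag] = current[tag] + " " + line.strip()
            else:
                raise FormatError(f"{path}: line {lineno}: unparseable line {line!r}")
    docs = []
    for rec in records:
        if "PMID" not in rec:
            raise FormatError(f"{path}: record without PMID")
        docs.append(_make_document(rec["PMID"], rec.get("TI", ""), rec.get("AB", "")))
    return docs


def write_corpus(docs: Sequence[Document], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CORPUS_COLUMNS)
        for d in docs:
            writer.writerow([d.doc_id, d.title, d.abstract])


# ---------------------------------------------------------------------------
# lexicon and interaction-term I/O
# ---------------------------------------------------------------------------

_LEXICON_COLUMNS = ("canonical", "synonyms", "color", "species")


def read_lexicon(path: str | Path, species: str | None = None) -> Lexicon:
    """Read a lexicon TSV (canonical, |-separated synonyms, color, species).

    With ``species`` set, entries for other taxa are dropped before
    validation, restricting tagging to the target organism.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty lexicon file")
        missing = set(_LEXICON_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing lexicon columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in _LEXICON_COLUMNS):
                raise FormatError(f"{path}: line {i}: short record")
            synonyms = tuple(s for s in row["synonyms"].split("|") if s)
            entries.append(LexiconEntry(row["canonical"], synonyms,
                                        row["color"], row["species"]))
    if species is not None:
        entries = [e for e in entries if e.species.casefold() == species.casefold()]
    if not entries:
        raise ValidationError(f"{path}: no lexicon entries"
                              + (f" for species {species!r}" if species else ""))
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_LEXICON_COLUMNS)
        for e in lexicon.entries:
            writer.writerow([e.canonical, "|".join(e.synonyms), e.color, e.species])


def read_interaction_terms(path: str | Path) -> InteractionTerms:
    """Read one term per line; blank lines and ``#`` comments are skipped."""
    terms: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            terms.append(stripped)
    if not terms:
        raise ValidationError(f"{path}: interaction-term file has no terms")
    return InteractionTerms(tuple(terms))


def write_interaction_terms(terms: InteractionTerms, path: str | Path) -> None:
    Path(path).write_text("\n".join(terms.terms) + "\n", encoding="utf-8")
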