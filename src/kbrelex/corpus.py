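"""Standoff-annotated corpora: reading, writing, tokenization and the BIOE codec.

The corpus model follows the BioNLP shared-task standoff convention: a raw
``.txt`` document, an ``.a1`` file of typed entity mentions keyed by character
offsets, and an optional ``.a2`` file of directed binary relations between
those mentions.  Offsets are 0-based and end-exclusive throughout.

Only gene and protein mentions are kept at load time; mentions of any other
type are dropped (with a logged count), since only those two types can be
grounded in the protein knowledge base downstream.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

#: Entity types retained at load time.
ENTITY_TYPES = ("Gene", "Protein")

#: The eight directed relation types of the gene/protein subtask, in a fixed
#: order used everywhere a label index is needed.
RELATION_TYPES = (
    "Is_Functionally_Equivalent_To",
    "Interacts_With",
    "Has_Sequence_Identical_To",
    "Transcribes_Or_Translates_To",
    "Regulates_Expression",
    "Is_Linked_To",
    "Binds_To",
    "Regulates_Molecule_Activity",
)

#: Label used for candidate pairs that carry no annotated relation.
NONE_LABEL = "NONE"

#: BIOE position-tag alphabet, in fixed index order.
TAGS = ("B", "I", "O", "E")


class ParseError(ValueError):
    """A standoff or embedding file line that does not match the dialect."""


class IntegrityError(ValueError):
    """Annotations that are internally inconsistent (dangling ids, bad spans)."""


@dataclass
class Token:
    """A surface token with exact character offsets into the document text."""

    surface: str
    char_start: int
    char_end: int
    pos: Optional[str] = None
    lemma: Optional[str] = None

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(f"empty token span {self.char_start}:{self.char_end}")


@dataclass
class Sentence:
    """An ordered, non-overlapping token sequence covering one sentence span."""

    tokens: list[Token]
    char_start: int
    char_end: int

    def __len__(self) -> int:
        return len(self.tokens)

    def contains_span(self, start: int, end: int) -> bool:
        return self.char_start <= start and end <= self.char_end


@dataclass
class EntityMention:
    """A typed entity mention anchored to document character offsets."""

    id: str
    etype: str
    char_start: int
    char_end: int
    surface: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"entity type {self.etype!r} not in {ENTITY_TYPES}")


@dataclass
class RelationInstance:
    """A directed binary relation between two entity mentions (by id)."""

    id: str
    rtype: str
    arg1: str
    arg2: str

    def __post_init__(self) -> None:
        if self.arg1 == self.arg2:
            raise ValueError(f"relation {self.id} has identical arguments")
        if self.rtype not in RELATION_TYPES and self.rtype != NONE_LABEL:
            raise ValueError(f"unknown relation type {self.rtype!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        """Exact-match key: (type, arg1, arg2); direction is significant."""
        return (self.rtype, self.arg1, self.arg2)


@dataclass
class Document:
    id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)

    def entity_by_id(self, eid: str) -> EntityMention:
        for e in self.entities:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def sentence_of(self, entity: EntityMention) -> Sentence:
        """The unique sentence containing the mention (guaranteed at load)."""
        for s in self.sentences:
            if s.contains_span(entity.char_start, entity.char_end):
                return s
        raise IntegrityError(f"entity {entity.id} lies in no sentence")

    def entities_in(self, sentence: Sentence) -> list[EntityMention]:
        return [
            e
            for e in self.entities
            if sentence.contains_span(e.char_start, e.char_end)
        ]


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting
# ---------------------------------------------------------------------------

_PUNCT = set("()[]{},.;:!?\"'")

#: Abbreviations that never terminate a sentence despite the trailing period.
DEFAULT_ABBREVIATIONS = (
    "Fig.",
    "Figs.",
    "et al.",
    "e.g.",
    "i.e.",
    "cf.",
    "vs.",
    "Eq.",
    "No.",
    "Ref.",
    "Dr.",
)


def tokenize(text: str) -> list[Token]:
    """Rule-based tokenizer with exact offsets.

    Splits on whitespace, peels leading/trailing punctuation characters into
    their own tokens, and splits on internal ``/``.  Hyphens and digits stay
    inside tokens so names like ``14-3-3`` survive intact.  Concatenating the
    token surfaces with the original inter-token characters reconstructs the
    input exactly.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        _split_chunk(m.group(), m.start(), tokens)
    return tokens


def _split_chunk(chunk: str, start: int, out: list[Token]) -> None:
    i, j = 0, len(chunk)
    lead: list[tuple[str, int]] = []
    while i < j and chunk[i] in _PUNCT:
        lead.append((chunk[i], start + i))
        i += 1
    trail: list[tuple[str, int]] = []
    while j > i and chunk[j - 1] in _PUNCT:
        trail.append((chunk[j - 1], start + j - 1))
        j -= 1
    for s, p in lead:
        out.append(Token(s, p, p + 1))
    core = chunk[i:j]
    pos = start + i
    for part in re.split(r"(/)", core):
        if part:
            out.append(Token(part, pos, pos + len(part)))
        pos += len(part)
    for s, p in reversed(trail):
        out.append(Token(s, p, p + 1))


def split_sentences(
    text: str, abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Sentence spans as (start, end) offsets partitioning the text.

    A sentence ends after ``.``, ``!`` or ``?`` followed by whitespace and an
    uppercase letter, unless the terminator closes a protected abbreviation.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in re.finditer(r"([.!?])\s+(?=[A-Z])", text):
        end = m.end(1)
        if m.group(1) == "." and any(
            text[:end].endswith(a) for a in abbreviations
        ):
            continue
        spans.append((start, end))
        start = m.end()
    if text[start:].strip():
        spans.append((start, len(text)))
    # trim leading/trailing whitespace from each span
    trimmed = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    return trimmed


def segment(text: str) -> list[Sentence]:
    """Sentence-split then tokenize, preserving document offsets."""
    sentences = []
    for s, e in split_sentences(text):
        toks = [
            Token(t.surface, t.char_start + s, t.char_end + s, t.pos, t.lemma)
            for t in tokenize(text[s:e])
        ]
        sentences.append(Sentence(toks, s, e))
    return sentences


# ---------------------------------------------------------------------------
# Standoff reading / writing
# ---------------------------------------------------------------------------

def read_standoff(
    txt_path: str | Path,
    a1_path: str | Path,
    a2_path: str | Path | None = None,
    doc_id: str | None = None,
) -> Document:
    """Load a standoff-annotated document.

    Entities whose type is not Gene or Protein are skipped (count logged).
    Discontinuous spans (``;`` in the offset field) are rejected.  Entities
    crossing a sentence boundary are dropped with a warning, along with any
    relation that references them.
    """
    txt_path, a1_path = Path(txt_path), Path(a1_path)
    text = txt_path.read_text(encoding="utf-8")
    if doc_id is None:
        doc_id = txt_path.stem

    entities: list[EntityMention] = []
    skipped = 0
    for lineno, line in _lines(a1_path):
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{a1_path}:{lineno}: expected 3 tab fields")
        eid, type_span, surface = parts
        if ";" in type_span:
            raise IntegrityError(
                f"{a1_path}:{lineno}: discontinuous spans are not supported"
            )
        bits = type_span.split()
        if len(bits) != 3:
            raise ParseError(f"{a1_path}:{lineno}: expected 'TYPE START END'")
        etype, s_str, e_str = bits
        try:
            s, e = int(s_str), int(e_str)
        except ValueError as exc:
            raise ParseError(f"{a1_path}:{lineno}: non-integer offsets") from exc
        if etype not in ENTITY_TYPES:
            skipped += 1
            continue
        if text[s:e] != surface:
            raise IntegrityError(
                f"{a1_path}:{lineno}: surface {surface!r} != text slice "
                f"{text[s:e]!r}"
            )
        entities.append(EntityMention(eid, etype, s, e, surface))
    if skipped:
        logger.info("%s: skipped %d non-Gene/Protein entities", a1_path, skipped)

    known = {e.id for e in entities}
    relations: list[RelationInstance] = []
    if a2_path is not None:
        a2_path = Path(a2_path)
        for lineno, line in _lines(a2_path):
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{a2_path}:{lineno}: expected 2 tab fields")
            rid, body = parts
            bits = body.split()
            if len(bits) != 3 or not (
                bits[1].startswith("Arg1:") and bits[2].startswith("Arg2:")
            ):
                raise ParseError(
                    f"{a2_path}:{lineno}: expected 'TYPE Arg1:Tx Arg2:Ty'"
                )
            rtype, a1_ref, a2_ref = bits[0], bits[1][5:], bits[2][5:]
            for ref in (a1_ref, a2_ref):
                if ref not in known:
                    raise IntegrityError(
                        f"{a2_path}:{lineno}: relation {rid} references "
                        f"unknown entity {ref}"
                    )
            relations.append(RelationInstance(rid, rtype, a1_ref, a2_ref))

    sentences = segment(text)
    kept_entities = []
    for ent in entities:
        if any(s.contains_span(ent.char_start, ent.char_end) for s in sentences):
            kept_entities.append(ent)
        else:
            logger.warning(
                "%s: entity %s crosses a sentence boundary; dropped",
                doc_id,
                ent.id,
            )
    kept_ids = {e.id for e in kept_entities}
    kept_relations = [
        r for r in relations if r.arg1 in kept_ids and r.arg2 in kept_ids
    ]
    return Document(doc_id, text, sentences, kept_entities, kept_relations)


def write_standoff(
    doc: Document,
    txt_path: str | Path,
    a1_path: str | Path,
    a2_path: str | Path | None = None,
) -> None:
    """Write a document back to standoff files (same column order as read)."""
    Path(txt_path).write_text(doc.text, encoding="utf-8")
    with open(a1_path, "w", encoding="utf-8") as fh:
        for e in doc.entities:
            fh.write(f"{e.id}\t{e.etype} {e.char_start} {e.char_end}\t{e.surface}\n")
    if a2_path is not None:
        with open(a2_path, "w", encoding="utf-8") as fh:
            for r in doc.relations:
                fh.write(f"{r.id}\t{r.rtype} Arg1:{r.arg1} Arg2:{r.arg2}\n")


def read_corpus_dir(directory: str | Path) -> list[Document]:
    """Load every ``<id>.txt`` / ``<id>.a1`` (+ optional ``.a2``) in a directory."""
    directory = Path(directory)
    docs = []
    for txt in sorted(directory.glob("*.txt")):
        a1 = txt.with_suffix(".a1")
        if not a1.exists():
            continue
        a2 = txt.with_suffix(".a2")
        docs.append(read_standoff(txt, a1, a2 if a2.exists() else None))
    return docs


def write_corpus_dir(docs: Iterable[Document], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_standoff(
            doc,
            directory / f"{doc.id}.txt",
            directory / f"{doc.id}.a1",
            directory / f"{doc.id}.a2",
        )


def _lines(path: Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if line.strip():
                yield lineno, line


# ---------------------------------------------------------------------------
# BIOE codec
# ---------------------------------------------------------------------------

def spans_to_bioe(
    sentence: Sentence, entities: Sequence[EntityMention]
) -> list[str]:
    """Encode entity spans as per-token B/I/O/E position tags.

    A k-token entity becomes ``B, I*(k-2), E``; a single-token entity is a
    bare ``B``.  Entities must align exactly to token boundaries and must not
    overlap.
    """
    tags = ["O"] * len(sentence.tokens)
    starts = {t.char_start: i for i, t in enumerate(sentence.tokens)}
    ends = {t.char_end: i for i, t in enumerate(sentence.tokens)}
    for ent in entities:
        if ent.char_start not in starts or ent.char_end not in ends:
            raise ValueError(
                f"entity {ent.id} ({ent.char_start}:{ent.char_end}) does not "
                "align to token boundaries"
            )
        i, j = starts[ent.char_start], ends[ent.char_end]
        if any(tags[k] != "O" for k in range(i, j + 1)):
            raise ValueError(f"entity {ent.id} overlaps a previous entity")
        if i == j:
            tags[i] = "B"
        else:
            tags[i] = "B"
            for k in range(i + 1, j):
                tags[k] = "I"
            tags[j] = "E"
    return tags


def bioe_to_spans(tags: Sequence[str], sentence: Sentence) -> list[tuple[int, int]]:
    """Decode a BIOE tag sequence back to character spans.

    Lenient: an ``I``/``E`` with no open span opens one at that token; an
    unclosed ``B…I`` run closes at its last token.  Decoding never raises on
    tag content, so raw model output is always usable.
    """
    if len(tags) != len(sentence.tokens):
        raise ValueError("tag/token length mismatch")
    spans: list[tuple[int, int]] = []
    start: Optional[int] = None
    last = -1

    def flush() -> None:
        nonlocal start
        if start is not None:
            spans.append(
                (
                    sentence.tokens[start].char_start,
                    sentence.tokens[last].char_end,
                )
            )
            start = None

    for t, tag in enumerate(tags):
        if tag == "O":
            flush()
        elif tag == "B":
            flush()
            start = t
            last = t
        elif tag == "I":
            if start is None:
                start = t
            last = t
        elif tag == "E":
            if start is None:
                start = t
            last = t
            flush()
        else:
            raise ValueError(f"unknown tag {tag!r}")
    flush()
    return spans


def candidate_pairs(
    sentence: Sentence, entities: Sequence[EntityMention]
) -> list[tuple[EntityMention, EntityMention]]:
    """All ordered same-sentence entity pairs (a, b), a != b.

    Relation candidates never cross sentence boundaries.
    """
    for e in entities:
        if not sentence.contains_span(e.char_start, e.char_end):
            raise ValueError(f"entity {e.id} not inside sentence")
    return [(a, b) for a in entities for b in entities if a is not b]
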