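"""Document model, BRAT standoff I/O, segmentation, BIO conversion, partition.

Character offsets are 0-based half-open throughout, matching the BRAT
standoff convention.  A :class:`Document` carries its text plus sentence and
paragraph boundaries; entity mentions are typed character spans and relation
mentions typed links between them, both validated against an active
:class:`~slrminer.schema.ExtractionSchema`.

Datasets are partitioned into train/validation/test at *paragraph*
granularity: paragraphs are randomly allocated to the three sets following
predetermined ratios (largest-remainder rounding makes the counts
deterministic), so entity/relation ratios per split vary with paragraph
content.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .schema import ExtractionSchema

logger = logging.getLogger(__name__)

Span = tuple[int, int]


class BratParseError(ValueError):
    """Raised when a BRAT standoff line cannot be parsed or validated."""


class AnnotationError(ValueError):
    """Raised when annotations violate document or schema invariants."""


@dataclass(frozen=True)
class EntityMention:
    mention_id: str
    entity_type: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"empty span for {self.mention_id}")

    @property
    def span(self) -> Span:
        return (self.start, self.end)

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class RelationMention:
    relation_id: str
    label: str
    arg1: str  # mention_id
    arg2: str  # mention_id


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Span] = field(default_factory=list)
    paragraphs: list[Span] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationMention] = field(default_factory=list)

    def mention_by_id(self, mid: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mid:
                return m
        raise KeyError(mid)

    def sentence_index(self, offset: int) -> int:
        """Index of the sentence containing ``offset`` (nearest if in a gap)."""
        best = 0
        for i, (s, e) in enumerate(self.sentences):
            if s <= offset < e:
                return i
            if offset >= e:
                best = i
        return best

    def validate(self, schema: ExtractionSchema | None = None) -> None:
        n = len(self.text)
        prev_end = 0
        for s, e in self.sentences:
            if not (0 <= s < e <= n) or s < prev_end:
                raise AnnotationError(f"{self.doc_id}: bad sentence interval ({s},{e})")
            prev_end = e
        for s, e in self.sentences:
            if sum(1 for ps, pe in self.paragraphs if ps <= s and e <= pe) != 1:
                raise AnnotationError(
                    f"{self.doc_id}: sentence ({s},{e}) not inside exactly one paragraph"
                )
        ids = set()
        for m in self.mentions:
            if m.mention_id in ids:
                raise AnnotationError(f"{self.doc_id}: duplicate mention id {m.mention_id}")
            ids.add(m.mention_id)
            if not (0 <= m.start < m.end <= n):
                raise AnnotationError(f"{self.doc_id}: span out of bounds for {m.mention_id}")
            if self.text[m.start : m.end] != m.surface:
                raise AnnotationError(
                    f"{self.doc_id}: surface mismatch for {m.mention_id}: "
                    f"{self.text[m.start:m.end]!r} != {m.surface!r}"
                )
            if schema is not None and not schema.has_entity_type(m.entity_type):
                raise AnnotationError(f"{self.doc_id}: unknown type {m.entity_type}")
        by_id = {m.mention_id: m for m in self.mentions}
        for r in self.relations:
            if r.arg1 not in by_id or r.arg2 not in by_id:
                raise AnnotationError(f"{self.doc_id}: dangling relation argument in {r.relation_id}")
            if schema is not None:
                t1 = by_id[r.arg1].entity_type
                t2 = by_id[r.arg2].entity_type
                if not schema.is_admissible_pair(r.label, t1, t2):
                    raise AnnotationError(
                        f"{self.doc_id}: inadmissible relation {r.label}({t1},{t2})"
                    )


@dataclass
class AnnotatedCorpus:
    documents: list[Document]
    schema_id: str = "custom"

    def validate(self, schema: ExtractionSchema | None = None) -> None:
        for d in self.documents:
            d.validate(schema)

    def n_paragraphs(self) -> int:
        return sum(len(d.paragraphs) for d in self.documents)


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[float, float, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9 or any(r < 0 for r in self.ratios):
            raise ValueError(f"split ratios must be non-negative and sum to 1: {self.ratios}")


# ---------------------------------------------------------------------------
# Segmentation

# tokens before a period that do not end a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "al", "et", "fig", "figs", "dr", "prof", "no",
    "ref", "refs", "eq", "ca", "cf", "approx", "resp", "inc", "ltd",
}

_PARA_RE = re.compile(r"\n[ \t]*\n")


def segment(text: str) -> tuple[list[Span], list[Span]]:
    """Sentence and paragraph boundaries of ``text`` (deterministic, rule-based).

    Paragraphs are blocks separated by blank lines.  Sentences end at runs of
    ``. ! ?`` unless the period sits between digits (decimals such as
    ``1.73``) or closes a known abbreviation.  Returns ``(sentences,
    paragraphs)`` as half-open character intervals.
    """
    paragraphs: list[Span] = []
    pos = 0
    for m in _PARA_RE.finditer(text):
        block = text[pos : m.start()]
        if block.strip():
            paragraphs.append(_strip_span(text, pos, m.start()))
        pos = m.end()
    if text[pos:].strip():
        paragraphs.append(_strip_span(text, pos, len(text)))

    sentences: list[Span] = []
    for ps, pe in paragraphs:
        sentences.extend(_split_sentences(text, ps, pe))
    return sentences, paragraphs


def _strip_span(text: str, s: int, e: int) -> Span:
    while s < e and text[s].isspace():
        s += 1
    while e > s and text[e - 1].isspace():
        e -= 1
    return (s, e)


def _split_sentences(text: str, start: int, end: int) -> list[Span]:
    spans: list[Span] = []
    sent_start = start
    i = start
    while i < end:
        c = text[i]
        if c in ".!?":
            # absorb a run of terminal punctuation
            j = i
            while j + 1 < end and text[j + 1] in ".!?":
                j += 1
            if _is_boundary(text, i, j, end):
                spans.append(_strip_span(text, sent_start, j + 1))
                i = j + 1
                while i < end and text[i].isspace():
                    i += 1
                sent_start = i
                continue
            i = j + 1
        else:
            i += 1
    if sent_start < end and text[sent_start:end].strip():
        spans.append(_strip_span(text, sent_start, end))
    return [s for s in spans if s[0] < s[1]]


def _is_boundary(text: str, i: int, j: int, end: int) -> bool:
    c = text[i]
    if c == ".":
        if 0 < i and i + 1 < len(text) and text[i - 1].isdigit() and text[i + 1].isdigit():
            return False  # decimal point
        k = i
        while k > 0 and (text[k - 1].isalpha() or text[k - 1] == "."):
            k -= 1
        token = text[k:i].lower().rstrip(".")
        if token in _ABBREVIATIONS:
            return False
    # must be followed by whitespace/para end
    return j + 1 >= end or text[j + 1].isspace()


# ---------------------------------------------------------------------------
# BIO conversion

TagSequence = list[str]


def is_valid_bio(tags: Sequence[str]) -> bool:
    prev = "O"
    for t in tags:
        if t.startswith("I-"):
            typ = t[2:]
            if prev not in (f"B-{typ}", f"I-{typ}"):
                return False
        prev = t
    return True


def repair_bio(tags: Sequence[str]) -> TagSequence:
    """Turn stray ``I-x`` (not continuing a same-type run) into ``B-x``."""
    out: TagSequence = []
    prev = "O"
    for t in tags:
        if t.startswith("I-"):
            typ = t[2:]
            if prev not in (f"B-{typ}", f"I-{typ}"):
                t = f"B-{typ}"
        out.append(t)
        prev = t
    return out


def spans_to_bio(word_spans: Sequence[Span], mentions: Sequence[EntityMention]) -> TagSequence:
    """BIO tags over ``word_spans`` for non-overlapping ``mentions``.

    A word carries a mention's type when their character spans intersect; the
    first such word gets ``B-``, subsequent ones ``I-``.  Overlapping mentions
    must be resolved first (see :func:`resolve_overlaps`).
    """
    for a in range(len(mentions)):
        for b in range(a + 1, len(mentions)):
            if mentions[a].overlaps(mentions[b]):
                raise AnnotationError(
                    f"overlapping mentions {mentions[a].mention_id}/{mentions[b].mention_id}"
                )
    tags: TagSequence = ["O"] * len(word_spans)
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        first = True
        for wi, (ws, we) in enumerate(word_spans):
            if ws < m.end and m.start < we:
                tags[wi] = ("B-" if first else "I-") + m.entity_type
                first = False
    return tags


def bio_to_spans(tags: Sequence[str], word_spans: Sequence[Span]) -> list[tuple[str, int, int]]:
    """Maximal B-I runs -> ``(entity_type, char_start, char_end)`` triples."""
    out: list[tuple[str, int, int]] = []
    run_type: str | None = None
    run_start = run_end = 0
    for t, (ws, we) in zip(tags, word_spans):
        if t.startswith("B-"):
            if run_type is not None:
                out.append((run_type, run_start, run_end))
            run_type, run_start, run_end = t[2:], ws, we
        elif t.startswith("I-") and run_type == t[2:]:
            run_end = we
        else:
            if run_type is not None:
                out.append((run_type, run_start, run_end))
                run_type = None
            if t.startswith("I-"):  # invalid continuation: treat as begin
                run_type, run_start, run_end = t[2:], ws, we
    if run_type is not None:
        out.append((run_type, run_start, run_end))
    return out


def resolve_overlaps(mentions: Sequence[EntityMention]) -> tuple[list[EntityMention], list[EntityMention]]:
    """Single-layer selection: keep the longer mention, tie-break earlier start.

    Returns ``(kept, dropped)``; drops are logged.  Needed because single-layer
    BIO cannot encode overlapping entities of different types.
    """
    order = sorted(mentions, key=lambda m: (-(m.end - m.start), m.start, m.mention_id))
    kept: list[EntityMention] = []
    dropped: list[EntityMention] = []
    for m in order:
        if any(m.overlaps(k) for k in kept):
            dropped.append(m)
        else:
            kept.append(m)
    if dropped:
        logger.info("resolve_overlaps: dropped %d overlapping mention(s)", len(dropped))
    kept.sort(key=lambda m: (m.start, m.end))
    return kept, dropped


def snap_to_words(mention: EntityMention, word_spans: Sequence[Span], text: str) -> EntityMention:
    """Snap mid-word boundaries outward to word boundaries (BIO is word-granular)."""
    s, e = mention.start, mention.end
    for ws, we in word_spans:
        if ws < mention.end and mention.start < we:
            s = min(s, ws)
            e = max(e, we)
    if (s, e) != (mention.start, mention.end):
        logger.info("snap_to_words: %s snapped (%d,%d)->(%d,%d)",
                    mention.mention_id, mention.start, mention.end, s, e)
        return replace(mention, start=s, end=e, surface=text[s:e])
    return mention


# ---------------------------------------------------------------------------
# BRAT standoff

_T_LINE = re.compile(r"^(T\d+)\t(\S+) ([0-9;][0-9; ]*)\t(.*)$")
_R_LINE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")


def read_brat(text: str, ann: str, schema: ExtractionSchema, doc_id: str = "doc") -> Document:
    """Parse a BRAT ``.txt``/``.ann`` pair into a validated :class:`Document`.

    Supports entity (``T``) and binary relation (``R``) lines.  Discontinuous
    spans (semicolon-separated fragments) are rejected: the supported schemas
    annotate contiguous phrases only.
    """
    sentences, paragraphs = segment(text)
    doc = Document(doc_id=doc_id, text=text, sentences=sentences, paragraphs=paragraphs)
    for lineno, raw in enumerate(ann.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        kind = line[0]
        if kind == "T":
            m = _T_LINE.match(line)
            if not m:
                raise BratParseError(f"line {lineno}: malformed T line: {line!r}")
            tid, etype, offsets, surface = m.groups()
            if ";" in offsets:
                raise BratParseError(
                    f"line {lineno}: discontinuous span not supported: {line!r}"
                )
            parts = offsets.split()
            if len(parts) != 2:
                raise BratParseError(f"line {lineno}: malformed offsets: {line!r}")
            start, end = int(parts[0]), int(parts[1])
            if not (0 <= start < end <= len(text)):
                raise BratParseError(f"line {lineno}: offsets ({start},{end}) outside text")
            if text[start:end] != surface:
                raise BratParseError(
                    f"line {lineno}: surface mismatch: text has {text[start:end]!r}"
                )
            if not schema.has_entity_type(etype):
                raise BratParseError(f"line {lineno}: unknown entity type {etype!r}")
            doc.mentions.append(EntityMention(tid, etype, start, end, surface))
        elif kind == "R":
            m = _R_LINE.match(line)
            if not m:
                raise BratParseError(f"line {lineno}: malformed R line: {line!r}")
            rid, label, a1, a2 = m.groups()
            doc.relations.append(RelationMention(rid, label, a1, a2))
        elif kind in "#AMNE*":
            continue  # comments / attribute lines are ignored
        else:
            raise BratParseError(f"line {lineno}: unsupported line: {line!r}")
    try:
        doc.validate(schema)
    except AnnotationError as exc:
        raise BratParseError(str(exc)) from exc
    return doc


def write_brat(doc: Document) -> tuple[str, str]:
    """Serialise a document to a BRAT ``(text, ann)`` pair.

    Identifiers are renumbered deterministically (mentions by offset);
    symmetric (``equivalent``) relation arguments are emitted in canonical
    document-offset order.
    """
    mentions = sorted(doc.mentions, key=lambda m: (m.start, m.end, m.entity_type))
    renum = {m.mention_id: f"T{i + 1}" for i, m in enumerate(mentions)}
    by_id = {m.mention_id: m for m in doc.mentions}
    lines = [
        f"{renum[m.mention_id]}\t{m.entity_type} {m.start} {m.end}\t{m.surface}"
        for m in mentions
    ]

    def rel_key(r: RelationMention) -> tuple:
        a, b = by_id[r.arg1], by_id[r.arg2]
        return (min(a.start, b.start), max(a.start, b.start), r.label)

    for i, r in enumerate(sorted(doc.relations, key=rel_key), start=1):
        a1, a2 = r.arg1, r.arg2
        if r.label == "equivalent":
            m1, m2 = by_id[a1], by_id[a2]
            if (m2.start, m2.end) < (m1.start, m1.end):
                a1, a2 = a2, a1
        lines.append(f"R{i}\t{r.label} Arg1:{renum[a1]} Arg2:{renum[a2]}")
    ann = "\n".join(lines) + ("\n" if lines else "")
    return doc.text, ann


def save_corpus(corpus: AnnotatedCorpus, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc in corpus.documents:
        text, ann = write_brat(doc)
        safe = doc.doc_id.replace("/", "_").replace(":", "_")
        (out / f"{safe}.txt").write_text(text, encoding="utf-8")
        (out / f"{safe}.ann").write_text(ann, encoding="utf-8")


def load_corpus(in_dir: str | Path, schema: ExtractionSchema) -> AnnotatedCorpus:
    docs = []
    for txt in sorted(Path(in_dir).glob("*.txt")):
        ann_path = txt.with_suffix(".ann")
        ann = ann_path.read_text(encoding="utf-8") if ann_path.exists() else ""
        docs.append(read_brat(txt.read_text(encoding="utf-8"), ann, schema, doc_id=txt.stem))
    return AnnotatedCorpus(documents=docs, schema_id=schema.schema_id)


# ---------------------------------------------------------------------------
# Partition

def largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    """Split ``n`` items into integer counts proportional to ``ratios``."""
    raw = [n * r for r in ratios]
    counts = [int(x) for x in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(ratios)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def partition(
    corpus: AnnotatedCorpus, spec: SplitSpec
) -> tuple[AnnotatedCorpus, AnnotatedCorpus, AnnotatedCorpus]:
    """Allocate paragraphs uniformly at random to train/validation/test.

    Each paragraph becomes a self-contained document in its split (offsets
    rebased to 0).  Relations whose arguments fall in different paragraphs
    cannot survive paragraph-level allocation; they are dropped and logged.
    """
    units: list[tuple[Document, int]] = [
        (d, pi) for d in corpus.documents for pi in range(len(d.paragraphs))
    ]
    n = len(units)
    if n < 3:
        raise ValueError("need at least 3 paragraphs to partition")
    counts = largest_remainder_counts(n, spec.ratios)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm[: counts[0]]] = 0
    assignment[perm[counts[0] : counts[0] + counts[1]]] = 1
    assignment[perm[counts[0] + counts[1] :]] = 2

    splits: tuple[list[Document], list[Document], list[Document]] = ([], [], [])
    dropped_relations = 0
    for ui, (doc, pi) in enumerate(units):
        ps, pe = doc.paragraphs[pi]
        sub = _paragraph_document(doc, pi, ps, pe)
        dropped_relations += sub_dropped_count(doc, ps, pe, sub)
        splits[assignment[ui]].append(sub)
    if dropped_relations:
        logger.info("partition: dropped %d cross-paragraph relation(s)", dropped_relations)
    return tuple(
        AnnotatedCorpus(documents=s, schema_id=corpus.schema_id) for s in splits
    )  # type: ignore[return-value]


def _paragraph_document(doc: Document, pi: int, ps: int, pe: int) -> Document:
    text = doc.text[ps:pe]
    sentences = [(s - ps, e - ps) for s, e in doc.sentences if ps <= s and e <= pe]
    mentions = [
        replace(m, start=m.start - ps, end=m.end - ps)
        for m in doc.mentions
        if ps <= m.start and m.end <= pe
    ]
    kept_ids = {m.mention_id for m in mentions}
    relations = [r for r in doc.relations if r.arg1 in kept_ids and r.arg2 in kept_ids]
    return Document(
        doc_id=f"{doc.doc_id}__p{pi:03d}",
        text=text,
        sentences=sentences,
        paragraphs=[(0, len(text))] if text else [],
        mentions=mentions,
        relations=relations,
    )


def sub_dropped_count(doc: Document, ps: int, pe: int, sub: Document) -> int:
    touching = [
        r
        for r in doc.relations
        if any(
            ps <= m.start < pe
            for m in (doc.mention_by_id(r.arg1), doc.mention_by_id(r.arg2))
        )
    ]
    return len(touching) - len(sub.relations)
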