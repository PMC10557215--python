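"""Two-stage tokenisation: word splitting, then greedy WordPiece sub-words.

Stage one splits text on whitespace and punctuation, so every punctuation
mark becomes a single-character word.  Stage two decomposes each word into
vocabulary pieces by greedy longest-match-first WordPiece; continuation
pieces carry the ``##`` prefix and a word with no matching prefix maps to
the unknown token.  Because downstream word classifiers consume only the
contextual vector of each word's *first* piece, a boolean first-piece mask
is provided alongside.

A small frequency-based vocabulary builder is included so the whole stack
trains offline: it always includes every single character seen (plus the
``##`` continuations), which guarantees that any word over the training
alphabet is coverable.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

Span = tuple[int, int]

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
RESERVED = (PAD, UNK, CLS, SEP, MASK)

_WORD_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")


@dataclass(frozen=True)
class Word:
    surface: str
    start: int
    end: int


@dataclass(frozen=True)
class WordPiece:
    surface: str
    word_index: int
    is_first: bool


def split_words(text: str, offset: int = 0) -> list[Word]:
    """Split on whitespace and punctuation; punctuation marks become words.

    ``offset`` shifts the reported character spans (useful when ``text`` is a
    sentence slice of a larger document).
    """
    return [
        Word(m.group(0), offset + m.start(), offset + m.end())
        for m in _WORD_RE.finditer(text)
    ]


class Vocabulary:
    """Piece-string -> dense integer id mapping with reserved tokens."""

    def __init__(self, pieces: Sequence[str]):
        for tok in RESERVED:
            if tok not in pieces:
                raise ValueError(f"vocabulary missing reserved token {tok}")
        self.itos: tuple[str, ...] = tuple(pieces)
        self.stoi: dict[str, int] = {p: i for i, p in enumerate(self.itos)}
        if len(self.stoi) != len(self.itos):
            raise ValueError("duplicate pieces in vocabulary")

    def __len__(self) -> int:
        return len(self.itos)

    def __contains__(self, piece: str) -> bool:
        return piece in self.stoi

    def id(self, piece: str) -> int:
        return self.stoi[piece]

    @property
    def pad_id(self) -> int:
        return self.stoi[PAD]

    @property
    def unk_id(self) -> int:
        return self.stoi[UNK]

    @property
    def mask_id(self) -> int:
        return self.stoi[MASK]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.itos) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([ln for ln in lines if ln != ""])


def wordpiece(word: Word | str, vocab: Vocabulary, lowercase: bool = True,
              word_index: int = 0) -> list[WordPiece]:
    """Greedy longest-match-first decomposition of one word.

    The first piece is matched against bare vocabulary entries, later pieces
    against ``##``-prefixed ones.  If at any point no prefix matches, the
    whole word becomes a single unknown-token piece.
    """
    surface = word.surface if isinstance(word, Word) else word
    if lowercase:
        surface = surface.lower()
    pieces: list[str] = []
    pos = 0
    n = len(surface)
    while pos < n:
        prefix = "" if pos == 0 else "##"
        found = None
        for end in range(n, pos, -1):
            cand = prefix + surface[pos:end]
            if cand in vocab:
                found = cand
                pos = end
                break
        if found is None:
            return [WordPiece(UNK, word_index, True)]
        pieces.append(found)
    if not pieces:
        return [WordPiece(UNK, word_index, True)]
    return [WordPiece(p, word_index, i == 0) for i, p in enumerate(pieces)]


def tokenize_words(words: Sequence[Word], vocab: Vocabulary,
                   lowercase: bool = True) -> list[WordPiece]:
    out: list[WordPiece] = []
    for wi, w in enumerate(words):
        out.extend(wordpiece(w, vocab, lowercase=lowercase, word_index=wi))
    return out


def first_piece_mask(pieces: Sequence[WordPiece]) -> list[bool]:
    """True exactly at each word's first piece; #True == number of words."""
    return [p.is_first for p in pieces]


def piece_ids(pieces: Sequence[WordPiece], vocab: Vocabulary) -> list[int]:
    return [vocab.stoi.get(p.surface, vocab.unk_id) for p in pieces]


def build_vocabulary(
    texts: Iterable[str],
    max_size: int = 4000,
    min_freq: int = 2,
    lowercase: bool = True,
) -> Vocabulary:
    """Frequency-based WordPiece vocabulary over ``texts``.

    Reserved tokens first, then every single character seen (and its ``##``
    continuation form, guaranteeing full coverage of the training alphabet),
    then whole words by descending frequency up to ``max_size``.
    """
    word_freq: Counter[str] = Counter()
    chars: set[str] = set()
    for text in texts:
        for w in split_words(text):
            s = w.surface.lower() if lowercase else w.surface
            word_freq[s] += 1
            chars.update(s)
    pieces: list[str] = list(RESERVED)
    seen = set(pieces)
    for c in sorted(chars):
        pieces.append(c)
        pieces.append("##" + c)
        seen.update((c, "##" + c))
    for surface, freq in sorted(word_freq.items(), key=lambda kv: (-kv[1], kv[0])):
        if len(pieces) >= max_size:
            break
        if freq >= min_freq and surface not in seen and len(surface) > 1:
            pieces.append(surface)
            seen.add(surface)
    return Vocabulary(pieces)
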