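"""Relation extraction over typed entity mentions.

Candidate pairs are restricted to entities within a *context window*: a
maximum sentence distance (absolute difference of containing-sentence
indices, so entities in the same sentence are at distance 0 and a
three-sentence window admits distances 0-3).  Two architectures are
provided:

* **relation classification** (one step): both entities are given; their
  spans are marked with learned marker embeddings added to the wordpiece
  representations, and a classifier over the pooled window plus the two
  first-piece argument vectors assigns ``refers_to``, ``equivalent`` or
  ``no_relation``.
* **role labelling** (two steps): one *query* entity is given; step one tags
  the words of its context window with role labels (BIO over role classes
  relative to the marked query), step two types each recovered span's
  relation to the query.  Outputs are always filtered to schema-admissible
  pairs.

Symmetric (``equivalent``) pairs are classified once, in canonical document
order.  The directed ``refers_to`` label is only ever assigned to an ordered
pair the schema admits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import metrics
from .corpus import AnnotatedCorpus, Document, EntityMention, RelationMention, repair_bio
from .nn import Adam, Embedding, Linear, Tensor, build_encoder, encoder_from_config
from .nn.autograd import DTYPE
from .schema import SYMMETRIC_LABELS, ExtractionSchema
from .tagger import EncoderConfig, TrainConfig, resolve_lr
from .tokenize import Vocabulary, Word, build_vocabulary, piece_ids, split_words, tokenize_words

logger = logging.getLogger(__name__)

NO_RELATION = "no_relation"


@dataclass(frozen=True)
class CandidatePair:
    arg1: EntityMention
    arg2: EntityMention
    sentence_distance: int


@dataclass(frozen=True)
class RelationExample:
    doc_id: str
    pair: CandidatePair
    label: str


def _canonical_before(a: EntityMention, b: EntityMention) -> bool:
    return (a.start, a.end, a.mention_id) < (b.start, b.end, b.mention_id)


def generate_candidates(
    doc: Document,
    mentions: Sequence[EntityMention],
    schema: ExtractionSchema,
    window: int,
) -> list[CandidatePair]:
    """All type-admissible ordered pairs within the sentence-distance window.

    An ordered pair (a, b) is a candidate when the schema admits a directed
    label for (type(a), type(b)), or — once per unordered pair, in canonical
    offset order — when it admits a symmetric label.  Ordering is
    deterministic (document offsets).
    """
    sent_of = {m.mention_id: doc.sentence_index(m.start) for m in mentions}
    out: list[CandidatePair] = []
    for a in mentions:
        for b in mentions:
            if a.mention_id == b.mention_id:
                continue
            dist = abs(sent_of[a.mention_id] - sent_of[b.mention_id])
            if dist > window:
                continue
            directed = any(
                schema.is_admissible_pair(lbl, a.entity_type, b.entity_type)
                for lbl in schema.relation_labels() if lbl not in SYMMETRIC_LABELS
            )
            symmetric = _canonical_before(a, b) and any(
                schema.is_admissible_pair(lbl, a.entity_type, b.entity_type)
                for lbl in schema.relation_labels() if lbl in SYMMETRIC_LABELS
            )
            if directed or symmetric:
                out.append(CandidatePair(a, b, dist))
    out.sort(key=lambda c: (c.arg1.start, c.arg1.end, c.arg2.start, c.arg2.end))
    return out


def build_training_examples(
    corpus: AnnotatedCorpus,
    schema: ExtractionSchema,
    window: int,
    negative_ratio: float | None = None,
    seed: int = 0,
) -> tuple[list[RelationExample], int]:
    """Positives = annotated relations within the window; negatives = the
    remaining admissible candidates, labelled ``no_relation``.

    Gold relations farther apart than the window cannot be candidates; they
    are dropped and counted (second return value).  ``negative_ratio`` caps
    negatives at that multiple of the positives (default: keep all).
    """
    examples: list[RelationExample] = []
    negatives: list[RelationExample] = []
    dropped = 0
    for doc in corpus.documents:
        by_id = {m.mention_id: m for m in doc.mentions}
        gold: dict[tuple[str, str], str] = {}
        for r in doc.relations:
            a, b = by_id[r.arg1], by_id[r.arg2]
            if r.label in SYMMETRIC_LABELS and not _canonical_before(a, b):
                a, b = b, a
            dist = abs(doc.sentence_index(a.start) - doc.sentence_index(b.start))
            if dist > window:
                dropped += 1
                continue
            gold[(a.mention_id, b.mention_id)] = r.label
        for cand in generate_candidates(doc, doc.mentions, schema, window):
            label = gold.get((cand.arg1.mention_id, cand.arg2.mention_id), NO_RELATION)
            ex = RelationExample(doc.doc_id, cand, label)
            (examples if label != NO_RELATION else negatives).append(ex)
    if dropped:
        logger.info("build_training_examples: %d gold relation(s) beyond window %d",
                    dropped, window)
    if negative_ratio is not None:
        cap = int(round(negative_ratio * max(1, len(examples))))
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(negatives))[:cap]
        negatives = [negatives[i] for i in sorted(idx)]
    return examples + negatives, dropped


# ---------------------------------------------------------------------------
# Window encoding shared by both architectures


@dataclass
class EncodedPair:
    pieces: list[int]
    marker_idx: list[int]        # 0 none, 1 arg1/query, 2 arg2
    arg1_first: int              # piece position
    arg2_first: int
    words: list[Word]
    word_first_piece: list[int]  # piece position of each word's first piece


def window_words(doc: Document, s_lo: int, s_hi: int) -> list[Word]:
    words: list[Word] = []
    for si in range(s_lo, min(s_hi, len(doc.sentences) - 1) + 1):
        s, e = doc.sentences[si]
        words.extend(split_words(doc.text[s:e], offset=s))
    return words


def encode_pair(
    doc: Document,
    arg1: EntityMention,
    arg2: EntityMention | None,
    vocab: Vocabulary,
    max_len: int,
    window: int | None = None,
) -> EncodedPair:
    """Tokenise the sentence window spanning the argument(s) and mark their spans."""
    s1 = doc.sentence_index(arg1.start)
    s2 = doc.sentence_index(arg2.start) if arg2 is not None else s1
    if window is not None and arg2 is None:
        lo, hi = max(0, s1 - window), s1 + window
    else:
        lo, hi = min(s1, s2), max(s1, s2)
    words = window_words(doc, lo, hi)
    if not words:
        raise ValueError("empty context window")
    wps = tokenize_words(words, vocab)
    ids = piece_ids(wps, vocab)
    word_first = [i for i, p in enumerate(wps) if p.is_first]

    def word_marker(w: Word) -> int:
        if w.start < arg1.end and arg1.start < w.end:
            return 1
        if arg2 is not None and w.start < arg2.end and arg2.start < w.end:
            return 2
        return 0

    markers = [word_marker(words[p.word_index]) for p in wps]

    def first_piece_of(arg: EntityMention) -> int:
        for wi, w in enumerate(words):
            if w.start < arg.end and arg.start < w.end:
                return word_first[wi]
        raise ValueError(f"argument {arg.mention_id} outside the window")

    a1 = first_piece_of(arg1)
    a2 = first_piece_of(arg2) if arg2 is not None else a1
    if len(ids) > max_len:
        marked = [i for i, m in enumerate(markers) if m] or [a1, a2]
        span = max(marked) - min(marked) + 1
        if span > max_len:
            raise ValueError("argument pair exceeds the encoder window")
        start = max(0, min(marked) - (max_len - span) // 2)
        start = min(start, len(ids) - max_len)
        ids = ids[start : start + max_len]
        markers = markers[start : start + max_len]
        keep = [wi for wi, fp in enumerate(word_first) if start <= fp < start + max_len]
        words = [words[wi] for wi in keep]
        word_first = [word_first[wi] - start for wi in keep]
        a1, a2 = a1 - start, a2 - start
    return EncodedPair(ids, markers, a1, a2, words, word_first)


def _bucket_batches(items: Sequence, length_of, batch_size: int,
                    rng: np.random.Generator | None) -> list[list]:
    buckets: dict[int, list] = {}
    for it in items:
        buckets.setdefault(length_of(it), []).append(it)
    batches = []
    for k in sorted(buckets):
        group = buckets[k]
        if rng is not None:
            group = [group[i] for i in rng.permutation(len(group))]
        for i in range(0, len(group), batch_size):
            batches.append(group[i : i + batch_size])
    if rng is not None:
        batches = [batches[i] for i in rng.permutation(len(batches))]
    return batches


# ---------------------------------------------------------------------------
# One-step relation classification


class RelationModel:
    """Marker-based relation classifier over labels + ``no_relation``."""

    def __init__(self, vocab: Vocabulary, encoder, schema: ExtractionSchema,
                 window: int = 3, seed: int = 0):
        self.vocab = vocab
        self.encoder = encoder
        self.schema = schema
        self.window = window
        self.classes = tuple(schema.relation_labels()) + (NO_RELATION,)
        self.class_index = {c: i for i, c in enumerate(self.classes)}
        rng = np.random.default_rng(seed + 2)
        self.markers = Embedding(3, encoder.d_model, rng)
        self.classifier = Linear(3 * encoder.d_model, len(self.classes), rng)
        self.meta: dict = {"seed": seed}

    def params(self) -> dict[str, Tensor]:
        out = self.encoder.params("enc.")
        out.update(self.markers.params("markers."))
        out.update(self.classifier.params("cls."))
        return out

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params().items():
            t.data = np.asarray(state[k], dtype=DTYPE).copy()

    def logits(self, encoded: Sequence[EncodedPair]) -> Tensor:
        ids = np.asarray([e.pieces for e in encoded], dtype=np.intp)
        marks = np.asarray([e.marker_idx for e in encoded], dtype=np.intp)
        extra = self.markers(marks)  # (B,T,d)
        enc = self.encoder(ids, extra=extra)
        B = len(encoded)
        rows = np.arange(B)
        a1 = enc[(rows, np.asarray([e.arg1_first for e in encoded], dtype=np.intp))]
        a2 = enc[(rows, np.asarray([e.arg2_first for e in encoded], dtype=np.intp))]
        pooled = enc.mean(axis=1)
        return self.classifier(Tensor.concatenate([pooled, a1, a2], axis=-1))

    def classify(self, doc: Document, pair: CandidatePair) -> str:
        if pair.sentence_distance > self.window:
            raise ValueError("pair outside the context window")
        enc = encode_pair(doc, pair.arg1, pair.arg2, self.vocab, self.encoder.max_len)
        logits = self.logits([enc]).data[0]
        order = np.argsort(-logits, kind="stable")
        for ci in order:
            label = self.classes[ci]
            if label == NO_RELATION:
                return NO_RELATION
            if self._admissible(label, pair):
                return label
        return NO_RELATION

    def _admissible(self, label: str, pair: CandidatePair) -> bool:
        ok = self.schema.is_admissible_pair(label, pair.arg1.entity_type, pair.arg2.entity_type)
        if label in SYMMETRIC_LABELS:
            return ok and _canonical_before(pair.arg1, pair.arg2)
        return ok

    def save(self, path: str | Path) -> None:
        cfg = {"encoder": self.encoder.config(), "vocab": list(self.vocab.itos),
               "window": self.window, "schema": _schema_dict(self.schema),
               "seed": self.meta.get("seed", 0), "meta": self.meta}
        arrays = {f"param/{k}": v for k, v in self.state().items()}
        with open(path, "wb") as fh:
            np.savez(fh, __config__=json.dumps(cfg, sort_keys=True), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RelationModel":
        from .schema import load_schema
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        model = cls(Vocabulary(cfg["vocab"]), encoder_from_config(cfg["encoder"]),
                    load_schema(cfg["schema"]), cfg["window"], cfg.get("seed", 0))
        model.meta = cfg.get("meta", {})
        model.load_state(state)
        return model


def _schema_dict(schema: ExtractionSchema) -> dict:
    from .schema import write_schema
    return write_schema(schema)


def classify_relation(model: RelationModel, doc: Document, pair: CandidatePair) -> str:
    return model.classify(doc, pair)


def extract_relations(
    doc: Document,
    mentions: Sequence[EntityMention],
    model: RelationModel,
    window: int | None = None,
) -> list[RelationMention]:
    """Candidate generation + classification; keeps non-``no_relation`` outputs."""
    window = model.window if window is None else window
    out: list[RelationMention] = []
    cands = generate_candidates(doc, mentions, model.schema, window)
    if not cands:
        return out
    encoded, kept = [], []
    for c in cands:
        try:
            encoded.append(encode_pair(doc, c.arg1, c.arg2, model.vocab, model.encoder.max_len))
            kept.append(c)
        except ValueError:
            logger.info("skipping candidate outside encoder window in %s", doc.doc_id)
    n = 0
    for batch_idx in _bucket_batches(range(len(kept)), lambda i: len(encoded[i].pieces),
                                     64, rng=None):
        logits = model.logits([encoded[i] for i in batch_idx]).data
        for row, i in enumerate(batch_idx):
            c = kept[i]
            order = np.argsort(-logits[row], kind="stable")
            label = NO_RELATION
            for ci in order:
                cand_label = model.classes[ci]
                if cand_label == NO_RELATION:
                    break
                if model._admissible(cand_label, c):
                    label = cand_label
                    break
            if label != NO_RELATION:
                n += 1
                out.append(RelationMention(f"R{n}", label,
                                           c.arg1.mention_id, c.arg2.mention_id))
    return out


def train_relation_model(
    train_corpus: AnnotatedCorpus,
    val_corpus: AnnotatedCorpus,
    schema: ExtractionSchema,
    window: int = 3,
    encoder_config: EncoderConfig | None = None,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    negative_ratio: float | None = None,
    vocab: Vocabulary | None = None,
    pretrained_encoder=None,
) -> tuple[RelationModel, list[dict]]:
    """Train one-step relation classification on gold mentions and relations.

    Model selection keeps the epoch with the best validation positive-class
    micro F1 (predicted vs gold labels over validation candidate pairs).
    """
    enc_cfg = encoder_config or EncoderConfig()
    tr_cfg = train_config or TrainConfig()
    if vocab is None:
        vocab = build_vocabulary(d.text for d in train_corpus.documents)
    encoder = pretrained_encoder or build_encoder(
        enc_cfg.kind, len(vocab), enc_cfg.hidden_width, enc_cfg.layers,
        enc_cfg.heads, enc_cfg.max_len, enc_cfg.seed)
    model = RelationModel(vocab, encoder, schema, window, seed)

    def prepare(corpus: AnnotatedCorpus) -> list[tuple[EncodedPair, int]]:
        examples, _ = build_training_examples(corpus, schema, window,
                                              negative_ratio=negative_ratio, seed=seed)
        docs = {d.doc_id: d for d in corpus.documents}
        prepared = []
        for ex in examples:
            try:
                enc = encode_pair(docs[ex.doc_id], ex.pair.arg1, ex.pair.arg2,
                                  vocab, encoder.max_len)
            except ValueError:
                continue
            prepared.append((enc, model.class_index[ex.label]))
        return prepared

    train_data = prepare(train_corpus)
    if not train_data:
        raise ValueError("no relation training examples")
    val_data = prepare(val_corpus)

    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=resolve_lr(tr_cfg, encoder.kind),
               warmup_steps=tr_cfg.warmup_steps)
    log: list[dict] = []
    best_f1, best_state = -1.0, None
    for epoch in range(tr_cfg.epochs):
        total_loss, n_batches = 0.0, 0
        for batch in _bucket_batches(train_data, lambda it: len(it[0].pieces),
                                     tr_cfg.batch_size, rng):
            encs = [b[0] for b in batch]
            gold = np.asarray([b[1] for b in batch], dtype=np.intp)
            logp = model.logits(encs).log_softmax(axis=-1)
            loss = -logp[(np.arange(len(gold)), gold)].mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
            n_batches += 1
        val_f1 = _example_f1(model, val_data)
        log.append({"epoch": epoch, "train_loss": total_loss / max(1, n_batches),
                    "val_positive_f1": val_f1})
        logger.info("relation epoch %d: loss=%.4f val F1=%.4f",
                    epoch, log[-1]["train_loss"], val_f1)
        if val_f1 > best_f1:
            best_f1, best_state = val_f1, model.state()
    if best_state is not None:
        model.load_state(best_state)
    model.meta.update({"best_val_positive_f1": best_f1, "epochs": tr_cfg.epochs,
                       "window": window})
    return model, log


def _example_f1(model: RelationModel, data: Sequence[tuple[EncodedPair, int]]) -> float:
    """Micro F1 over the positive (non-``no_relation``) classes of example pairs."""
    if not data:
        return 0.0
    no_rel = model.class_index[NO_RELATION]
    tp = fp = fn = 0
    for batch in _bucket_batches(data, lambda it: len(it[0].pieces), 64, rng=None):
        logits = model.logits([b[0] for b in batch]).data
        pred = np.argmax(logits, axis=-1)
        for (_, gold), p in zip(batch, pred):
            if p != no_rel and p == gold:
                tp += 1
            if p != no_rel and p != gold:
                fp += 1
            if gold != no_rel and p != gold:
                fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return metrics.f1(precision, recall)


# ---------------------------------------------------------------------------
# Two-step role labelling


def role_tag_set(schema: ExtractionSchema) -> tuple[str, ...]:
    """BIO tags over role classes relative to a marked query entity.

    ``arg1_of_<label>`` marks a span that is the *first* argument of a
    directed relation whose second argument is the query; ``arg2_of_<label>``
    the converse; symmetric labels get a single undirected role.
    """
    roles: list[str] = []
    for lbl in schema.relation_labels():
        if lbl in SYMMETRIC_LABELS:
            roles.append(lbl)
        else:
            roles.append(f"arg1_of_{lbl}")
            roles.append(f"arg2_of_{lbl}")
    tags = ["O"]
    for r in roles:
        tags.append(f"B-{r}")
        tags.append(f"I-{r}")
    return tuple(tags)


def _role_of(label: str, query_is_arg1: bool) -> str:
    if label in SYMMETRIC_LABELS:
        return label
    # the role names the *other* entity's argument slot
    return f"arg2_of_{label}" if query_is_arg1 else f"arg1_of_{label}"


class RoleLabelModel:
    """Query-conditioned BIO tagger over role classes, plus role -> relation typing."""

    def __init__(self, vocab: Vocabulary, encoder, schema: ExtractionSchema,
                 window: int = 3, seed: int = 0):
        self.vocab = vocab
        self.encoder = encoder
        self.schema = schema
        self.window = window
        self.tags = role_tag_set(schema)
        self.tag_index = {t: i for i, t in enumerate(self.tags)}
        rng = np.random.default_rng(seed + 3)
        self.markers = Embedding(2, encoder.d_model, rng)  # 0 none, 1 query
        self.head = Linear(encoder.d_model, len(self.tags), rng)
        self.meta: dict = {"seed": seed}

    def params(self) -> dict[str, Tensor]:
        out = self.encoder.params("enc.")
        out.update(self.markers.params("markers."))
        out.update(self.head.params("head."))
        return out

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params().items():
            t.data = np.asarray(state[k], dtype=DTYPE).copy()

    def tag_window(self, encoded: EncodedPair) -> list[str]:
        ids = np.asarray([encoded.pieces], dtype=np.intp)
        marks = np.asarray([[min(m, 1) for m in encoded.marker_idx]], dtype=np.intp)
        enc = self.encoder(ids, extra=self.markers(marks))
        firsts = np.asarray(encoded.word_first_piece, dtype=np.intp)
        sel = enc[(np.zeros(len(firsts), dtype=np.intp), firsts)]
        logits = self.head(sel).data  # (W, n_tags)
        raw = [self.tags[int(i)] for i in np.argmax(logits, axis=-1)]
        return repair_bio(raw)

    def role_label(self, doc: Document, query: EntityMention,
                   mentions: Sequence[EntityMention] | None = None,
                   ) -> list[tuple[EntityMention, str]]:
        """Entities related to ``query`` with their relation labels.

        Step 1 tags the query's context window with role classes; step 2 maps
        each recovered span to the best-overlapping provided mention (or a new
        mention over the span) and types its relation, keeping only
        schema-admissible outputs.
        """
        encoded = encode_pair(doc, query, None, self.vocab, self.encoder.max_len,
                              window=self.window)
        tags = self.tag_window(encoded)
        word_spans = [(w.start, w.end) for w in encoded.words]
        out: list[tuple[EntityMention, str]] = []
        from .corpus import bio_to_spans
        n = 0
        for role, s, e in bio_to_spans(tags, word_spans):
            if s <= query.start < e or query.start <= s < query.end:
                continue  # the query's own span
            target = _best_overlap_mention(mentions or (), s, e)
            if target is None:
                n += 1
                target = EntityMention(f"RL{n}", _guess_type(self.schema, role), s, e,
                                       doc.text[s:e])
            label, query_is_arg1 = _role_to_relation(role)
            t_query, t_other = query.entity_type, target.entity_type
            if query_is_arg1:
                ok = self.schema.is_admissible_pair(label, t_query, t_other)
            else:
                ok = self.schema.is_admissible_pair(label, t_other, t_query)
            if ok:
                out.append((target, label))
        return out

    def save(self, path: str | Path) -> None:
        cfg = {"encoder": self.encoder.config(), "vocab": list(self.vocab.itos),
               "window": self.window, "schema": _schema_dict(self.schema),
               "seed": self.meta.get("seed", 0), "meta": self.meta, "kind": "role"}
        arrays = {f"param/{k}": v for k, v in self.state().items()}
        with open(path, "wb") as fh:
            np.savez(fh, __config__=json.dumps(cfg, sort_keys=True), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RoleLabelModel":
        from .schema import load_schema
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        model = cls(Vocabulary(cfg["vocab"]), encoder_from_config(cfg["encoder"]),
                    load_schema(cfg["schema"]), cfg["window"], cfg.get("seed", 0))
        model.meta = cfg.get("meta", {})
        model.load_state(state)
        return model


def _role_to_relation(role: str) -> tuple[str, bool]:
    """(relation label, query_is_arg1) for a role class name."""
    if role.startswith("arg1_of_"):
        return role[len("arg1_of_"):], False  # found span is arg1, query is arg2
    if role.startswith("arg2_of_"):
        return role[len("arg2_of_"):], True
    return role, True  # symmetric


def _best_overlap_mention(mentions: Sequence[EntityMention], s: int, e: int
                          ) -> EntityMention | None:
    best, best_ov = None, 0
    for m in mentions:
        ov = max(0, min(m.end, e) - max(m.start, s))
        if ov > best_ov or (ov == best_ov and ov > 0 and best is not None
                            and (m.start, m.end) < (best.start, best.end)):
            best, best_ov = m, ov
    return best


def _guess_type(schema: ExtractionSchema, role: str) -> str:
    """Fallback type for a recovered span with no provided mention to attach to."""
    label, _ = _role_to_relation(role)
    for r in schema.relation_types:
        if r.label == label and r.first_arg != "ANY":
            return r.first_arg
    return schema.entity_names[0]


def train_role_model(
    train_corpus: AnnotatedCorpus,
    val_corpus: AnnotatedCorpus,
    schema: ExtractionSchema,
    window: int = 3,
    encoder_config: EncoderConfig | None = None,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
    pretrained_encoder=None,
) -> tuple[RoleLabelModel, list[dict]]:
    """Train the two-step role labeller: each gold mention becomes a query whose
    window words are tagged with the roles of its related entities."""
    enc_cfg = encoder_config or EncoderConfig()
    tr_cfg = train_config or TrainConfig()
    if vocab is None:
        vocab = build_vocabulary(d.text for d in train_corpus.documents)
    encoder = pretrained_encoder or build_encoder(
        enc_cfg.kind, len(vocab), enc_cfg.hidden_width, enc_cfg.layers,
        enc_cfg.heads, enc_cfg.max_len, enc_cfg.seed)
    model = RoleLabelModel(vocab, encoder, schema, window, seed)

    def prepare(corpus: AnnotatedCorpus):
        data = []
        for doc in corpus.documents:
            by_id = {m.mention_id: m for m in doc.mentions}
            related: dict[str, list[tuple[EntityMention, str]]] = {}
            for r in doc.relations:
                a, b = by_id[r.arg1], by_id[r.arg2]
                related.setdefault(a.mention_id, []).append((b, _role_of(r.label, True)))
                related.setdefault(b.mention_id, []).append((a, _role_of(r.label, False)))
            for query in doc.mentions:
                try:
                    enc = encode_pair(doc, query, None, vocab, encoder.max_len,
                                      window=window)
                except ValueError:
                    continue
                word_spans = [(w.start, w.end) for w in enc.words]
                tags = ["O"] * len(enc.words)
                for other, role in related.get(query.mention_id, ()):
                    first = True
                    for wi, (ws, we) in enumerate(word_spans):
                        if ws < other.end and other.start < we:
                            tags[wi] = ("B-" if first else "I-") + role
                            first = False
                tag_ids = [model.tag_index[t] for t in tags]
                data.append((enc, tag_ids))
        return data

    train_data = prepare(train_corpus)
    if not train_data:
        raise ValueError("no role-labelling training examples")
    val_data = prepare(val_corpus)

    rng = np.random.default_rng(seed)
    opt = Adam(model.params(), lr=resolve_lr(tr_cfg, encoder.kind),
               warmup_steps=tr_cfg.warmup_steps)
    log: list[dict] = []
    best_acc, best_state = -1.0, None
    for epoch in range(tr_cfg.epochs):
        total_loss, n_batches = 0.0, 0
        for batch in _bucket_batches(train_data,
                                     lambda it: (len(it[0].pieces), len(it[0].words)),
                                     tr_cfg.batch_size, rng):
            encs = [b[0] for b in batch]
            ids = np.asarray([e.pieces for e in encs], dtype=np.intp)
            marks = np.asarray([[min(m, 1) for m in e.marker_idx] for e in encs],
                               dtype=np.intp)
            enc_out = model.encoder(ids, extra=model.markers(marks))
            firsts = np.asarray([e.word_first_piece for e in encs], dtype=np.intp)
            rows = np.arange(len(encs))[:, None]
            sel = enc_out[(rows, firsts)]
            logp = model.head(sel).log_softmax(axis=-1)
            gold = np.asarray([b[1] for b in batch], dtype=np.intp)
            B, W = gold.shape
            r = np.repeat(np.arange(B), W)
            c = np.tile(np.arange(W), B)
            loss = -logp[(r, c, gold.reshape(-1))].mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
            n_batches += 1
        acc = _role_tag_accuracy(model, val_data)
        log.append({"epoch": epoch, "train_loss": total_loss / max(1, n_batches),
                    "val_tag_accuracy": acc})
        logger.info("role epoch %d: loss=%.4f val acc=%.4f",
                    epoch, log[-1]["train_loss"], acc)
        if acc > best_acc:
            best_acc, best_state = acc, model.state()
    if best_state is not None:
        model.load_state(best_state)
    model.meta.update({"best_val_tag_accuracy": best_acc, "epochs": tr_cfg.epochs})
    return model, log


def _role_tag_accuracy(model: RoleLabelModel, data) -> float:
    if not data:
        return 0.0
    correct = total = 0
    for enc, tag_ids in data:
        pred = model.tag_window(enc)
        for p, g in zip(pred, tag_ids):
            correct += int(model.tag_index[p] == g)
            total += 1
    return correct / max(1, total)
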