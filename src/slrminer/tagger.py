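"""Named-entity recognition: encoder + (linear | CRF) decoder over BIO tags.

Per sentence, the pipeline is: word split -> WordPiece -> contextual encoding
of the pieces -> selection of each word's *first* piece vector -> per-word
emission scores over the BIO label set (``O`` plus B-/I- per schema entity
type) -> decoding.  The linear decoder takes a position-wise argmax and
repairs stray ``I-x`` tags to ``B-x``; the CRF decoder runs Viterbi under a
BIO constraint mask and therefore cannot emit an invalid sequence.

Sentences are the decoding unit.  Gold mentions that overlap (single-layer
BIO cannot encode them) are resolved by keeping the longer mention; mentions
crossing a sentence boundary are split at the boundary for tagging.
Training is plain mini-batch Adam from a fixed seed; model selection keeps
the epoch with the best validation relaxed F1.  An encoder can optionally be
pretrained first with masked language modelling on raw text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import metrics
from .corpus import (
    AnnotatedCorpus,
    Document,
    EntityMention,
    bio_to_spans,
    repair_bio,
    resolve_overlaps,
    segment,
    snap_to_words,
    spans_to_bio,
)
from .crf import CrfParameters, crf_nll, linear_decode, viterbi_decode
from .nn import Adam, Linear, Tensor, build_encoder, encoder_from_config
from .nn.autograd import DTYPE
from .schema import ExtractionSchema, bio_labels
from .tokenize import Vocabulary, Word, build_vocabulary, piece_ids, split_words, tokenize_words

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EncoderConfig:
    """Desk-scale defaults: 2 layers, width 128, 4 heads, 256-piece maximum."""

    kind: str = "transformer"
    hidden_width: int = 128
    layers: int = 2
    heads: int = 4
    max_len: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind == "bilstm" and self.hidden_width % 2:
            raise ValueError("bilstm hidden width must be even (split across directions)")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 4
    batch_size: int = 32
    lr: float | None = None  # resolved per encoder kind (recurrent nets need more)
    warmup_steps: int = 50


DEFAULT_LR = {"transformer": 5e-4, "bilstm": 2e-3}


def resolve_lr(cfg: TrainConfig, encoder_kind: str) -> float:
    return cfg.lr if cfg.lr is not None else DEFAULT_LR.get(encoder_kind, 5e-4)


@dataclass
class SentenceInstance:
    doc_id: str
    sent_span: tuple[int, int]
    words: list[Word]
    pieces: list[int]
    first_positions: list[int]
    tag_ids: list[int] | None = None


# ---------------------------------------------------------------------------
# Instance preparation


def sentence_instance(
    doc: Document,
    sent_span: tuple[int, int],
    vocab: Vocabulary,
    max_len: int,
    label_index: dict[str, int] | None = None,
) -> SentenceInstance | None:
    s, e = sent_span
    words = split_words(doc.text[s:e], offset=s)
    if not words:
        return None
    wps = tokenize_words(words, vocab)
    # truncate whole words so the piece sequence fits the encoder window
    counts: dict[int, int] = {}
    for p in wps:
        counts[p.word_index] = counts.get(p.word_index, 0) + 1
    kept_words = 0
    total = 0
    for wi in range(len(words)):
        if total + counts[wi] > max_len:
            logger.info("truncating sentence in %s at %d/%d words", doc.doc_id, wi, len(words))
            break
        total += counts[wi]
        kept_words += 1
    words = words[:kept_words]
    wps = [p for p in wps if p.word_index < kept_words]
    firsts = [i for i, p in enumerate(wps) if p.is_first]

    tag_ids = None
    if label_index is not None:
        word_spans = [(w.start, w.end) for w in words]
        sent_mentions = []
        for m in doc.mentions:
            if m.start < e and s < m.end:  # clip at the sentence boundary
                cs, ce = max(m.start, s), min(m.end, e)
                if ce > cs:
                    sent_mentions.append(replace(m, start=cs, end=ce, surface=doc.text[cs:ce]))
        sent_mentions = [snap_to_words(m, word_spans, doc.text) for m in sent_mentions]
        kept, _ = resolve_overlaps(sent_mentions)
        kept = [m for m in kept if m.start < words[-1].end]
        tags = spans_to_bio(word_spans, kept)
        tag_ids = [label_index[t] for t in tags]
    return SentenceInstance(doc.doc_id, sent_span, words, piece_ids(wps, vocab), firsts, tag_ids)


def _bucketed_batches(
    instances: Sequence[SentenceInstance],
    batch_size: int,
    rng: np.random.Generator | None,
) -> list[list[SentenceInstance]]:
    buckets: dict[tuple[int, int], list[SentenceInstance]] = {}
    for inst in instances:
        buckets.setdefault((len(inst.pieces), len(inst.words)), []).append(inst)
    batches: list[list[SentenceInstance]] = []
    for key in sorted(buckets):
        group = buckets[key]
        if rng is not None:
            group = [group[i] for i in rng.permutation(len(group))]
        for i in range(0, len(group), batch_size):
            batches.append(group[i : i + batch_size])
    if rng is not None:
        batches = [batches[i] for i in rng.permutation(len(batches))]
    return batches


# ---------------------------------------------------------------------------
# Model


class TaggerModel:
    """Serialisable NER model: vocabulary + encoder + emission head (+ CRF)."""

    def __init__(self, vocab: Vocabulary, encoder, head: Linear, labels: Sequence[str],
                 schema_id: str, decoder: str = "crf", crf: CrfParameters | None = None,
                 meta: dict | None = None):
        if decoder not in ("linear", "crf"):
            raise ValueError(f"unknown decoder {decoder!r}")
        if decoder == "crf" and crf is None:
            raise ValueError("crf decoder requires CrfParameters")
        self.vocab = vocab
        self.encoder = encoder
        self.head = head
        self.labels = tuple(labels)
        self.label_index = {l: i for i, l in enumerate(self.labels)}
        self.schema_id = schema_id
        self.decoder = decoder
        self.crf = crf
        self.meta = meta or {}

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict[str, Tensor]:
        out = self.encoder.params("enc.")
        out.update(self.head.params("head."))
        if self.crf is not None:
            out.update(self.crf.params("crf."))
        return out

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params().items():
            t.data = np.asarray(state[k], dtype=DTYPE).copy()

    # -- forward ------------------------------------------------------------
    def encode(self, pieces: Sequence[int]) -> np.ndarray:
        """Contextual vectors for one piece-id sequence, shape (T, d)."""
        if len(pieces) == 0:
            return np.zeros((0, self.encoder.d_model), dtype=DTYPE)
        ids = np.asarray(pieces, dtype=np.intp)[None, :]
        return self.encoder(ids).data[0]

    def batch_emissions(self, batch: Sequence[SentenceInstance]) -> Tensor:
        ids = np.asarray([inst.pieces for inst in batch], dtype=np.intp)
        firsts = np.asarray([inst.first_positions for inst in batch], dtype=np.intp)
        enc = self.encoder(ids)  # (B,T,d)
        rows = np.arange(len(batch))[:, None]
        sel = enc[(rows, firsts)]  # (B,W,d)
        return self.head(sel)  # (B,W,L)

    def decode(self, emissions: np.ndarray) -> list[str]:
        """Tag strings for one sentence's (W, L) emission matrix."""
        if self.decoder == "crf":
            ids = viterbi_decode(emissions, self.crf)
            return [self.labels[i] for i in ids]
        ids = linear_decode(emissions)
        return repair_bio([self.labels[i] for i in ids])

    def predict_document(self, doc: Document, merge_cross_sentence: bool = False) -> list[EntityMention]:
        if not doc.sentences:
            sentences, paragraphs = segment(doc.text)
            doc = replace_boundaries(doc, sentences, paragraphs)
        insts = []
        for span in doc.sentences:
            inst = sentence_instance(doc, span, self.vocab, self.encoder.max_len)
            if inst is not None:
                insts.append(inst)
        found: list[tuple[str, int, int]] = []
        for batch in _bucketed_batches(insts, 64, rng=None):
            em = self.batch_emissions(batch).data
            for b, inst in enumerate(batch):
                tags = self.decode(em[b])
                word_spans = [(w.start, w.end) for w in inst.words]
                found.extend(bio_to_spans(tags, word_spans))
        found.sort(key=lambda x: (x[1], x[2]))
        if merge_cross_sentence:
            found = _merge_adjacent(found, doc.text)
        return [
            EntityMention(f"P{i + 1}", t, s, e, doc.text[s:e])
            for i, (t, s, e) in enumerate(found)
        ]

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        cfg = {
            "labels": list(self.labels),
            "schema_id": self.schema_id,
            "decoder": self.decoder,
            "encoder": self.encoder.config(),
            "vocab": list(self.vocab.itos),
            "crf_seed": self.meta.get("crf_seed", 0),
            "meta": self.meta,
        }
        arrays = {f"param/{k}": v for k, v in self.state().items()}
        with open(path, "wb") as fh:
            np.savez(fh, __config__=json.dumps(cfg, sort_keys=True), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["__config__"]))
            state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        vocab = Vocabulary(cfg["vocab"])
        encoder = encoder_from_config(cfg["encoder"])
        rng = np.random.default_rng(cfg["encoder"]["seed"] + 1)
        head = Linear(encoder.d_model, len(cfg["labels"]), rng)
        crf = None
        if cfg["decoder"] == "crf":
            crf = CrfParameters(cfg["labels"], seed=cfg.get("crf_seed", 0))
        model = cls(vocab, encoder, head, cfg["labels"], cfg["schema_id"],
                    cfg["decoder"], crf, cfg.get("meta", {}))
        model.load_state(state)
        return model


def replace_boundaries(doc: Document, sentences, paragraphs) -> Document:
    return Document(doc.doc_id, doc.text, list(sentences), list(paragraphs),
                    list(doc.mentions), list(doc.relations))


def _merge_adjacent(found: list[tuple[str, int, int]], text: str) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for t, s, e in found:
        if out and out[-1][0] == t and text[out[-1][2]: s].strip() == "":
            logger.info("merging cross-sentence run of %s at %d", t, s)
            out[-1] = (t, out[-1][1], e)
        else:
            out.append((t, s, e))
    return out


# ---------------------------------------------------------------------------
# Training


def corpus_instances(corpus: AnnotatedCorpus, vocab: Vocabulary, max_len: int,
                     label_index: dict[str, int]) -> list[SentenceInstance]:
    out = []
    for doc in corpus.documents:
        for span in doc.sentences:
            inst = sentence_instance(doc, span, vocab, max_len, label_index)
            if inst is not None:
                out.append(inst)
    return out


def train_tagger(
    train_corpus: AnnotatedCorpus,
    val_corpus: AnnotatedCorpus,
    schema: ExtractionSchema,
    encoder_config: EncoderConfig | None = None,
    decoder: str = "crf",
    seed: int = 0,
    train_config: TrainConfig | None = None,
    vocab: Vocabulary | None = None,
    pretrained_encoder=None,
) -> tuple[TaggerModel, list[dict]]:
    """Fine-tune an encoder + decoder on an annotated corpus.

    Returns the model (restored to the epoch with the best validation relaxed
    F1) and a per-epoch training log.  Fully deterministic for a fixed seed.
    """
    if not train_corpus.documents:
        raise ValueError("empty training corpus")
    enc_cfg = encoder_config or EncoderConfig()
    tr_cfg = train_config or TrainConfig()
    labels = list(bio_labels(schema))
    label_index = {l: i for i, l in enumerate(labels)}

    if vocab is None:
        vocab = build_vocabulary(d.text for d in train_corpus.documents)
    if pretrained_encoder is not None:
        encoder = pretrained_encoder
    else:
        encoder = build_encoder(enc_cfg.kind, len(vocab), enc_cfg.hidden_width,
                                enc_cfg.layers, enc_cfg.heads, enc_cfg.max_len, enc_cfg.seed)
    rng = np.random.default_rng(seed)
    head = Linear(encoder.d_model, len(labels), np.random.default_rng(enc_cfg.seed + 1))
    crf = CrfParameters(labels, seed=enc_cfg.seed) if decoder == "crf" else None
    model = TaggerModel(vocab, encoder, head, labels, schema.schema_id, decoder, crf,
                        meta={"seed": seed, "crf_seed": enc_cfg.seed})

    train_insts = corpus_instances(train_corpus, vocab, encoder.max_len, label_index)
    if not train_insts:
        raise ValueError("training corpus yields no sentences")
    val_docs = [(d, d.mentions) for d in val_corpus.documents]

    opt = Adam(model.params(), lr=resolve_lr(tr_cfg, encoder.kind),
               warmup_steps=tr_cfg.warmup_steps)
    log: list[dict] = []
    best_f1, best_state, best_epoch = -1.0, None, -1
    for epoch in range(tr_cfg.epochs):
        total_loss, n_batches = 0.0, 0
        for batch in _bucketed_batches(train_insts, tr_cfg.batch_size, rng):
            em = model.batch_emissions(batch)  # (B,W,L)
            gold = np.asarray([inst.tag_ids for inst in batch], dtype=np.intp)
            if decoder == "crf":
                loss = crf_nll(em, crf, gold).mean()
            else:
                logp = em.log_softmax(axis=-1)
                B, W = gold.shape
                rows = np.repeat(np.arange(B), W)
                cols = np.tile(np.arange(W), B)
                loss = -logp[(rows, cols, gold.reshape(-1))].mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
            n_batches += 1
        val_f1 = _validation_f1(model, val_docs, schema)
        log.append({"epoch": epoch, "train_loss": total_loss / max(1, n_batches),
                    "val_relaxed_f1": val_f1})
        logger.info("epoch %d: loss=%.4f val relaxed F1=%.4f", epoch, log[-1]["train_loss"], val_f1)
        if val_f1 > best_f1:
            best_f1, best_state, best_epoch = val_f1, model.state(), epoch
    if best_state is not None:
        model.load_state(best_state)
    model.meta.update({"best_epoch": best_epoch, "best_val_relaxed_f1": best_f1,
                       "epochs": tr_cfg.epochs})
    return model, log


def _validation_f1(model: TaggerModel, val_docs, schema: ExtractionSchema) -> float:
    if not val_docs:
        return 0.0
    pairs = [(model.predict_document(d), gold) for d, gold in val_docs]
    return metrics.evaluate(pairs, schema).relaxed.f1


def predict_entities(model: TaggerModel, doc: Document) -> list[EntityMention]:
    """Convenience wrapper: segment if needed, tag every sentence, return mentions."""
    return model.predict_document(doc)


# ---------------------------------------------------------------------------
# Masked language modelling


def mlm_pretrain(
    encoder,
    texts: Iterable[str],
    vocab: Vocabulary,
    mask_rate: float = 0.15,
    steps: int = 500,
    seed: int = 0,
    batch_size: int = 16,
    lr: float = 5e-4,
) -> tuple[object, list[float]]:
    """Self-supervised pretraining: predict masked wordpieces from context.

    Of the sampled positions, 80% become ``[MASK]``, 10% a random piece and
    10% stay unchanged; only sampled positions contribute to the loss.
    Returns the encoder and the per-step loss history.
    """
    if not (0.0 < mask_rate < 1.0):
        raise ValueError(f"mask_rate must lie in (0,1), got {mask_rate}")
    sentences: list[list[int]] = []
    for text in texts:
        for s, e in segment(text)[0]:
            words = split_words(text[s:e], offset=s)
            if not words:
                continue
            wps = tokenize_words(words, vocab)
            ids = piece_ids(wps, vocab)[: encoder.max_len]
            if len(ids) >= 2:
                sentences.append(ids)
    if not sentences:
        raise ValueError("empty pretraining corpus")
    buckets: dict[int, list[list[int]]] = {}
    for ids in sentences:
        buckets.setdefault(len(ids), []).append(ids)
    keys = sorted(buckets)
    weights = np.array([len(buckets[k]) for k in keys], dtype=float)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    head = Linear(encoder.d_model, len(vocab), np.random.default_rng(seed + 1))
    params = encoder.params("enc.")
    params.update(head.params("mlm."))
    opt = Adam(params, lr=lr)
    losses: list[float] = []
    for _ in range(steps):
        k = keys[rng.choice(len(keys), p=weights)]
        group = buckets[k]
        idx = rng.integers(0, len(group), size=min(batch_size, len(group)))
        ids = np.asarray([group[i] for i in idx], dtype=np.intp)
        B, T = ids.shape
        n_mask = max(1, int(round(mask_rate * T)))
        masked = ids.copy()
        rows, cols = [], []
        for b in range(B):
            pos = rng.choice(T, size=n_mask, replace=False)
            for p in pos:
                rows.append(b)
                cols.append(p)
                r = rng.random()
                if r < 0.8:
                    masked[b, p] = vocab.mask_id
                elif r < 0.9:
                    masked[b, p] = rng.integers(len(RESERVED_SAFE), len(vocab))
        rows_a, cols_a = np.asarray(rows), np.asarray(cols)
        enc_out = encoder(masked)
        logits = head(enc_out[(rows_a, cols_a)])  # (n_masked, V)
        logp = logits.log_softmax(axis=-1)
        gold = ids[rows_a, cols_a]
        loss = -logp[(np.arange(len(gold)), gold)].mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    return encoder, losses


RESERVED_SAFE = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")


def save_encoder(encoder, vocab: Vocabulary, path: str | Path) -> None:
    """Persist a (possibly pretrained) encoder together with its vocabulary."""
    cfg = {"encoder": encoder.config(), "vocab": list(vocab.itos)}
    arrays = {f"param/{k}": t.data.copy() for k, t in encoder.params().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __config__=json.dumps(cfg, sort_keys=True), **arrays)


def load_encoder(path: str | Path):
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["__config__"]))
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    encoder = encoder_from_config(cfg["encoder"])
    encoder.load_state(state)
    return encoder, Vocabulary(cfg["vocab"])
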