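"""Candidate windows, training-example construction, both relation architectures."""

import numpy as np
import pytest

from slrminer import load_schema
from slrminer.corpus import Document, EntityMention, RelationMention, segment
from slrminer.relations import (
    NO_RELATION,
    CandidatePair,
    RelationModel,
    build_training_examples,
    classify_relation,
    extract_relations,
    generate_candidates,
    role_tag_set,
    train_relation_model,
    train_role_model,
)
from slrminer.corpus import AnnotatedCorpus
from slrminer.synthgen import SynthConfig, generate_corpus
from slrminer.tagger import EncoderConfig, TrainConfig

TINY = EncoderConfig(kind="transformer", hidden_width=32, layers=1, heads=2,
                     max_len=128, seed=0)


def toy_document(sent_indices):
    """One admissible (egfr_metric) mention in each of the given sentences."""
    sentences = []
    text_parts = []
    offset = 0
    mentions = []
    n_sents = max(sent_indices) + 1
    for si in range(n_sents):
        s = "The mean eGFR was reported here."
        text_parts.append(s)
        sentences.append((offset, offset + len(s)))
        if si in sent_indices:
            start = offset + s.index("mean eGFR")
            mentions.append(EntityMention(f"T{si}", "egfr_metric", start, start + 9,
                                          "mean eGFR"))
        offset += len(s) + 1
    text = " ".join(text_parts)
    return Document("toy", text, sentences, [(0, len(text))], mentions)


class TestCandidates:
    def test_window_distance_filter(self, slr2):
        doc = toy_document({0, 1, 4})
        cands = generate_candidates(doc, doc.mentions, slr2, window=3)
        dists = {(c.arg1.mention_id, c.arg2.mention_id): c.sentence_distance for c in cands}
        # equivalent Any/Any admits each unordered pair once (canonical order)
        assert ("T0", "T1") in dists and dists[("T0", "T1")] == 1
        assert ("T1", "T4") in dists and dists[("T1", "T4")] == 3
        assert ("T0", "T4") not in dists  # distance 4 > window
        assert ("T1", "T0") not in dists  # canonical order only (no directed label)

    def test_included_at_distance_two(self, slr2):
        doc = toy_document({1, 3})
        cands = generate_candidates(doc, doc.mentions, slr2, window=3)
        assert len(cands) == 1 and cands[0].sentence_distance == 2

    def test_excluded_beyond_window(self, slr2):
        doc = toy_document({0, 6})
        assert generate_candidates(doc, doc.mentions, slr2, window=5) == []

    def test_brute_force_oracle(self, slr2, small_corpus):
        """generate_candidates == double loop + filter, on synthetic documents."""
        for doc in small_corpus.documents[:20]:
            for window in (3, 5):
                got = {(c.arg1.mention_id, c.arg2.mention_id)
                       for c in generate_candidates(doc, doc.mentions, slr2, window)}
                expected = set()
                for a in doc.mentions:
                    for b in doc.mentions:
                        if a.mention_id == b.mention_id:
                            continue
                        d = abs(doc.sentence_index(a.start) - doc.sentence_index(b.start))
                        if d > window:
                            continue
                        if slr2.is_admissible_pair("refers_to", a.entity_type, b.entity_type):
                            expected.add((a.mention_id, b.mention_id))
                        if (a.start, a.end, a.mention_id) < (b.start, b.end, b.mention_id):
                            expected.add((a.mention_id, b.mention_id))  # equivalent Any/Any
                assert got == expected

    def test_window_monotonicity(self, slr2, small_corpus):
        for doc in small_corpus.documents:
            c3 = {(c.arg1.mention_id, c.arg2.mention_id)
                  for c in generate_candidates(doc, doc.mentions, slr2, 3)}
            c5 = {(c.arg1.mention_id, c.arg2.mention_id)
                  for c in generate_candidates(doc, doc.mentions, slr2, 5)}
            assert c3 <= c5


class TestTrainingExamples:
    def _doc_with_one_relation(self):
        doc = toy_document({0, 1, 2})
        # add an egfr_number so a refers_to candidate exists
        text = doc.text
        num_start = doc.sentences[0][0]  # overlay onto sentence 0 text positions
        doc.relations = [RelationMention("R1", "equivalent", "T0", "T1")]
        return doc

    def test_positive_negative_split(self, slr2):
        doc = self._doc_with_one_relation()
        corpus = AnnotatedCorpus([doc], "slr2")
        examples, dropped = build_training_examples(corpus, slr2, window=3)
        labels = sorted(e.label for e in examples)
        # candidates: (T0,T1),(T0,T2),(T1,T2); one annotated
        assert labels == ["equivalent", NO_RELATION, NO_RELATION]
        assert dropped == 0

    def test_window_zero_drops_cross_sentence_gold(self, slr2):
        doc = toy_document({0, 2})
        doc.relations = [RelationMention("R1", "equivalent", "T0", "T2")]
        corpus = AnnotatedCorpus([doc], "slr2")
        examples, dropped = build_training_examples(corpus, slr2, window=0)
        assert dropped == 1
        assert all(e.label == NO_RELATION for e in examples)

    def test_no_candidates(self, slr2):
        doc = toy_document({0})
        corpus = AnnotatedCorpus([doc], "slr2")
        examples, dropped = build_training_examples(corpus, slr2, window=3)
        assert examples == [] and dropped == 0

    def test_negative_ratio_caps_negatives(self, slr2, small_corpus):
        full, _ = build_training_examples(small_corpus, slr2, window=3)
        capped, _ = build_training_examples(small_corpus, slr2, window=3,
                                            negative_ratio=0.5, seed=0)
        n_pos = sum(1 for e in full if e.label != NO_RELATION)
        n_neg_capped = sum(1 for e in capped if e.label == NO_RELATION)
        assert n_neg_capped == round(0.5 * n_pos)


@pytest.fixture(scope="module")
def overfit_relation_model(slr2):
    corpus = generate_corpus(SynthConfig(schema_id="slr2", n_documents=12, seed=9)).corpus
    model, log = train_relation_model(corpus, corpus, slr2, window=3,
                                      encoder_config=TINY, seed=0,
                                      train_config=TrainConfig(epochs=8))
    return corpus, model, log


class TestRelationClassification:
    def test_overfit_recovers_gold_relations(self, overfit_relation_model, slr2):
        corpus, model, _ = overfit_relation_model
        recovered = total = 0
        for doc in corpus.documents:
            by_id = {m.mention_id: m for m in doc.mentions}
            pred = {(r.label, r.arg1, r.arg2)
                    for r in extract_relations(doc, doc.mentions, model)}
            for r in doc.relations:
                a, b = by_id[r.arg1], by_id[r.arg2]
                d = abs(doc.sentence_index(a.start) - doc.sentence_index(b.start))
                if d > 3:
                    continue  # outside the window by construction
                total += 1
                canon = {(r.label, r.arg1, r.arg2), (r.label, r.arg2, r.arg1)}
                if canon & pred:
                    recovered += 1
        assert total > 0
        assert recovered / total >= 0.9

    def test_outputs_schema_admissible(self, overfit_relation_model, slr2):
        corpus, model, _ = overfit_relation_model
        for doc in corpus.documents[:4]:
            by_id = {m.mention_id: m for m in doc.mentions}
            for r in extract_relations(doc, doc.mentions, model):
                assert slr2.is_admissible_pair(
                    r.label, by_id[r.arg1].entity_type, by_id[r.arg2].entity_type)

    def test_no_mentions_no_relations(self, overfit_relation_model):
        _, model, _ = overfit_relation_model
        text = "Nothing to see here."
        doc = Document("d", text, *segment(text))
        assert extract_relations(doc, [], model) == []

    def test_deterministic_classification(self, overfit_relation_model, slr2):
        corpus, model, _ = overfit_relation_model
        doc = next(d for d in corpus.documents if d.mentions)
        cands = generate_candidates(doc, doc.mentions, slr2, 3)
        if cands:
            assert classify_relation(model, doc, cands[0]) == \
                classify_relation(model, doc, cands[0])

    def test_pair_beyond_window_rejected(self, overfit_relation_model, slr2):
        _, model, _ = overfit_relation_model
        doc = toy_document({0, 3})
        pair = CandidatePair(doc.mentions[0], doc.mentions[1], 9)
        with pytest.raises(ValueError, match="window"):
            model.classify(doc, pair)

    def test_save_load_round_trip(self, overfit_relation_model, tmp_path):
        corpus, model, _ = overfit_relation_model
        path = tmp_path / "re.npz"
        model.save(path)
        again = RelationModel.load(path)
        s1, s2 = model.state(), again.state()
        for k in s1:
            assert np.array_equal(s1[k], s2[k])
        doc = corpus.documents[0]
        a = [(r.label, r.arg1, r.arg2) for r in extract_relations(doc, doc.mentions, model)]
        b = [(r.label, r.arg1, r.arg2) for r in extract_relations(doc, doc.mentions, again)]
        assert a == b


class TestRoleLabelling:
    def test_role_tag_set(self, slr2):
        tags = role_tag_set(slr2)
        assert tags[0] == "O"
        assert "B-arg1_of_refers_to" in tags and "B-equivalent" in tags
        assert len(tags) == 1 + 2 * 3  # O + B/I over {arg1_of, arg2_of, equivalent}

    def test_overfit_recovers_related_entities(self, slr2):
        corpus = generate_corpus(SynthConfig(schema_id="slr2", n_documents=10, seed=13)).corpus
        model, log = train_role_model(corpus, corpus, slr2, window=3,
                                      encoder_config=TINY, seed=0,
                                      train_config=TrainConfig(epochs=20, lr=1e-3))
        assert log[-1]["train_loss"] < log[0]["train_loss"]
        hits = total = 0
        for doc in corpus.documents:
            by_id = {m.mention_id: m for m in doc.mentions}
            for r in doc.relations:
                a, b = by_id[r.arg1], by_id[r.arg2]
                if abs(doc.sentence_index(a.start) - doc.sentence_index(b.start)) > 3:
                    continue
                total += 1
                found = model.role_label(doc, a, doc.mentions)
                if any(other.mention_id == b.mention_id and lbl == r.label
                       for other, lbl in found):
                    hits += 1
        assert total > 0
        assert hits / total >= 0.7

    def test_query_with_no_relations_returns_empty_or_admissible(self, slr2):
        corpus = generate_corpus(SynthConfig(schema_id="slr2", n_documents=4, seed=21)).corpus
        model, _ = train_role_model(corpus, corpus, slr2, window=3,
                                    encoder_config=TINY, seed=0,
                                    train_config=TrainConfig(epochs=1))
        doc = corpus.documents[0]
        for query in doc.mentions:
            for other, label in model.role_label(doc, query, doc.mentions):
                ok1 = slr2.is_admissible_pair(label, query.entity_type, other.entity_type)
                ok2 = slr2.is_admissible_pair(label, other.entity_type, query.entity_type)
                assert ok1 or ok2
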