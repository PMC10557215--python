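import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slrminer.corpus import (
    AnnotatedCorpus,
    AnnotationError,
    BratParseError,
    Document,
    EntityMention,
    RelationMention,
    SplitSpec,
    bio_to_spans,
    is_valid_bio,
    largest_remainder_counts,
    partition,
    read_brat,
    repair_bio,
    resolve_overlaps,
    segment,
    snap_to_words,
    spans_to_bio,
    write_brat,
)
from slrminer.tokenize import split_words


class TestSegment:
    def test_two_sentences(self):
        sentences, paragraphs = segment("A. B.")
        assert len(sentences) == 2
        assert len(paragraphs) == 1

    def test_blank_line_makes_two_paragraphs(self):
        text = "First block here.\n\nSecond block here."
        sentences, paragraphs = segment(text)
        assert len(paragraphs) == 2
        assert len(sentences) == 2

    def test_decimal_point_does_not_split(self):
        text = "eGFR was 20 mL/min/1.73 m2. Next sentence."
        sentences, _ = segment(text)
        assert len(sentences) == 2
        assert text[slice(*sentences[0])].endswith("m2.")

    def test_abbreviation_guard(self):
        sentences, _ = segment("Smith et al. reported eGFR values. A second point.")
        assert len(sentences) == 2

    def test_sentences_inside_one_paragraph(self):
        text = "One. Two. Three.\n\nFour. Five."
        doc = Document("d", text, *segment(text))
        doc.validate()

    def test_deterministic(self):
        text = "Alpha beta. Gamma delta!\n\nEpsilon?"
        assert segment(text) == segment(text)


class TestBrat:
    def test_t_line_parse(self, slr2):
        text = "Patients were given 24h of dexamethasone daily."
        start = text.index("dexamethasone")
        ann = f"T1\tarm_description {start} {start + 13}\tdexamethasone\n"
        doc = read_brat(text, ann, slr2)
        (m,) = doc.mentions
        assert (m.entity_type, m.start, m.end, m.surface) == \
            ("arm_description", start, start + 13, "dexamethasone")

    def test_r_line_parse(self, slr2):
        text = "Patients received migalastat at 123 mg."
        ann = ("T1\tarm_description 18 28\tmigalastat\n"
               "T2\tarm_dosage 32 38\t123 mg\n"
               "R1\trefers_to Arg1:T1 Arg2:T2\n")
        doc = read_brat(text, ann, slr2)
        (r,) = doc.relations
        assert (r.label, r.arg1, r.arg2) == ("refers_to", "T1", "T2")

    def test_empty_ann(self, slr2):
        doc = read_brat("Some text.", "", slr2)
        assert doc.mentions == [] and doc.relations == []

    @pytest.mark.parametrize("ann,msg", [
        ("T1\tarm_description 0 500\tx", "outside text"),
        ("T1\tarm_description 0 4\twrong", "mismatch"),
        ("T1\tbogus_type 0 4\tSome", "unknown entity type"),
        ("T1\tarm_description 0 4;6 8\tSome te", "discontinuous"),
        ("R1\trefers_to Arg1:T8 Arg2:T9", "dangling"),
    ])
    def test_parse_errors_name_the_line(self, slr2, ann, msg):
        with pytest.raises(BratParseError, match=msg):
            read_brat("Some text here.", ann, slr2)

    def test_round_trip(self, slr2, small_corpus):
        for doc in small_corpus.documents[:10]:
            text, ann = write_brat(doc)
            again = read_brat(text, ann, slr2, doc.doc_id)
            assert text == doc.text
            assert ({(m.entity_type, m.start, m.end) for m in again.mentions}
                    == {(m.entity_type, m.start, m.end) for m in doc.mentions})
            assert len(again.relations) == len(doc.relations)

    def test_no_annotations_gives_empty_ann(self):
        doc = Document("d", "Hello there.", *segment("Hello there."))
        _, ann = write_brat(doc)
        assert ann == ""

    def test_equivalent_written_in_offset_order(self, slr2):
        text = "Alpha arm one. Beta arm two."
        doc = Document("d", text, *segment(text))
        doc.mentions = [
            EntityMention("T1", "arm_description", 15, 19, "Beta"),
            EntityMention("T2", "arm_description", 0, 5, "Alpha"),
        ]
        doc.relations = [RelationMention("R1", "equivalent", "T1", "T2")]
        _, ann = write_brat(doc)
        # T ids are renumbered by offset; arg1 must be the earlier mention
        assert "R1\tequivalent Arg1:T1 Arg2:T2" in ann


class TestBio:
    def test_mention_to_tags(self):
        words = split_words("median PFS was 10 months")
        spans = [(w.start, w.end) for w in words]
        m = EntityMention("T1", "pfs_metric", 0, 10, "median PFS")
        assert spans_to_bio(spans, [m]) == \
            ["B-pfs_metric", "I-pfs_metric", "O", "O", "O"]

    def test_no_mentions_all_outside(self):
        spans = [(0, 3), (4, 7)]
        assert spans_to_bio(spans, []) == ["O", "O"]

    def test_adjacent_same_type_mentions_get_two_begins(self):
        spans = [(0, 3), (4, 7)]
        ms = [EntityMention("T1", "x", 0, 3, "abc"),
              EntityMention("T2", "x", 4, 7, "def")]
        assert spans_to_bio(spans, ms) == ["B-x", "B-x"]

    def test_overlapping_mentions_rejected(self):
        spans = [(0, 3), (4, 7)]
        ms = [EntityMention("T1", "x", 0, 5, "abc d"),
              EntityMention("T2", "y", 4, 7, "def")]
        with pytest.raises(AnnotationError):
            spans_to_bio(spans, ms)

    def test_runs_to_spans(self):
        assert bio_to_spans(["B-x", "I-x", "O"], [(0, 2), (3, 5), (6, 8)]) == \
            [("x", 0, 5)]

    def test_type_switch_breaks_run(self):
        assert bio_to_spans(["B-x", "B-y", "I-y"], [(0, 1), (2, 3), (4, 5)]) == \
            [("x", 0, 1), ("y", 2, 5)]

    def test_repair(self):
        assert repair_bio(["O", "I-x"]) == ["O", "B-x"]
        assert repair_bio(["B-x", "I-y"]) == ["B-x", "B-y"]
        assert is_valid_bio(repair_bio(["I-x", "I-x", "O", "I-y"]))

    @given(st.lists(st.tuples(st.integers(0, 19), st.sampled_from(["x", "y"])),
                    max_size=6, unique_by=lambda t: t[0]))
    @settings(deadline=None, derandomize=True)
    def test_round_trip_random_mentions(self, picks):
        """spans->bio->spans is the identity for word-aligned non-overlapping mentions."""
        word_spans = [(3 * i, 3 * i + 2) for i in range(20)]
        mentions = [EntityMention(f"T{i}", typ, 3 * w, 3 * w + 2, "ab")
                    for i, (w, typ) in enumerate(picks)]
        tags = spans_to_bio(word_spans, mentions)
        assert is_valid_bio(tags)
        back = bio_to_spans(tags, word_spans)
        # adjacent same-type word mentions at consecutive words stay separate (B-,B-)
        assert {(m.entity_type, m.start, m.end) for m in mentions} == set(back)


class TestOverlapResolution:
    def test_longer_mention_wins(self):
        ms = [EntityMention("T1", "x", 0, 10, "a" * 10),
              EntityMention("T2", "y", 5, 8, "aaa")]
        kept, dropped = resolve_overlaps(ms)
        assert [m.mention_id for m in kept] == ["T1"]
        assert [m.mention_id for m in dropped] == ["T2"]

    def test_tie_breaks_earlier_start(self):
        ms = [EntityMention("T2", "y", 2, 6, "abcd"),
              EntityMention("T1", "x", 0, 4, "abcd")]
        kept, _ = resolve_overlaps(ms)
        assert [m.mention_id for m in kept] == ["T1"]

    def test_snap_outward(self):
        text = "dexamethasone therapy"
        word_spans = [(0, 13), (14, 21)]
        m = EntityMention("T1", "arm_description", 3, 13, text[3:13])
        snapped = snap_to_words(m, word_spans, text)
        assert (snapped.start, snapped.end, snapped.surface) == (0, 13, "dexamethasone")


class TestPartition:
    def _corpus(self, n_paragraphs):
        docs = []
        for i in range(n_paragraphs):
            text = f"Paragraph number {i} stands alone."
            docs.append(Document(f"d{i}", text, *segment(text)))
        return AnnotatedCorpus(docs, "slr2")

    def test_counts_70_16_14(self):
        train, val, test = partition(self._corpus(100), SplitSpec((0.70, 0.16, 0.14), 0))
        assert (len(train.documents), len(val.documents), len(test.documents)) == (70, 16, 14)

    def test_counts_largest_remainder(self):
        train, val, test = partition(self._corpus(200), SplitSpec((0.77, 0.115, 0.115), 0))
        assert (len(train.documents), len(val.documents), len(test.documents)) == (154, 23, 23)

    def test_deterministic_for_fixed_seed(self, small_corpus):
        spec = SplitSpec((0.77, 0.115, 0.115), seed=9)
        a = partition(small_corpus, spec)
        b = partition(small_corpus, spec)
        for sa, sb in zip(a, b):
            assert [d.doc_id for d in sa.documents] == [d.doc_id for d in sb.documents]

    def test_disjoint_cover(self, small_corpus):
        splits = partition(small_corpus, SplitSpec((0.5, 0.25, 0.25), seed=3))
        ids = [d.doc_id for s in splits for d in s.documents]
        assert len(ids) == len(set(ids)) == small_corpus.n_paragraphs()

    def test_annotations_survive_rebasing(self, slr2, small_corpus):
        for sub in partition(small_corpus, SplitSpec((0.77, 0.115, 0.115), seed=1)):
            sub.validate(slr2)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.4, 0.2), 0)

    def test_largest_remainder_exact(self):
        assert largest_remainder_counts(100, [0.70, 0.16, 0.14]) == [70, 16, 14]
        assert largest_remainder_counts(200, [0.77, 0.115, 0.115]) == [154, 23, 23]
        assert sum(largest_remainder_counts(17, [0.77, 0.115, 0.115])) == 17
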