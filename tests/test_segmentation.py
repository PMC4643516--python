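"""Masking, subsection detection, segment splitting and layout statistics."""

from echotex import (
    Document,
    SegmentationConfig,
    Span,
    detect_prep_phrases,
    detect_subsections,
    layout_stats,
    mask_ignored_sections,
    split_segments,
)
from echotex.segmentation import HEADERLESS


def _segments(text, terminology, matcher, config=None):
    doc = Document(id="d", text=text)
    config = config or SegmentationConfig(
        ignore_section_patterns=terminology.ignore_section_patterns
    )
    masked = mask_ignored_sections(doc, config.ignore_section_patterns, matcher)
    segs = []
    for sub in detect_subsections(doc, matcher, masked):
        for seg in split_segments(sub, doc, config):
            segs.append(text[seg.span.begin:seg.span.end])
    return segs


class TestMasking:
    def test_tee_block_masked_until_next_header(self, matcher):
        text = "LVEF 60%.\nTEE: befund.\nzeile zwei.\nBeurteilung: ok.\n"
        masked = mask_ignored_sections(Document(id="d", text=text), (r"^\s*TEE\b",), matcher)
        assert len(masked) == 1
        assert text[masked[0].begin:masked[0].end] == "TEE: befund.\nzeile zwei.\n"

    def test_no_ignore_headers_no_masking(self, matcher):
        doc = Document(id="d", text="LVEF 60%.\nBeurteilung: ok.\n")
        assert mask_ignored_sections(doc, (r"^\s*TEE\b",), matcher) == []

    def test_two_disjoint_blocks_two_ordered_spans(self, matcher):
        text = "TEE: a.\nBefund: b.\nTEE: c.\nBefund: d.\n"
        masked = mask_ignored_sections(Document(id="d", text=text), (r"^\s*TEE\b",), matcher)
        assert [text[s.begin:s.end] for s in masked] == ["TEE: a.\n", "TEE: c.\n"]


class TestSubsections:
    def test_object_header_sets_context(self, terminology, matcher):
        doc = Document(id="d", text="Mitralklappe:\nGeringe Insuffizienz.\n")
        subs = detect_subsections(doc, matcher, [])
        assert [s.context_object_id for s in subs] == ["mv"]

    def test_text_before_first_header_is_headerless(self, matcher):
        doc = Document(id="d", text="Vorbemerkung.\nMitralklappe: ok.\n")
        subs = detect_subsections(doc, matcher, [])
        assert subs[0].label == HEADERLESS
        assert subs[0].context_object_id is None
        assert subs[1].context_object_id == "mv"

    def test_attribute_label_line_is_not_a_header(self, matcher):
        # "LVEF: 60%" names an attribute, not an object context
        doc = Document(id="d", text="Mitralklappe: ok.\nLVEF: 60%\nweiter.\n")
        subs = detect_subsections(doc, matcher, [])
        assert [s.context_object_id for s in subs] == ["mv"]

    def test_list_element_header(self, matcher):
        doc = Document(id="d", text="- AK: unauffällig\n- MK: geringe Insuffizienz\n")
        subs = detect_subsections(doc, matcher, [])
        assert [s.context_object_id for s in subs] == ["av", "mv"]

    def test_partition_masked_plus_subsections_cover_text(self, terminology, matcher):
        text = "Intro.\nTEE: weg.\nMitralklappe: ok.\nLVEF 60%\n"
        doc = Document(id="d", text=text)
        masked = mask_ignored_sections(doc, terminology.ignore_section_patterns, matcher)
        subs = detect_subsections(doc, matcher, masked)
        spans = sorted([s for s in masked] + [s.span for s in subs], key=lambda s: s.begin)
        assert spans[0].begin == 0 and spans[-1].end == len(text)
        for a, b in zip(spans, spans[1:]):
            assert a.end == b.begin


class TestSegments:
    def test_newlines_and_sentences_split(self, terminology, matcher):
        segs = _segments("Satz eins. Satz zwei.\nZeile zwei.\n", terminology, matcher)
        assert segs == ["Satz eins.", "Satz zwei.", "Zeile zwei."]

    def test_comma_splits_plain_clauses(self, terminology, matcher):
        segs = _segments("Keine Insuffizienz, mittelgradige Stenose.\n", terminology, matcher)
        assert segs == ["Keine Insuffizienz", "mittelgradige Stenose."]

    def test_shared_head_enumeration_not_split(self, terminology, matcher):
        text = "Unauffälliger Befund an Aortenklappe, Mitralklappe und Trikuspidalklappe.\n"
        segs = _segments(text, terminology, matcher)
        assert len(segs) == 1

    def test_measurement_enumeration_is_split(self, terminology, matcher):
        segs = _segments("Septum 9mm, Hinterwand 9mm\n", terminology, matcher)
        assert segs == ["Septum 9mm", "Hinterwand 9mm"]

    def test_decimal_comma_not_a_boundary(self, terminology, matcher):
        segs = _segments("Vmax 1,1 m/s\n", terminology, matcher)
        assert segs == ["Vmax 1,1 m/s"]

    def test_und_with_parenthesized_measurements_splits(self, terminology, matcher):
        text = ("Normal großer linker Ventrikel (LVDd 48 mm) und "
                "dilatierter linker Vorhof (LA 44 mm).\n")
        segs = _segments(text, terminology, matcher)
        assert len(segs) == 2
        assert "LVDd" in segs[0] and "LA" in segs[1]

    def test_header_text_excluded_from_segments(self, terminology, matcher):
        segs = _segments("Mitralklappe: geringe Insuffizienz.\n", terminology, matcher)
        assert segs == ["geringe Insuffizienz."]

    def test_list_marker_trimmed(self, terminology, matcher):
        segs = _segments("- AK: unauffällig\n", terminology, matcher)
        assert segs == ["unauffällig"]


class TestPrepPhrases:
    def test_bei_phrase_detected(self, matcher):
        text = "Diastolische Funktion bei Tachykardie nicht sicher beurteilbar."
        doc = Document(id="d", text=text)
        from echotex.segmentation import Segment
        seg = Segment(span=Span(0, len(text)), subsection_index=0)
        phrases = detect_prep_phrases(seg, doc, ("bei",), ("nicht",))
        assert len(phrases) == 1
        assert text[phrases[0].begin:phrases[0].end] == "bei Tachykardie"


class TestLayoutStats:
    def test_counts_nonspace_and_list_elements(self):
        doc = Document(id="d", text="- a: x\n- b: y\nlang " + "x" * 10)
        nonspace, elems = layout_stats(doc)
        assert nonspace == len("-a:x-b:ylang") + 10
        assert elems == 2

    def test_monotone_in_text_extension(self):
        base = "- a: x\nbefund\n"
        n1, e1 = layout_stats(Document(id="d", text=base))
        n2, e2 = layout_stats(Document(id="d", text=base + "- b: y\nmehr\n"))
        assert n2 > n1 and e2 >= e1
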