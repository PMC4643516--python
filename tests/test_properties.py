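"""Property-based invariants across the library."""

import random

from hypothesis import given, strategies as st

from echotex import (
    Document,
    EvalCounts,
    build_aggregates,
    categorize,
    compute_metrics,
    extract_document,
    layout_stats,
    match_annotations,
    micro_average,
    normalize_phrase,
)
from echotex.evaluation import CATEGORIES, ReferenceAnnotation, round_half_up
from echotex.segmentation import (
    SegmentationConfig,
    detect_subsections,
    mask_ignored_sections,
    split_segments,
)
from naive_matcher import compiled_find_keys, naive_find

# word pool mixing variant surfaces, their fragments, casing variants and noise
_WORDS = [
    "Mitralklappe", "mitralklappe", "MITRALKLAPPE", "Mitralklappeninsuffizienz",
    "Insuffizienz", "Insuff", "Stenose", "keine", "kein", "ohne", "gering",
    "geringe", "mittelgradige", "hochgradig", "Grad", "I", "II", "III", "AK",
    "MK", "LVEF", "LVDd", "Vmax", "Septum", "Hinterwand", "Perikarderguss",
    "Tachykardie", "normal", "Befund", "unauffällig", "Klappe", "xyz", "mm",
    "m/s", "%", "60", "9", "1,1", ":", ",", ".", "(", ")", "-",
]


def _random_text(rng: random.Random, max_words: int = 12) -> str:
    n = rng.randint(0, max_words)
    parts = []
    for _ in range(n):
        parts.append(rng.choice(_WORDS))
        parts.append(rng.choice([" ", " ", " ", "\n", ""]))
    return "".join(parts)


class TestMatcherOracle:
    def test_compiled_equals_naive_on_randomized_strings(self, terminology, matcher):
        rng = random.Random(20240601)
        for _ in range(200):
            text = _random_text(rng)
            assert compiled_find_keys(matcher, text) == naive_find(terminology, text), repr(text)

    @given(st.lists(st.sampled_from(_WORDS), max_size=10))
    def test_compiled_equals_naive_hypothesis(self, terminology, matcher, words):
        text = " ".join(words)
        assert compiled_find_keys(matcher, text) == naive_find(terminology, text)


class TestSegmentationInvariants:
    @given(st.text(alphabet="abXY .,:\n-09Insufiz", max_size=120))
    def test_partition_property(self, terminology, matcher, text):
        doc = Document(id="d", text=text)
        masked = mask_ignored_sections(doc, terminology.ignore_section_patterns, matcher)
        subs = detect_subsections(doc, matcher, masked)
        spans = sorted(list(masked) + [s.span for s in subs], key=lambda s: s.begin)
        if text:
            assert spans[0].begin == 0 and spans[-1].end == len(text)
        for a, b in zip(spans, spans[1:]):
            assert a.end == b.begin

    @given(st.text(alphabet="abXY .,:\n-09", max_size=120))
    def test_segments_nest_in_their_subsection(self, terminology, matcher, text):
        doc = Document(id="d", text=text)
        cfg = SegmentationConfig(ignore_section_patterns=terminology.ignore_section_patterns)
        for sub in detect_subsections(doc, matcher, []):
            for seg in split_segments(sub, doc, cfg):
                assert sub.span.begin <= seg.span.begin <= seg.span.end <= sub.span.end

    @given(st.text(alphabet="ab .:\n-", max_size=120))
    def test_layout_stats_bounds(self, text):
        nonspace, elems = layout_stats(Document(id="d", text=text))
        assert 0 <= nonspace <= len(text)
        assert 0 <= elems <= text.count("\n") + 1


class TestExtractionInvariants:
    @given(st.lists(st.sampled_from(_WORDS), max_size=14))
    def test_never_crashes_and_spans_in_bounds(self, terminology, words):
        text = " ".join(words)
        res = extract_document(Document(id="d", text=text), terminology)
        for p in res.pairs:
            assert 0 <= p.begin <= p.end <= len(text)
            assert p.value_id in {
                v.value_id for v in terminology.effective_values(p.attribute_id)
            }

    @given(st.lists(st.sampled_from(_WORDS), max_size=14))
    def test_suppression_soundness(self, terminology, words):
        # an implicit presence pair never coexists with an activator pair on
        # the same attribute *instance* (suppression is per mention: a
        # negation binds only the nearest attribute occurrence)
        text = " ".join(words)
        res = extract_document(Document(id="d", text=text), terminology)
        by_instance = {}
        for p in res.pairs:
            key = (p.segment_index, p.attribute_id, p.attribute_span)
            by_instance.setdefault(key, []).append(p)
        for pairs in by_instance.values():
            has_implicit = any(p.implicit for p in pairs)
            has_activator = any(
                not terminology.value_suppress(p.attribute_id, p.value_id)
                for p in pairs if not p.implicit
            )
            assert not (has_implicit and has_activator)


class TestNormalizationProperties:
    @given(st.text(max_size=80))
    def test_normalize_idempotent(self, s):
        assert normalize_phrase(normalize_phrase(s)) == normalize_phrase(s)

    @given(st.text(max_size=80))
    def test_normalize_removes_multidigit_runs(self, s):
        out = normalize_phrase(s)
        ascii_digit = lambda ch: "0" <= ch <= "9"  # str.isdigit also covers superscripts
        assert not any(
            ascii_digit(a) and ascii_digit(b) for a, b in zip(out, out[1:])
        )


class TestAggregationProperties:
    @given(st.permutations(list(range(4))))
    def test_counts_independent_of_document_order(self, terminology, matcher, order):
        texts = [
            "Mitralklappe: Geringe Insuffizienz.\n",
            "Mitralklappe: Keine Insuffizienz.\n",
            "LVEF 60%\n",
            "Aortenklappe: unauffällig.\n",
        ]
        docs = [Document(id=f"d{i}", text=texts[i]) for i in order]
        agg = build_aggregates(docs, t=terminology, matcher=matcher)
        base = build_aggregates(
            [Document(id=f"d{i}", text=t_) for i, t_ in enumerate(texts)],
            t=terminology, matcher=matcher,
        )
        assert {k: v.counts for k, v in agg.items()} == {k: v.counts for k, v in base.items()}


class TestMetricProperties:
    counts = st.builds(
        EvalCounts,
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn_covered=st.integers(0, 50), fn_missing=st.integers(0, 50),
    )

    @given(counts)
    def test_metrics_in_unit_interval(self, c):
        m = compute_metrics(c)
        for x in (m.precision, m.recall, m.f1):
            assert x is None or 0.0 <= x <= 1.0

    @given(st.lists(counts, min_size=1, max_size=6))
    def test_micro_equals_metrics_of_pooled_counts(self, parts):
        total = EvalCounts()
        for c in parts:
            total = total + c
        assert micro_average(parts) == compute_metrics(total)

    @given(counts, st.integers(1, 20))
    def test_adding_fp_never_raises_precision(self, c, extra):
        before = compute_metrics(c).precision
        after = compute_metrics(EvalCounts(c.tp, c.fp + extra, c.fn_covered, c.fn_missing)).precision
        if before is not None:
            assert after <= before

    @given(st.floats(0, 1, allow_nan=False), st.integers(0, 6))
    def test_round_half_up_within_half_ulp(self, x, nd):
        r = round_half_up(x, nd)
        assert abs(r - x) <= 0.5 * 10 ** -nd + 1e-12

    @given(st.lists(
        st.tuples(st.sampled_from("abc"), st.sampled_from("vw"),
                  st.integers(0, 5), st.integers(6, 9)),
        max_size=6,
    ))
    def test_matching_against_self_is_perfect(self, keys):
        gold = [ReferenceAnnotation("d", a, v, b, e) for a, v, b, e in keys]

        class P:
            def __init__(self, a, v, b, e):
                self.attribute_id, self.value_id, self.begin, self.end = a, v, b, e

        pred = [P(a, v, b, e) for a, v, b, e in keys]
        c = match_annotations(gold, pred)
        assert (c.tp, c.fp, c.fn) == (len(keys), 0, 0)


class TestCategorizerTotality:
    @given(st.text(max_size=300), st.one_of(st.none(), st.sampled_from(["A", "B"])))
    def test_every_document_gets_exactly_one_category(self, text, site):
        assert categorize(Document(id="d", text=text, site=site)) in CATEGORIES
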