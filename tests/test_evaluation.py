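"""Metric arithmetic, exact-agreement matching, categorization, and the
recomputation of the bundled published count tables."""

import pytest

from echotex import (
    CategoryConfig,
    Document,
    EvalCounts,
    Metrics,
    ReferenceAnnotation,
    agreement_accuracy,
    categorize,
    compute_metrics,
    evaluate_corpus,
    macro_average,
    match_annotations,
    micro_average,
)
from echotex.datasets import aspect_counts, category_counts
from echotex.evaluation import round_half_up


def ann(attr, val, b, e, doc="d", missing=False):
    return ReferenceAnnotation(doc, attr, val, b, e, missing_concept=missing)


class FakePair:
    def __init__(self, attr, val, b, e):
        self.attribute_id, self.value_id, self.begin, self.end = attr, val, b, e


class TestMatching:
    def test_exact_key_match_is_tp(self):
        c = match_annotations([ann("a", "v", 0, 5)], [FakePair("a", "v", 0, 5)])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_offset_shift_is_fp_plus_fn(self):
        c = match_annotations([ann("a", "v", 0, 5)], [FakePair("a", "v", 0, 6)])
        assert (c.tp, c.fp, c.fn_covered) == (0, 1, 1)

    def test_one_to_one_no_double_credit(self):
        c = match_annotations([ann("a", "v", 0, 5)],
                              [FakePair("a", "v", 0, 5), FakePair("a", "v", 0, 5)])
        assert (c.tp, c.fp) == (1, 1)

    def test_missing_concept_counts_separately(self):
        c = match_annotations([ann(None, None, 0, 5, missing=True)], [])
        assert (c.fn_covered, c.fn_missing, c.fn) == (0, 1, 1)

    def test_doc_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_annotations([ann("a", "v", 0, 5, doc="other")], [], doc_id="d")


class TestMetrics:
    def test_formulas(self):
        m = compute_metrics(EvalCounts(tp=8, fp=2, fn_covered=2))
        assert m.precision == 0.8 and m.recall == 0.8 and m.f1 == pytest.approx(0.8)

    def test_zero_denominators_are_none(self):
        m = compute_metrics(EvalCounts())
        assert m.precision is None and m.recall is None and m.f1 is None
        m = compute_metrics(EvalCounts(fp=1))
        assert m.precision == 0.0 and m.recall is None and m.f1 is None

    def test_round_half_up_at_boundary(self):
        assert round_half_up(0.9615, 3) == 0.962
        assert round_half_up(0.0005, 3) == 0.001
        assert round_half_up(None, 3) is None

    def test_micro_pools_counts(self):
        parts = [EvalCounts(tp=1, fp=1), EvalCounts(tp=3, fn_covered=1)]
        m = micro_average(parts)
        assert m.precision == 0.8 and m.recall == 0.8

    def test_macro_means_defined_components(self):
        m = macro_average([Metrics(1.0, 0.5, None), Metrics(0.5, None, 0.4)])
        assert m.precision == 0.75 and m.recall == 0.5 and m.f1 == 0.4

    def test_precision_antitone_in_fp(self):
        base = compute_metrics(EvalCounts(tp=10, fp=1, fn_covered=2))
        worse = compute_metrics(EvalCounts(tp=10, fp=5, fn_covered=2))
        assert worse.precision < base.precision
        assert worse.recall == base.recall


class TestAgreement:
    def test_identical_sets_agree_fully(self):
        a = [ann("a", "v", 0, 5), ann("b", "w", 6, 9)]
        assert agreement_accuracy(a, list(a)) == 1.0

    def test_disjoint_sets_agree_zero(self):
        assert agreement_accuracy([ann("a", "v", 0, 5)], [ann("b", "w", 0, 5)]) == 0.0

    def test_partial_overlap_uses_union_denominator(self):
        a = [ann("a", "v", 0, 5), ann("b", "w", 6, 9)]
        b = [ann("a", "v", 0, 5), ann("c", "x", 6, 9)]
        assert agreement_accuracy(a, b) == pytest.approx(1 / 3)

    def test_both_empty_is_full_agreement(self):
        assert agreement_accuracy([], []) == 1.0

    def test_symmetric(self):
        a = [ann("a", "v", 0, 5)]
        b = [ann("a", "v", 0, 5), ann("b", "w", 6, 9)]
        assert agreement_accuracy(a, b) == agreement_accuracy(b, a)


class TestCategorize:
    def test_precedence_order(self):
        cfg = CategoryConfig(excluded_sites=frozenset({"EXT"}))
        assert categorize(Document(id="d", text="x" * 1000, site="EXT"), cfg) == "excluded_site"
        assert categorize(Document(id="d", text="kurz"), cfg) == "defective"
        listy = "\n".join(f"- a{i}: wert" for i in range(20))
        assert categorize(Document(id="d", text=listy), cfg) == "uncommon"
        assert categorize(Document(id="d", text="x" * 900), cfg) == "dominant"
        assert categorize(Document(id="d", text="x" * 300), cfg) == "unstructured"

    def test_total_function_over_arbitrary_text(self):
        from echotex.evaluation import CATEGORIES
        for text in ["", "\n\n", "a" * 99, "a" * 100, "a" * 800, "- :\n" * 50]:
            assert categorize(Document(id="d", text=text)) in CATEGORIES


class TestCorpusReport:
    def test_micro_over_documents_and_aspect_breakdown(self):
        gold = {
            "d1": [ann("a", "v", 0, 5, doc="d1")],
            "d2": [ann("b", "w", 0, 5, doc="d2"), ann("a", "v", 6, 9, doc="d2")],
        }
        pred = {
            "d1": [FakePair("a", "v", 0, 5)],
            "d2": [FakePair("b", "w", 0, 5)],
        }
        rep = evaluate_corpus(gold, pred, aspect_map={"A": {"a"}, "B": {"b"}})
        assert rep.micro.precision == 1.0
        assert rep.micro.recall == pytest.approx(2 / 3)
        assert rep.per_aspect["A"].fn == 1 and rep.per_aspect["B"].fn == 0
        assert rep.aspect_micro.recall == pytest.approx(2 / 3)

    def test_report_serializes_with_rounding(self):
        rep = evaluate_corpus({"d": [ann("a", "v", 0, 5)]}, {"d": [FakePair("a", "v", 0, 5)]})
        d = rep.to_dict(2)
        assert d["micro"] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}


class TestPublishedTables:
    """The bundled count tables must reproduce their published metrics
    exactly under this module's arithmetic."""

    def test_dominant_category_metrics(self):
        m = compute_metrics(category_counts()["dominant"]).rounded(3)
        assert (m.precision, m.recall, m.f1) == (0.996, 0.961, 0.978)

    def test_unstructured_category_metrics(self):
        m = compute_metrics(category_counts()["unstructured"]).rounded(3)
        assert (m.precision, m.recall, m.f1) == (0.920, 0.560, 0.696)

    def test_aspect_micro(self):
        m = micro_average(list(aspect_counts().values())).rounded(3)
        assert (m.precision, m.recall, m.f1) == (0.993, 0.986, 0.989)

    def test_aspect_macro(self):
        m = macro_average(
            [compute_metrics(c) for c in aspect_counts().values()]
        ).rounded(3)
        assert (m.precision, m.recall, m.f1) == (0.991, 0.950, 0.963)

    def test_aspect_counts_sum_to_micro_totals(self):
        total = EvalCounts()
        for c in aspect_counts().values():
            total = total + c
        assert (total.tp, total.fp, total.fn) == (2872, 20, 41)

    def test_sparse_aspect_row(self):
        m = compute_metrics(aspect_counts()["MV Stenosis"]).rounded(2)
        assert (m.precision, m.recall, m.f1) == (1.0, 0.33, 0.5)
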