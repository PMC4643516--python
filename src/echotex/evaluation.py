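"""Reference-standard comparison and the metric suite.

Predictions and reference annotations match only when they agree exactly in
type (attribute id, value id) and in begin/end offsets.  Missed reference
annotations split into *covered* (the concept exists in the terminology) and
*missing* (it does not) — the latter measures terminology coverage rather
than engine quality.

Metrics: precision p = tp/(tp+fp), recall r = tp/(tp+fn) with
fn = fn_covered + fn_missing, and f1 = 2pr/(p+r).  Micro averages pool the
counts; macro averages take the arithmetic mean of per-group metrics.
Undefined components (zero denominators) are represented as ``None`` and
excluded from macro means.  Reported values are rounded half-up.

Document categorization reproduces the corpus filters: excluded sites,
defective (<100 non-whitespace characters), uncommon layout (>= 5 list
elements), dominant layout (>= 800 characters, < 5 list elements) and
unstructured (100-799 characters, < 5 list elements).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .extraction import AttributeValuePair
from .segmentation import Document, layout_stats


@dataclass(frozen=True)
class ReferenceAnnotation:
    doc_id: str
    attribute_id: Optional[str]
    value_id: Optional[str]
    begin: int
    end: int
    missing_concept: bool = False
    label: Optional[str] = None  # free-text label for missing-concept mentions

    def key(self) -> tuple:
        return (self.attribute_id, self.value_id, self.begin, self.end)


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn_covered: int = 0
    fn_missing: int = 0

    @property
    def fn(self) -> int:
        return self.fn_covered + self.fn_missing

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn_covered + other.fn_covered,
            self.fn_missing + other.fn_missing,
        )


@dataclass(frozen=True)
class Metrics:
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def rounded(self, ndigits: int = 3) -> "Metrics":
        return Metrics(
            round_half_up(self.precision, ndigits),
            round_half_up(self.recall, ndigits),
            round_half_up(self.f1, ndigits),
        )


def round_half_up(x: Optional[float], ndigits: int = 3) -> Optional[float]:
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def match_annotations(
    gold: Sequence[ReferenceAnnotation],
    pred: Sequence[AttributeValuePair],
    doc_id: Optional[str] = None,
) -> EvalCounts:
    """One-to-one exact matching of predictions against reference annotations.

    tp: predictions agreeing with a reference annotation on attribute id,
    value id, begin and end.  fp: unmatched predictions.  Unmatched reference
    annotations count as fn_covered or fn_missing by their flag.
    """
    if doc_id is not None:
        bad = [g for g in gold if g.doc_id != doc_id]
        if bad:
            raise ValueError(f"annotations for {bad[0].doc_id!r} scored against {doc_id!r}")
    remaining: dict[tuple, list[ReferenceAnnotation]] = {}
    for g in gold:
        remaining.setdefault(g.key(), []).append(g)
    counts = EvalCounts()
    for p in pred:
        key = (p.attribute_id, p.value_id, p.begin, p.end)
        bucket = remaining.get(key)
        if bucket:
            bucket.pop()
            counts.tp += 1
        else:
            counts.fp += 1
    for bucket in remaining.values():
        for g in bucket:
            if g.missing_concept:
                counts.fn_missing += 1
            else:
                counts.fn_covered += 1
    return counts


def compute_metrics(c: EvalCounts) -> Metrics:
    """Unrounded precision/recall/f1 with zero-denominator conventions."""
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if p is None or r is None or (p == 0.0 and r == 0.0):
        f1 = None
    else:
        f1 = 2 * p * r / (p + r)
    return Metrics(p, r, f1)


def micro_average(counts: Sequence[EvalCounts]) -> Metrics:
    """Metrics of the component-wise sum of per-group counts."""
    if not counts:
        raise ValueError("micro_average needs at least one counts object")
    total = EvalCounts()
    for c in counts:
        total = total + c
    return compute_metrics(total)


def macro_average(per_group: Sequence[Metrics]) -> Metrics:
    """Arithmetic mean per component over groups where it is defined."""
    if not per_group:
        raise ValueError("macro_average needs at least one metrics object")

    def mean(values: list[float]) -> Optional[float]:
        return sum(values) / len(values) if values else None

    return Metrics(
        mean([m.precision for m in per_group if m.precision is not None]),
        mean([m.recall for m in per_group if m.recall is not None]),
        mean([m.f1 for m in per_group if m.f1 is not None]),
    )


def agreement_accuracy(
    a: Sequence[ReferenceAnnotation], b: Sequence[ReferenceAnnotation]
) -> float:
    """Inter-annotator accuracy: |matched| / |union of both annotation sets|.

    Annotations match on type and exact offsets; matched pairs count once.
    """
    remaining: dict[tuple, int] = {}
    for ann in b:
        remaining[ann.key()] = remaining.get(ann.key(), 0) + 1
    matched = 0
    for ann in a:
        k = ann.key()
        if remaining.get(k, 0) > 0:
            remaining[k] -= 1
            matched += 1
    union = len(a) + len(b) - matched
    return matched / union if union else 1.0


# ---------------------------------------------------------------------------
# document categories
# ---------------------------------------------------------------------------

CATEGORIES = ("excluded_site", "defective", "uncommon", "dominant", "unstructured")


@dataclass
class CategoryConfig:
    excluded_sites: frozenset[str] = frozenset()
    min_chars: int = 100
    dominant_chars: int = 800
    min_list_elements: int = 5


def categorize(doc: Document, cfg: Optional[CategoryConfig] = None) -> str:
    """Document category by site, length and layout, in filter precedence:
    excluded_site, defective, uncommon, dominant, unstructured."""
    cfg = cfg or CategoryConfig()
    if doc.site is not None and doc.site in cfg.excluded_sites:
        return "excluded_site"
    nonspace, list_elements = layout_stats(doc)
    if nonspace < cfg.min_chars:
        return "defective"
    if list_elements >= cfg.min_list_elements:
        return "uncommon"
    if nonspace >= cfg.dominant_chars:
        return "dominant"
    return "unstructured"


# ---------------------------------------------------------------------------
# corpus-level evaluation report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_document: dict[str, EvalCounts]
    micro: Metrics
    per_aspect: dict[str, EvalCounts] = field(default_factory=dict)
    aspect_micro: Optional[Metrics] = None
    aspect_macro: Optional[Metrics] = None

    def to_dict(self, ndigits: int = 3) -> dict:
        def m(x: Optional[Metrics]) -> Optional[dict]:
            if x is None:
                return None
            r = x.rounded(ndigits)
            return {"precision": r.precision, "recall": r.recall, "f1": r.f1}

        def c(x: EvalCounts) -> dict:
            return {
                "tp": x.tp, "fp": x.fp,
                "fn_covered": x.fn_covered, "fn_missing": x.fn_missing,
            }

        out = {
            "per_document": {k: c(v) for k, v in sorted(self.per_document.items())},
            "micro": m(self.micro),
        }
        if self.per_aspect:
            out["per_aspect"] = {k: c(v) for k, v in sorted(self.per_aspect.items())}
            out["aspect_micro"] = m(self.aspect_micro)
            out["aspect_macro"] = m(self.aspect_macro)
        return out


def evaluate_corpus(
    gold_by_doc: dict[str, Sequence[ReferenceAnnotation]],
    pred_by_doc: dict[str, Sequence[AttributeValuePair]],
    aspect_map: Optional[dict[str, set[str]]] = None,
) -> EvaluationReport:
    """Score a corpus: per-document counts, pooled micro metrics and, when an
    aspect map is given, per-aspect counts with micro and macro averages."""
    per_document: dict[str, EvalCounts] = {}
    for doc_id in sorted(set(gold_by_doc) | set(pred_by_doc)):
        per_document[doc_id] = match_annotations(
            list(gold_by_doc.get(doc_id, ())), list(pred_by_doc.get(doc_id, ())), doc_id
        )
    micro = micro_average(list(per_document.values())) if per_document else Metrics(None, None, None)

    per_aspect: dict[str, EvalCounts] = {}
    aspect_micro = aspect_macro = None
    if aspect_map is not None:
        attr_to_aspect = {
            aid: aspect for aspect, aids in aspect_map.items() for aid in aids
        }
        per_aspect = {aspect: EvalCounts() for aspect in aspect_map}
        for doc_id in per_document:
            gold = list(gold_by_doc.get(doc_id, ()))
            pred = list(pred_by_doc.get(doc_id, ()))
            for aspect in aspect_map:
                g = [x for x in gold if attr_to_aspect.get(x.attribute_id) == aspect]
                p = [x for x in pred if attr_to_aspect.get(x.attribute_id) == aspect]
                per_aspect[aspect] = per_aspect[aspect] + match_annotations(g, p, doc_id)
        populated = {a: c for a, c in per_aspect.items() if c.tp + c.fp + c.fn > 0}
        if populated:
            aspect_micro = micro_average(list(populated.values()))
            aspect_macro = macro_average([compute_metrics(c) for c in populated.values()])
    return EvaluationReport(per_document, micro, per_aspect, aspect_micro, aspect_macro)
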