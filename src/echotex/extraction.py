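"""Ontology-driven attribute-value extraction.

Pipeline (per document): mask out-of-domain sections → detect subsections →
split segments → detect prepositional phrases → match concepts → resolve
object contexts → pair attributes with values → semantic postprocessing
(implicit presence, suppression, redundancy).

Disambiguation follows the containment structure: for an ambiguous attribute
(an ``object_attribute``), the resolving object is looked up in this order —
the compound's implied object, the nearest object mention in the same
segment (preceding before following), then the subsection's context object.
The search never leaves the subsection; attributes that stay unresolved are
dropped (precision over recall) and logged in the diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .segmentation import (
    Document,
    Segment,
    SegmentationConfig,
    Span,
    Subsection,
    detect_prep_phrases,
    detect_subsections,
    mask_ignored_sections,
    split_segments,
)
from .terminology import (
    COMPOSED_SEP,
    CompiledMatcher,
    MatchTarget,
    RawHit,
    Terminology,
    compile_matcher,
    tokenize,
)

UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class ConceptMatch:
    """One surface match of a concept (or of several candidate concepts that
    share the matched variant, e.g. the four per-valve senses of
    "Insuffizienz"); ``concept_id`` is the first candidate in terminology
    order until object resolution picks the definitive sense."""

    concept_id: Optional[str]
    span: Span
    variant: str
    layer: str  # object | attribute | value
    targets: tuple[MatchTarget, ...]
    implied_object_id: Optional[str] = None
    implied_value_id: Optional[str] = None


@dataclass(frozen=True)
class AttributeValuePair:
    attribute_id: str
    value_id: str  # possibly composed "<attr>:<local>"
    object_id: Optional[str]
    attribute_span: Span
    value_span: Optional[Span]  # absent for implicit values
    implicit: bool
    segment_index: int
    subsection_index: int

    @property
    def begin(self) -> int:
        b = self.attribute_span.begin
        return min(b, self.value_span.begin) if self.value_span else b

    @property
    def end(self) -> int:
        e = self.attribute_span.end
        return max(e, self.value_span.end) if self.value_span else e

    def key(self) -> tuple[str, str, int, int]:
        """Exact-agreement key used for evaluation: type + offsets."""
        return (self.attribute_id, self.value_id, self.begin, self.end)


@dataclass
class ExtractionResult:
    document_id: str
    pairs: list[AttributeValuePair]
    diagnostics: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# concept matching
# ---------------------------------------------------------------------------


def _select_leftmost_longest(hits: list[RawHit]) -> list[RawHit]:
    chosen: list[RawHit] = []
    last_end = -1
    for h in sorted(hits, key=lambda h: (h.begin, -(h.end - h.begin), h.pattern)):
        if h.begin >= last_end:
            chosen.append(h)
            last_end = h.end
        elif chosen and h.begin == chosen[-1].begin and h.end == chosen[-1].end:
            # same span, different variant entry: merge candidate targets
            prev = chosen[-1]
            chosen[-1] = RawHit(
                prev.begin, prev.end, prev.layer,
                prev.targets + h.targets, prev.pattern, prev.vtype,
            )
    return chosen


def find_matches(matcher: CompiledMatcher, seg: Segment, doc: Document) -> list[ConceptMatch]:
    """Leftmost-longest non-overlapping matches per layer within a segment.

    Matches of different layers may overlap (e.g. an av-compound measurement
    covers the span of the bare attribute keyword it subsumes).
    """
    text = doc.text[seg.span.begin: seg.span.end]
    hits = matcher.find(text, base=seg.span.begin)
    out: list[ConceptMatch] = []
    for layer in ("object", "attribute", "value"):
        layer_hits = [h for h in hits if h.layer == layer]
        for h in _select_leftmost_longest(layer_hits):
            primary = h.targets[0]
            out.append(
                ConceptMatch(
                    concept_id=primary.concept_id,
                    span=Span(h.begin, h.end),
                    variant=h.pattern,
                    layer=layer,
                    targets=h.targets,
                    implied_object_id=next(
                        (t.implied_object_id for t in h.targets if t.implied_object_id), None
                    ),
                    implied_value_id=next(
                        (t.implied_value_id for t in h.targets if t.implied_value_id), None
                    ),
                )
            )
    out.sort(key=lambda m: (m.span.begin, ("object", "attribute", "value").index(m.layer)))
    return out


# ---------------------------------------------------------------------------
# object-context resolution
# ---------------------------------------------------------------------------


def _candidate_objects(t: Terminology, m: ConceptMatch) -> dict[str, str]:
    """object ancestor id -> candidate object_attribute concept id."""
    out: dict[str, str] = {}
    for target in m.targets:
        if target.concept_id is None:
            continue
        anc = t.object_ancestor(target.concept_id)
        if anc is not None:
            out.setdefault(anc, target.concept_id)
    return out


def resolve_object_context(
    m: ConceptMatch,
    seg: Segment,
    sub: Subsection,
    segment_matches: Sequence[ConceptMatch],
    t: Terminology,
) -> str:
    """Resolving object for an ambiguous attribute match, or ``UNRESOLVED``.

    Order: the compound's implied object; the nearest preceding, then nearest
    following, object match inside the same segment; the subsection's context
    object.  A candidate only resolves if it is the object ancestor of one of
    the match's concept senses.
    """
    valid = _candidate_objects(t, m)
    if m.implied_object_id is not None and m.implied_object_id in valid:
        return m.implied_object_id
    preceding = [
        om for om in segment_matches
        if om.layer == "object" and om.span.end <= m.span.begin
    ]
    following = [
        om for om in segment_matches
        if om.layer == "object" and om.span.begin >= m.span.end
    ]
    for om in sorted(preceding, key=lambda o: -o.span.end) + sorted(
        following, key=lambda o: o.span.begin
    ):
        for target in om.targets:
            if target.concept_id in valid:
                return target.concept_id
    if sub.context_object_id is not None and sub.context_object_id in valid:
        return sub.context_object_id
    return UNRESOLVED


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


@dataclass
class _ResolvedAttr:
    match: ConceptMatch
    concept_id: str
    object_id: Optional[str]


def _resolve_attributes(
    matches: Sequence[ConceptMatch],
    seg: Segment,
    sub: Subsection,
    t: Terminology,
    diagnostics: list[dict],
    doc: Document,
) -> list[_ResolvedAttr]:
    out: list[_ResolvedAttr] = []
    for m in matches:
        if m.layer != "attribute":
            continue
        plain = [
            tgt for tgt in m.targets
            if tgt.concept_id and t.get(tgt.concept_id).ctype == "attribute"
        ]
        if plain:
            cid = plain[0].concept_id
            out.append(_ResolvedAttr(m, cid, t.object_ancestor(cid)))
            continue
        obj = resolve_object_context(m, seg, sub, matches, t)
        if obj == UNRESOLVED:
            diagnostics.append(
                {
                    "kind": "unresolved_attribute",
                    "span": [m.span.begin, m.span.end],
                    "text": doc.text[m.span.begin: m.span.end],
                    "candidates": sorted(
                        tgt.concept_id for tgt in m.targets if tgt.concept_id
                    ),
                }
            )
            continue
        cid = _candidate_objects(t, m)[obj]
        out.append(_ResolvedAttr(m, cid, obj))
    return out


def _admissible_value_id(
    t: Terminology, attr_id: str, value_match: ConceptMatch
) -> Optional[tuple[str, bool]]:
    """(effective value id, suppress flag) if the value match fits *attr_id*."""
    attr = t.get(attr_id)
    for target in value_match.targets:
        if target.concept_id is not None:
            parent = t.get(target.concept_id).parent_id
            if parent == attr_id:
                return target.concept_id, t.get(target.concept_id).suppress
        elif target.template_id is not None and attr.template_ref == target.template_id:
            return f"{attr_id}{COMPOSED_SEP}{target.local_id}", target.suppress
    return None


def _token_distance(doc: Document, a: Span, b: Span) -> int:
    lo, hi = (a.end, b.begin) if a.end <= b.begin else (b.end, a.begin)
    if lo >= hi:
        return 0
    return len(tokenize(doc.text[lo:hi]))


def pair_values(
    seg: Segment,
    matches: Sequence[ConceptMatch],
    t: Terminology,
    sub: Subsection,
    doc: Document,
    diagnostics: Optional[list[dict]] = None,
    segment_index: int = 0,
    subsection_index: int = 0,
    resolved_attrs: Optional[list["_ResolvedAttr"]] = None,
) -> list[AttributeValuePair]:
    """Attribute-centric pairing within one segment.

    av-compound matches pair intrinsically.  Each explicit value match is
    consumed by at most one attribute: the nearest admissible one by token
    distance (ties to the preceding attribute), subject to the prepositional
    constraint — an attribute inside a prep phrase cannot take a value from
    outside that phrase.
    """
    diagnostics = diagnostics if diagnostics is not None else []
    attrs = (
        resolved_attrs
        if resolved_attrs is not None
        else _resolve_attributes(matches, seg, sub, t, diagnostics, doc)
    )
    pairs: list[AttributeValuePair] = []

    for ra in attrs:
        if ra.match.implied_value_id is not None:
            pairs.append(
                AttributeValuePair(
                    attribute_id=ra.concept_id,
                    value_id=ra.match.implied_value_id,
                    object_id=ra.object_id,
                    attribute_span=ra.match.span,
                    value_span=ra.match.span,
                    implicit=False,
                    segment_index=segment_index,
                    subsection_index=subsection_index,
                )
            )

    for vm in (m for m in matches if m.layer == "value"):
        candidates: list[tuple[int, int, _ResolvedAttr, str]] = []
        for idx, ra in enumerate(attrs):
            fit = _admissible_value_id(t, ra.concept_id, vm)
            if fit is None:
                continue
            phrase = next(
                (p for p in seg.prep_phrases if p.contains(ra.match.span)), None
            )
            if phrase is not None and not phrase.contains(vm.span):
                continue
            dist = _token_distance(doc, ra.match.span, vm.span)
            precedes = 0 if ra.match.span.begin <= vm.span.begin else 1
            candidates.append((dist, precedes, idx, fit[0]))
        if not candidates:
            continue
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        _, _, idx, value_id = candidates[0]
        ra = attrs[idx]
        pairs.append(
            AttributeValuePair(
                attribute_id=ra.concept_id,
                value_id=value_id,
                object_id=ra.object_id,
                attribute_span=ra.match.span,
                value_span=vm.span,
                implicit=False,
                segment_index=segment_index,
                subsection_index=subsection_index,
            )
        )

    pairs.sort(key=lambda p: (p.attribute_span.begin, p.value_span.begin if p.value_span else -1))
    return pairs


# ---------------------------------------------------------------------------
# postprocessing
# ---------------------------------------------------------------------------


def postprocess(
    pairs: Sequence[AttributeValuePair],
    matches: Sequence[ConceptMatch],
    t: Terminology,
    sub: Optional[Subsection] = None,
    seg: Optional[Segment] = None,
    diagnostics: Optional[list[dict]] = None,
    segment_index: int = 0,
    subsection_index: int = 0,
    resolved_attrs: Optional[Sequence[_ResolvedAttr]] = None,
) -> list[AttributeValuePair]:
    """Semantic postprocessing of one segment's pairs.

    1. implicit presence: every matched boolean-nature attribute instance
       gains one implicit pair carrying its declared presence value;
    2. suppression: if an attribute instance has an activator value
       (``suppress=False``), all its passive values are removed;
    3. redundancy: duplicate (attribute, value) pairs collapse to the first.
    """
    diagnostics = diagnostics if diagnostics is not None else []
    out = list(pairs)

    if resolved_attrs is None and sub is not None and seg is not None:
        resolved_attrs = _resolve_attributes(matches, seg, sub, t, [], _DUMMY_DOC)
    for ra in resolved_attrs or ():
        concept = t.get(ra.concept_id)
        if concept.boolean_nature and concept.implicit_value is not None:
            out.append(
                AttributeValuePair(
                    attribute_id=ra.concept_id,
                    value_id=concept.implicit_value,
                    object_id=ra.object_id,
                    attribute_span=ra.match.span,
                    value_span=None,
                    implicit=True,
                    segment_index=segment_index,
                    subsection_index=subsection_index,
                )
            )

    # suppression per attribute instance (identified by attribute span)
    by_instance: dict[tuple[str, int, int], list[AttributeValuePair]] = {}
    for p in out:
        by_instance.setdefault(
            (p.attribute_id, p.attribute_span.begin, p.attribute_span.end), []
        ).append(p)
    kept: list[AttributeValuePair] = []
    for instance_pairs in by_instance.values():
        flags = {
            id(p): t.value_suppress(p.attribute_id, p.value_id) for p in instance_pairs
        }
        has_activator = any(not f for f in flags.values())
        for p in instance_pairs:
            if has_activator and flags[id(p)]:
                diagnostics.append(
                    {
                        "kind": "suppressed_value",
                        "attribute_id": p.attribute_id,
                        "value_id": p.value_id,
                        "span": [p.begin, p.end],
                    }
                )
            else:
                kept.append(p)

    kept.sort(
        key=lambda p: (p.attribute_span.begin, p.implicit, p.value_span.begin if p.value_span else -1)
    )
    seen: set[tuple[str, str]] = set()
    final: list[AttributeValuePair] = []
    for p in kept:
        k = (p.attribute_id, p.value_id)
        if k in seen:
            diagnostics.append(
                {"kind": "redundant_pair", "attribute_id": p.attribute_id, "value_id": p.value_id}
            )
            continue
        seen.add(k)
        final.append(p)
    return final


_DUMMY_DOC = Document(id="_", text="")


# ---------------------------------------------------------------------------
# whole-document extraction
# ---------------------------------------------------------------------------


def extract_document(
    doc: Document,
    t: Terminology,
    config: Optional[SegmentationConfig] = None,
    matcher: Optional[CompiledMatcher] = None,
) -> ExtractionResult:
    """Run the full pipeline on one document."""
    config = config or SegmentationConfig(
        ignore_section_patterns=t.ignore_section_patterns
    )
    matcher = matcher or compile_matcher(t)
    diagnostics: list[dict] = []
    patterns = config.ignore_section_patterns or t.ignore_section_patterns
    masked = mask_ignored_sections(doc, patterns, matcher)
    for s in masked:
        diagnostics.append({"kind": "masked_section", "span": [s.begin, s.end]})
    subsections = detect_subsections(doc, matcher, masked)
    all_pairs: list[AttributeValuePair] = []
    seg_counter = 0
    for si, sub in enumerate(subsections):
        for seg in split_segments(sub, doc, config):
            seg.subsection_index = si
            seg.prep_phrases = detect_prep_phrases(
                seg, doc, config.prepositions, config.verb_stopwords
            )
            matches = find_matches(matcher, seg, doc)
            resolved = _resolve_attributes(matches, seg, sub, t, diagnostics, doc)
            pairs = pair_values(
                seg, matches, t, sub, doc, diagnostics, seg_counter, si,
                resolved_attrs=resolved,
            )
            pairs = postprocess(
                pairs, matches, t, sub, seg, diagnostics, seg_counter, si,
                resolved_attrs=resolved,
            )
            all_pairs.extend(pairs)
            seg_counter += 1
    all_pairs.sort(key=lambda p: (p.begin, p.end, p.attribute_id, p.value_id))
    return ExtractionResult(document_id=doc.id, pairs=all_pairs, diagnostics=diagnostics)


def map_to_aspects(
    res: ExtractionResult, aspect_map: dict[str, set[str]], t: Optional[Terminology] = None
) -> dict[str, list[AttributeValuePair]]:
    """Group pairs by aspect label; unmapped attributes go under "UNMAPPED"."""
    if t is not None:
        known = set(t.concepts)
        for aspect, attr_ids in aspect_map.items():
            unknown = set(attr_ids) - known
            if unknown:
                raise KeyError(f"aspect {aspect!r} references unknown attributes {sorted(unknown)}")
    attr_to_aspect: dict[str, str] = {}
    for aspect, attr_ids in aspect_map.items():
        for aid in attr_ids:
            attr_to_aspect[aid] = aspect
    out: dict[str, list[AttributeValuePair]] = {aspect: [] for aspect in aspect_map}
    out["UNMAPPED"] = []
    for p in res.pairs:
        out[attr_to_aspect.get(p.attribute_id, "UNMAPPED")].append(p)
    return out


# ---------------------------------------------------------------------------
# prediction I/O (JSON lines, one pair per line)
# ---------------------------------------------------------------------------


def write_predictions(results: Sequence[ExtractionResult], path) -> None:
    """One JSON record per pair: ids, spans and provenance indices."""
    import json

    with open(path, "w", encoding="utf-8") as fh:
        for res in results:
            for p in res.pairs:
                fh.write(json.dumps({
                    "doc_id": res.document_id,
                    "attribute_id": p.attribute_id,
                    "value_id": p.value_id,
                    "object_id": p.object_id,
                    "attribute_span": [p.attribute_span.begin, p.attribute_span.end],
                    "value_span": (
                        [p.value_span.begin, p.value_span.end] if p.value_span else None
                    ),
                    "implicit": p.implicit,
                    "segment_index": p.segment_index,
                    "subsection_index": p.subsection_index,
                }, ensure_ascii=False) + "\n")


def read_predictions(path) -> dict[str, list[AttributeValuePair]]:
    """Inverse of :func:`write_predictions`, grouped by document id."""
    import json

    out: dict[str, list[AttributeValuePair]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            vs = rec.get("value_span")
            pair = AttributeValuePair(
                attribute_id=rec["attribute_id"],
                value_id=rec["value_id"],
                object_id=rec.get("object_id"),
                attribute_span=Span(*rec["attribute_span"]),
                value_span=Span(*vs) if vs else None,
                implicit=bool(rec.get("implicit", False)),
                segment_index=rec.get("segment_index", 0),
                subsection_index=rec.get("subsection_index", 0),
            )
            out.setdefault(rec["doc_id"], []).append(pair)
    return out
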