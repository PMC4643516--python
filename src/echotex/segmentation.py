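"""Report structure: ignored sections, subsections, segments, prep phrases.

A semi-structured echocardiography report decomposes into

* *ignored spans* — out-of-domain blocks (e.g. a transesophageal-echo section)
  that are masked before any further processing;
* *subsections* — regions opened by header lines like ``"Mitralklappe:"`` or
  ``"- AK:"``; when the header names a terminology object, the subsection
  provides the object context for ambiguous attributes inside it;
* *segments* — minimal statement units within a subsection, split at sentence
  punctuation, line breaks and (most) commas;
* *prepositional phrases* — shallow spans like ``"bei Tachykardie"`` that
  restrict value assignment.

All offsets are 0-based, half-open, counted in code points of the raw text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .terminology import CompiledMatcher, tokenize

HEADERLESS = "HEADERLESS"

# header-shaped line: optional list marker, short label, colon
_HEADER_RE = re.compile(r"^[ \t]*(-[ \t]*)?([^:\n]{1,60}?)[ \t]*:")

_DEFAULT_PREPOSITIONS = ("bei", "nach", "vor", "unter", "mit", "trotz")
_ARTICLES = {
    "der", "die", "das", "dem", "den", "des", "ein", "eine", "einer",
    "eines", "einem", "einen",
}
_VERBLIKE_SUFFIXES = ("bar", "iert", "elt")


@dataclass(frozen=True)
class Span:
    begin: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.begin <= self.end):
            raise ValueError(f"invalid span ({self.begin}, {self.end})")

    def contains(self, other: "Span") -> bool:
        return self.begin <= other.begin and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.begin < other.end and other.begin < self.end


@dataclass
class Document:
    id: str
    text: str
    site: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("document id must be non-empty")


@dataclass
class Subsection:
    span: Span
    header_span: Optional[Span]
    context_object_id: Optional[str]
    label: str


@dataclass
class Segment:
    span: Span
    subsection_index: int
    prep_phrases: list[Span] = field(default_factory=list)


@dataclass
class SegmentationConfig:
    prepositions: tuple[str, ...] = _DEFAULT_PREPOSITIONS
    ignore_section_patterns: tuple[str, ...] = ()
    verb_stopwords: tuple[str, ...] = ("nicht", "gut", "sicher", "ist", "sind", "war", "waren")


# ---------------------------------------------------------------------------
# ignored sections
# ---------------------------------------------------------------------------


def _lines(text: str) -> list[tuple[int, int]]:
    """(begin, end) of every line, end excluding the newline."""
    out = []
    start = 0
    for m in re.finditer(r"\n", text):
        out.append((start, m.start()))
        start = m.end()
    out.append((start, len(text)))
    return out


def _header_label(text: str, line: tuple[int, int]) -> Optional[tuple[Span, str]]:
    """If the line is header-shaped, the span+text of its pre-colon label."""
    m = _HEADER_RE.match(text[line[0]: line[1]])
    if m is None:
        return None
    begin = line[0] + m.start(2)
    end = line[0] + m.end(2)
    return Span(begin, end), text[begin:end]


def _is_header_line(
    text: str, line: tuple[int, int], matcher: Optional[CompiledMatcher]
) -> Optional[tuple[Span, str, Optional[str]]]:
    """Header decision for one line.

    Returns (label span, label text, context object id or None), or None when
    the line is not a header.  A header-shaped line whose label matches an
    attribute or value (e.g. ``"LVEF: 60%"``) is a content line, not a header.
    """
    got = _header_label(text, line)
    if got is None:
        return None
    lspan, label = got
    if matcher is None:
        return lspan, label, None
    hits = matcher.find(label)
    full = [h for h in hits if h.begin == 0 and h.end == len(label)]
    for h in full:
        if h.layer == "object":
            return lspan, label, h.targets[0].concept_id
    if any(h.layer in ("attribute", "value") for h in hits):
        return None
    return lspan, label, None


def mask_ignored_sections(
    doc: Document,
    patterns: Sequence[str],
    matcher: Optional[CompiledMatcher] = None,
) -> list[Span]:
    """Maximal spans of out-of-domain sections, excluded from all processing.

    A span runs from a line matching one of *patterns* to the next header
    line (see :func:`detect_subsections`) or the end of the text.
    """
    compiled = [re.compile(p) for p in patterns]
    lines = _lines(doc.text)
    masked: list[Span] = []
    i = 0
    while i < len(lines):
        b, e = lines[i]
        line_text = doc.text[b:e]
        if any(rx.search(line_text) for rx in compiled):
            j = i + 1
            while j < len(lines):
                nb, ne = lines[j]
                if any(rx.search(doc.text[nb:ne]) for rx in compiled):
                    j += 1
                    continue
                if _is_header_line(doc.text, lines[j], matcher) is not None:
                    break
                j += 1
            end = lines[j][0] if j < len(lines) else len(doc.text)
            masked.append(Span(b, end))
            i = j
        else:
            i += 1
    return masked


# ---------------------------------------------------------------------------
# subsections
# ---------------------------------------------------------------------------


def detect_subsections(
    doc: Document, matcher: CompiledMatcher, masked: Sequence[Span]
) -> list[Subsection]:
    """Partition the non-masked text into subsections.

    Headers are line-initial labels followed by ``":"`` (optionally behind a
    ``"- "`` list marker).  A header naming a terminology object sets the
    subsection's context object; any text before the first header forms a
    HEADERLESS subsection without context.
    """
    text = doc.text
    if not text:
        return []
    masked = sorted(masked, key=lambda s: s.begin)

    def is_masked(pos: int) -> bool:
        return any(s.begin <= pos < s.end for s in masked)

    headers: list[tuple[tuple[int, int], Span, str, Optional[str]]] = []
    for line in _lines(text):
        if is_masked(line[0]):
            continue
        got = _is_header_line(text, line, matcher)
        if got is not None:
            headers.append((line, *got))

    # region boundaries: header line starts, mask edges, text edges
    cuts = {0, len(text)}
    for line, _, _, _ in headers:
        cuts.add(line[0])
    for s in masked:
        cuts.add(s.begin)
        cuts.add(s.end)
    ordered = sorted(cuts)

    header_at = {line[0]: (lspan, label, ctx) for line, lspan, label, ctx in headers}
    subs: list[Subsection] = []
    current: Optional[Subsection] = None
    for a, b in zip(ordered, ordered[1:]):
        if a == b or any(s.begin <= a and b <= s.end for s in masked):
            current = None
            continue
        if a in header_at:
            lspan, label, ctx = header_at[a]
            current = Subsection(Span(a, b), lspan, ctx, label)
            subs.append(current)
        elif current is not None:
            # continuation of the running subsection across a mask-free cut
            current.span = Span(current.span.begin, b)
        else:
            subs.append(Subsection(Span(a, b), None, None, HEADERLESS))
            current = subs[-1]
    return subs


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

_SENT_BOUND_RE = re.compile(r"[.!?]+(?=\s|$)")
_UND_RE = re.compile(r"\bund\b|\boder\b")


def _enumeration_comma(text: str, comma_pos: int, piece: tuple[int, int]) -> bool:
    """True when the comma at *comma_pos* joins a shared-head enumeration.

    Pattern: ``<head> <prep>? A, B und C`` — a later "und"/"oder" with only
    simple (short, digit-free) items between the comma and it.
    """
    tail = text[comma_pos + 1: piece[1]]
    m = _UND_RE.search(tail)
    if m is None:
        return False
    between = tail[: m.start()]
    for item in between.split(","):
        toks = item.split()
        if len(toks) == 0 or len(toks) > 4 or any(any(ch.isdigit() for ch in t) for t in toks):
            return False
    after = tail[m.end():].strip().rstrip(".!?")
    toks = after.split()
    if len(toks) == 0 or len(toks) > 4 or any(any(ch.isdigit() for ch in t) for t in toks):
        return False
    return True


def _paren_measurement_positions(text: str, a: int, b: int) -> list[int]:
    """Start offsets of parenthesized groups containing a digit inside [a, b)."""
    return [
        a + m.start()
        for m in re.finditer(r"\([^()]*\d[^()]*\)", text[a:b])
    ]


def _split_at_und(text: str, a: int, b: int) -> list[tuple[int, int]]:
    """Split a piece at "und" joining two findings that each carry a
    parenthesized measurement; otherwise return the piece unchanged."""
    for m in re.finditer(r"\bund\b", text[a:b]):
        u0, u1 = a + m.start(), a + m.end()
        before = _paren_measurement_positions(text, a, u0)
        after = _paren_measurement_positions(text, u1, b)
        if before and after:
            return [(a, u0), *_split_at_und(text, u1, b)]
    return [(a, b)]


def _trim(text: str, a: int, b: int) -> Optional[tuple[int, int]]:
    while a < b and text[a].isspace():
        a += 1
    while b > a and text[b - 1].isspace():
        b -= 1
    # strip a leading list marker
    while a < b and text[a] in "-•":
        a += 1
        while a < b and text[a].isspace():
            a += 1
    return (a, b) if a < b else None


def split_segments(
    sub: Subsection, doc: Document, rules: Optional[SegmentationConfig] = None
) -> list[Segment]:
    """Segments of one subsection.

    Boundaries: line breaks, sentence-final punctuation, and commas — except
    commas inside a shared-head enumeration (``"... an A, B und C"``), which
    stay merged.  Coordinations of two findings that each carry their own
    parenthesized measurement are additionally split at ``"und"``.
    The header label and its colon are not part of any segment.
    """
    del rules  # segment boundary rules are currently not configurable
    text = doc.text
    start = sub.span.begin
    if sub.header_span is not None:
        colon = text.find(":", sub.header_span.end, sub.span.end)
        start = colon + 1 if colon != -1 else sub.header_span.end
    pieces: list[tuple[int, int]] = []
    # line-level split first
    a = start
    for m in re.finditer(r"\n", text[start: sub.span.end]):
        pieces.append((a, start + m.start()))
        a = start + m.end()
    pieces.append((a, sub.span.end))

    # sentence-level split
    sent_pieces: list[tuple[int, int]] = []
    for a, b in pieces:
        last = a
        for m in _SENT_BOUND_RE.finditer(text[a:b]):
            sent_pieces.append((last, a + m.end()))
            last = a + m.end()
        if last < b:
            sent_pieces.append((last, b))

    # comma-level split with enumeration exception
    comma_pieces: list[tuple[int, int]] = []
    for a, b in sent_pieces:
        last = a
        for m in re.finditer(",", text[a:b]):
            pos = a + m.start()
            if 0 < pos < len(text) - 1 and text[pos - 1].isdigit() and text[pos + 1].isdigit():
                continue  # decimal comma, e.g. "1,1 m/s"
            if _enumeration_comma(text, pos, (a, b)):
                continue
            comma_pieces.append((last, pos))
            last = pos + 1
        comma_pieces.append((last, b))

    # und-split for coordinated measured findings
    final: list[tuple[int, int]] = []
    for a, b in comma_pieces:
        final.extend(_split_at_und(text, a, b))

    segs: list[Segment] = []
    for a, b in final:
        trimmed = _trim(text, a, b)
        if trimmed is not None:
            segs.append(Segment(Span(*trimmed), subsection_index=-1))
    return segs


# ---------------------------------------------------------------------------
# prepositional phrases
# ---------------------------------------------------------------------------


def detect_prep_phrases(
    seg: Segment,
    doc: Document,
    prepositions: Sequence[str] = _DEFAULT_PREPOSITIONS,
    stopwords: Sequence[str] = SegmentationConfig().verb_stopwords,
) -> list[Span]:
    """Shallow prepositional phrases within one segment.

    A phrase starts at a configured preposition and covers the following noun
    group: articles and capitalized/numeric tokens, up to the next verb-like
    token (closed suffix list), stopword, comma, or segment end.
    """
    text = doc.text[seg.span.begin: seg.span.end]
    toks = tokenize(text)
    preps = {p.casefold() for p in prepositions}
    stops = {s.casefold() for s in stopwords}
    spans: list[Span] = []
    i = 0
    while i < len(toks):
        tok, tb, te = toks[i]
        if tok.casefold() in preps:
            j = i + 1
            end = None
            while j < len(toks):
                w = toks[j][0]
                wl = w.casefold()
                if w == "," or wl in stops or any(wl.endswith(s) for s in _VERBLIKE_SUFFIXES):
                    break
                if wl in _ARTICLES or w[0].isupper() or any(ch.isdigit() for ch in w):
                    end = toks[j][2]
                    j += 1
                    continue
                break
            if end is not None:
                spans.append(Span(seg.span.begin + tb, seg.span.begin + end))
                i = j
                continue
        i += 1
    return spans


# ---------------------------------------------------------------------------
# layout statistics
# ---------------------------------------------------------------------------


def layout_stats(doc: Document) -> tuple[int, int]:
    """(non-whitespace code points, lines whose first non-blank char is '-')."""
    nonspace = sum(1 for ch in doc.text if not ch.isspace())
    list_elements = 0
    for b, e in _lines(doc.text):
        stripped = doc.text[b:e].lstrip()
        if stripped.startswith("-"):
            list_elements += 1
    return nonspace, list_elements
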