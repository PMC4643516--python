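"""Terminology bootstrapping: aggregated context files and term candidates.

Clinical reports of one hospital repeat a small inventory of phrases.
Aggregating a corpus into per-context frequency tables of normalized distinct
phrases ("aggregated documents") lets a domain expert inspect a few hundred
lines instead of thousands of reports, ranked by how often each phrase
occurs.  Attribute-term candidates are then proposed from those phrases.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .segmentation import (
    Document,
    SegmentationConfig,
    detect_subsections,
    mask_ignored_sections,
    split_segments,
)
from .terminology import CompiledMatcher, Terminology, compile_matcher, fold, tokenize

_NUMBER_RE = re.compile(r"\d+(?:[.,]\d+)*")


def normalize_phrase(text: str) -> str:
    """Normalize a segment phrase for aggregation.

    Every maximal digit run (with optional decimal comma/point) becomes the
    single character "9"; whitespace is collapsed; case is preserved.
    """
    out = _NUMBER_RE.sub("9", text)
    return " ".join(out.split())


@dataclass
class AggregatedContext:
    """Frequency table of normalized phrases observed in one context
    (subsection label, or HEADERLESS)."""

    label: str
    counts: dict[str, int] = field(default_factory=dict)

    def add(self, phrase: str) -> None:
        self.counts[phrase] = self.counts.get(phrase, 0) + 1

    @property
    def entries(self) -> list[tuple[str, int]]:
        """(phrase, frequency) sorted by descending frequency, then phrase."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def render(self) -> str:
        """Export format: one ``<phrase> ((<count>))`` line per entry."""
        return "\n".join(f"{p} (({n}))" for p, n in self.entries)


@dataclass
class CandidateTerm:
    term: str
    frequency: int
    contexts: tuple[str, ...]
    status: str = "proposed"  # proposed | accepted | rejected


def build_aggregates(
    corpus: Iterable[Document],
    config: Optional[SegmentationConfig] = None,
    t: Optional[Terminology] = None,
    matcher: Optional[CompiledMatcher] = None,
) -> dict[str, AggregatedContext]:
    """Per-context frequency tables over all segments of a corpus."""
    if matcher is None and t is not None:
        matcher = compile_matcher(t)
    if config is None:
        config = SegmentationConfig(
            ignore_section_patterns=t.ignore_section_patterns if t else ()
        )
    out: dict[str, AggregatedContext] = {}
    for doc in corpus:
        masked = mask_ignored_sections(doc, config.ignore_section_patterns, matcher)
        if matcher is None:
            raise ValueError("build_aggregates needs a terminology or matcher")
        for sub in detect_subsections(doc, matcher, masked):
            for seg in split_segments(sub, doc, config):
                phrase = normalize_phrase(doc.text[seg.span.begin: seg.span.end])
                if not phrase:
                    continue
                ctx = out.setdefault(sub.label, AggregatedContext(sub.label))
                ctx.add(phrase)
    return out


def write_aggregates(aggregates: dict[str, AggregatedContext], outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, ctx in sorted(aggregates.items()):
        safe = re.sub(r"[^\w-]+", "_", label) or "_"
        (outdir / f"{safe}.txt").write_text(ctx.render() + "\n", encoding="utf-8")


def _known_terms(t: Optional[Terminology]) -> set[str]:
    if t is None:
        return set()
    known: set[str] = set()
    for c in t:
        for v in t.concept_variants(c.id):
            if v.vtype == "std":
                known.add(fold(v.pattern))
    for tmpl in t.templates.values():
        for tv in tmpl.values:
            for v in tv.variants:
                if v.vtype == "std":
                    known.add(fold(v.pattern))
    return known


def propose_candidates(
    aggregates: dict[str, AggregatedContext],
    accept_list: Sequence[str] = (),
    reject_list: Sequence[str] = (),
    min_freq: int = 1,
    terminology: Optional[Terminology] = None,
) -> list[CandidateTerm]:
    """Attribute-term candidates from aggregated phrases.

    Candidates are n-grams (n <= 3) of consecutive capitalized tokens — the
    German-noun heuristic — excluding reject-list members and terms whose
    surface form already appears as a terminology variant, keeping those with
    total frequency >= *min_freq*.  Accept-list members are marked accepted.
    """
    rejects = {fold(r) for r in reject_list}
    accepts = {fold(a) for a in accept_list}
    known = _known_terms(terminology)
    freq: dict[str, int] = {}
    contexts: dict[str, set[str]] = {}
    display: dict[str, str] = {}
    for label, ctx in aggregates.items():
        for phrase, n in ctx.counts.items():
            toks = [tok for tok, _, _ in tokenize(phrase)]
            eligible = [
                tok if (tok[0].isupper() and tok[0].isalpha() and fold(tok) not in rejects) else None
                for tok in toks
            ]
            # maximal runs of eligible tokens, clipped to trigrams
            run: list[str] = []
            runs: list[list[str]] = []
            for e in eligible:
                if e is None:
                    if run:
                        runs.append(run)
                    run = []
                else:
                    run.append(e)
            if run:
                runs.append(run)
            for r in runs:
                term = " ".join(r[:3])
                k = fold(term)
                if k in known:
                    continue
                freq[k] = freq.get(k, 0) + n
                contexts.setdefault(k, set()).add(label)
                display.setdefault(k, term)
    out = [
        CandidateTerm(
            term=display[k],
            frequency=n,
            contexts=tuple(sorted(contexts[k])),
            status="accepted" if k in accepts else "proposed",
        )
        for k, n in freq.items()
        if n >= min_freq
    ]
    out.sort(key=lambda c: (-c.frequency, fold(c.term)))
    return out


def write_candidates(candidates: Sequence[CandidateTerm], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "frequency", "contexts", "status"])
        for c in candidates:
            w.writerow([c.term, c.frequency, ";".join(c.contexts), c.status])


#: qualifiers that look like capitalized nouns at phrase starts but are
#: degree/negation adjectives, not attribute terms
DEFAULT_REJECT_LIST = (
    "Hochgradige", "Hochgradig", "Mittelgradige", "Mittelgradig",
    "Geringgradige", "Geringgradig", "Geringe", "Gering", "Leichtgradige",
    "Leichtgradig", "Kein", "Keine", "Normale", "Normal", "Unauffällige",
    "Unauffälliger", "Unauffällig", "Diskrete", "Deutliche", "Grad",
)
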