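"""Terminology knowledge representation.

The extraction engine is driven entirely by a terminology: a tree of typed
concepts (structure / object / object_attribute / attribute / value) with
surface *variants* (plain strings or regular expressions), shared value
*templates*, and shared variant *dictionaries*.  This module loads, validates,
saves and compiles that terminology.

Concept roles
-------------
* ``object`` — an anatomical anchor (e.g. the mitral valve) that disambiguates
  ambiguous attributes.
* ``object_attribute`` — a finding type that only makes sense relative to an
  object (e.g. regurgitation); it must sit below an object in the tree or be
  reachable through an object-attribute compound variant.
* ``attribute`` — an unambiguous finding type (e.g. LVEF).
* ``value`` — a possible state of an attribute (e.g. absent, moderate).
* ``structure`` — purely organisational; carries no extraction semantics.

Values carry a ``suppress`` flag: passive values (``suppress=True``) are
removed whenever a suppression *activator* (``suppress=False``, typically a
negation like "keine") is found for the same attribute instance.

Templates hold reusable value sets (e.g. severity grades).  A value imported
from a template into attribute ``a`` gets the composed id ``"a:<local id>"``.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import yaml

CTYPES = ("structure", "object", "object_attribute", "attribute", "value")
ATTRIBUTE_CTYPES = ("attribute", "object_attribute")

COMPOSED_SEP = ":"


def fold(s: str) -> str:
    """Locale-independent case folding used for std-variant matching."""
    return unicodedata.normalize("NFC", s).casefold()


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A surface form referring to a concept.

    ``vtype`` is ``"std"`` (plain string, matched case-insensitively at token
    boundaries) or ``"regexp"`` (matched as written).  ``compound`` marks
    lexically fused forms: ``"oa"`` (object+attribute, e.g.
    "Mitralklappeninsuffizienz") or ``"av"`` (attribute+value, e.g. a numeric
    measurement pattern).
    """

    pattern: str
    vtype: str = "std"
    compound: str = "none"  # none | oa | av
    implied_object_id: Optional[str] = None
    implied_value_id: Optional[str] = None


@dataclass
class Concept:
    id: str
    label: str
    ctype: str
    parent_id: Optional[str] = None
    boolean_nature: bool = False
    suppress: bool = True  # meaningful on values: True = passive
    template_ref: Optional[str] = None
    dictionary_refs: tuple[str, ...] = ()
    aspect: Optional[str] = None
    implicit_value: Optional[str] = None  # effective value id used for implicit presence
    variants: tuple[Variant, ...] = ()


@dataclass(frozen=True)
class TemplateValue:
    local_id: str
    label: str
    suppress: bool = True
    variants: tuple[Variant, ...] = ()


@dataclass
class Template:
    id: str
    label: str
    values: tuple[TemplateValue, ...] = ()


@dataclass
class Dictionary:
    name: str
    variants: tuple[Variant, ...] = ()


@dataclass(frozen=True)
class Violation:
    code: str
    concept_id: str
    message: str


@dataclass(frozen=True)
class EffectiveValue:
    """One admissible value of an attribute, local or template-imported."""

    value_id: str  # composed "<attr>:<local>" for template imports
    label: str
    suppress: bool
    variants: tuple[Variant, ...]
    source: str  # "local" | "template"


class Terminology:
    """Concept tree plus templates, dictionaries and ignore-section patterns."""

    def __init__(
        self,
        concepts: Iterable[Concept],
        templates: Iterable[Template] = (),
        dictionaries: Iterable[Dictionary] = (),
        ignore_section_patterns: Iterable[str] = (),
    ) -> None:
        self.concepts: dict[str, Concept] = {}
        self._order: list[str] = []
        for c in concepts:
            if c.id in self.concepts:
                raise ValidationError(
                    [Violation("duplicate-id", c.id, f"concept id {c.id!r} defined twice")]
                )
            self.concepts[c.id] = c
            self._order.append(c.id)
        self.templates: dict[str, Template] = {t.id: t for t in templates}
        self.dictionaries: dict[str, Dictionary] = {d.name: d for d in dictionaries}
        self.ignore_section_patterns: tuple[str, ...] = tuple(ignore_section_patterns)

    # -- traversal ----------------------------------------------------------

    def __iter__(self) -> Iterator[Concept]:
        return (self.concepts[cid] for cid in self._order)

    def get(self, cid: str) -> Concept:
        return self.concepts[cid]

    def children(self, cid: Optional[str]) -> list[Concept]:
        return [c for c in self if c.parent_id == cid]

    def object_ancestor(self, cid: str) -> Optional[str]:
        """Nearest ancestor (or self) of ctype object, else None."""
        cur: Optional[str] = cid
        seen = set()
        while cur is not None and cur not in seen:
            seen.add(cur)
            c = self.concepts.get(cur)
            if c is None:
                return None
            if c.ctype == "object":
                return c.id
            cur = c.parent_id
        return None

    def concept_variants(self, cid: str) -> tuple[Variant, ...]:
        """Own variants plus dictionary-referenced variants."""
        c = self.concepts[cid]
        out = list(c.variants)
        for dname in c.dictionary_refs:
            d = self.dictionaries.get(dname)
            if d is not None:
                out.extend(d.variants)
        return tuple(out)

    def aspect_map(self) -> dict[str, set[str]]:
        """Aspect label -> attribute ids, from per-concept aspect fields."""
        out: dict[str, set[str]] = {}
        for c in self:
            if c.aspect and c.ctype in ATTRIBUTE_CTYPES:
                out.setdefault(c.aspect, set()).add(c.id)
        return out

    # -- semantics ----------------------------------------------------------

    def effective_values(self, attribute_id: str) -> list[EffectiveValue]:
        """Admissible values of an attribute: local children first, then
        template-imported values with composed ids ``"<attr>:<local>"``."""
        if attribute_id not in self.concepts:
            raise KeyError(f"unknown attribute id {attribute_id!r}")
        attr = self.concepts[attribute_id]
        if attr.ctype not in ATTRIBUTE_CTYPES:
            raise KeyError(f"concept {attribute_id!r} is not an attribute")
        out: list[EffectiveValue] = []
        seen: set[str] = set()
        for child in self.children(attribute_id):
            if child.ctype == "value" and child.id not in seen:
                seen.add(child.id)
                out.append(
                    EffectiveValue(
                        child.id, child.label, child.suppress,
                        self.concept_variants(child.id), "local",
                    )
                )
        if attr.template_ref is not None:
            tmpl = self.templates[attr.template_ref]
            for tv in tmpl.values:
                vid = f"{attribute_id}{COMPOSED_SEP}{tv.local_id}"
                if vid not in seen:
                    seen.add(vid)
                    out.append(
                        EffectiveValue(vid, tv.label, tv.suppress, tv.variants, "template")
                    )
        return out

    def value_suppress(self, attribute_id: str, value_id: str) -> bool:
        """Suppress flag of an effective value of *attribute_id*."""
        for ev in self.effective_values(attribute_id):
            if ev.value_id == value_id:
                return ev.suppress
        if value_id in self.concepts:
            return self.concepts[value_id].suppress
        return True


class ValidationError(Exception):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        msg = "; ".join(f"[{v.code}] {v.concept_id}: {v.message}" for v in violations)
        super().__init__(msg or "invalid terminology")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_variant(v: Variant, owner: str, owner_ctype: Optional[str], out: list[Violation]) -> None:
    if v.vtype not in ("std", "regexp"):
        out.append(Violation("bad-vtype", owner, f"unknown variant type {v.vtype!r}"))
        return
    if v.vtype == "std":
        if not v.pattern.strip():
            out.append(Violation("empty-pattern", owner, "std variant pattern is empty"))
    else:
        try:
            re.compile(v.pattern)
        except re.error as exc:
            out.append(
                Violation("bad-regexp", owner, f"pattern {v.pattern!r} does not compile: {exc}")
            )
    if v.compound not in ("none", "oa", "av"):
        out.append(Violation("bad-compound", owner, f"unknown compound kind {v.compound!r}"))
        return
    if v.compound == "oa":
        if owner_ctype is not None and owner_ctype != "object_attribute":
            out.append(
                Violation("oa-on-non-oa", owner, "oa compound on a non-object_attribute concept")
            )
        if v.implied_object_id is None:
            out.append(Violation("oa-no-object", owner, "oa compound without implied_object"))
    elif v.implied_object_id is not None:
        out.append(Violation("stray-implied-object", owner, "implied_object without compound=oa"))
    if v.compound == "av":
        if owner_ctype is not None and owner_ctype not in ATTRIBUTE_CTYPES:
            out.append(
                Violation("av-on-non-attribute", owner, "av compound on a non-attribute concept")
            )
        if v.implied_value_id is None:
            out.append(Violation("av-no-value", owner, "av compound without implied_value"))
    elif v.implied_value_id is not None:
        out.append(Violation("stray-implied-value", owner, "implied_value without compound=av"))


def validate_terminology(t: Terminology) -> list[Violation]:
    """All invariant violations, ordered by concept id then code.

    An empty list means the terminology is valid.  Violations are data, not
    exceptions; :func:`load_terminology` raises when this list is non-empty.
    """
    out: list[Violation] = []

    for c in t:
        if c.ctype not in CTYPES:
            out.append(Violation("bad-ctype", c.id, f"unknown concept type {c.ctype!r}"))
            continue
        if COMPOSED_SEP in c.id:
            out.append(
                Violation("id-has-separator", c.id, f"concept id must not contain {COMPOSED_SEP!r}")
            )
        if c.parent_id is not None and c.parent_id not in t.concepts:
            out.append(Violation("dangling-parent", c.id, f"unknown parent {c.parent_id!r}"))
        if c.ctype == "structure" and c.variants:
            out.append(Violation("structure-variants", c.id, "structure concepts carry no variants"))
        if c.ctype == "value":
            parent = t.concepts.get(c.parent_id) if c.parent_id else None
            if parent is None or parent.ctype not in ATTRIBUTE_CTYPES:
                out.append(
                    Violation("value-orphan", c.id, "value concept without attribute parent")
                )
        if c.ctype == "object_attribute":
            has_oa = any(v.compound == "oa" for v in t.concept_variants(c.id))
            if t.object_ancestor(c.id) is None and not has_oa:
                out.append(
                    Violation(
                        "unreachable-object-attribute", c.id,
                        "object_attribute has no object ancestor and no oa-compound variant",
                    )
                )
        if c.template_ref is not None:
            if c.ctype not in ATTRIBUTE_CTYPES:
                out.append(Violation("template-on-non-attribute", c.id, "template on non-attribute"))
            elif c.template_ref not in t.templates:
                out.append(Violation("dangling-template", c.id, f"unknown template {c.template_ref!r}"))
        for dname in c.dictionary_refs:
            if dname not in t.dictionaries:
                out.append(Violation("dangling-dictionary", c.id, f"unknown dictionary {dname!r}"))
        for v in c.variants:
            _check_variant(v, c.id, c.ctype, out)
        for v in c.variants:
            if v.compound == "oa" and v.implied_object_id is not None:
                if v.implied_object_id not in t.concepts:
                    out.append(
                        Violation("dangling-implied-object", c.id,
                                  f"unknown implied object {v.implied_object_id!r}")
                    )
                elif t.concepts[v.implied_object_id].ctype != "object":
                    out.append(
                        Violation("implied-object-not-object", c.id,
                                  f"{v.implied_object_id!r} is not an object")
                    )
            if v.compound == "av" and v.implied_value_id is not None:
                if not _value_id_resolves(t, v.implied_value_id):
                    out.append(
                        Violation("dangling-implied-value", c.id,
                                  f"unknown implied value {v.implied_value_id!r}")
                    )
        if c.boolean_nature:
            if c.ctype not in ATTRIBUTE_CTYPES:
                out.append(Violation("boolean-on-non-attribute", c.id, "boolean_nature on non-attribute"))
            elif c.implicit_value is None:
                out.append(
                    Violation("no-implicit-value", c.id,
                              "boolean_nature attribute must declare implicit_value")
                )
            elif validate_ref := _implicit_value_missing(t, c):
                out.append(validate_ref)

    for tmpl in t.templates.values():
        seen: set[str] = set()
        for tv in tmpl.values:
            if tv.local_id in seen:
                out.append(
                    Violation("duplicate-template-value", tmpl.id,
                              f"local value id {tv.local_id!r} defined twice")
                )
            seen.add(tv.local_id)
            for v in tv.variants:
                _check_variant(v, tmpl.id, None, out)

    for d in t.dictionaries.values():
        for v in d.variants:
            _check_variant(v, d.name, None, out)

    for pat in t.ignore_section_patterns:
        try:
            re.compile(pat)
        except re.error as exc:
            out.append(Violation("bad-ignore-pattern", "", f"{pat!r} does not compile: {exc}"))

    out.sort(key=lambda v: (v.concept_id, v.code, v.message))
    return out


def _value_id_resolves(t: Terminology, value_id: str) -> bool:
    if value_id in t.concepts and t.concepts[value_id].ctype == "value":
        return True
    if COMPOSED_SEP in value_id:
        attr_id, local = value_id.split(COMPOSED_SEP, 1)
        attr = t.concepts.get(attr_id)
        if attr is not None and attr.template_ref in t.templates:
            return any(tv.local_id == local for tv in t.templates[attr.template_ref].values)
    return False


def _implicit_value_missing(t: Terminology, c: Concept) -> Optional[Violation]:
    try:
        evs = {ev.value_id for ev in t.effective_values(c.id)}
    except KeyError:
        return None
    if c.implicit_value not in evs:
        return Violation(
            "dangling-implicit-value", c.id,
            f"implicit_value {c.implicit_value!r} is not an effective value",
        )
    return None


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _variant_from_node(node: Union[str, dict]) -> Variant:
    if isinstance(node, str):
        return Variant(pattern=node)
    return Variant(
        pattern=node["pattern"],
        vtype=node.get("vtype", "std"),
        compound=node.get("compound", "none"),
        implied_object_id=node.get("implied_object"),
        implied_value_id=node.get("implied_value"),
    )


def _variant_to_node(v: Variant) -> Union[str, dict]:
    if v.vtype == "std" and v.compound == "none":
        return v.pattern
    node: dict = {"pattern": v.pattern}
    if v.vtype != "std":
        node["vtype"] = v.vtype
    if v.compound != "none":
        node["compound"] = v.compound
    if v.implied_object_id is not None:
        node["implied_object"] = v.implied_object_id
    if v.implied_value_id is not None:
        node["implied_value"] = v.implied_value_id
    return node


def _concepts_from_tree(nodes: list[dict], parent_id: Optional[str], out: list[Concept]) -> None:
    for node in nodes:
        if not isinstance(node, dict) or "id" not in node or "type" not in node:
            raise ParseError(f"concept node must have 'id' and 'type': {node!r}")
        c = Concept(
            id=str(node["id"]),
            label=str(node.get("label", node["id"])),
            ctype=str(node["type"]),
            parent_id=parent_id,
            boolean_nature=bool(node.get("boolean_nature", False)),
            suppress=bool(node.get("suppress", True)),
            template_ref=node.get("template"),
            dictionary_refs=tuple(node.get("dictionaries", ())),
            aspect=node.get("aspect"),
            implicit_value=node.get("implicit_value"),
            variants=tuple(_variant_from_node(v) for v in node.get("variants", ())),
        )
        out.append(c)
        _concepts_from_tree(node.get("children", []), c.id, out)


def _concept_to_node(t: Terminology, c: Concept) -> dict:
    node: dict = {"id": c.id, "label": c.label, "type": c.ctype}
    if c.boolean_nature:
        node["boolean_nature"] = True
    if c.ctype == "value" and not c.suppress:
        node["suppress"] = False
    if c.template_ref is not None:
        node["template"] = c.template_ref
    if c.dictionary_refs:
        node["dictionaries"] = list(c.dictionary_refs)
    if c.aspect is not None:
        node["aspect"] = c.aspect
    if c.implicit_value is not None:
        node["implicit_value"] = c.implicit_value
    if c.variants:
        node["variants"] = [_variant_to_node(v) for v in c.variants]
    kids = [_concept_to_node(t, k) for k in t.children(c.id)]
    if kids:
        node["children"] = kids
    return node


class ParseError(Exception):
    pass


def _terminology_from_data(data: dict) -> Terminology:
    if not isinstance(data, dict):
        raise ParseError("terminology file must contain a mapping at top level")
    concepts: list[Concept] = []
    _concepts_from_tree(data.get("concepts", []), None, concepts)
    templates = []
    for tnode in data.get("templates", []):
        values = tuple(
            TemplateValue(
                local_id=str(v["id"]),
                label=str(v.get("label", v["id"])),
                suppress=bool(v.get("suppress", True)),
                variants=tuple(_variant_from_node(x) for x in v.get("variants", ())),
            )
            for v in tnode.get("values", ())
        )
        templates.append(Template(id=str(tnode["id"]), label=str(tnode.get("label", tnode["id"])), values=values))
    dictionaries = [
        Dictionary(name=str(d["name"]), variants=tuple(_variant_from_node(x) for x in d.get("variants", ())))
        for d in data.get("dictionaries", [])
    ]
    return Terminology(
        concepts,
        templates,
        dictionaries,
        ignore_section_patterns=tuple(data.get("ignore_sections", ())),
    )


def _terminology_to_data(t: Terminology) -> dict:
    roots = [c for c in t if c.parent_id is None]
    return {
        "concepts": [_concept_to_node(t, c) for c in roots],
        "templates": [
            {
                "id": tmpl.id,
                "label": tmpl.label,
                "values": [
                    {
                        "id": tv.local_id,
                        "label": tv.label,
                        **({"suppress": False} if not tv.suppress else {}),
                        **({"variants": [_variant_to_node(v) for v in tv.variants]} if tv.variants else {}),
                    }
                    for tv in tmpl.values
                ],
            }
            for tmpl in t.templates.values()
        ],
        "dictionaries": [
            {"name": d.name, "variants": [_variant_to_node(v) for v in d.variants]}
            for d in t.dictionaries.values()
        ],
        "ignore_sections": list(t.ignore_section_patterns),
    }


def load_terminology(path: Union[str, Path]) -> Terminology:
    """Load a terminology from a YAML (default) or JSON file and validate it.

    Raises :class:`ParseError` on malformed files and :class:`ValidationError`
    listing every violated invariant otherwise.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    t = _terminology_from_data(data)
    violations = validate_terminology(t)
    if violations:
        raise ValidationError(violations)
    return t


def save_terminology(t: Terminology, path: Union[str, Path]) -> None:
    path = Path(path)
    data = _terminology_to_data(t)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, ensure_ascii=False, indent=2), encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(data, allow_unicode=True, sort_keys=False), encoding="utf-8"
        )


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Offset-faithful tokens: word-character runs and single punctuation marks."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass(frozen=True)
class MatchTarget:
    """What a matched surface form refers to.

    ``concept_id`` is set for concept-owned variants; template values carry
    ``template_id``/``local_id`` instead and are bound to a concrete attribute
    only at pairing time (their value id is then composed).
    """

    layer: str  # object | attribute | value
    concept_id: Optional[str] = None
    template_id: Optional[str] = None
    local_id: Optional[str] = None
    compound: str = "none"
    implied_object_id: Optional[str] = None
    implied_value_id: Optional[str] = None
    suppress: bool = True


@dataclass(frozen=True)
class RawHit:
    begin: int
    end: int
    layer: str
    targets: tuple[MatchTarget, ...]
    pattern: str
    vtype: str


_LAYER_OF_CTYPE = {
    "object": "object",
    "object_attribute": "attribute",
    "attribute": "attribute",
    "value": "value",
}


class _TrieNode:
    __slots__ = ("children", "targets", "patterns")

    def __init__(self) -> None:
        self.children: dict[str, _TrieNode] = {}
        self.targets: list[MatchTarget] = []
        self.patterns: list[str] = []


class CompiledMatcher:
    """Keyword trie over case-folded std variants plus a compiled regexp bank.

    ``find`` reports every place where any variant of any non-structure
    concept (or template value) occurs.  std variants match case-insensitively
    at token boundaries; regexp variants match as written.
    """

    def __init__(self, t: Terminology) -> None:
        violations = validate_terminology(t)
        if violations:
            raise ValidationError(violations)
        self.terminology = t
        self._root = _TrieNode()
        self._regexps: list[tuple[re.Pattern, str, list[MatchTarget], str]] = []
        self.entry_count = 0
        for c in t:
            if c.ctype == "structure":
                continue
            layer = _LAYER_OF_CTYPE[c.ctype]
            for v in t.concept_variants(c.id):
                target = MatchTarget(
                    layer=layer,
                    concept_id=c.id,
                    compound=v.compound,
                    implied_object_id=v.implied_object_id,
                    implied_value_id=v.implied_value_id,
                    suppress=c.suppress if c.ctype == "value" else True,
                )
                self._add(v, target, layer)
        for tmpl in t.templates.values():
            for tv in tmpl.values:
                target = MatchTarget(
                    layer="value",
                    template_id=tmpl.id,
                    local_id=tv.local_id,
                    suppress=tv.suppress,
                )
                for v in tv.variants:
                    self._add(v, target, "value")

    def _add(self, v: Variant, target: MatchTarget, layer: str) -> None:
        self.entry_count += 1
        if v.vtype == "regexp":
            self._regexps.append((re.compile(v.pattern), layer, [target], v.pattern))
            return
        tokens = [tok for tok, _, _ in tokenize(fold(v.pattern))]
        node = self._root
        for tok in tokens:
            node = node.children.setdefault(tok, _TrieNode())
        node.targets.append(target)
        node.patterns.append(v.pattern)

    def find(self, text: str, base: int = 0) -> list[RawHit]:
        """All variant occurrences in *text*; offsets shifted by *base*.

        Equivalent to trying every variant at every token position (the naive
        oracle); overlaps are NOT resolved here.
        """
        hits: dict[tuple[int, int, str, str], list[MatchTarget]] = {}
        vt: dict[tuple[int, int, str, str], str] = {}
        toks = tokenize(text)
        folded = [fold(tok) for tok, _, _ in toks]
        for i in range(len(toks)):
            node = self._root
            j = i
            while j < len(toks):
                node = node.children.get(folded[j])
                if node is None:
                    break
                j += 1
                if node.targets:
                    span = (toks[i][1] + base, toks[j - 1][2] + base)
                    for target, pat in zip(node.targets, node.patterns):
                        key = (span[0], span[1], target.layer, pat)
                        hits.setdefault(key, []).append(target)
                        vt[key] = "std"
        for rx, layer, targets, pat in self._regexps:
            for m in rx.finditer(text):
                if m.start() == m.end():
                    continue
                key = (m.start() + base, m.end() + base, layer, pat)
                hits.setdefault(key, []).extend(targets)
                vt[key] = "regexp"
        out = [
            RawHit(begin=k[0], end=k[1], layer=k[2], targets=tuple(tgs), pattern=k[3], vtype=vt[k])
            for k, tgs in hits.items()
        ]
        out.sort(key=lambda h: (h.begin, -(h.end - h.begin), h.layer, h.pattern))
        return out


def compile_matcher(t: Terminology) -> CompiledMatcher:
    """Compile the terminology into a trie + regexp bank for matching."""
    return CompiledMatcher(t)
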