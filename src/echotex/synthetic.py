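"""Fixture terminology and a seeded generator of synthetic German
echocardiography reports with exact gold annotations.

Real clinical corpora are private; this module emulates the structural
phenomena of semi-structured transthoracic-echo reports — subsection headers
naming cardiac objects, telegram-style noun-phrase segments, numeric
measurements, enumerations, negations, object-attribute compounds,
list-element layouts and short unstructured notes — and emits, for every
generated statement, the reference annotations a human annotator would
create.  Gold is produced from the same random draw as the text, never by
re-parsing it.

Layouts:

* ``A`` / ``B`` — the two dominant semi-structured styles (numeric parameter
  block plus valve subsections, in different orders), >= 800 non-whitespace
  characters, < 5 list elements;
* ``C`` — list-element layout (``- AK: ...``), >= 5 hyphen-initial lines;
* ``unstructured`` — short free-text notes, 100-799 non-whitespace
  characters, no headers.

Statements whose concepts a deployed terminology would not cover are drawn
from a separate *unknown-phrase* pool (non-medical filler, checked at build
time to collide with no terminology variant).  They enter the gold standard
only as missing-concept mentions (no terminology ids), so they depress
recall but can never reward or punish precision.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

from .evaluation import ReferenceAnnotation
from .segmentation import Document
from .terminology import (
    Concept,
    Dictionary,
    Template,
    TemplateValue,
    Terminology,
    Variant,
    compile_matcher,
)

LAYOUTS = ("A", "B", "C", "unstructured")


# ---------------------------------------------------------------------------
# fixture terminology
# ---------------------------------------------------------------------------

_NUM = r"\d+(?:[.,]\d+)?"


def _oa(pattern: str, obj: str) -> Variant:
    return Variant(pattern=pattern, compound="oa", implied_object_id=obj)


def _av(pattern: str, value_id: str) -> Variant:
    return Variant(pattern=pattern, vtype="regexp", compound="av", implied_value_id=value_id)


def _valve_attr(
    cid: str, label: str, parent: str, dic: str, aspect: Optional[str], oa_variants: Sequence[Variant]
) -> list[Concept]:
    """An ambiguous valve finding attribute with presence/absence values and
    the shared severity template."""
    return [
        Concept(
            id=cid, label=label, ctype="object_attribute", parent_id=parent,
            boolean_nature=True, implicit_value=f"{cid}-p", template_ref="T1",
            dictionary_refs=(dic,), aspect=aspect, variants=tuple(oa_variants),
        ),
        Concept(id=f"{cid}-p", label="vorhanden", ctype="value", parent_id=cid),
        Concept(
            id=f"{cid}-a", label="nicht vorhanden", ctype="value", parent_id=cid,
            suppress=False, dictionary_refs=("d-neg",),
        ),
    ]


def _measurement(
    cid: str, label: str, aspect: str, names: Sequence[str], unit_re: str
) -> list[Concept]:
    """An unambiguous numeric attribute recognized via an av-compound regexp."""
    name_re = "(?:" + "|".join(re.escape(n) for n in names) + ")"
    return [
        Concept(
            id=cid, label=label, ctype="attribute", parent_id="messwerte",
            aspect=aspect,
            variants=(
                *(Variant(pattern=n) for n in names),
                _av(rf"{name_re}\s*:?\s*{_NUM}\s*{unit_re}", f"{cid}-w"),
            ),
        ),
        Concept(id=f"{cid}-w", label="Messwert", ctype="value", parent_id=cid),
    ]


def build_fixture_terminology() -> Terminology:
    """The valve/measurement fixture terminology used by tests and examples.

    Four valve objects, each with regurgitation and stenosis object
    attributes sharing dictionary variants; a severity template with composed
    value ids; negation activators; object-attribute compounds; ten numeric
    measurement attributes; boolean attributes; aspect labels; and an ignore
    pattern for transesophageal (TEE) sections.
    """
    concepts: list[Concept] = [
        Concept(id="klappen", label="Klappen", ctype="structure"),
        Concept(id="av", label="Aortenklappe", ctype="object", parent_id="klappen",
                variants=(Variant("Aortenklappe"), Variant("AK"))),
        Concept(id="mv", label="Mitralklappe", ctype="object", parent_id="klappen",
                variants=(Variant("Mitralklappe"), Variant("MK"))),
        Concept(id="tv", label="Trikuspidalklappe", ctype="object", parent_id="klappen",
                variants=(Variant("Trikuspidalklappe"), Variant("TK"))),
        Concept(id="pv", label="Pulmonalklappe", ctype="object", parent_id="klappen",
                variants=(Variant("Pulmonalklappe"), Variant("PK"))),
    ]
    concepts += _valve_attr(
        "av-insuff", "Aorteninsuffizienz", "av", "d-insuff", "AV Regurgitation",
        [_oa("Aortenklappeninsuffizienz", "av"), _oa("Aorteninsuffizienz", "av")],
    )
    concepts += _valve_attr(
        "av-sten", "Aortenstenose", "av", "d-sten", "AV Stenosis",
        [_oa("Aortenklappenstenose", "av"), _oa("Aortenstenose", "av")],
    )
    concepts += _valve_attr(
        "mv-insuff", "Mitralinsuffizienz", "mv", "d-insuff", "MV Regurgitation",
        [_oa("Mitralklappeninsuffizienz", "mv"), _oa("Mitralinsuffizienz", "mv")],
    )
    concepts += _valve_attr(
        "12", "Mitralklappenstenose", "mv", "d-sten", "MV Stenosis",
        [_oa("Mitralklappenstenose", "mv"), _oa("Mitralstenose", "mv")],
    )
    concepts += _valve_attr(
        "tv-insuff", "Trikuspidalinsuffizienz", "tv", "d-insuff", "TV Regurgitation",
        [_oa("Trikuspidalklappeninsuffizienz", "tv"), _oa("Trikuspidalinsuffizienz", "tv")],
    )
    concepts += _valve_attr(
        "tv-sten", "Trikuspidalstenose", "tv", "d-sten", None,
        [_oa("Trikuspidalklappenstenose", "tv")],
    )
    concepts += _valve_attr(
        "pv-insuff", "Pulmonalinsuffizienz", "pv", "d-insuff", None,
        [_oa("Pulmonalklappeninsuffizienz", "pv"), _oa("Pulmonalinsuffizienz", "pv")],
    )
    concepts += _valve_attr(
        "pv-sten", "Pulmonalstenose", "pv", "d-sten", None,
        [_oa("Pulmonalklappenstenose", "pv"), _oa("Pulmonalstenose", "pv")],
    )

    concepts += [
        Concept(id="raeume", label="Herzhöhlen", ctype="structure"),
        Concept(id="lv", label="linker Ventrikel", ctype="object", parent_id="raeume",
                variants=(Variant("linker Ventrikel"),)),
        Concept(id="lvor", label="linker Vorhof", ctype="object", parent_id="raeume",
                variants=(Variant("linker Vorhof"),)),
    ]

    concepts += [Concept(id="messwerte", label="Messwerte", ctype="structure")]
    concepts += _measurement("lvdd", "LVDd", "LVD_d", ["LVDd"], "mm")
    concepts += _measurement("lvds", "LVDs", "LVD_s", ["LVDs"], "mm")
    concepts += _measurement("ivsdd", "IVSDd", "IVSD_d", ["IVSDd", "Septum"], "mm")
    concepts += _measurement("pwdd", "PWDd", "PWD_d", ["PWDd", "Hinterwand"], "mm")
    concepts += _measurement("lvef", "LVEF", "LVEF (%)", ["LVEF"], "%")
    concepts += _measurement("spap", "sPAP", "sPAP", ["sPAP"], "mmHg")
    concepts += _measurement("aow", "Aortenwurzel", "Aortic Root Diameter", ["Aortenwurzel"], "mm")
    concepts += _measurement("la", "LA", "LAD (LADs, LADsI)", ["LA"], "mm")
    concepts += _measurement("vmax", "Vmax", "V_max", ["Vmax"], "m/s")
    concepts += _measurement("dpmax", "dPmax", "ΔP_max (pressure gradient)", ["dPmax", "ΔPmax"], "mmHg")

    concepts += [
        Concept(id="befunde", label="Befunde", ctype="structure"),
        Concept(id="diafu", label="Diastolische Funktion", ctype="attribute",
                parent_id="befunde", aspect="Diastolic Function",
                variants=(Variant("Diastolische Funktion"),)),
        Concept(id="diafu-norm", label="normal", ctype="value", parent_id="diafu",
                variants=(Variant("normal"),)),
        Concept(id="diafu-nb", label="nicht sicher beurteilbar", ctype="value",
                parent_id="diafu",
                variants=(Variant("nicht sicher beurteilbar"), Variant("nicht beurteilbar"))),
        Concept(id="diafu-rest", label="Relaxationsstörung", ctype="value", parent_id="diafu",
                variants=(Variant("Relaxationsstörung"),)),
        Concept(id="tachy", label="Tachykardie", ctype="attribute", parent_id="befunde",
                boolean_nature=True, implicit_value="tachy-p",
                variants=(Variant("Tachykardie"),)),
        Concept(id="tachy-p", label="vorhanden", ctype="value", parent_id="tachy"),
        Concept(id="tachy-a", label="nicht vorhanden", ctype="value", parent_id="tachy",
                suppress=False, dictionary_refs=("d-neg",)),
        Concept(id="perik", label="Perikarderguss", ctype="attribute", parent_id="befunde",
                boolean_nature=True, implicit_value="perik-p", template_ref="T1",
                aspect="Pericardial Effusion", variants=(Variant("Perikarderguss"),)),
        Concept(id="perik-p", label="vorhanden", ctype="value", parent_id="perik"),
        Concept(id="perik-a", label="nicht vorhanden", ctype="value", parent_id="perik",
                suppress=False, dictionary_refs=("d-neg",)),
    ]

    templates = [
        Template(
            id="T1", label="Severity",
            values=(
                TemplateValue("0", "gering", variants=tuple(
                    Variant(p) for p in
                    ("gering", "geringe", "geringer", "geringgradig", "geringgradige",
                     "leichtgradig", "leichtgradige", "Grad I", "I°", "I")
                )),
                TemplateValue("1", "mittelgradig", variants=tuple(
                    Variant(p) for p in
                    ("mittelgradig", "mittelgradige", "mäßiggradig", "Grad II", "II°", "II")
                )),
                TemplateValue("2", "hochgradig", variants=tuple(
                    Variant(p) for p in
                    ("hochgradig", "hochgradige", "schwer", "Grad III", "III°", "III")
                )),
            ),
        )
    ]
    dictionaries = [
        Dictionary("d-insuff", (Variant("Insuffizienz"), Variant("Insuff"))),
        Dictionary("d-sten", (Variant("Stenose"),)),
        Dictionary("d-neg", (Variant("kein"), Variant("keine"),
                             Variant("nicht nachweisbar"), Variant("ohne"))),
    ]
    return Terminology(
        concepts, templates, dictionaries,
        ignore_section_patterns=(r"^\s*TEE\b",),
    )


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    n_documents: int = 20
    layout_mixture: dict = field(
        default_factory=lambda: {"A": 0.472, "B": 0.472, "C": 0.016, "unstructured": 0.040}
    )
    negation_rate: float = 0.3
    enumeration_rate: float = 0.2
    oa_compound_rate: float = 0.3
    unknown_phrase_rate: float = 0.0
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("GeneratorConfig.seed is mandatory")
        total = sum(self.layout_mixture.get(k, 0.0) for k in LAYOUTS)
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.layout_mixture.values()):
            raise ValueError("layout mixture must be a distribution over " + "/".join(LAYOUTS))
        for name in ("negation_rate", "enumeration_rate", "oa_compound_rate", "unknown_phrase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    gold: dict[str, list[ReferenceAnnotation]]
    provenance: dict[str, dict]


#: non-medical German filler; must collide with no terminology variant
#: (enforced at generator construction) and stay digit-free
UNKNOWN_PHRASES = (
    "Der Patient wurde über den Ablauf der Untersuchung informiert",
    "Die Untersuchung erfolgte in Ruhe und störungsfrei",
    "Gute Mitarbeit während der gesamten Untersuchung",
    "Weitere Kontrolle im Verlauf empfohlen",
    "Die Aufnahmen wurden digital archiviert",
    "Vorbefunde lagen zum Zeitpunkt der Untersuchung nicht vor",
    "Das Ergebnis wurde mit dem Patienten besprochen",
    "Eine schriftliche Befundkopie geht an den Hausarzt",
)

_SEV_WORDS = {
    # surface form (capitalized for sentence starts) -> template local id
    "Geringe": "0", "Geringgradige": "0", "Leichtgradige": "0",
    "Mittelgradige": "1", "Mäßiggradig": "1",
    "Hochgradige": "2",
}
_GRADES = {"I": "0", "II": "1", "III": "2"}

_MEASUREMENTS = [
    # attr id, printed name, unit, (lo, hi), decimals
    ("lvdd", "LVDd", "mm", (38, 60), 0),
    ("lvds", "LVDs", "mm", (22, 45), 0),
    ("ivsdd", "IVSDd", "mm", (7, 14), 0),
    ("ivsdd", "Septum", "mm", (7, 14), 0),
    ("pwdd", "PWDd", "mm", (7, 13), 0),
    ("pwdd", "Hinterwand", "mm", (7, 13), 0),
    ("lvef", "LVEF", "%", (25, 75), 0),
    ("spap", "sPAP", "mmHg", (18, 45), 0),
    ("aow", "Aortenwurzel", "mm", (26, 40), 0),
    ("la", "LA", "mm", (28, 48), 0),
    ("vmax", "Vmax", "m/s", (10, 45), 1),
    ("dpmax", "dPmax", "mmHg", (4, 30), 0),
]

_OA_WORDS = [
    ("av-insuff", "Aortenklappeninsuffizienz"),
    ("av-sten", "Aortenklappenstenose"),
    ("mv-insuff", "Mitralklappeninsuffizienz"),
    ("12", "Mitralklappenstenose"),
    ("tv-insuff", "Trikuspidalklappeninsuffizienz"),
    ("pv-insuff", "Pulmonalklappeninsuffizienz"),
]

_VALVES = [
    ("av", "Aortenklappe", "AK", "av-insuff", "av-sten"),
    ("mv", "Mitralklappe", "MK", "mv-insuff", "12"),
    ("tv", "Trikuspidalklappe", "TK", "tv-insuff", "tv-sten"),
    ("pv", "Pulmonalklappe", "PK", "pv-insuff", "pv-sten"),
]


@dataclass
class _Statement:
    text: str
    # (attribute_id, value_id, begin, end) relative to text, or missing mention
    pairs: list[tuple[str, str, int, int]] = field(default_factory=list)
    missing: list[tuple[int, int, str]] = field(default_factory=list)


class _Builder:
    """Statement builders; every builder returns text plus the exact gold a
    reference annotator following the engine's span conventions would add."""

    def __init__(self, rng: random.Random, cfg: GeneratorConfig):
        self.rng = rng
        self.cfg = cfg

    def measurement(self, idx: Optional[int] = None, period: bool = False) -> _Statement:
        attr, name, unit, (lo, hi), dec = (
            _MEASUREMENTS[idx] if idx is not None else self.rng.choice(_MEASUREMENTS)
        )
        if dec:
            val = f"{self.rng.randint(lo, hi) / 10:.1f}".replace(".", ",")
        else:
            val = str(self.rng.randint(lo, hi))
        sep = self.rng.choice([" ", " ", ""])
        core = f"{name} {val}{sep}{unit}"
        text = core + "." if period else core
        return _Statement(text, pairs=[(attr, f"{attr}-w", 0, len(core))])

    def _finding(self, attr_id: str, word: str) -> _Statement:
        """negated or graded finding over a bare ambiguous keyword."""
        if self.rng.random() < self.cfg.negation_rate:
            neg = "Keine"
            text = f"{neg} {word}."
            a0 = len(neg) + 1
            return _Statement(text, pairs=[(attr_id, f"{attr_id}-a", 0, a0 + len(word))])
        sev = self.rng.choice(sorted(_SEV_WORDS))
        loc = _SEV_WORDS[sev]
        text = f"{sev} {word}."
        a0 = len(sev) + 1
        return _Statement(
            text,
            pairs=[
                (attr_id, f"{attr_id}:{loc}", 0, a0 + len(word)),
                (attr_id, f"{attr_id}-p", a0, a0 + len(word)),
            ],
        )

    def valve_finding(self, valve: tuple) -> _Statement:
        _, _, _, insuff, sten = valve
        if self.rng.random() < 0.5:
            return self._finding(insuff, "Insuffizienz")
        return self._finding(sten, "Stenose")

    def valve_double(self, valve: tuple) -> _Statement:
        """Negated regurgitation plus graded stenosis in one comma-joined sentence."""
        _, _, _, insuff, sten = valve
        sev = self.rng.choice(sorted(_SEV_WORDS)).lower()
        loc = _SEV_WORDS[sev.capitalize()]
        text = f"Keine Insuffizienz, {sev} Stenose."
        i0 = text.index("Insuffizienz")
        s0 = text.index("Stenose")
        v0 = text.index(sev)
        return _Statement(
            text,
            pairs=[
                (insuff, f"{insuff}-a", 0, i0 + len("Insuffizienz")),
                (sten, f"{sten}:{loc}", v0, s0 + len("Stenose")),
                (sten, f"{sten}-p", s0, s0 + len("Stenose")),
            ],
        )

    def oa_statement(self) -> _Statement:
        attr, word = self.rng.choice(_OA_WORDS)
        style = self.rng.random()
        if style < self.cfg.negation_rate:
            text = f"Keine {word}."
            a0 = len("Keine ")
            return _Statement(text, pairs=[(attr, f"{attr}-a", 0, a0 + len(word))])
        if style < 0.7:
            sev = self.rng.choice(sorted(_SEV_WORDS))
            loc = _SEV_WORDS[sev]
            text = f"{sev} {word}."
            a0 = len(sev) + 1
            return _Statement(
                text,
                pairs=[
                    (attr, f"{attr}:{loc}", 0, a0 + len(word)),
                    (attr, f"{attr}-p", a0, a0 + len(word)),
                ],
            )
        grade = self.rng.choice(sorted(_GRADES))
        loc = _GRADES[grade]
        text = f"{word} {grade}."
        g0 = len(word) + 1
        return _Statement(
            text,
            pairs=[
                (attr, f"{attr}:{loc}", 0, g0 + len(grade)),
                (attr, f"{attr}-p", 0, len(word)),
            ],
        )

    def prep_statement(self) -> _Statement:
        text = "Diastolische Funktion bei Tachykardie nicht sicher beurteilbar."
        d0, dlen = 0, len("Diastolische Funktion")
        t0 = text.index("Tachykardie")
        n0 = text.index("nicht sicher beurteilbar")
        return _Statement(
            text,
            pairs=[
                ("diafu", "diafu-nb", d0, n0 + len("nicht sicher beurteilbar")),
                ("tachy", "tachy-p", t0, t0 + len("Tachykardie")),
            ],
        )

    def diafu_statement(self) -> _Statement:
        value, vid = self.rng.choice(
            [("normal", "diafu-norm"), ("Relaxationsstörung", "diafu-rest")]
        )
        text = f"Diastolische Funktion {value}."
        return _Statement(
            text, pairs=[("diafu", vid, 0, len(text) - 1)]
        )

    def perik_statement(self) -> _Statement:
        if self.rng.random() < self.cfg.negation_rate:
            text = "Kein Perikarderguss."
            return _Statement(text, pairs=[("perik", "perik-a", 0, len(text) - 1)])
        text = "Geringer Perikarderguss."
        p0 = len("Geringer ")
        return _Statement(
            text,
            pairs=[
                ("perik", "perik:0", 0, len(text) - 1),
                ("perik", "perik-p", p0, len(text) - 1),
            ],
        )

    def enum_statement(self) -> _Statement:
        items = self.rng.sample(["Aortenklappe", "Mitralklappe", "Trikuspidalklappe",
                                 "Pulmonalklappe"], 3)
        text = f"Unauffälliger Befund an {items[0]}, {items[1]} und {items[2]}."
        return _Statement(text)

    def coord_statement(self) -> _Statement:
        lvdd = self.measurement(idx=0)
        la = self.measurement(idx=9)
        text = (
            f"Normal großer linker Ventrikel ({lvdd.text}) und "
            f"leichtgradig dilatierter linker Vorhof ({la.text})."
        )
        o1 = text.index("(") + 1
        o2 = text.index("(", o1) + 1
        pairs = [
            (a, v, o1 + b, o1 + e) for a, v, b, e in lvdd.pairs
        ] + [
            (a, v, o2 + b, o2 + e) for a, v, b, e in la.pairs
        ]
        return _Statement(text, pairs=pairs)

    def tachy_statement(self) -> _Statement:
        text = "Intermittierende Tachykardie."
        t0 = text.index("Tachykardie")
        return _Statement(text, pairs=[("tachy", "tachy-p", t0, t0 + len("Tachykardie"))])

    def unknown_statement(self) -> _Statement:
        phrase = self.rng.choice(UNKNOWN_PHRASES)
        text = phrase + "."
        return _Statement(text, missing=[(0, len(phrase), phrase)])


class _DocAssembler:
    def __init__(self, doc_id: str, site: Optional[str]):
        self.doc_id = doc_id
        self.site = site
        self.parts: list[str] = []
        self.length = 0
        self.gold: list[ReferenceAnnotation] = []

    def add_text(self, text: str) -> int:
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start

    def add_statement(self, st: _Statement) -> None:
        start = self.add_text(st.text)
        for attr, value, b, e in st.pairs:
            self.gold.append(
                ReferenceAnnotation(self.doc_id, attr, value, start + b, start + e)
            )
        for b, e, label in st.missing:
            self.gold.append(
                ReferenceAnnotation(
                    self.doc_id, None, None, start + b, start + e,
                    missing_concept=True, label=label,
                )
            )

    def finish(self) -> Document:
        return Document(id=self.doc_id, text="".join(self.parts), site=self.site)


class CorpusGenerator:
    def __init__(self, cfg: GeneratorConfig, terminology: Optional[Terminology] = None):
        cfg.validate()
        self.cfg = cfg
        self.terminology = terminology or build_fixture_terminology()
        matcher = compile_matcher(self.terminology)
        for phrase in UNKNOWN_PHRASES:
            hits = matcher.find(phrase)
            if hits:
                raise ValueError(
                    f"unknown-phrase pool collides with terminology: {phrase!r} "
                    f"matches {hits[0].pattern!r}"
                )

    # -- statement slots ----------------------------------------------------

    def _slot(self, b: _Builder, known: Callable[[], _Statement]) -> _Statement:
        if b.rng.random() < self.cfg.unknown_phrase_rate:
            return b.unknown_statement()
        return known()

    def _valve_section(self, asm: _DocAssembler, b: _Builder, valve: tuple, abbrev: bool = False) -> None:
        _, label, abbr, _, _ = valve
        asm.add_text(f"{abbr if abbrev else label}: ")
        n = b.rng.randint(1, 2)
        for i in range(n):
            st = self._slot(
                b,
                lambda: b.valve_double(valve)
                if b.rng.random() < self.cfg.enumeration_rate
                else b.valve_finding(valve),
            )
            asm.add_statement(st)
            if i < n - 1:
                asm.add_text(" ")
        asm.add_text("\n")

    def _numeric_block(self, asm: _DocAssembler, b: _Builder, k: int) -> None:
        picks = b.rng.sample(range(len(_MEASUREMENTS)), k)
        for idx in picks:
            asm.add_statement(b.measurement(idx=idx))
            asm.add_text("\n")

    def _assessment_section(self, asm: _DocAssembler, b: _Builder) -> None:
        asm.add_text("Beurteilung: ")
        statements: list[Callable[[], _Statement]] = [
            b.oa_statement, b.prep_statement, b.diafu_statement,
            b.perik_statement, b.coord_statement, b.tachy_statement,
        ]
        if b.rng.random() < self.cfg.enumeration_rate:
            statements.append(b.enum_statement)
        n = b.rng.randint(2, 4)
        for i, maker in enumerate(b.rng.sample(statements, n)):
            asm.add_statement(self._slot(b, maker))
            if i < n - 1:
                asm.add_text(" ")
        asm.add_text("\n")

    def _tee_section(self, asm: _DocAssembler, b: _Builder) -> None:
        # masked downstream: contributes no gold despite known phrases
        word = b.rng.choice([w for _, w in _OA_WORDS])
        asm.add_text(f"TEE: {word} {b.rng.choice(sorted(_GRADES))}. "
                     "Eingeschränkte Schallbedingungen.\n")

    # -- layouts ------------------------------------------------------------

    def _doc_dominant(self, asm: _DocAssembler, b: _Builder, style: str) -> None:
        def sections() -> None:
            for valve in _VALVES:
                self._valve_section(asm, b, valve)
            asm.add_text("Linker Ventrikel: ")
            asm.add_statement(self._slot(b, b.coord_statement))
            asm.add_text("\n")

        if style == "A":
            self._numeric_block(asm, b, k=8)
            sections()
        else:
            sections()
            asm.add_text("Messwerte:\n")
            self._numeric_block(asm, b, k=8)
        if b.rng.random() < 0.25:
            self._tee_section(asm, b)
        self._assessment_section(asm, b)
        while sum(1 for ch in "".join(asm.parts) if not ch.isspace()) < 800:
            self._assessment_section(asm, b)

    def _doc_list(self, asm: _DocAssembler, b: _Builder) -> None:
        lines = 0
        while lines < 6:
            for valve in _VALVES:
                asm.add_text("- ")
                self._valve_section(asm, b, valve, abbrev=True)
                lines += 1
            if lines < 6:
                asm.add_text("- ")
                asm.add_statement(self._slot(b, b.measurement))
                asm.add_text("\n")
                lines += 1

    def _doc_unstructured(self, asm: _DocAssembler, b: _Builder) -> None:
        makers: list[Callable[[], _Statement]] = [
            b.oa_statement, b.diafu_statement, b.perik_statement,
            b.tachy_statement, lambda: b.measurement(period=True), b.prep_statement,
        ]
        n = b.rng.randint(3, 5)
        for i, maker in enumerate(b.rng.sample(makers, n)):
            asm.add_statement(self._slot(b, maker))
            asm.add_text(" " if i < n - 1 else "\n")
        # keep under 800 non-whitespace characters by construction
        nonspace = sum(1 for ch in "".join(asm.parts) if not ch.isspace())
        if nonspace < 100:
            while nonspace < 100:
                asm.add_statement(self._slot(b, b.oa_statement))
                asm.add_text("\n")
                nonspace = sum(1 for ch in "".join(asm.parts) if not ch.isspace())

    # -- corpus -------------------------------------------------------------

    def generate(self) -> SyntheticCorpus:
        rng = random.Random(self.cfg.seed)
        documents: list[Document] = []
        gold: dict[str, list[ReferenceAnnotation]] = {}
        provenance: dict[str, dict] = {}
        labels = [k for k in LAYOUTS if self.cfg.layout_mixture.get(k, 0) > 0]
        weights = [self.cfg.layout_mixture[k] for k in labels]
        for i in range(self.cfg.n_documents):
            layout = rng.choices(labels, weights=weights, k=1)[0]
            doc_id = f"synthetic-{i:04d}"
            asm = _DocAssembler(doc_id, site=rng.choice(["KARD-A", "KARD-B"]))
            b = _Builder(rng, self.cfg)
            if layout in ("A", "B"):
                self._doc_dominant(asm, b, layout)
            elif layout == "C":
                self._doc_list(asm, b)
            else:
                self._doc_unstructured(asm, b)
            doc = asm.finish()
            documents.append(doc)
            gold[doc_id] = asm.gold
            provenance[doc_id] = {"layout": layout, "site": doc.site}
        return SyntheticCorpus(documents, gold, provenance)


def generate_corpus(
    cfg: GeneratorConfig, terminology: Optional[Terminology] = None
) -> SyntheticCorpus:
    """Generate a seeded synthetic corpus with gold annotations."""
    return CorpusGenerator(cfg, terminology).generate()


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------


def write_corpus(corpus: SyntheticCorpus, outdir: Union[str, Path]) -> None:
    """corpus.jsonl + per-document text files + gold standoff TSV."""
    outdir = Path(outdir)
    (outdir / "texts").mkdir(parents=True, exist_ok=True)
    with open(outdir / "corpus.jsonl", "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(json.dumps(
                {"id": doc.id, "text": doc.text, "site": doc.site}, ensure_ascii=False
            ) + "\n")
            (outdir / "texts" / f"{doc.id}.txt").write_text(doc.text, encoding="utf-8")
    with open(outdir / "gold.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tattribute_id\tvalue_id\tbegin\tend\tmissing\tlabel\n")
        for doc in corpus.documents:
            for g in corpus.gold[doc.id]:
                fh.write(
                    f"{g.doc_id}\t{g.attribute_id or ''}\t{g.value_id or ''}\t"
                    f"{g.begin}\t{g.end}\t{int(g.missing_concept)}\t{g.label or ''}\n"
                )
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(corpus.provenance, fh, ensure_ascii=False, indent=2)


def read_gold(path: Union[str, Path]) -> dict[str, list[ReferenceAnnotation]]:
    out: dict[str, list[ReferenceAnnotation]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            ann = ReferenceAnnotation(
                doc_id=row["doc_id"],
                attribute_id=row["attribute_id"] or None,
                value_id=row["value_id"] or None,
                begin=int(row["begin"]),
                end=int(row["end"]),
                missing_concept=bool(int(row.get("missing", "0") or 0)),
                label=row.get("label") or None,
            )
            out.setdefault(ann.doc_id, []).append(ann)
    return out


def read_corpus(path: Union[str, Path]) -> list[Document]:
    """Documents from a JSON-lines collection (id, text, site)."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                docs.append(Document(id=rec["id"], text=rec["text"], site=rec.get("site")))
    return docs
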