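"""Terminology model, validation, file round-trips and compiled matching."""

import pytest

from echotex import (
    Concept,
    Dictionary,
    Template,
    Terminology,
    Variant,
    compile_matcher,
    load_terminology,
    save_terminology,
    validate_terminology,
)
from echotex.terminology import TemplateValue, fold, tokenize


def test_fold_is_casefold_and_unicode_normal():
    assert fold("Mäßiggradig") == fold("MÄSSIGGRADIG".replace("SS", "ß".upper()))
    assert fold("AK") == "ak"


def test_tokenize_offsets_are_faithful():
    text = "LVEF: 60 %."
    toks = tokenize(text)
    assert [t[0] for t in toks] == ["LVEF", ":", "60", "%", "."]
    for tok, b, e in toks:
        assert text[b:e] == tok


class TestModel:
    def test_fixture_validates_clean(self, terminology):
        assert validate_terminology(terminology) == []

    def test_effective_values_compose_template_ids(self, terminology):
        vals = {v.value_id for v in terminology.effective_values("12")}
        # local children first, then template imports with composed ids
        assert {"12-p", "12-a", "12:0", "12:1", "12:2"} <= vals

    def test_local_values_precede_template_values(self, terminology):
        ids = [v.value_id for v in terminology.effective_values("perik")]
        assert ids.index("perik-p") < ids.index("perik:0")

    def test_value_suppress_flags(self, terminology):
        assert terminology.value_suppress("mv-insuff", "mv-insuff-p") is True
        assert terminology.value_suppress("mv-insuff", "mv-insuff-a") is False

    def test_duplicate_ids_rejected(self):
        from echotex import ValidationError
        with pytest.raises(ValidationError):
            Terminology([
                Concept(id="a", label="A", ctype="structure"),
                Concept(id="a", label="A2", ctype="structure"),
            ])


class TestValidation:
    def test_separator_in_id_flagged(self):
        t = Terminology([Concept(id="a:b", label="x", ctype="structure")])
        assert any(v.code == "id-has-separator" for v in validate_terminology(t))

    def test_dangling_parent_flagged(self):
        t = Terminology([Concept(id="v", label="x", ctype="value", parent_id="ghost")])
        assert any(v.code == "dangling-parent" for v in validate_terminology(t))

    def test_boolean_without_implicit_value_flagged(self):
        t = Terminology([
            Concept(id="o", label="O", ctype="object", variants=(Variant("O"),)),
            Concept(id="a", label="A", ctype="attribute", parent_id="o",
                    boolean_nature=True, variants=(Variant("A"),)),
        ])
        codes = {v.code for v in validate_terminology(t)}
        assert codes  # boolean attribute lacks a resolvable implicit value

    def test_violations_sorted_deterministically(self):
        t = Terminology([
            Concept(id="z", label="x", ctype="value", parent_id="g1"),
            Concept(id="a", label="x", ctype="value", parent_id="g2"),
        ])
        v = validate_terminology(t)
        assert v == sorted(v, key=lambda x: (x.concept_id, x.code, x.message))


class TestRoundTrip:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_save_load_identity(self, terminology, tmp_path, suffix):
        p = tmp_path / f"t{suffix}"
        save_terminology(terminology, p)
        t2 = load_terminology(p)
        assert set(t2.concepts) == set(terminology.concepts)
        assert set(t2.templates) == set(terminology.templates)
        assert set(t2.dictionaries) == set(terminology.dictionaries)
        assert t2.ignore_section_patterns == terminology.ignore_section_patterns
        for cid, c in terminology.concepts.items():
            c2 = t2.concepts[cid]
            assert (c2.ctype, c2.parent_id, c2.boolean_nature, c2.suppress,
                    c2.template_ref, c2.dictionary_refs, c2.aspect,
                    c2.implicit_value, c2.variants) == (
                c.ctype, c.parent_id, c.boolean_nature, c.suppress,
                c.template_ref, c.dictionary_refs, c.aspect,
                c.implicit_value, c.variants)

    def test_saved_file_revalidates(self, terminology, tmp_path):
        p = tmp_path / "t.yaml"
        save_terminology(terminology, p)
        assert validate_terminology(load_terminology(p)) == []


class TestMatcher:
    def test_std_variant_is_case_insensitive_token_bounded(self, matcher):
        hits = matcher.find("mitralklappe ok")
        assert any(h.begin == 0 and h.end == len("mitralklappe") for h in hits)
        # no hit inside a longer word
        assert not any(h.begin == 0 for h in matcher.find("Mitralklappenring"))

    def test_leftmost_longest_prefers_compound(self, matcher):
        hits = [h for h in matcher.find("Mitralklappeninsuffizienz") if h.begin == 0]
        assert max(h.end for h in hits) == len("Mitralklappeninsuffizienz")

    def test_regexp_variant_matches_number_formats(self, matcher):
        for text in ["LVEF 60%", "LVEF: 60 %", "Vmax 1,1 m/s"]:
            assert any(h.end - h.begin == len(text) for h in matcher.find(text)), text

    def test_base_offset_shifts_spans(self, matcher):
        a = matcher.find("LVEF 60%")
        b = matcher.find("LVEF 60%", base=10)
        assert [(h.begin + 10, h.end + 10) for h in a] == [(h.begin, h.end) for h in b]

    def test_shared_dictionary_variant_yields_all_candidates(self, matcher):
        hits = [h for h in matcher.find("Insuffizienz")]
        (hit,) = [h for h in hits if h.layer == "attribute"]
        ids = {t.concept_id for t in hit.targets}
        assert {"av-insuff", "mv-insuff", "tv-insuff", "pv-insuff"} <= ids

    def test_template_value_hits_carry_template_identity(self, matcher):
        hits = matcher.find("mittelgradige")
        targets = [t for h in hits for t in h.targets]
        assert any(t.template_id == "T1" and t.local_id == "1" for t in targets)


def test_minimal_handbuilt_terminology_matches():
    t = Terminology(
        [
            Concept(id="o", label="Obj", ctype="object", variants=(Variant("Herz"),)),
            Concept(id="a", label="Attr", ctype="attribute", parent_id="o",
                    template_ref="T", variants=(Variant("Groesse"),)),
        ],
        templates=[Template(id="T", label="grades", values=(
            TemplateValue("0", "klein", variants=(Variant("klein"),)),
        ))],
        dictionaries=[Dictionary("d", (Variant("weit"),))],
    )
    assert validate_terminology(t) == []
    m = compile_matcher(t)
    assert {h.layer for h in m.find("Herz Groesse klein")} == {"object", "attribute", "value"}
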