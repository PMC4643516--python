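"""A tour of the terminology model.

The extraction engine is generic; everything domain-specific lives in a
terminology: a containment tree of structures, objects, attributes and
values, with surface variants, shared dictionaries, graded value templates
and compound forms.  This script builds the bundled echocardiography fixture
terminology, validates it, and shows how its pieces fit together.
"""

from echotex import save_terminology, validate_terminology
from echotex.synthetic import build_fixture_terminology

t = build_fixture_terminology()

print(f"{len(t.concepts)} concepts, {len(t.templates)} templates, "
      f"{len(t.dictionaries)} dictionaries")
assert validate_terminology(t) == [], "fixture must validate clean"

# An ambiguous attribute: "Insuffizienz" alone could belong to any valve.
# Each valve has its own object_attribute sharing the d-insuff dictionary.
mv_insuff = t.concepts["mv-insuff"]
print(f"\n{mv_insuff.id}: type={mv_insuff.ctype}, "
      f"dictionaries={mv_insuff.dictionary_refs}, template={mv_insuff.template_ref}")

# Its admissible values: local children (presence / absence) first, then the
# severity template imported with composed ids "<attribute>:<grade>".
for v in t.effective_values("mv-insuff"):
    print(f"  value {v.value_id!r} ({v.label}) suppress={v.suppress}")

# Compound variants carry their own context: the oa-compound
# "Mitralklappeninsuffizienz" implies the mitral valve object, and the
# av-compound regexp of a measurement implies its numeric value.
for v in mv_insuff.variants:
    print(f"  variant {v.pattern!r} compound={v.compound}")
lvef = t.concepts["lvef"]
print(f"\nlvef variants: {[ (v.pattern, v.vtype, v.compound) for v in lvef.variants ]}")

# The whole terminology round-trips through YAML (or JSON).
save_terminology(t, "/tmp/echotex_fixture.yaml")
print("\nwritten to /tmp/echotex_fixture.yaml")
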