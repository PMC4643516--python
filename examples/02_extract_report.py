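"""Extract attribute-value pairs from a German echocardiography report.

The pipeline masks out-of-domain (TEE) sections, splits the report into
subsections and segments, matches terminology variants, resolves ambiguous
attributes through object contexts, pairs attributes with values, and adds
implicit presence / suppression semantics.
"""

from echotex import Document, extract_document
from echotex.synthetic import build_fixture_terminology

REPORT = """\
Transthorakale Echokardiographie.
LVDd 48 mm, LVDs 31 mm, IVSDd 10 mm. LVEF 60%.
Aortenklappe: Keine Stenose. Geringe Insuffizienz.
Mitralklappe: keine Insuffizienz, mittelgradige Stenose.
Vmax 1,1 m/s
TEE: Mitralklappeninsuffizienz II. Eingeschränkte Schallbedingungen.
Beurteilung: Diastolische Funktion bei Tachykardie nicht sicher beurteilbar.
"""

t = build_fixture_terminology()
doc = Document(id="demo", text=REPORT)
result = extract_document(doc, t)

print(f"{len(result.pairs)} pairs extracted:\n")
for p in result.pairs:
    snippet = REPORT[p.begin:p.end].replace("\n", " ")
    kind = "implicit" if p.implicit else "explicit"
    print(f"  {p.attribute_id:>10} = {p.value_id:<14} [{p.begin:>3}:{p.end:<3}] "
          f"{kind:<8} {snippet!r}")

print("\ndiagnostics:")
for d in result.diagnostics:
    print(" ", d)

# Things worth noticing in the output:
# - the TEE line contributed nothing (masked as out-of-domain),
# - "Geringe Insuffizienz" under "Aortenklappe:" became av-insuff, the same
#   words under "Mitralklappe:" would become mv-insuff,
# - "keine Insuffizienz" produced the absence value and *no* implicit
#   presence, while "mittelgradige Stenose" kept both grade and presence,
# - "Vmax 1,1 m/s" survived the decimal comma intact.
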