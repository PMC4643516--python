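# echotex

Ontology-driven extraction of attribute–value pairs from German
semi-structured echocardiography reports.

Clinical echocardiography findings are dictated as telegram-style German
noun phrases under object headers ("Mitralklappe: geringe Insuffizienz,
LVEF 60%"). `echotex` turns such reports into structured
`(attribute, value)` pairs with exact character offsets. All domain
knowledge lives in a declarative *terminology* — a containment tree of
structures, objects, attributes and values with surface variants — so the
engine itself is generic: adapting it to new report content means editing a
YAML file, not code.

## What it does

- **Terminology model** (`echotex.terminology`): concepts with standard and
  regexp variants, shared dictionaries, graded value templates with composed
  ids (`mv-insuff:1` = "moderate mitral regurgitation"), object–attribute
  compounds ("Mitralklappeninsuffizienz"), attribute–value measurement
  compounds ("LVEF 60%"), negation activator values, validation, YAML/JSON
  round-trip, and compilation into a token-trie + regexp matcher.
- **Segmentation** (`echotex.segmentation`): masking of out-of-domain (TEE)
  sections, subsection detection from object headers, segment splitting with
  enumeration handling ("an A, B und C" stays whole; "Septum 9mm,
  Hinterwand 9mm" splits), prepositional-phrase scoping ("bei Tachykardie")
  and layout statistics.
- **Extraction** (`echotex.extraction`): leftmost-longest concept matching,
  object-context disambiguation of ambiguous attributes, attribute–value
  pairing under phrase constraints, implicit presence for boolean findings,
  and negation-driven suppression.
- **Aggregation** (`echotex.aggregation`): per-context frequency tables of
  digit-normalized phrases plus candidate-term proposal, for bootstrapping a
  terminology from a report archive.
- **Evaluation** (`echotex.evaluation`): exact-offset matching against
  reference annotations, the fn-covered/fn-missing split, micro/macro
  precision–recall–F1 with half-up rounding, inter-annotator agreement and
  document categorization. `echotex.datasets` bundles the aggregate counts
  of a published clinical evaluation as worked examples.
- **Synthetic corpus** (`echotex.synthetic`): a seeded generator that emits
  report-shaped documents *together with* the exact gold annotations implied
  by their construction — an oracle for end-to-end testing without clinical
  data.

## Worked example

```python
from echotex import Document, extract_document
from echotex.synthetic import build_fixture_terminology

t = build_fixture_terminology()
report = ("Aortenklappeninsuffizienz I.\n"
          "Mitralklappe: keine Insuffizienz, mittelgradige Stenose.\n")
for p in extract_document(Document(id="r1", text=report), t).pairs:
    print(p.attribute_id, p.value_id, (p.begin, p.end), "implicit" if p.implicit else "")
```

prints

```
av-insuff av-insuff-p (0, 25) implicit
av-insuff av-insuff:0 (0, 27)
mv-insuff mv-insuff-a (43, 61)
12 12:1 (63, 84)
12 12-p (77, 84) implicit
```

Reading: the compound "Aortenklappeninsuffizienz" resolves to the aortic
valve and grade I binds as the composed value `av-insuff:0`; under the
mitral-valve header, "keine Insuffizienz" yields the absence value and
*suppresses* the implicit presence, while "mittelgradige Stenose" keeps both
its grade (`12:1`) and its presence (`12-p`).

## Command line

```bash
echotex synth --seed 11 -o corpus/          # seeded corpus + gold + terminology
echotex validate -t corpus/terminology.yaml
echotex extract  -t corpus/terminology.yaml -i corpus/ -o pred.jsonl
echotex evaluate --pred pred.jsonl --gold corpus/gold.tsv -o report.json
echotex evaluate --counts counts.json -o report.json   # metric arithmetic only
echotex aggregate -t corpus/terminology.yaml -i corpus/ -o agg/
echotex categorize -i corpus/
```

All subcommands are byte-idempotent given identical inputs and seed.

## Repository layout

```
src/echotex/        library (terminology, segmentation, extraction,
                    aggregation, evaluation, synthetic, datasets, cli)
tests/              unit, property-based and acceptance tests
examples/           narrative scripts (terminology tour, extraction,
                    bootstrapping, evaluation, published metrics)
scripts/            acceptance.py
docs/               methods note + terminology schema
```
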