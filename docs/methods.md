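# Methods

This note documents the model implemented by `echotex`, the parameters it
exposes, and the reasoning behind the design decisions that were open to
choice. The package targets ontology-driven information extraction from
German transthoracic echocardiography (TTE) reports: semi-structured,
telegram-style clinical text whose findings are attribute–value pairs
anchored to cardiac objects.

## 1. Terminology model

A terminology is a containment forest over five concept types:
`structure > object > (object_)attribute > value`. Containment encodes
"part-of/aspect-of" knowledge: values belong to attributes, attributes to
objects. Matching-relevant content:

- **Variants.** `std` variants match case-insensitively (NFC + casefold) at
  token boundaries; `regexp` variants match as written (Python `re`).
  Tokens are word-character runs or single punctuation marks, so "Grad I"
  and "I°" both tokenize predictably.
- **Dictionaries** share variant lists across concepts. All four valves
  reference `d-insuff` ("Insuffizienz", "Insuff"), which is what makes the
  bare keyword ambiguous and forces context resolution.
- **Templates** share graded value sets. A matched template value is bound
  to a concrete attribute only at pairing time; its value id is composed as
  `<attribute>:<local>` (e.g. `12:1` = moderate mitral stenosis). Concept
  ids therefore must not contain `:`.
- **Compounds.** An `oa` variant ("Mitralklappeninsuffizienz") is an
  attribute mention that lexically contains its object; it carries an
  `implied_object` that overrides all other context. An `av` variant (a
  measurement regexp such as `LVEF\s*:?\s*\d+...%`) carries an
  `implied_value`, pairing intrinsically.
- **Boolean nature and suppression.** A `boolean_nature` attribute states a
  finding that is present when mentioned; `implicit_value` names the
  presence value emitted without explicit evidence. Values have a
  `suppress` flag: `True` (default) marks passive values; `False` marks
  activators — typically negations ("keine Insuffizienz") — which remove
  the passive presence value *of the same attribute instance*.

*Design decision — implicit presence always.* The implicit presence value
is emitted for every resolved boolean-attribute mention, not only for bare
mentions. A graded finding ("mittelgradige Stenose") therefore yields both
the grade and the presence pair. This makes presence queries uniform
("is stenosis present?" never requires knowing which grade values exist)
and negation is still handled correctly because the activator suppresses
the presence pair per instance.

*Design decision — per-instance suppression.* A negation binds the nearest
attribute mention only. In "Insuffizienz … Insuffizienz keine" the second
instance is suppressed, the first keeps its presence. Scope-wide
suppression was rejected because clinical segments routinely contrast
("keine Insuffizienz, mittelgradige Stenose").

## 2. Pipeline

Per document: (1) mask out-of-domain sections, (2) detect subsections,
(3) split segments, (4) detect prepositional phrases, (5) match concepts,
(6) resolve object contexts, (7) pair attributes with values,
(8) postprocess.

- **Masking.** Lines matching an ignore pattern (default: `^\s*TEE\b`)
  open a masked span running to the next subsection header or end of text.
  TTE reports embed transesophageal passages that would otherwise produce
  spurious, modality-wrong findings.
- **Subsections.** A header is a line-initial label followed by `:`
  (optionally a list-element `- AK: …`). Labels matching an *object*
  variant set that object as the subsection's context; labels matching an
  attribute or value ("LVEF: 60%") are findings, not headers, and unknown
  labels open context-free subsections. Text before the first header is a
  HEADERLESS subsection. Masked spans plus subsections partition the text.
- **Segments.** Newlines and sentence punctuation split always. Commas
  split unless (a) the comma sits between digits (decimal comma, "1,1"),
  or (b) the clause is a shared-head enumeration — a later "und/oder"
  with short (≤ 4 tokens), digit-free items ("an A, B und C"), which must
  stay whole because the items share one finding. "und" itself splits only
  when both conjuncts carry parenthesized measurements, the pattern of
  coordinated object descriptions ("Normal großer LV (LVDd 48 mm) und
  dilatierter LA (LA 44 mm)").
- **Prepositional phrases.** A preposition (default: bei, nach, vor,
  unter, mit, trotz) opens a phrase consumed greedily until a verb-like
  token, stopword or comma. The phrase is an island: an attribute inside
  it cannot take a value outside it. This keeps "Diastolische Funktion bei
  Tachykardie nicht sicher beurteilbar" from attaching the outer value to
  the embedded finding.
- **Matching.** Per layer (object/attribute/value), leftmost-longest
  non-overlapping selection; layers may overlap each other (an `av`
  measurement covers the bare attribute keyword it subsumes). Ambiguous
  hits keep all candidate senses until resolution.
- **Object resolution** for ambiguous attributes, in order: the compound's
  implied object; the nearest object mention in the same segment
  (preceding preferred over following); the subsection's context object.
  The search never leaves the subsection. Unresolved attributes are
  dropped and logged — precision over recall, because emitting a guessed
  valve would fabricate clinical content.
- **Pairing.** Explicit values attach to the nearest admissible attribute
  (token distance; ties prefer the preceding attribute), where
  admissibility means the value is a local child or an import of the
  attribute's template. Each value binds at most one attribute.
- **Postprocessing.** Implicit presence pairs; activator-driven
  suppression; collapse of duplicate `(attribute, value)` pairs within one
  segment (dictation redundancy).

## 3. Evaluation

Predictions match reference annotations one-to-one on the exact key
`(attribute_id, value_id, begin, end)`; a pair's region is the min/max over
its attribute and value spans (the attribute span alone for implicit
pairs). False negatives split into `fn_covered` (concept exists in the
terminology — an engine miss) and `fn_missing` (concept absent — a
coverage gap); recall uses their sum, so terminology gaps hurt recall but
never precision.

Precision `tp/(tp+fp)`, recall `tp/(tp+fn)`, F1 `2pr/(p+r)`. Zero
denominators make a component undefined (`None`), excluded from macro
means — preferable to conventional 0.0 or 1.0 fill-ins, which distort
macro averages over sparse aspects. Micro averages pool counts; macro
averages take arithmetic means of defined components. Reported values are
rounded half-up via `decimal` (banker's rounding would mis-reproduce
printed clinical tables).

Inter-annotator agreement is `|matched| / |union|` of the two annotation
sets (1.0 when both are empty): a symmetric accuracy that punishes both
omissions and additions with one denominator.

Document categories mirror typical corpus filters, with precedence:
`excluded_site` → `defective` (< 100 non-whitespace characters) →
`uncommon` (≥ 5 list elements, a layout using one line per finding) →
`dominant` (≥ 800 characters) → `unstructured` (everything between).

`echotex.datasets` bundles the aggregate tp/fp/fn counts of a published
clinical evaluation of such a system (the corpus and full terminology are
private hospital data). They serve as exact worked examples: dominant
documents 5332/23/214 → 0.996/0.961/0.978; short unstructured notes
126/11/99 → 0.920/0.560/0.696; the 29 report aspects sum to 2872/20/41 →
micro 0.993/0.986/0.989, macro 0.991/0.950/0.963.

## 4. Synthetic corpus generator

The generator is the package's oracle: every statement builder computes,
by hand, the exact annotations a reference annotator following the span
conventions above would produce — gold is *never* obtained by running the
engine on the generated text, which would make the test circular.

Layouts: `A` and `B` are header-structured dominant-layout variants
(≥ 800 non-space characters), `C` is a list-element layout (`- AK: …`,
≥ 6 lines), `unstructured` is a short free-text note (100–799 characters,
no headers). Default mixture {A: .472, B: .472, C: .016, unstructured:
.040} keeps rare layouts present in moderate corpora without dominating.
Statement knobs: `negation_rate` 0.3, `enumeration_rate` 0.2,
`oa_compound_rate` 0.3, `unknown_phrase_rate` 0.0. The seed is mandatory;
all draws come from one `random.Random(seed)`, making corpora
byte-identical across runs.

Unknown phrases come from a fixed pool of administrative/filler sentences
checked at generator construction to produce *zero* matcher hits; they
enter gold only as `missing_concept` annotations. Consequences, used as
acceptance properties: a clean corpus must score micro precision = recall
= 1.0, and raising `unknown_phrase_rate` must drop recall strictly below
1.0 while precision stays exactly 1.0.

The generator aims at structural realism only (headers, enumerations,
compounds, negations, measurements, decimal commas, TEE blocks); it makes
no claim of clinical plausibility, German morphology generation, or
coverage beyond its fixture inventory. Problem sizes in tests (50-document
oracle corpora, 100-document category runs, 200 matcher-oracle strings)
are the package's own choices: large enough to exercise every layout and
statement type under the default mixture, small enough for a
seconds-scale test suite.

## 5. Numerical and implementation choices

- Offsets are half-open `[begin, end)` character indices into the
  unmodified document text; no stage rewrites text, so spans survive the
  whole pipeline.
- Matching is a hand-written token trie over casefolded tokens plus a
  compiled regexp bank. A trie (rather than one alternation regexp) keeps
  compilation linear in terminology size and makes the naive per-variant
  scan a meaningful independent test oracle.
- Rounding uses `decimal.Decimal` with `ROUND_HALF_UP` on `repr(float)`;
  metric values themselves stay unrounded floats until presentation.
- Determinism throughout: no global random state, sorted iteration
  orders, and byte-idempotent CLI artifacts.
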