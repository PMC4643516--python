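"""Bootstrap terminology content from an aggregated corpus.

Hospital reports repeat a small inventory of phrases.  Aggregating all
segments per subsection context into normalized frequency tables gives a
domain expert a few hundred lines to review instead of thousands of
reports; candidate attribute terms are proposed from the unknown phrases.
"""

from echotex import GeneratorConfig, build_aggregates, generate_corpus, propose_candidates
from echotex.synthetic import build_fixture_terminology

t = build_fixture_terminology()

# A seeded synthetic corpus stands in for the hospital archive; half of the
# documents contain phrases the terminology does not know yet.
corpus = generate_corpus(
    GeneratorConfig(n_documents=40, seed=5, unknown_phrase_rate=0.5), t
)

aggregates = build_aggregates(corpus.documents, t=t)

print("aggregated contexts (top 3 phrases each):")
for label, ctx in sorted(aggregates.items()):
    print(f"\n[{label}]  ({ctx.total} segments, {len(ctx.counts)} distinct)")
    for phrase, n in ctx.entries[:3]:
        print(f"  {phrase} (({n}))")

# Candidate terms: capitalized n-grams that are frequent but unknown.
# The expert reviews these, extends the terminology, and re-aggregates —
# the refinement loop converges once no productive candidates remain.
candidates = propose_candidates(aggregates, min_freq=2, terminology=t)
print(f"\n{len(candidates)} candidate terms (frequency >= 2):")
for c in candidates[:10]:
    print(f"  {c.frequency:>3}x  {c.term}  (seen in: {', '.join(c.contexts)})")
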