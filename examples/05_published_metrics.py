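"""Recompute published clinical evaluation metrics from their counts.

The package bundles the aggregate tp/fp/fn counts of a published clinical
evaluation of an ontology-driven echocardiography extraction system (the
underlying corpus and full terminology are private hospital data).  Every
printed precision/recall/F1 is reproducible exactly from the counts with
this package's metric arithmetic — a worked example for the evaluation
module and a regression anchor for its rounding rules.
"""

from echotex import compute_metrics, macro_average, micro_average
from echotex.datasets import aspect_counts, category_counts


def fmt(m, nd=3):
    r = m.rounded(nd)
    return f"precision={r.precision} recall={r.recall} f1={r.f1}"


print("document categories:")
for label, c in category_counts().items():
    print(f"  {label:<13} tp={c.tp:<5} fp={c.fp:<3} fn={c.fn:<4} {fmt(compute_metrics(c))}")

aspects = aspect_counts()
print(f"\n29 report aspects (dominant-layout test documents):")
for label, c in sorted(aspects.items(), key=lambda kv: -kv[1].tp)[:5]:
    print(f"  {label:<22} tp={c.tp:<4} {fmt(compute_metrics(c))}")
print("  ...")

print(f"\n  micro: {fmt(micro_average(list(aspects.values())))}")
print(f"  macro: {fmt(macro_average([compute_metrics(c) for c in aspects.values()]))}")

# A sparse row shows the zero-denominator conventions: with tp=1, fp=0,
# fn=2 the metrics are perfectly defined but fragile.
m = compute_metrics(aspects["MV Stenosis"])
print(f"\n  MV Stenosis: {fmt(m, nd=2)}")
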