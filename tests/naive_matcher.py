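"""Reference implementation of variant matching used as a test oracle.

Tries every variant at every token position independently — no trie, no
shared scan — and reports every occurrence as (begin, end, layer, pattern).
The compiled matcher must agree exactly on arbitrary input.
"""

import re

from echotex.terminology import Terminology, fold, tokenize

_LAYER_OF_CTYPE = {
    "object": "object",
    "object_attribute": "attribute",
    "attribute": "attribute",
    "value": "value",
}


def _entries(t: Terminology):
    """(pattern, vtype, layer) for every matchable variant, with dictionary
    references expanded, in both concept and template scope."""
    out = []
    for c in t:
        if c.ctype == "structure":
            continue
        layer = _LAYER_OF_CTYPE[c.ctype]
        for v in t.concept_variants(c.id):
            out.append((v.pattern, v.vtype, layer))
    for tmpl in t.templates.values():
        for tv in tmpl.values:
            for v in tv.variants:
                out.append((v.pattern, v.vtype, "value"))
    return out


def naive_find(t: Terminology, text: str) -> set[tuple[int, int, str, str]]:
    toks = tokenize(text)
    folded = [fold(tok) for tok, _, _ in toks]
    found: set[tuple[int, int, str, str]] = set()
    for pattern, vtype, layer in _entries(t):
        if vtype == "regexp":
            for m in re.finditer(pattern, text):
                if m.start() != m.end():
                    found.add((m.start(), m.end(), layer, pattern))
            continue
        want = [tok for tok, _, _ in tokenize(fold(pattern))]
        if not want:
            continue
        n = len(want)
        for i in range(len(toks) - n + 1):
            if folded[i:i + n] == want:
                found.add((toks[i][1], toks[i + n - 1][2], layer, pattern))
    return found


def compiled_find_keys(matcher, text: str) -> set[tuple[int, int, str, str]]:
    return {(h.begin, h.end, h.layer, h.pattern) for h in matcher.find(text)}
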