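"""Bundled count tables from a published clinical evaluation of an
ontology-driven echocardiography extraction system.

The corpus and terminology behind these numbers are private hospital data;
only the aggregate counts were published.  They serve as worked examples for
the metric suite: every precision/recall/F1 reported alongside them can be
recomputed exactly from the tp/fp/fn counts with
:func:`echotex.evaluation.compute_metrics`, :func:`micro_average` and
:func:`macro_average`.
"""

from __future__ import annotations

from .evaluation import EvalCounts

#: document-category results: category -> (tp, fp, fn)
#: "dominant" covers the two predominant semi-structured layouts (100 test
#: documents); "unstructured" the short free-text reports (20 documents).
CORPUS_CATEGORY_COUNTS: dict[str, tuple[int, int, int]] = {
    "dominant": (5332, 23, 214),
    "unstructured": (126, 11, 99),
}

#: per-aspect results over the 29 central aspects of a standardized German
#: echocardiography report guideline, measured on the 100 dominant-layout
#: test documents: aspect -> (tp, fp, fn)
ASPECT_COUNTS: dict[str, tuple[int, int, int]] = {
    "Prosthetic Valves (type)": (16, 0, 3),
    "Imaging Quality": (263, 0, 3),
    "No Regurgitation": (8, 0, 0),
    "AV Morphology": (74, 0, 15),
    "V_max": (84, 0, 0),
    "AV Regurgitation": (136, 1, 0),
    "AV Prosthesis Regurgitation": (8, 0, 0),
    "AV Stenosis": (48, 0, 1),
    "AV Area": (15, 2, 0),
    "ΔP_max (pressure gradient)": (23, 2, 0),
    "Aortic Root Diameter": (186, 0, 0),
    "MV Morphology": (3, 0, 0),
    "MV Regurgitation": (229, 6, 1),
    "MV Prosthesis (Pmean, PHT)": (4, 0, 2),
    "MV Stenosis": (1, 0, 2),
    "MV Area": (2, 0, 0),
    "TV Morphology": (67, 0, 0),
    "TV Regurgitation": (259, 2, 0),
    "sPAP": (178, 0, 0),
    "LVD_d": (15, 0, 0),
    "LVD_s": (67, 0, 0),
    "IVSD_d": (97, 0, 0),
    "PWD_d": (96, 0, 1),
    "LVEF (%)": (221, 0, 0),
    "Wall Motion Abnormalities": (51, 0, 1),
    "Diastolic Function": (350, 2, 6),
    "LAD (LADs, LADsI)": (88, 0, 0),
    "RV Dimension": (101, 0, 1),
    "Pericardial Effusion": (182, 5, 5),
}


def category_counts() -> dict[str, EvalCounts]:
    return {
        k: EvalCounts(tp=tp, fp=fp, fn_covered=fn)
        for k, (tp, fp, fn) in CORPUS_CATEGORY_COUNTS.items()
    }


def aspect_counts() -> dict[str, EvalCounts]:
    return {
        k: EvalCounts(tp=tp, fp=fp, fn_covered=fn)
        for k, (tp, fp, fn) in ASPECT_COUNTS.items()
    }
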