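"""TNM-based slide labelling rules for lymph-node metastases.

A slide's label derives from the diameter of its largest tumor deposit:
deposits ≤ 0.2 mm are isolated tumor cells (ITC, node-negative under
TNM), deposits > 0.2 mm and ≤ 2 mm are micro-metastases, and deposits
> 2 mm are macro-metastases.  Micro and macro are slide-positive.
"""

from __future__ import annotations

#: Largest deposit diameter (mm) still classified as isolated tumor cells.
ITC_MAX_MM: float = 0.2

#: Largest deposit diameter (mm) still classified as micro-metastasis.
MICRO_MAX_MM: float = 2.0

LABEL_NEGATIVE = "negative"
LABEL_MICRO = "micro"
LABEL_MACRO = "macro"
LABEL_ITC_ONLY = "itc_only"

#: Labels that count as slide-positive.
POSITIVE_LABELS = frozenset({LABEL_MICRO, LABEL_MACRO})


def tnm_slide_label(largest_diameter_mm: float | None) -> str:
    """Slide label from the largest tumor deposit's diameter.

    ``None`` (no deposit) and diameters ≤ 0.2 mm map to ``negative``;
    the distinct ``itc_only`` ground-truth label is assigned upstream,
    where it is known that deposits exist but all are ITC-sized.
    """
    if largest_diameter_mm is None:
        return LABEL_NEGATIVE
    if largest_diameter_mm < 0:
        raise ValueError(f"negative diameter: {largest_diameter_mm}")
    if largest_diameter_mm > MICRO_MAX_MM:
        return LABEL_MACRO
    if largest_diameter_mm > ITC_MAX_MM:
        return LABEL_MICRO
    return LABEL_NEGATIVE


def gt_label_from_diameters(diameters_mm) -> str:
    """Ground-truth label for a slide carrying the given planted deposits.

    Unlike :func:`tnm_slide_label`, a slide whose deposits are all
    ITC-sized is labelled ``itc_only`` (it carries tumor cells, but is
    node-negative under TNM and excluded from the study).
    """
    diameters = list(diameters_mm)
    if not diameters:
        return LABEL_NEGATIVE
    label = tnm_slide_label(max(diameters))
    if label == LABEL_NEGATIVE:
        return LABEL_ITC_ONLY
    return label
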