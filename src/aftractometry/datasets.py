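"""Bundled example data: a published nine-patient glioma cohort summary.

Tumor volumes (cm^3) of four low-grade (DNT / WHO grade II) and five
high-grade (WHO grade III–IV) tumors in language-eloquent regions, plus
the twelve unadjusted Mann-Whitney p-values of the low- vs. high-grade
comparison over tumor volume, eight along-tract DTI summary measures
and three fMRI laterality indices.  These numbers serve as worked
examples for the exact Mann-Whitney test and the Benjamini–Hochberg
adjustment on a realistically tiny neurosurgical cohort.
"""

from __future__ import annotations

__all__ = ["TUMOR_VOLUMES_CM3", "GROUP_COMPARISON_MEASURES", "GROUP_COMPARISON_PVALUES"]

TUMOR_VOLUMES_CM3: dict[str, list[float]] = {
    "LG": [4.2, 22.8, 122.0, 43.0],
    "HG": [26.4, 17.5, 13.1, 57.9, 115.7],
}

#: measure order of the low- vs. high-grade comparison table
GROUP_COMPARISON_MEASURES: list[str] = [
    "Tumor volume",
    "FA # decreased segments",
    "Median FA",
    "AD # decreased segments",
    "Median AD",
    "MD # increased segments",
    "Median MD",
    "RD # increased segments",
    "Median RD",
    "LI fMRI frontal",
    "LI fMRI parietal",
    "LI fMRI temporal",
]

#: unadjusted two-sided Mann-Whitney p-values, same order as the measures
GROUP_COMPARISON_PVALUES: list[float] = [
    1.0, 0.047, 0.142, 0.306, 0.027, 0.017, 0.014, 0.012, 0.086, 0.221, 0.142, 0.806,
]
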