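"""Published gene-catalog summary counts for the Solanaceae annotation
releases this tool targets, and the arithmetic on them.

The counts are the per-crop totals of annotated genes and of genes that
fell into a cross-crop homolog group at the 95% identity cutoff, as
reported for the public releases named in ``release``. They serve as a
desk-scale consistency check (the homologous fraction each crop's numbers
imply) without re-downloading the multi-gigabase gene sets.
"""

from __future__ import annotations

ANNOTATION_SUMMARY: dict[str, dict] = {
    "tomato": {"genes": 34_727, "homologous": 22_831, "release": "ITAG 2.3"},
    "pepper": {"genes": 34_915, "homologous": 18_554, "release": "Pepper v1.55"},
    "potato": {"genes": 39_028, "homologous": 34_369, "release": "DM v4.3"},
    "arabidopsis": {"genes": 35_386, "homologous": 12_715, "release": "TAIR 10"},
}

#: total cross-crop homolog groups reported for the four releases combined
TOTAL_HOMOLOG_GROUPS = 17_635


def homolog_percentage(crop: str) -> float:
    """Homologous genes as a percentage of annotated genes for one crop."""
    entry = ANNOTATION_SUMMARY[crop]
    return 100.0 * entry["homologous"] / entry["genes"]
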