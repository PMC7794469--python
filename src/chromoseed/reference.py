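"""Reference statistics from the published Drosophila Hi-C datasets.

Genome-wide totals of specific vs. all nonzero Hi-C contact pairs
reported for the three cell types (embryos at pre-MBT nuclear cycles
9-13 and post-MBT stages 5-8 from GSE103625; S2R+ cells from GSE101317,
dm3 assembly). These summarize full-genome runs of the pipeline on the
deep sequencing data and serve as documented reference points; the
percentages are recomputed from the pair counts, not stored.
"""

from __future__ import annotations

#: (specific pairs, total nonzero Hi-C pairs), genome-wide
REPORTED_PAIR_COUNTS: dict[str, tuple[float, float]] = {
    "pre-mbt": (2.28e6, 42.39e6),
    "post-mbt": (2.03e6, 40.07e6),
    "s2r+": (2.20e6, 34.98e6),
}


def specific_interaction_pct(cell: str) -> float:
    """Percentage of Hi-C contact pairs called specific for a cell type."""
    spec, total = REPORTED_PAIR_COUNTS[cell]
    return 100.0 * spec / total
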