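"""Accumulate chromatin-mark peak intensities into TSS-proximal regions.

A gene's TSS-proximal region is the symmetric window [TSS − flank,
TSS + flank], inclusive at both ends and clipped at zero; the default flank
is 2 kb. A peak is assigned by its midpoint, floor((start + end) / 2) for a
0-based half-open interval: every gene whose window (union over the gene's
TSS rows) contains the midpoint receives the peak's score, added once.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import PeakSet, TSSTable

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 2000


def tss_region(pos: int, flank: int = DEFAULT_FLANK) -> tuple[int, int]:
    """Closed interval [pos - flank, pos + flank], clipped at 0.

    Strand does not affect the window (it is symmetric).
    """
    return (max(0, pos - flank), pos + flank)


def _window_trees(tss: TSSTable, flank: int) -> dict[str, IntervalTree]:
    """One interval tree per chromosome; data = gene id.

    Our windows are inclusive at both ends while IntervalTree is half-open,
    hence the +1 on the upper bound.
    """
    trees: dict[str, IntervalTree] = {}
    for row in tss.table.itertuples(index=False):
        lo, hi = tss_region(int(row.pos), flank)
        trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi + 1, row.gene)
    return trees


def map_peaks(peaks: PeakSet, tss: TSSTable, flank: int = DEFAULT_FLANK) -> pd.Series:
    """Accumulated intensity per gene for one mark.

    Every gene of the TSS table gets a row (zero when nothing maps). A gene
    with multiple TSS rows counts a midpoint once even if it falls in
    several of its windows. Peaks on chromosomes absent from the TSS table
    are ignored with a log entry.
    """
    trees = _window_trees(tss, flank)
    intensity: dict[str, float] = {g: 0.0 for g in tss.genes}
    skipped_chroms: set[str] = set()
    mids = peaks.midpoints()
    for (chrom, score), mid in zip(
        peaks.table[["chrom", "score"]].itertuples(index=False), mids
    ):
        tree = trees.get(chrom)
        if tree is None:
            skipped_chroms.add(chrom)
            continue
        hit_genes = {iv.data for iv in tree.at(int(mid))}
        for g in hit_genes:
            intensity[g] += float(score)
    if skipped_chroms:
        logger.info(
            "map_peaks: ignored peaks on chromosomes absent from TSS table: %s",
            sorted(skipped_chroms),
        )
    return pd.Series(intensity, name="intensity").sort_index()


def build_chromatin_matrix(
    peaks_by_mark: dict[str, PeakSet], tss: TSSTable, flank: int = DEFAULT_FLANK
) -> pd.DataFrame:
    """Gene x mark matrix of accumulated intensities (zeros allowed)."""
    cols = {mark: map_peaks(ps, tss, flank) for mark, ps in peaks_by_mark.items()}
    mat = pd.DataFrame(cols)
    assert np.isfinite(mat.to_numpy()).all()
    return mat
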