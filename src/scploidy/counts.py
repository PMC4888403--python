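"""Read filtering, per-bin counting and GC correction.

Reads are kept when they are not duplicates and map with MAPQ > 10 (the
``mapq_min = 11`` default), then assigned to the unique bin whose half-open
interval contains the leftmost mapped position.  Counts are subsequently
corrected for the systematic dependence of read density on a bin's GC
fraction before entering the copy-number model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .bins import BinGrid

__all__ = ["ReadRecord", "BinnedCell", "count_reads", "gc_correct", "iter_sam_reads"]


class ReadRecord(NamedTuple):
    """A minimally described aligned read: position, quality, duplicate flag."""

    chrom: str
    pos: int  # 0-based leftmost mapped position
    mapq: int
    is_duplicate: bool = False


@dataclass
class BinnedCell:
    """One cell's per-bin read counts plus library metadata."""

    cell_id: str
    counts: np.ndarray
    corrected: np.ndarray | None = None
    sample: str = ""
    cohort: str = ""
    sex: str = "unknown"
    reads_sequenced: int = 0
    reads_kept: int = 0
    reads_dropped: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def observable(self) -> np.ndarray:
        """The vector the copy-number model consumes: corrected if present."""
        return self.corrected if self.corrected is not None else self.counts


def count_reads(
    reads: Iterable[ReadRecord],
    grid: BinGrid,
    mapq_min: int = 11,
    drop_duplicates: bool = True,
    cell_id: str = "cell",
) -> BinnedCell:
    """Filter reads and count the survivors per bin.

    A read is kept when ``mapq >= mapq_min`` and (if ``drop_duplicates``)
    it is not flagged as a duplicate; kept reads falling outside every bin
    — including reads on chromosomes absent from the grid — are tallied in
    ``reads_dropped``.  ``reads_kept`` always equals ``sum(counts)``.
    """
    slices = grid.chrom_slices()
    starts = {c: grid.df["start"].to_numpy()[s] for c, s in slices.items()}
    ends = {c: grid.df["end"].to_numpy()[s] for c, s in slices.items()}

    counts = np.zeros(grid.n_bins, dtype=np.int64)
    n_seen = 0
    n_dropped = 0
    for read in reads:
        n_seen += 1
        if read.mapq < mapq_min or (drop_duplicates and read.is_duplicate):
            continue
        sl = slices.get(read.chrom)
        if sl is None:
            n_dropped += 1
            continue
        s = starts[read.chrom]
        e = ends[read.chrom]
        j = int(np.searchsorted(s, read.pos, side="right")) - 1
        if j < 0 or read.pos >= e[j]:
            n_dropped += 1
            continue
        counts[sl.start + j] += 1

    return BinnedCell(
        cell_id=cell_id,
        counts=counts,
        reads_sequenced=n_seen,
        reads_kept=int(counts.sum()),
        reads_dropped=n_dropped,
    )


def iter_sam_reads(path: str) -> Iterator[ReadRecord]:
    """Stream mapped reads from a SAM/BAM file as :class:`ReadRecord`.

    Uses the duplicate FLAG bit (0x400) and the MAPQ field; unmapped
    records are skipped.  Requires :mod:`pysam` (the ``sam`` extra).
    """
    import pysam  # deferred: alignment input is optional

    with pysam.AlignmentFile(path, check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped:
                continue
            yield ReadRecord(
                chrom=aln.reference_name,
                pos=aln.reference_start,
                mapq=aln.mapping_quality,
                is_duplicate=aln.is_duplicate,
            )


def _gc_trend_lowess(counts: np.ndarray, gc: np.ndarray, span: float) -> np.ndarray:
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(counts, gc, frac=span, return_sorted=False)
    return np.asarray(fitted, dtype=float)


def _gc_trend_decile(counts: np.ndarray, gc: np.ndarray) -> np.ndarray:
    # decile-median ratio: robust trend estimate for small grids
    n_groups = min(10, max(2, len(gc) // 10))
    qs = np.quantile(gc, np.linspace(0, 1, n_groups + 1))
    qs[0] -= 1e-9
    groups = np.clip(np.searchsorted(qs, gc, side="right") - 1, 0, n_groups - 1)
    fitted = np.empty_like(counts, dtype=float)
    for g in range(n_groups):
        mask = groups == g
        if mask.any():
            fitted[mask] = np.median(counts[mask])
    return fitted


def gc_correct(cell: BinnedCell, grid: BinGrid, span: float = 0.3) -> BinnedCell:
    """Divide counts by the fitted count-vs-GC trend, normalised to mean 1.

    The trend is a lowess fit of counts on GC fraction (span 0.3), with a
    decile-median fallback below 200 bins.  Corrected values are rescaled
    so total corrected mass equals total raw mass exactly; zeros stay
    zeros, so the nullisomy state of the caller is preserved.
    """
    if cell.n_bins != grid.n_bins:
        raise ValueError("cell count vector does not match grid")
    if cell.n_bins < 20:
        raise ValueError("GC correction needs at least 20 bins")
    counts = cell.counts.astype(float)
    total = counts.sum()
    if total == 0:
        out = replace(cell, corrected=np.zeros_like(counts))
        out.flags = cell.flags + ["all_zero"]
        return out

    gc = grid.gc
    if cell.n_bins >= 200:
        fitted = _gc_trend_lowess(counts, gc, span)
    else:
        fitted = _gc_trend_decile(counts, gc)
    fitted = np.maximum(fitted, 1e-12)
    factor = fitted / fitted.mean()
    factor = np.maximum(factor, 0.05)  # cap the boost for GC-starved bins
    corrected = counts / factor
    corrected *= total / corrected.sum()
    out = replace(cell, corrected=corrected)
    out.flags = list(cell.flags)
    return out
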