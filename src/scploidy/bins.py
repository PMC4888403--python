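"""Genomic bin grids with variable widths driven by mappability.

Shallow single-cell WGS libraries are analysed on a fixed genome-wide grid
of non-overlapping bins.  Bin widths vary inversely with local mappability
so that every bin holds the same expected number of uniquely mappable
positions; with a 1 Mb mean width each bin then collects a comparable
expected read count from a diploid genome, which is what makes per-bin
counts usable as copy-number observables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GRCH37_CHROM_LENGTHS",
    "GenomeTrack",
    "BinGrid",
    "build_variable_bins",
]

# GRCh37 primary-assembly chromosome lengths (bp).
GRCH37_CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

_BIN_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "bin_id"]


@dataclass
class GenomeTrack:
    """Windowed per-chromosome mappability (and optional GC) values.

    Each chromosome is described by a fixed ``window_size`` and one value
    per window; the final window may be truncated at the chromosome end.
    """

    window_size: int
    lengths: Mapping[str, int]
    mappability: Mapping[str, np.ndarray]
    gc: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for chrom, length in self.lengths.items():
            if chrom not in self.mappability:
                raise ValueError(f"chromosome {chrom!r} absent from mappability track")
            n_windows = -(-length // self.window_size)
            m = np.asarray(self.mappability[chrom], dtype=float)
            if len(m) != n_windows:
                raise ValueError(
                    f"chromosome {chrom!r}: expected {n_windows} windows, got {len(m)}"
                )
            if np.any(m <= 0) or np.any(m > 1):
                raise ValueError(f"chromosome {chrom!r}: mappability must be in (0, 1]")

    @classmethod
    def flat(
        cls,
        lengths: Mapping[str, int],
        window_size: int = 10_000,
        mappability: float = 1.0,
        gc: float = 0.41,
    ) -> "GenomeTrack":
        mapp = {}
        gcs = {}
        for chrom, length in lengths.items():
            n = -(-length // window_size)
            mapp[chrom] = np.full(n, mappability)
            gcs[chrom] = np.full(n, gc)
        return cls(window_size=window_size, lengths=dict(lengths), mappability=mapp, gc=gcs)


class BinGrid:
    """Ordered, non-overlapping genomic bins annotated with GC and mappability.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``chrom, start, end, gc, mappability, bin_id`` (0-based half-open
    coordinates).  Validated on construction: bins are sorted within each
    chromosome, never overlap, and chromosomes are contiguous blocks.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in _BIN_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"bin table missing columns: {missing}")
        df = df[_BIN_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad = df.index[df["end"] <= df["start"]]
        if len(bad):
            raise ValueError(f"bins with end <= start at rows {list(bad[:5])}")
        if df["gc"].min() < 0 or df["gc"].max() > 1:
            raise ValueError("gc fractions must lie in [0, 1]")
        if df["mappability"].min() <= 0 or df["mappability"].max() > 1:
            raise ValueError("mappability must lie in (0, 1]")
        seen: set[str] = set()
        prev_chrom = None
        prev_end = -1
        for row in df.itertuples(index=True):
            if row.chrom != prev_chrom:
                if row.chrom in seen:
                    raise ValueError(
                        f"chromosome {row.chrom!r} appears in non-contiguous blocks (row {row.Index})"
                    )
                seen.add(row.chrom)
                prev_chrom = row.chrom
                prev_end = -1
            if row.start < prev_end:
                raise ValueError(
                    f"overlapping or unsorted bins on {row.chrom!r} at row {row.Index}"
                )
            prev_end = row.end

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    @property
    def widths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy()

    @property
    def mappability(self) -> np.ndarray:
        return self.df["mappability"].to_numpy()

    def chrom_bin_index(self) -> pd.Series:
        """Chromosome label per bin, aligned with count vectors."""
        return self.df["chrom"]

    def chrom_slices(self) -> dict[str, slice]:
        """Half-open bin-index ranges per chromosome, in grid order."""
        out: dict[str, slice] = {}
        chroms = self.df["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"BinGrid({self.n_bins} bins, {len(self.chromosomes)} chromosomes)"


def build_variable_bins(track: GenomeTrack, target_mean_width: int | float) -> BinGrid:
    """Tile the genome into bins of equal mappability mass.

    Each bin accumulates summed mappability equal to
    ``target_mean_width * genome-mean mappability``, so bin width is
    inversely proportional to local mappability and the genome-wide mean
    width equals ``target_mean_width``.  Bins never cross chromosome
    boundaries; a trailing remainder shorter than half a bin is merged
    into the previous bin.

    Parameters
    ----------
    track
        Windowed mappability (and optionally GC) values covering every
        chromosome.
    target_mean_width
        Desired mean bin width in base pairs.
    """
    if target_mean_width <= 0:
        raise ValueError("target_mean_width must be positive")

    w = track.window_size
    total_mass = 0.0
    total_len = 0
    for chrom, length in track.lengths.items():
        m = np.asarray(track.mappability[chrom], dtype=float)
        widths = np.full(len(m), w, dtype=float)
        widths[-1] = length - w * (len(m) - 1)
        total_mass += float(np.sum(m * widths))
        total_len += length
    mean_mapp = total_mass / total_len
    target_mass = float(target_mean_width) * mean_mapp

    rows: list[tuple] = []
    bin_idx = 0
    for chrom, length in track.lengths.items():
        m = np.asarray(track.mappability[chrom], dtype=float)
        g = (
            np.asarray(track.gc[chrom], dtype=float)
            if track.gc is not None
            else np.full(len(m), 0.41)
        )
        widths = np.full(len(m), w, dtype=float)
        widths[-1] = length - w * (len(m) - 1)

        # cumulative mappability mass at window ends; invert to bin cuts
        cum = np.concatenate([[0.0], np.cumsum(m * widths)])
        edges_bp = np.concatenate([[0.0], np.cumsum(widths)])
        chrom_mass = cum[-1]
        # equal-mass split: every bin on this chromosome carries exactly
        # chrom_mass / n_bins, so no trailing bin with excess mass exists
        n_bins = max(1, round(chrom_mass / target_mass))
        cut_mass = np.arange(1, n_bins) * chrom_mass / n_bins
        # interpolate mass -> bp within windows (mappability uniform per window)
        cut_bp = np.interp(cut_mass, cum, edges_bp)
        bounds = np.concatenate([[0.0], cut_bp, [float(length)]]).round().astype(np.int64)
        bounds = np.unique(bounds)

        for s, e in zip(bounds[:-1], bounds[1:]):
            # length-weighted window averages over [s, e)
            lo = np.clip(edges_bp[:-1], s, e)
            hi = np.clip(edges_bp[1:], s, e)
            ov = hi - lo
            span = ov.sum()
            gc_val = float(np.sum(g * ov) / span)
            mp_val = float(np.sum(m * ov) / span)
            rows.append((chrom, int(s), int(e), gc_val, mp_val, f"bin_{bin_idx}"))
            bin_idx += 1

    return BinGrid(pd.DataFrame(rows, columns=_BIN_COLUMNS))
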