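"""Synthetic single-cell libraries with programmed karyotypes.

The generator emulates shallow pre-amplification-free single-neuron
libraries: a few hundred thousand uniquely mapped reads per cell spread
over ~1 Mb variable-width bins, with negative-binomial overdispersion, a
smooth multiplicative GC bias, whole-chromosome copy-number changes
(euploid XX/XY, trisomy 21, sporadic monosomies/trisomies, up to ten
copies) and duplicate-read structure for library-complexity estimation.

The generative model is deliberately the same tied-moment negative
binomial the copy-number caller assumes: a haploid (monosomy) unit with
mean mu and variance mu * (1 + mu / dispersion); a chromosome at copy
number s contributes bins with mean s*mu and variance s*var.  Parameter
recovery by the caller is therefore well-posed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bins import GRCH37_CHROM_LENGTHS, BinGrid, GenomeTrack, build_variable_bins
from .counts import BinnedCell

__all__ = [
    "KaryotypeSpec",
    "SimulationConfig",
    "simulate_bin_grid",
    "simulate_grch37_grid",
    "simulate_cell",
    "simulate_cohort",
    "simulate_duplicate_library",
    "resolve_karyotype",
]

_MAX_CN = 10


@dataclass(frozen=True)
class KaryotypeSpec:
    """Programmed integer copy numbers per chromosome, 0 (nullisomy) to 10.

    Autosomes default to 2; sex chromosomes default by sex (XX -> X:2 Y:0,
    XY -> X:1 Y:1) and can be overridden explicitly.
    """

    sex: str = "XX"
    autosome_cn: Mapping[str, int] = field(default_factory=dict)
    x_cn: int | None = None
    y_cn: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be 'XX' or 'XY'")
        for chrom, cn in self.autosome_cn.items():
            if chrom in ("X", "Y"):
                raise ValueError("use x_cn / y_cn for sex chromosomes")
            if not 0 <= cn <= _MAX_CN:
                raise ValueError(f"copy number for {chrom} outside [0, {_MAX_CN}]")
        for cn in (self.x_cn, self.y_cn):
            if cn is not None and not 0 <= cn <= _MAX_CN:
                raise ValueError(f"sex-chromosome copy number outside [0, {_MAX_CN}]")

    def copy_number(self, chrom: str) -> int:
        if chrom == "X":
            return self.x_cn if self.x_cn is not None else (2 if self.sex == "XX" else 1)
        if chrom == "Y":
            return self.y_cn if self.y_cn is not None else (0 if self.sex == "XX" else 1)
        return int(self.autosome_cn.get(chrom, 2))

    @classmethod
    def euploid(cls, sex: str = "XX") -> "KaryotypeSpec":
        return cls(sex=sex)

    @classmethod
    def trisomy(cls, chrom: str, sex: str = "XX") -> "KaryotypeSpec":
        return cls(sex=sex, autosome_cn={chrom: 3})

    @classmethod
    def monosomy(cls, chrom: str, sex: str = "XX") -> "KaryotypeSpec":
        return cls(sex=sex, autosome_cn={chrom: 1})


def resolve_karyotype(label: str | KaryotypeSpec, sex: str = "XX") -> KaryotypeSpec:
    """Resolve a karyotype label like ``'euploid'`` or ``'trisomy_21'``.

    Recognised labels: ``euploid``, ``trisomy_<chrom>``, ``monosomy_<chrom>``.
    """
    if isinstance(label, KaryotypeSpec):
        return label
    if label == "euploid":
        return KaryotypeSpec.euploid(sex)
    m = re.fullmatch(r"(trisomy|monosomy)_([0-9]{1,2})", label)
    if m:
        kind, chrom = m.groups()
        return (
            KaryotypeSpec.trisomy(chrom, sex)
            if kind == "trisomy"
            else KaryotypeSpec.monosomy(chrom, sex)
        )
    raise ValueError(f"unknown karyotype label: {label!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Library-level simulation parameters.

    ``reads_per_cell_mean`` defaults to 333 000, the typical number of
    uniquely mapped reads retained per library after duplicate and MAPQ
    filtering in shallow single-neuron sequencing; total sequenced depth
    (used only for duplicate-library simulation) is around 2.5x that.
    ``dispersion`` is the negative-binomial size parameter of the
    haploid unit: variance = mu * (1 + mu / dispersion).  For unit means
    well above the dispersion, whole-chromosome detectability scales as
    ~0.5 * sqrt(dispersion * bins_per_chromosome / 3) independent of
    depth; the default of 100 gives the desk-scale genome (shortest
    chromosome ~10 bins) the same per-chromosome separation a full-scale
    ~3000-bin grid has at dispersion ~20.
    """

    n_cells: int = 92
    reads_per_cell_mean: float = 333_000.0
    dispersion: float = 100.0
    gc_bias_coefficients: tuple[float, float] = (0.6, -5.0)
    seed: int = 0
    quality_tier: str = "good"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.reads_per_cell_mean <= 0:
            raise ValueError("reads_per_cell_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.quality_tier not in ("good", "noisy"):
            raise ValueError("quality_tier must be 'good' or 'noisy'")


def simulate_bin_grid(
    n_chromosomes: int,
    chrom_lengths: Sequence[int],
    target_mean_width: int | float,
    seed: int,
) -> BinGrid:
    """Draw a random mappability/GC landscape and tile it into bins.

    Chromosomes are named ``'1'..'n'``.  Window-level mappability is drawn
    from a Beta(20, 3) (mean ~0.87, support (0, 1]) and GC from a normal
    around 0.41 with SD 0.05, clipped to [0.25, 0.65].
    """
    if len(chrom_lengths) != n_chromosomes:
        raise ValueError("chrom_lengths length must equal n_chromosomes")
    lengths = {str(i + 1): int(l) for i, l in enumerate(chrom_lengths)}
    return _simulate_grid(lengths, target_mean_width, seed)


def _simulate_grid(
    lengths: Mapping[str, int], target_mean_width: int | float, seed: int
) -> BinGrid:
    if target_mean_width <= 0:
        raise ValueError("target_mean_width must be positive")
    if any(l <= 0 for l in lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    if target_mean_width > min(lengths.values()):
        raise ValueError("target_mean_width exceeds the shortest chromosome")
    rng = np.random.default_rng(seed)
    window = max(1000, int(target_mean_width) // 20)
    mapp = {}
    gc = {}
    block = max(1, round(target_mean_width / window))  # GC isochore scale ~ bin scale
    for chrom, length in lengths.items():
        n = -(-length // window)
        m = rng.beta(20.0, 3.0, size=n)
        mapp[chrom] = np.clip(m, 0.05, 1.0)
        # GC varies at the Mb (isochore) scale, not per 50 kb window, so that
        # bin-average GC retains realistic spread (~0.05 SD)
        base = rng.normal(0.41, 0.05, size=-(-n // block))
        g = np.repeat(base, block)[:n] + rng.normal(0.0, 0.01, size=n)
        gc[chrom] = np.clip(g, 0.25, 0.65)
    track = GenomeTrack(window_size=window, lengths=dict(lengths), mappability=mapp, gc=gc)
    return build_variable_bins(track, target_mean_width)


def simulate_grch37_grid(
    scale: int = 5, target_mean_width: int | float = 1_000_000, seed: int = 0
) -> BinGrid:
    """A desk-scale grid: GRCh37-proportioned chromosomes shrunk ``scale``-fold.

    With the defaults (1/5 genome, 1 Mb mean bins) the grid has ~620 bins
    across 22 autosomes plus X and Y — the same geometry as a real ~3000-bin
    genome grid but fast enough for test suites, while the shortest
    chromosome still holds ~9-10 bins so modal chromosome calls stay
    meaningful.
    """
    lengths = {c: max(int(l // scale), int(target_mean_width)) for c, l in GRCH37_CHROM_LENGTHS.items()}
    return _simulate_grid(lengths, target_mean_width, seed)


def _gc_factor(gc: np.ndarray, coefficients: tuple[float, float]) -> np.ndarray:
    """Multiplicative quadratic GC bias, normalised to unit mean over the grid."""
    b1, b2 = coefficients
    x = gc - 0.41
    g = np.maximum(1.0 + b1 * x + b2 * x * x, 0.02)
    return g / g.mean()


def _bin_copy_numbers(grid: BinGrid, karyotype: KaryotypeSpec) -> np.ndarray:
    chroms = grid.df["chrom"].to_numpy()
    cn_by_chrom = {c: karyotype.copy_number(c) for c in grid.chromosomes}
    return np.array([cn_by_chrom[c] for c in chroms], dtype=float)


def simulate_cell(
    grid: BinGrid,
    karyotype: KaryotypeSpec,
    config: SimulationConfig,
    cell_seed: int,
    cell_id: str = "cell",
) -> BinnedCell:
    """Draw one cell's per-bin counts from the tied-moment NB model.

    Bin i at copy number s has mean ``s * u * g(gc_i) * map_i * w_i / mean_w``
    where the haploid unit rate ``u`` is set so the expected total equals
    ``reads_per_cell_mean``; the variance is s times the haploid-unit
    variance.  Nullisomic bins are exactly zero.  The ``noisy`` quality
    tier divides the dispersion by 10 and inflates 5 % of bins fivefold,
    producing libraries that fail quality control.
    """
    if grid.n_bins == 0:
        raise ValueError("empty bin grid")
    rng = np.random.default_rng(cell_seed)
    dispersion = config.dispersion
    if config.quality_tier == "noisy":
        dispersion = dispersion / 10.0

    cn = _bin_copy_numbers(grid, karyotype)
    g = _gc_factor(grid.gc, config.gc_bias_coefficients)
    w = grid.widths.astype(float)
    shape = g * grid.mappability * w / w.mean()
    denom = float(np.sum(cn * shape))
    if denom == 0:
        return BinnedCell(
            cell_id=cell_id,
            counts=np.zeros(grid.n_bins, dtype=np.int64),
            sex=karyotype.sex,
            flags=["all_zero"],
        )
    u = config.reads_per_cell_mean / denom
    mu1 = u * shape  # haploid-unit mean per bin

    outlier = np.zeros(grid.n_bins, dtype=bool)
    if config.quality_tier == "noisy":
        outlier = rng.random(grid.n_bins) < 0.05

    counts = np.zeros(grid.n_bins, dtype=np.int64)
    pos = cn > 0
    # tied moments: mean = s*mu1, var = s*mu1*(1 + mu1/dispersion)
    # => NB(r = s*dispersion, p = dispersion/(dispersion + mu1))
    mu_eff = np.where(outlier, mu1 * 5.0, mu1)
    p = dispersion / (dispersion + mu_eff[pos])
    r = cn[pos] * dispersion
    counts[pos] = rng.negative_binomial(r, p)

    total = int(counts.sum())
    return BinnedCell(
        cell_id=cell_id,
        counts=counts,
        sex=karyotype.sex,
        reads_sequenced=total,
        reads_kept=total,
    )


def simulate_cohort(
    grid: BinGrid,
    cohort_spec: Sequence[tuple],
    config: SimulationConfig,
) -> tuple[list[BinnedCell], pd.DataFrame]:
    """Simulate a multi-sample cohort with programmed karyotype mixtures.

    ``cohort_spec`` is a sequence of ``(sample_id, n_cells, karyotypes)``
    where ``karyotypes`` is either a single karyotype (spec or label), or a
    list of ``(weight, karyotype)`` pairs sampled per cell.  Returns the
    cells and a truth table with one row per cell carrying the programmed
    per-chromosome copy numbers.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cells: list[BinnedCell] = []
    truth_rows: list[dict] = []
    chroms = grid.chromosomes
    for sample_id, n_cells, karyos in cohort_spec:
        if n_cells < 1:
            raise ValueError(f"sample {sample_id!r}: n_cells must be >= 1")
        if isinstance(karyos, (str, KaryotypeSpec)):
            choices = [(1.0, resolve_karyotype(karyos))]
        else:
            choices = [(float(wt), resolve_karyotype(k)) for wt, k in karyos]
        weights = np.array([wt for wt, _ in choices], dtype=float)
        weights = weights / weights.sum()
        for i in range(n_cells):
            idx = int(rng.choice(len(choices), p=weights))
            karyotype = choices[idx][1]
            cell_seed = int(rng.integers(0, 2**31 - 1))
            cell_id = f"{sample_id}_c{i:03d}"
            cell = simulate_cell(grid, karyotype, config, cell_seed, cell_id=cell_id)
            cell.sample = str(sample_id)
            cells.append(cell)
            row = {"cell_id": cell_id, "sample": str(sample_id), "sex": karyotype.sex}
            for c in chroms:
                row[f"cn_{c}"] = karyotype.copy_number(c)
            truth_rows.append(row)
    return cells, pd.DataFrame(truth_rows)


def simulate_duplicate_library(
    n_unique_molecules: int, n_sequenced_reads: int, seed: int
) -> np.ndarray:
    """Sample read-to-molecule assignments with replacement.

    Models PCR/optical duplication as uniform sampling of
    ``n_sequenced_reads`` reads from ``n_unique_molecules`` distinct
    molecules; the number of distinct identifiers observed follows the
    occupancy (coupon-collector) distribution.
    """
    if n_unique_molecules <= 0 or n_sequenced_reads <= 0:
        raise ValueError("molecule and read counts must be positive")
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_unique_molecules, size=n_sequenced_reads)
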