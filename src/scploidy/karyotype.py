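"""Whole-chromosome karyotyping and cohort-level aneuploidy statistics.

The modal (most common) decoded state across a chromosome's bins is
assigned as that chromosome's copy number; a cell is aneuploid when any
chromosome deviates from its sex-aware expected ploidy (autosomes 2;
X, Y expectations 2, 0 for XX and 1, 1 for XY — male X monosomy is
normal).  Cohort prevalences carry exact Clopper-Pearson binomial
confidence intervals and groups are compared with the two-sided
Wilcoxon rank-sum (Mann-Whitney) test.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.proportion import proportion_confint

from .bins import BinGrid
from .hmm import CopyNumberHMMResults

__all__ = [
    "ChromosomeKaryotype",
    "AneuploidyCall",
    "CohortSummary",
    "call_chromosomes",
    "classify_aneuploid",
    "focal_scan",
    "aneuploidy_prevalence",
    "per_chromosome_rates",
    "compare_rates_wilcoxon",
    "build_cohort_summary",
    "APP_LOCUS",
]

# GRCh37 amyloid precursor protein (APP) gene region, 0-based half-open
APP_LOCUS: tuple[str, int, int] = ("21", 27_252_861, 27_543_446)

_AUTOSOMES = [str(i) for i in range(1, 23)]


@dataclass
class ChromosomeKaryotype:
    """Per-chromosome modal copy-number calls for one cell."""

    cell_id: str
    calls: dict[str, int]  # chromosome -> called copy number
    support: dict[str, float]  # fraction of the chromosome's bins in the modal state
    sex: str = "unknown"


@dataclass
class AneuploidyCall:
    """Sex-aware classification of a cell as euploid or aneuploid."""

    cell_id: str
    is_aneuploid: bool
    gained: list[str] = field(default_factory=list)
    lost: list[str] = field(default_factory=list)
    expected_cn: dict[str, int] = field(default_factory=dict)
    sex: str = "unknown"
    flags: list[str] = field(default_factory=list)


@dataclass
class CohortSummary:
    """Per-sample and pooled cohort aneuploidy tables."""

    per_sample: pd.DataFrame
    pooled: pd.DataFrame
    per_chromosome: pd.DataFrame


def _modal_state(states: np.ndarray) -> tuple[int, float]:
    """Most common state; ties broken toward the state nearer 2, then smaller."""
    values, counts = np.unique(states, return_counts=True)
    order = sorted(
        range(len(values)),
        key=lambda i: (-counts[i], abs(int(values[i]) - 2), int(values[i])),
    )
    best = order[0]
    return int(values[best]), float(counts[best] / len(states))


def call_chromosomes(
    fit: CopyNumberHMMResults, grid: BinGrid, cell_id: str | None = None, sex: str = "unknown"
) -> ChromosomeKaryotype:
    """Assign each chromosome the modal state of its bins."""
    states = fit.states
    if len(states) != grid.n_bins:
        raise ValueError("fit does not match grid")
    calls: dict[str, int] = {}
    support: dict[str, float] = {}
    for chrom, sl in grid.chrom_slices().items():
        s = states[sl]
        if len(s) == 0:
            warnings.warn(f"chromosome {chrom!r} has no bins; omitted")
            continue
        calls[chrom], support[chrom] = _modal_state(s)
    return ChromosomeKaryotype(
        cell_id=cell_id or "cell", calls=calls, support=support, sex=sex
    )


def _infer_sex(calls: Mapping[str, int]) -> str:
    x = calls.get("X")
    y = calls.get("Y")
    if x == 1 and (y is not None and y >= 1):
        return "XY"
    if x == 2 and (y is None or y == 0):
        return "XX"
    return "unknown"


def classify_aneuploid(karyotype: ChromosomeKaryotype, sex: str | None = None) -> AneuploidyCall:
    """Compare chromosome calls against sex-aware expected ploidies.

    Expected copy number is 2 for every autosome; X and Y expectations are
    (2, 0) for XX cells and (1, 1) for XY cells, so a single X in a male
    cell is euploid.  When sex is unknown it is inferred from the X and Y
    calls; if the pattern is irreconcilable the cell is classified on
    autosomes only and flagged.
    """
    flags: list[str] = []
    sex = sex or (karyotype.sex if karyotype.sex in ("XX", "XY") else None)
    if sex is None:
        sex = _infer_sex(karyotype.calls)
    expected: dict[str, int] = {}
    for chrom in karyotype.calls:
        if chrom == "X":
            if sex == "unknown":
                continue
            expected[chrom] = 2 if sex == "XX" else 1
        elif chrom == "Y":
            if sex == "unknown":
                continue
            expected[chrom] = 0 if sex == "XX" else 1
        else:
            expected[chrom] = 2
    if sex == "unknown":
        flags.append("sex_unresolved_autosomes_only")

    gained = [c for c, e in expected.items() if karyotype.calls[c] > e]
    lost = [c for c, e in expected.items() if karyotype.calls[c] < e]
    return AneuploidyCall(
        cell_id=karyotype.cell_id,
        is_aneuploid=bool(gained or lost),
        gained=gained,
        lost=lost,
        expected_cn=expected,
        sex=sex,
        flags=flags,
    )


def _parse_region(region: str | tuple) -> tuple[str, int, int]:
    if isinstance(region, tuple):
        return region
    if region == "APP":
        return APP_LOCUS
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", region)
    if not m:
        raise ValueError(f"cannot parse region {region!r}; use 'chrom:start-end'")
    chrom, start, end = m.group(1), m.group(2), m.group(3)
    return chrom, int(start.replace(",", "")), int(end.replace(",", ""))


def focal_scan(
    fit: CopyNumberHMMResults,
    grid: BinGrid,
    region: str | tuple[str, int, int],
    scale: int = 1,
) -> tuple[pd.DataFrame, int | None]:
    """Decoded states of all bins overlapping a half-open genomic region.

    ``scale`` divides the region coordinates, for scaled-down simulation
    grids.  Returns the overlapping bins with their states and the
    maximum state (None when no bin overlaps), which highlights focal
    copy-number gains such as amplifications of the APP locus.
    """
    chrom, start, end = _parse_region(region)
    start, end = start // scale, end // scale
    sl = grid.chrom_slices().get(chrom)
    if sl is None:
        raise ValueError(f"chromosome {chrom!r} not in grid")
    sub = grid.df.iloc[sl]
    mask = (sub["start"] < end) & (sub["end"] > start)
    idx = sub.index[mask]
    if len(idx) == 0:
        warnings.warn(f"region {chrom}:{start}-{end} overlaps no bin")
        return pd.DataFrame(columns=["chrom", "start", "end", "bin_index", "state"]), None
    out = pd.DataFrame(
        {
            "chrom": sub.loc[idx, "chrom"],
            "start": sub.loc[idx, "start"],
            "end": sub.loc[idx, "end"],
            "bin_index": idx,
            "state": fit.states[idx],
        }
    ).reset_index(drop=True)
    return out, int(out["state"].max())


def aneuploidy_prevalence(
    calls: Sequence[AneuploidyCall] | tuple[int, int],
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """Aneuploidy prevalence (%) with an exact Clopper-Pearson interval.

    Accepts either a list of :class:`AneuploidyCall` or a raw
    ``(n_aneuploid, n_total)`` pair.  Returns (prevalence, lower, upper),
    all on the percentage scale, unrounded.
    """
    if isinstance(calls, tuple):
        x, n = calls
    else:
        n = len(calls)
        x = sum(c.is_aneuploid for c in calls)
    if n < 1:
        raise ValueError("need at least one cell")
    lo, hi = proportion_confint(x, n, alpha=1 - confidence, method="beta")
    return 100.0 * x / n, 100.0 * float(lo), 100.0 * float(hi)


def per_chromosome_rates(
    calls: Sequence[AneuploidyCall], chromosomes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Percent of cells gaining, losing, or either, per chromosome.

    A cell contributes at most once per chromosome even when it carries
    several aneuploidies.
    """
    n = len(calls)
    if n < 1:
        raise ValueError("need at least one cell")
    if chromosomes is None:
        chromosomes = _AUTOSOMES + ["X", "Y"]
    rows = []
    for chrom in chromosomes:
        g = sum(chrom in c.gained for c in calls)
        l = sum(chrom in c.lost for c in calls)
        e = sum((chrom in c.gained) or (chrom in c.lost) for c in calls)
        rows.append(
            {
                "chrom": chrom,
                "gain_pct": 100.0 * g / n,
                "loss_pct": 100.0 * l / n,
                "total_pct": 100.0 * e / n,
            }
        )
    return pd.DataFrame(rows)


def compare_rates_wilcoxon(
    rates_a: Sequence[float], rates_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two rate vectors.

    Exact enumeration when both groups have at most 10 observations and
    there are no ties; otherwise the normal approximation with tie
    correction.  Degenerate all-equal inputs give p = 1.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def build_cohort_summary(
    cells: pd.DataFrame,
    confidence: float = 0.95,
    chromosomes: Sequence[str] | None = None,
) -> CohortSummary:
    """Aggregate per-cell calls into per-sample and pooled cohort tables.

    ``cells`` needs columns ``cell_id, sample, cohort, qc_pass, call``
    (the latter holding :class:`AneuploidyCall` objects).  Only
    QC-passing cells enter numerators and denominators.  Per-sample
    percentages are reported to 2 decimals and pooled prevalences to 1,
    alongside the unrounded values.
    """
    required = {"cell_id", "sample", "cohort", "qc_pass", "call"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cells table missing columns: {sorted(missing)}")
    if cells["cohort"].isna().any():
        raise ValueError("every cell needs a cohort label")

    kept = cells[cells["qc_pass"].astype(bool)]

    sample_rows = []
    for (cohort, sample), sub in cells.groupby(["cohort", "sample"], sort=False):
        sub_kept = sub[sub["qc_pass"].astype(bool)]
        n = len(sub_kept)
        if n == 0:
            warnings.warn(f"sample {sample!r}: no QC-passing cells; excluded")
            continue
        x = sum(c.is_aneuploid for c in sub_kept["call"])
        sample_rows.append(
            {
                "cohort": cohort,
                "sample": sample,
                "n_cells": n,
                "n_aneuploid": x,
                "percent": round(100.0 * x / n, 2),
            }
        )
    per_sample = pd.DataFrame(sample_rows)

    pooled_rows = []
    chrom_rows = []
    for cohort, sub in kept.groupby("cohort", sort=False):
        n = len(sub)
        if n == 0:
            continue
        calls = list(sub["call"])
        x = sum(c.is_aneuploid for c in calls)
        prev, lo, hi = aneuploidy_prevalence((x, n), confidence)
        pooled_rows.append(
            {
                "cohort": cohort,
                "n_cells": n,
                "n_aneuploid": x,
                "prevalence_pct": round(prev, 1),
                "ci_lower_pct": round(lo, 1),
                "ci_upper_pct": round(hi, 1),
                "prevalence_raw": prev,
                "ci_lower_raw": lo,
                "ci_upper_raw": hi,
            }
        )
        rates = per_chromosome_rates(calls, chromosomes)
        rates.insert(0, "cohort", cohort)
        chrom_rows.append(rates)

    pooled = pd.DataFrame(pooled_rows)
    per_chrom = (
        pd.concat(chrom_rows, ignore_index=True) if chrom_rows else pd.DataFrame()
    )
    return CohortSummary(per_sample=per_sample, pooled=pooled, per_chromosome=per_chrom)
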