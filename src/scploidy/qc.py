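"""Library quality control for shallow single-cell WGS.

Five metrics summarise each library: genomic coverage (fraction of bins
hit), spikiness (bin-to-bin variation in read density), Shannon entropy
of the count distribution, the number of decoded ploidy-state segments,
and the Bhattacharyya distance between the fitted monosomy and disomy
emission distributions.  Libraries are clustered on the standardised
metric vector and the highest-quality cluster is retained, with hard
thresholds spikiness < 0.21 and Bhattacharyya distance > 1.0 applied to
every selected cell.

Library complexity is estimated from a saturation curve fitted to
repeated downsampling: uni_reads = Cmax * seq_reads / (K + seq_reads),
where Cmax is the theoretical maximum number of unique reads and K the
sequencing depth at which half of them have been seen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from scipy.stats import nbinom

from .hmm import CopyNumberHMMResults

__all__ = [
    "QCReport",
    "ComplexityFit",
    "spikiness",
    "entropy",
    "bhattacharyya",
    "bhattacharyya_nb",
    "fit_saturation_curve",
    "estimate_complexity",
    "cluster_by_quality",
    "SPIKINESS_MAX",
    "BHATTACHARYYA_MIN",
]

# hard selection thresholds applied to the best cluster
SPIKINESS_MAX = 0.21
BHATTACHARYYA_MIN = 1.0


@dataclass
class QCReport:
    """Per-library quality metrics and the pass/fail verdict."""

    cell_id: str
    coverage: float
    spikiness: float
    entropy: float
    n_segments: int
    bhattacharyya: float
    complexity_cmax: float = float("nan")
    complexity_k: float = float("nan")
    passes: bool = False
    cluster_id: int | None = None

    def metric_vector(self) -> np.ndarray:
        return np.array(
            [self.spikiness, self.entropy, self.n_segments, self.bhattacharyya, self.coverage],
            dtype=float,
        )


@dataclass
class ComplexityFit:
    """Fitted saturation curve uni = cmax * s / (k + s)."""

    cmax: float
    k: float
    curve_points: list[tuple[int, int]]
    flagged: bool = False

    def predict(self, seq_reads: float | np.ndarray) -> float | np.ndarray:
        return self.cmax * np.asarray(seq_reads, dtype=float) / (self.k + seq_reads)


def spikiness(counts: Sequence[float] | np.ndarray) -> float:
    """Sum of absolute consecutive bin differences over the total count.

    Low for smooth profiles; large when read density jumps bin to bin.
    Returns NaN for an all-zero vector.
    """
    c = np.asarray(counts, dtype=float)
    if len(c) < 2:
        raise ValueError("spikiness needs at least 2 bins")
    total = c.sum()
    if total == 0:
        return float("nan")
    return float(np.abs(np.diff(c)).sum() / total)


def entropy(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon entropy (nats) of the per-bin read distribution.

    Zero when all reads fall in one bin, ln(n_bins) when uniform.
    Returns NaN for an all-zero vector.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total == 0:
        return float("nan")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def coverage(counts: Sequence[float] | np.ndarray) -> float:
    """Fraction of bins with a nonzero count."""
    c = np.asarray(counts)
    return float(np.mean(c > 0))


def bhattacharyya_nb(
    mu_a: float, var_a: float, mu_b: float, var_b: float, tail: float = 1e-12
) -> float:
    """Bhattacharyya distance between two negative binomials by moments.

    D = -ln sum_k sqrt(P1(k) P2(k)), summed until the remaining
    Cauchy-Schwarz tail bound sqrt(T1 * T2) is below ``tail``.
    Zero for identical distributions.
    """
    if var_a <= mu_a or var_b <= mu_b:
        raise ValueError("negative binomial requires var > mu")
    r1 = mu_a**2 / (var_a - mu_a)
    p1 = mu_a / var_a
    r2 = mu_b**2 / (var_b - mu_b)
    p2 = mu_b / var_b
    return _bhattacharyya_sum(r1, p1, r2, p2, tail)


def bhattacharyya(
    fit: CopyNumberHMMResults | "EmissionModel", tail: float = 1e-12
) -> float:
    """Bhattacharyya distance between the fitted monosomy and disomy emissions.

    Large when the two distributions are well separated, i.e. when
    sequencing depth suffices to distinguish adjacent copy-number
    states.  Returns NaN for a degenerate fit.  Accepts either a fitted
    results object or a bare :class:`~scploidy.hmm.EmissionModel`.
    """
    em = getattr(fit, "emission", fit)
    if em is None:
        return float("nan")
    p = em.nb_p
    r1, r2 = float(em.nb_r(1)), float(em.nb_r(2))
    return _bhattacharyya_sum(r1, p, r2, p, tail)


def _bhattacharyya_sum(r1: float, p1: float, r2: float, p2: float, tail: float) -> float:
    bc = 0.0
    k0 = 0
    block = 4096
    while True:
        k = np.arange(k0, k0 + block)
        bc += float(np.sum(np.sqrt(nbinom.pmf(k, r1, p1) * nbinom.pmf(k, r2, p2))))
        k0 += block
        t1 = nbinom.sf(k0 - 1, r1, p1)
        t2 = nbinom.sf(k0 - 1, r2, p2)
        if math.sqrt(max(t1, 0.0) * max(t2, 0.0)) < tail:
            break
        if k0 > 50_000_000:  # pathological parameters; refuse to loop forever
            warnings.warn("Bhattacharyya summation truncated", RuntimeWarning)
            break
    bc = min(bc, 1.0)
    return float(-math.log(max(bc, 1e-300)))


def estimate_complexity(
    total_reads: int,
    unique_counter: Callable[[int], int],
    n_points: int = 10,
) -> ComplexityFit:
    """Fit the saturation curve to repeated downsampling of a library.

    ``unique_counter(s)`` must return the number of unique reads observed
    in a subsample of ``s`` sequenced reads.  The curve
    uni = cmax * s / (k + s) is least-squares fitted to ``n_points``
    evenly spaced subsample sizes; by construction the fitted curve
    passes through cmax/2 at s = k.
    """
    if n_points < 3:
        raise ValueError("need at least 3 downsampling points")
    if total_reads < n_points:
        raise ValueError("total_reads must be at least n_points")
    sizes = np.unique(np.round(np.linspace(1, n_points, n_points) / n_points * total_reads)).astype(int)
    sizes = sizes[sizes > 0]
    uniques = np.array([int(unique_counter(int(s))) for s in sizes], dtype=float)
    return fit_saturation_curve(sizes, uniques)


def fit_saturation_curve(
    sizes: Sequence[int] | np.ndarray, uniques: Sequence[float] | np.ndarray
) -> ComplexityFit:
    """Least-squares fit of uni = cmax * s / (k + s) to explicit points.

    Point order is irrelevant (points are sorted internally).  Data
    where every subsample is entirely unique cannot constrain cmax and
    is returned flagged with infinite parameters.
    """
    sizes = np.asarray(sizes, dtype=float)
    uniques = np.asarray(uniques, dtype=float)
    if len(sizes) != len(uniques) or len(sizes) < 3:
        raise ValueError("need at least 3 matching (size, unique) points")
    order = np.argsort(sizes)
    sizes, uniques = sizes[order], uniques[order]
    points = list(zip(sizes.astype(int).tolist(), uniques.astype(int).tolist()))

    if np.all(uniques == sizes):
        return ComplexityFit(
            cmax=float("inf"), k=float("inf"), curve_points=points, flagged=True
        )

    def curve(s, cmax, k):
        return cmax * s / (k + s)

    u_max = float(uniques.max())
    p0 = (2.0 * u_max, float(np.median(sizes)))
    popt, _ = curve_fit(
        curve,
        sizes,
        uniques,
        p0=p0,
        bounds=([1e-6, 1e-6], [np.inf, np.inf]),
        maxfev=20_000,
    )
    return ComplexityFit(cmax=float(popt[0]), k=float(popt[1]), curve_points=points)


def _quality_score(z: np.ndarray) -> np.ndarray:
    """Scalar quality from z-scored metrics, higher is better.

    Columns: spikiness, entropy, n_segments, bhattacharyya, coverage.
    Good libraries are smooth (low spikiness), uniform (high entropy),
    unfragmented (few segments), well separated (high Bhattacharyya) and
    broad (high coverage).
    """
    return -z[:, 0] + z[:, 1] - z[:, 2] + z[:, 3] + z[:, 4]


def cluster_by_quality(
    reports: Sequence[QCReport],
    n_clusters_max: int = 4,
    spikiness_max: float = SPIKINESS_MAX,
    bhattacharyya_min: float = BHATTACHARYYA_MIN,
) -> tuple[np.ndarray, int]:
    """Partition libraries by QC similarity and select the best cluster.

    Complete-linkage agglomerative clustering on z-scored metric vectors,
    cut to at most ``n_clusters_max`` clusters.  The cluster with the
    highest mean quality score is selected; a library passes QC only if
    it belongs to the selected cluster *and* meets the hard thresholds
    (spikiness < ``spikiness_max`` and Bhattacharyya > ``bhattacharyya_min``).
    Mutates ``passes`` and ``cluster_id`` on the reports and returns
    (assignments, selected_cluster_id).
    """
    if len(reports) < 2:
        raise ValueError("clustering needs at least 2 libraries")
    X = np.vstack([r.metric_vector() for r in reports])
    X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    if np.allclose(Z, Z[0]):
        assignments = np.ones(len(reports), dtype=int)
    else:
        link = linkage(Z, method="complete")
        # cut at the largest merge-height gap among 2..n_clusters_max
        # clusters, so a clearly bimodal plate yields exactly two groups
        d = link[:, 2]
        n = len(reports)
        best_k, best_gap = 2, -np.inf
        for k in range(2, min(n_clusters_max, n - 1) + 1):
            gap = d[n - k] - d[n - k - 1]
            if gap > best_gap:
                best_k, best_gap = k, gap
        if best_gap > 0.5 * d[-1]:
            assignments = fcluster(link, t=best_k, criterion="maxclust")
        else:
            # no pronounced gap: the plate is one quality population
            assignments = np.ones(n, dtype=int)

    scores = _quality_score(Z)
    cluster_ids = np.unique(assignments)
    mean_scores = {cid: float(scores[assignments == cid].mean()) for cid in cluster_ids}
    selected = max(mean_scores, key=lambda cid: (mean_scores[cid], -cid))

    for r, cid, row in zip(reports, assignments, X):
        r.cluster_id = int(cid)
        r.passes = bool(
            cid == selected
            and row[0] < spikiness_max
            and row[3] > bhattacharyya_min
        )
    return assignments, int(selected)


def qc_report(
    cell_id: str,
    counts: np.ndarray,
    fit: CopyNumberHMMResults,
    grid=None,
    complexity: ComplexityFit | None = None,
) -> QCReport:
    """Assemble the five-metric report for one library from its fit."""
    return QCReport(
        cell_id=cell_id,
        coverage=coverage(counts),
        spikiness=spikiness(counts),
        entropy=entropy(counts),
        n_segments=fit.n_segments(grid),
        bhattacharyya=bhattacharyya(fit),
        complexity_cmax=complexity.cmax if complexity else float("nan"),
        complexity_k=complexity.k if complexity else float("nan"),
    )
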