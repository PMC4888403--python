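"""Readers, writers, run configuration and the end-to-end pipeline.

All tabular artifacts are TSV with explicit headers; bin grids and
per-cell copy-number profiles are BED-like (0-based half-open) for
genome-browser compatibility.  Gzip-compressed inputs are accepted
transparently.  A JSON run manifest records versions, the seed and the
thresholds, so any run is reproducible byte for byte.
"""

from __future__ import annotations

import gzip
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bins import BinGrid
from .counts import BinnedCell, gc_correct
from .hmm import fit_copy_number_hmm
from .karyotype import build_cohort_summary, call_chromosomes, classify_aneuploid
from .qc import BHATTACHARYYA_MIN, SPIKINESS_MAX, cluster_by_quality, qc_report

__all__ = [
    "read_bins",
    "write_bins",
    "read_counts",
    "write_counts",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("scploidy")

_BIN_HEADER = ["chrom", "start", "end", "gc", "mappability", "bin_id"]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_bins(grid: BinGrid, path: str | Path) -> None:
    """Write a bin grid as 6-column BED-like TSV with a '#' header line."""
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(_BIN_HEADER) + "\n")
        for row in grid.df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gc:.6f}"
                f"\t{row.mappability:.6f}\t{row.bin_id}\n"
            )


def read_bins(path: str | Path) -> BinGrid:
    """Read and validate a bin grid; names the offending line on error."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            chrom, start, end, gc, mapp, bin_id = parts
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise ValueError(f"{path}: line {lineno}: end <= start ({start_i}, {end_i})")
            rows.append((chrom, start_i, end_i, float(gc), float(mapp), bin_id))
    df = pd.DataFrame(rows, columns=_BIN_HEADER)
    try:
        return BinGrid(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_counts(
    cells: Sequence[BinnedCell], grid: BinGrid, prefix: str | Path
) -> tuple[Path, Path]:
    """Write a cohort as a cell x bin matrix TSV plus a metadata TSV.

    Returns the (matrix, metadata) paths: ``<prefix>.counts.tsv`` and
    ``<prefix>.meta.tsv``.  Matrix columns are bin ids in grid order.
    """
    prefix = Path(prefix)
    matrix_path = prefix.with_name(prefix.name + ".counts.tsv")
    meta_path = prefix.with_name(prefix.name + ".meta.tsv")
    bin_ids = list(grid.df["bin_id"])
    mat = pd.DataFrame(
        np.vstack([c.counts for c in cells]),
        columns=bin_ids,
    )
    mat.insert(0, "cell_id", [c.cell_id for c in cells])
    mat.to_csv(matrix_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "sample": [c.sample for c in cells],
            "cohort": [c.cohort for c in cells],
            "sex": [c.sex for c in cells],
            "reads_sequenced": [c.reads_sequenced for c in cells],
            "reads_kept": [c.reads_kept for c in cells],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)
    return matrix_path, meta_path


def read_counts(
    path: str | Path, grid: BinGrid, metadata_path: str | Path | None = None
) -> list[BinnedCell]:
    """Read a cell x bin matrix, validating columns against the grid."""
    mat = pd.read_csv(path, sep="\t")
    if mat.columns[0] != "cell_id":
        raise ValueError(f"{path}: first column must be 'cell_id'")
    expected = list(grid.df["bin_id"])
    got = list(mat.columns[1:])
    if got != expected:
        missing = [b for b in expected if b not in got]
        extra = [b for b in got if b not in expected]
        raise ValueError(
            f"{path}: bin columns do not match grid"
            + (f"; missing {missing[:5]}" if missing else "")
            + (f"; unexpected {extra[:5]}" if extra else "")
        )
    meta = None
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t").set_index("cell_id")
    cells = []
    for _, row in mat.iterrows():
        cell_id = str(row["cell_id"])
        counts = row[expected].to_numpy(dtype=np.int64)
        cell = BinnedCell(cell_id=cell_id, counts=counts, reads_kept=int(counts.sum()))
        if counts.sum() == 0:
            cell.flags.append("all_zero")
            log.warning("cell %s has an all-zero count row", cell_id)
        if meta is not None and cell_id in meta.index:
            m = meta.loc[cell_id]
            cell.sample = str(m.get("sample", ""))
            cell.cohort = str(m.get("cohort", ""))
            cell.sex = str(m.get("sex", "unknown"))
            cell.reads_sequenced = int(m.get("reads_sequenced", counts.sum()))
        cells.append(cell)
    return cells


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with study-default thresholds."""

    bins_path: str
    counts_path: str
    output_dir: str
    metadata_path: str | None = None
    min_mapq: int = 11
    spikiness_max: float = SPIKINESS_MAX
    bhattacharyya_min: float = BHATTACHARYYA_MIN
    s_max: int = 10
    max_iter: int = 200
    tol: float = 1e-4
    seed: int = 0
    gc_correction: bool = True
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.min_mapq < 0 or self.spikiness_max <= 0 or self.bhattacharyya_min <= 0:
            raise ValueError("thresholds must be positive")
        if self.s_max < 1:
            raise ValueError("s_max must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with _open_text(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def run_pipeline(config: RunConfig) -> int:
    """Chain the stages: load -> GC-correct -> HMM -> QC -> karyotype -> summarise.

    Writes per-cell profile BEDs, a QC TSV, per-sample and pooled cohort
    summary TSVs, and a JSON manifest.  Deterministic given the same
    inputs and seed.  Returns 0 on success; configuration errors raise
    before any compute.
    """
    logging.basicConfig(
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    bins_path = Path(config.bins_path)
    counts_path = Path(config.counts_path)
    for p in (bins_path, counts_path):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid = read_bins(bins_path)
    cells = read_counts(counts_path, grid, config.metadata_path)
    log.info("stage=load cells=%d bins=%d", len(cells), grid.n_bins)

    profiles_dir = out / "profiles"
    profiles_dir.mkdir(exist_ok=True)
    reports = []
    records = []
    for cell in cells:
        obs = cell.counts
        if config.gc_correction:
            cell = gc_correct(cell, grid)
            obs = cell.observable()
        fit = fit_copy_number_hmm(
            obs, grid, s_max=config.s_max, max_iter=config.max_iter, tol=config.tol
        )
        profile = fit.profile(grid)
        profile.to_csv(
            profiles_dir / f"{cell.cell_id}.profile.bed",
            sep="\t",
            index=False,
            header=False,
            float_format="%.6f",
        )
        report = qc_report(cell.cell_id, cell.counts, fit, grid)
        reports.append(report)
        karyo = call_chromosomes(fit, grid, cell_id=cell.cell_id, sex=cell.sex)
        call = classify_aneuploid(karyo)
        records.append(
            {
                "cell_id": cell.cell_id,
                "sample": cell.sample or "sample",
                "cohort": cell.cohort or "cohort",
                "call": call,
            }
        )
    log.info("stage=call cells=%d", len(records))

    if len(reports) >= 2:
        cluster_by_quality(
            reports,
            spikiness_max=config.spikiness_max,
            bhattacharyya_min=config.bhattacharyya_min,
        )
    else:
        for r in reports:
            r.passes = (
                r.spikiness < config.spikiness_max
                and r.bhattacharyya > config.bhattacharyya_min
            )
    n_pass = sum(r.passes for r in reports)
    log.info("stage=qc kept=%d total=%d", n_pass, len(reports))

    qc_df = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in reports],
            "coverage": [r.coverage for r in reports],
            "spikiness": [r.spikiness for r in reports],
            "entropy": [r.entropy for r in reports],
            "n_segments": [r.n_segments for r in reports],
            "bhattacharyya": [r.bhattacharyya for r in reports],
            "cluster_id": [r.cluster_id for r in reports],
            "passes": [r.passes for r in reports],
        }
    )
    qc_df.to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.6f")

    cell_table = pd.DataFrame(
        [
            {
                "cell_id": rec["cell_id"],
                "sample": rec["sample"],
                "cohort": rec["cohort"],
                "qc_pass": rep.passes,
                "call": rec["call"],
            }
            for rec, rep in zip(records, reports)
        ]
    )
    summary = build_cohort_summary(cell_table)
    summary.per_sample.to_csv(out / "per_sample.tsv", sep="\t", index=False)
    summary.pooled.to_csv(out / "cohort.tsv", sep="\t", index=False, float_format="%.6f")
    summary.per_chromosome.to_csv(
        out / "per_chromosome.tsv", sep="\t", index=False, float_format="%.6f"
    )
    log.info("stage=summarize samples=%d", len(summary.per_sample))

    manifest = {
        "scploidy_version": __version__,
        "python_version": sys.version.split()[0],
        "numpy_version": np.__version__,
        "seed": config.seed,
        "thresholds": {
            "min_mapq": config.min_mapq,
            "spikiness_max": config.spikiness_max,
            "bhattacharyya_min": config.bhattacharyya_min,
            "s_max": config.s_max,
        },
        "inputs": {"bins": str(bins_path), "counts": str(counts_path)},
        "n_cells": len(cells),
        "n_pass_qc": int(n_pass),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return 0
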