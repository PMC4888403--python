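# Methods

## Setting and data model

The package analyses shallow single-cell whole-genome sequencing
libraries prepared without whole-genome pre-amplification.  In that
regime each genomic locus is represented at most twice per diploid cell
(once per homolog), losses during library preparation are approximately
random, and the count of uniquely mapped reads in a genomic bin is, to
good approximation, proportional to the underlying copy number of that
bin.  All inference therefore happens on a fixed genome-wide grid of
bins; single reads are never interpreted individually.

Coordinates are 0-based half-open everywhere (BED convention on disk).
A read belongs to the bin containing its leftmost mapped position;
with ~50 nt reads and ~1 Mb bins, fractional overlap handling would
change assignments for a negligible fraction of reads.  Reads are
excluded when flagged as duplicates or when MAPQ ≤ 10 (`mapq_min = 11`);
filtered-out and out-of-grid reads are tallied so that
`reads_kept == sum(counts)` always holds.

## Variable-width bins

Uniquely mappable content varies along the genome, so fixed-width bins
would confound mappability with copy number.  Bins are instead cut so
that every bin on a chromosome carries the same summed mappability
mass: a chromosome with total mass M is split into
`n = round(M / m_target)` bins at mass quantiles, where
`m_target = target_mean_width × genome-mean mappability`.  Width is
therefore inversely proportional to local mappability, the genome-wide
mean width equals the target (1 Mb by default), and — important for the
caller — no bin (including each chromosome's last) carries excess mass
that would mimic a copy-number gain.  Per-bin GC and mappability are
length-weighted window averages.

## GC correction

Read density depends smoothly on bin GC content.  The correction
divides counts by a trend estimate f(gc) normalised to unit mean:
a lowess fit of counts on GC (span 0.3) on grids of ≥ 200 bins, and a
decile-median ratio on smaller grids where lowess is unstable.  The
trend factor is floored at 0.05 so GC-starved bins cannot be boosted
without bound, corrected values are rescaled to preserve the total
count exactly, and zeros map to zeros so the nullisomy state of the
caller remains observable.  An all-zero library is passed through
unchanged and flagged.

## The copy-number HMM

Hidden states are integer copy numbers 0..S_max (default 10).  The
nullisomy emission is a delta at zero, implemented as log-mass −∞ for
any positive count (no smoothing).  For s ≥ 1 the emission is negative
binomial with tied moments: mean s·μ₁ and variance s·σ₁², where μ₁ and
σ₁² are the monosomy (haploid-unit) mean and variance and σ₁² > μ₁.
Two algebraic consequences are used throughout: the NB success
probability p = μ₁/σ₁² is state-independent, and the size parameter
r_s = s·μ₁²/(σ₁² − μ₁) is linear in s.  Only two emission parameters
are free, which keeps the model identifiable from a single shallow
library and prevents adjacent states from collapsing onto each other.

Counts entering the HMM are the GC-corrected values rounded to the
nearest non-negative integer (the NB is integer-supported, and
correction precedes modelling).

**Estimation.**  Baum–Welch with a scaled forward–backward pass
(per-bin normalisation plus a per-bin log-shift of the emission row, so
3000-bin profiles cannot underflow).  Initialisation assumes the cell
is near-diploid: μ₁ ← mean(nonzero counts)/2,
σ₁² ← max(var(nonzero)/2, 1.2 μ₁), self-transition 0.99, initial mass
concentrated on states 1–4.  The transition and initial-distribution
updates are the standard EM formulas.  The emission update is
posterior-weighted moment matching on scaled observations: with weights
γᵢ(s) for s ≥ 1,

    μ₁ ← Σ γᵢ(s)·xᵢ/s / Σ γᵢ(s)
    σ₁² ← Σ γᵢ(s)·(xᵢ − s·μ₁)²/s / Σ γᵢ(s),

after which σ₁² > 1.05 μ₁ is re-imposed.  Moment matching is not the
exact maximiser of the EM surrogate for this tied family, so each
update is safeguarded: a candidate is accepted only if the
log-likelihood does not decrease; otherwise the step is halved toward
the previous iterate (convex blending of μ₁, σ₁², transition and
initial), and if no fraction of the step improves, estimation stops at
the current local optimum.  The recorded likelihood history is
therefore monotone by construction.  Convergence is declared when the
relative log-likelihood change falls below `tol` (default 1e-4).

**Decoding.**  The per-bin call is the state with the highest posterior
marginal; exact ties are broken toward the state nearest 2, then the
smaller state (conservative toward euploidy, deterministic).  Viterbi
decoding is exposed as an option but is not the default.  An all-zero
library short-circuits to all-nullisomy with log-likelihood 0.
Segments are maximal constant-state runs that never cross chromosome
boundaries.

## Quality control

Five per-library metrics:

- coverage — fraction of bins with a nonzero count (a binned-data
  notion, not base-level coverage);
- spikiness — Σ|cᵢ₊₁ − cᵢ| / Σcᵢ over bins in grid order;
- entropy — Shannon entropy (nats) of the normalised count vector;
- number of ploidy-state segments from the decoded profile;
- Bhattacharyya distance −ln Σₖ √(P₁(k)P₂(k)) between the fitted
  monosomy and disomy emissions, summed until the Cauchy–Schwarz tail
  bound √(T₁T₂) drops below 1e−12.

Libraries are clustered on z-scored metric vectors with complete-linkage
agglomerative clustering (deterministic).  The dendrogram is cut at the
largest merge-height gap among 2..4 clusters; if no gap exceeds half
the final merge height the plate is treated as one quality population.
The cluster with the highest mean quality score (low spikiness and
segment count, high entropy, Bhattacharyya and coverage) is selected,
and a library passes only if it is in the selected cluster *and* meets
the hard thresholds spikiness < 0.21 and Bhattacharyya > 1.0.  A cell
failing a threshold fails regardless of cluster membership.

Library complexity: the saturation curve uni = C_max·s/(K + s) is
least-squares fitted (bounded curve_fit) to unique-read counts at 10
evenly spaced subsample sizes.  By construction the fitted curve passes
through C_max/2 at s = K.  Fully unique data (no duplicates observed)
cannot constrain C_max and is returned flagged.  Unique reads are
counted by molecule identifier in simulation and would be counted by
(chromosome, position) on real reads.

## Karyotyping and cohort statistics

A chromosome's copy number is the modal decoded state over its bins,
weighted by bin count (bins hold equal mappable content, so bin count
and base-pair weighting nearly coincide); ties break toward 2, then the
smaller state, and the supporting fraction is reported.  Sub-chromosomal
segments change nothing unless they flip the modal state — aneuploidy
here means whole-chromosome gain or loss.

Expected ploidy is 2 for autosomes and (X, Y) = (2, 0) for XX or (1, 1)
for XY, so single-X male cells are euploid.  When sex is not recorded
it is inferred from the calls (X=1 with Y present → XY; X=2 with Y
absent → XX); an irreconcilable pattern yields an autosome-only
classification, flagged.

Prevalence intervals are exact Clopper–Pearson (beta-quantile) binomial
intervals; the method reproduces a printed interval of 0.2–1.3 % for
5 aneuploid cells in 893 and is deliberately conservative (coverage
≥ the nominal 95 %).  Group comparisons use the two-sided Wilcoxon
rank-sum test: exact enumeration when both groups have ≤ 10
observations without ties, otherwise the normal approximation with tie
correction; degenerate all-equal inputs return p = 1.  The focal scan
returns the decoded states of all bins overlapping a half-open region
("chrom:start-end" strings accepted; the GRCh37 APP locus
chr21:27,252,861–27,543,446 ships as the preset `"APP"`, with a `scale`
argument for scaled-down grids).

Report tables round pooled prevalences to 1 decimal and per-sample
percentages to 2, and always carry the unrounded values alongside.

## The synthetic-data generator

The simulator emulates the libraries this pipeline is designed for:
~333,000 uniquely mapped reads per cell (the post-filter depth of a
typical shallow single-neuron library) spread over ~1 Mb variable-width
bins with negative-binomial overdispersion, a smooth multiplicative GC
bias, programmed integer karyotypes and duplicate-read structure.

**Generative model.**  Deliberately the same tied-moment NB family the
caller assumes: bin i at copy number c has mean
c·u·g(gcᵢ)·mapᵢ·wᵢ/w̄ and variance c·μᵢ(1 + μᵢ/d), where u is set so
the expected total equals the configured depth, g is a quadratic GC
factor normalised to unit mean, and d is the dispersion (NB size of the
haploid unit).  Sharing the model between simulator and caller makes
parameter recovery well-posed; it also means passing tests certify the
inference machinery, not robustness to model misspecification (see
Limitations).

**Genome and grid.**  The default test genome is GRCh37-proportioned,
scaled to 1/5 length with 1 Mb bins (~620 bins, 22 autosomes + X + Y).
The scale was chosen so the shortest chromosomes (21, 22, Y) retain
~9–12 bins: whole-chromosome detectability in this model is
asymptotically depth-invariant, scaling as ≈ 0.5·√(d·n_bins/3) standard
deviations for a trisomy on an n_bin chromosome, so what matters when
shrinking the genome is bins per chromosome, not reads per bin.
Mappability is drawn per 50 kb window from Beta(20, 3); GC is drawn at
the ~1 Mb isochore scale (N(0.41, 0.05), clipped to [0.25, 0.65]) with
small window-level jitter, so bin-average GC keeps a realistic ~0.05
spread for the correction to remove.

**Dispersion default (d = 100).**  The paper-scale setting this
simulator emulates runs ~3000 bins, i.e. ~48 bins on chromosome 21;
on the 1/5-scale grid chromosome 21 has ~10.  The default dispersion is
calibrated so the desk-scale twin has the same per-chromosome
separation (≈ 9 SD for a trisomy on the shortest chromosome) that a
full-scale grid attains at a more library-like d ≈ 20 — matching
0.5·√(10·d/3) to 9 gives d ≈ 100.  Real library dispersion is not
reported for this protocol; the default is an explicit
separability-over-fidelity choice, and `SimulationConfig(dispersion=...)`
accepts anything positive.

**GC bias default (0.6, −5).**  A mild unimodal multiplicative curve
over the realistic bin-GC range, producing a raw count–GC correlation
of ~0.15 that the lowess correction removes to |r| < 0.05.

**Quality tiers.**  `good` draws from the model above; `noisy` divides
the dispersion by 10 and inflates 5 % of bins fivefold, producing
libraries with spikiness ≈ 0.5 and Bhattacharyya ≈ 0.6 that fail the
selection thresholds — negative fixtures for the QC stage.

**Duplicates.**  `simulate_duplicate_library` assigns each sequenced
read to one of N molecules uniformly with replacement; the distinct
count follows the occupancy distribution, against which the hyperbolic
complexity fit is validated (it recovers N within ~15 % at 20×
oversampling despite the functional-form mismatch).

**What the generator does not emulate:** base-level reads and alignment
error, segmental (sub-chromosomal) CNVs, replication-timing and strand
effects, chimeric molecules, cell-to-cell depth variation beyond NB
sampling, and GC bias shapes outside the quadratic family.  Passing
tests therefore demonstrate correct inference under the stated model at
desk scale, not performance on real libraries.

## Problem sizes used by the test suite and acceptance script

The suite runs the full pipeline on ~620-bin genomes: 36-cell
trisomy-21 cohorts, 81-cell euploid XY cohorts, 20-cell mixed-quality
plates, and smaller grids (~160 bins) for metric-level checks; the
exact-inference oracle enumerates all paths on ≤ 6-bin, ≤ 4-state toys.
The acceptance script simulates the 36-cell and 81-cell cohorts from
its `--seed` and re-derives every reported number at run time.

## Known limitations

- The simulator and caller share one generative family; no
  misspecification stress-testing is included.
- Modal chromosome calls on ~10-bin chromosomes are meaningful only
  because the simulator's separability is calibrated accordingly; real
  ~1 Mb grids provide 5× more bins per chromosome.
- The QC cluster-count heuristic (largest dendrogram gap, half-height
  fallback) is deterministic but heuristic; pathological metric
  distributions could merge tiers that thresholds would still separate.
- Clopper–Pearson intervals are conservative; other published intervals
  for the same counts can be narrower at the upper bound.
- Sub-bin breakpoints are not refined; cells are fitted independently
  (no joint multi-cell model).
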