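"""Chromosome calls, aneuploidy classification and cohort statistics."""

import itertools
import warnings
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import scploidy as sp
from scploidy.karyotype import _modal_state


def fake_fit(states):
    return SimpleNamespace(states=np.asarray(states))


class TestModalCall:
    def test_unanimous_chromosome(self):
        assert _modal_state(np.full(40, 3)) == (3, 1.0)

    def test_majority_with_support(self):
        states = np.array([2] * 30 + [3] * 70)
        assert _modal_state(states) == (3, 0.7)

    def test_tie_breaks_toward_disomy(self):
        assert _modal_state(np.array([2] * 50 + [3] * 50))[0] == 2
        assert _modal_state(np.array([1] * 50 + [3] * 50))[0] == 1  # nearer-2 tie -> smaller
        assert _modal_state(np.array([0] * 50 + [4] * 50))[0] == 0

    def test_call_chromosomes_per_chrom(self, grch_grid):
        states = np.full(grch_grid.n_bins, 2)
        chr21 = grch_grid.df["chrom"].to_numpy() == "21"
        states[chr21] = 3
        karyo = sp.call_chromosomes(fake_fit(states), grch_grid, cell_id="c1")
        assert karyo.calls["21"] == 3 and karyo.support["21"] == 1.0
        assert karyo.calls["1"] == 2


class TestClassifyAneuploid:
    def _karyo(self, calls, sex="unknown"):
        return sp.ChromosomeKaryotype(
            cell_id="c", calls=calls, support={k: 1.0 for k in calls}, sex=sex
        )

    def euploid_calls(self, sex):
        calls = {str(i): 2 for i in range(1, 23)}
        calls["X"], calls["Y"] = (2, 0) if sex == "XX" else (1, 1)
        return calls

    def test_trisomy_21_xx_flagged_as_gain(self):
        calls = self.euploid_calls("XX")
        calls["21"] = 3
        out = sp.classify_aneuploid(self._karyo(calls, "XX"))
        assert out.is_aneuploid and out.gained == ["21"] and out.lost == []

    def test_male_x_monosomy_is_euploid(self):
        out = sp.classify_aneuploid(self._karyo(self.euploid_calls("XY"), "XY"))
        assert not out.is_aneuploid

    def test_quadruple_gain(self):
        calls = self.euploid_calls("XX")
        for c in ("13", "16", "21", "22"):
            calls[c] = 3
        out = sp.classify_aneuploid(self._karyo(calls, "XX"))
        assert out.is_aneuploid and sorted(out.gained) == ["13", "16", "21", "22"]

    def test_sex_inferred_from_calls(self):
        out = sp.classify_aneuploid(self._karyo(self.euploid_calls("XY")))
        assert out.sex == "XY" and not out.is_aneuploid
        out = sp.classify_aneuploid(self._karyo(self.euploid_calls("XX")))
        assert out.sex == "XX" and not out.is_aneuploid

    def test_irreconcilable_sex_autosomes_only(self):
        calls = self.euploid_calls("XX")
        calls["X"], calls["Y"] = 1, 0  # single X, no Y: neither XX nor XY
        calls["7"] = 3
        out = sp.classify_aneuploid(self._karyo(calls))
        assert out.sex == "unknown"
        assert "sex_unresolved_autosomes_only" in out.flags
        assert out.gained == ["7"]
        assert "X" not in out.expected_cn


class TestFocalScan:
    def test_euploid_app_region_max_two(self, grch_grid):
        states = np.full(grch_grid.n_bins, 2)
        scan, max_state = sp.focal_scan(fake_fit(states), grch_grid, "APP", scale=5)
        assert len(scan) >= 1
        assert max_state == 2

    def test_planted_focal_amplification_detected(self, grch_grid):
        states = np.full(grch_grid.n_bins, 2)
        chr21_idx = np.flatnonzero(grch_grid.df["chrom"].to_numpy() == "21")
        scan, _ = sp.focal_scan(fake_fit(states), grch_grid, "APP", scale=5)
        target = scan["bin_index"].iloc[0]
        states[target] = 5
        _, max_state = sp.focal_scan(fake_fit(states), grch_grid, "APP", scale=5)
        assert max_state == 5

    def test_subbin_region_returns_single_bin(self, grch_grid):
        start = int(grch_grid.df["start"].iloc[0]) + 10
        scan, _ = sp.focal_scan(
            fake_fit(np.full(grch_grid.n_bins, 2)),
            grch_grid,
            ("1", start, start + 100),
        )
        assert len(scan) == 1

    def test_region_string_parsing_and_missing_overlap(self, grch_grid):
        states = fake_fit(np.full(grch_grid.n_bins, 2))
        scan, m = sp.focal_scan(states, grch_grid, "1:0-1,000,000")
        assert m == 2
        with pytest.raises(ValueError):
            sp.focal_scan(states, grch_grid, "chrUn:0-100")


class TestPrevalence:
    def test_ad_cohort_interval(self):
        """5 aneuploid of 893 cells: 0.6 % with 95 % CI [0.2, 1.3]."""
        prev, lo, hi = sp.aneuploidy_prevalence((5, 893))
        assert round(prev, 1) == 0.6
        assert prev == pytest.approx(100 * 5 / 893)
        assert round(lo, 1) == 0.2 and round(hi, 1) == 1.3
        assert lo == pytest.approx(0.182, abs=0.01)
        assert hi == pytest.approx(1.305, abs=0.01)

    def test_zero_events_interval_starts_at_zero(self):
        prev, lo, hi = sp.aneuploidy_prevalence((0, 100))
        assert prev == 0.0 and lo == 0.0 and hi > 0

    def test_per_sample_percentage(self):
        prev, _, _ = sp.aneuploidy_prevalence((4, 72))
        assert round(prev, 2) == 5.56

    def test_accepts_call_objects(self):
        calls = [
            sp.AneuploidyCall("a", True, gained=["18"]),
            sp.AneuploidyCall("b", False),
        ]
        prev, lo, hi = sp.aneuploidy_prevalence(calls)
        assert prev == 50.0 and lo < 50.0 < hi


class TestPerChromosomeRates:
    def test_control_cohort_chr16_rate(self):
        """Two of 589 control cells involve chr16 gains: 0.34 % total."""
        calls = [sp.AneuploidyCall(f"c{i}", False) for i in range(585)]
        calls += [
            sp.AneuploidyCall("a1", True, gained=["18"]),
            sp.AneuploidyCall("a2", True, lost=["6"]),
            sp.AneuploidyCall("a3", True, gained=["4", "16"]),
            sp.AneuploidyCall("a4", True, gained=["13", "16", "21", "22"]),
        ]
        rates = sp.per_chromosome_rates(calls).set_index("chrom")
        assert round(rates.loc["16", "total_pct"], 2) == 0.34
        assert rates.loc["5", "total_pct"] == 0.0
        # the double-gain cell contributes once to chr4 and once to chr16
        assert round(rates.loc["4", "gain_pct"], 2) == 0.17
        assert rates["total_pct"].max() == pytest.approx(100 * 2 / 589, rel=1e-9)

    def test_gain_and_loss_split(self):
        calls = [
            sp.AneuploidyCall("a", True, gained=["1"], lost=["2"]),
            sp.AneuploidyCall("b", False),
        ]
        rates = sp.per_chromosome_rates(calls).set_index("chrom")
        assert rates.loc["1", "gain_pct"] == 50.0
        assert rates.loc["2", "loss_pct"] == 50.0
        assert rates.loc["1", "loss_pct"] == 0.0


def exact_ranksum_p(a, b):
    """Exhaustive two-sided rank-sum p-value over all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1
    n_a = len(a)
    observed = ranks[:n_a].sum()
    mean = n_a * (len(pooled) + 1) / 2
    stats = [
        sum(combo)
        for combo in itertools.combinations(ranks, n_a)
    ]
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestWilcoxon:
    def test_identical_vectors_p_one(self):
        assert sp.compare_rates_wilcoxon([1.0, 1.0, 2.0], [1.0, 1.0, 2.0]) == 1.0

    def test_fully_separated_small_groups(self):
        """[1,2,3] vs [4,5,6]: the most extreme of C(6,3)=20 assignments."""
        p = sp.compare_rates_wilcoxon([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_ranksum_p(np.array([1., 2, 3]), np.array([4., 5, 6])))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_approximation_close_to_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        exact = exact_ranksum_p(a, b)
        from scipy.stats import mannwhitneyu
        approx = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert abs(approx - exact) < 0.02
        # the dispatcher picks the exact route here (n <= 10, no ties)
        assert sp.compare_rates_wilcoxon(a, b) == pytest.approx(exact)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sp.compare_rates_wilcoxon([], [1.0])


def _cells_table(rows):
    return pd.DataFrame(
        rows, columns=["cell_id", "sample", "cohort", "qc_pass", "call"]
    )


def make_cells(sample, cohort, n, n_aneuploid=0, start=0):
    rows = []
    for i in range(n):
        cid = f"{sample}_{start + i}"
        call = sp.AneuploidyCall(cid, i < n_aneuploid,
                                 gained=["18"] if i < n_aneuploid else [])
        rows.append((cid, sample, cohort, True, call))
    return rows


class TestCohortSummary:
    def test_control_cohort_matches_printed_arithmetic(self):
        """Six control samples, 4 aneuploid cells in the 72-cell sample."""
        rows = []
        for name, n, x in [
            ("Control 1", 81, 0), ("Control 2", 80, 0), ("Control 3", 108, 0),
            ("Control 4", 72, 4), ("Control 5", 128, 0), ("Control 6", 120, 0),
        ]:
            rows += make_cells(name, "control", n, x)
        summary = sp.build_cohort_summary(_cells_table(rows))
        pooled = summary.pooled.iloc[0]
        assert pooled["n_cells"] == 589
        assert pooled["prevalence_pct"] == 0.7
        per_sample = summary.per_sample.set_index("sample")
        assert per_sample.loc["Control 4", "percent"] == 5.56
        assert per_sample.loc["Control 1", "percent"] == 0.0

    def test_qc_failing_cells_excluded_everywhere(self):
        rows = make_cells("S1", "ad", 10, 1)
        bad_call = sp.AneuploidyCall("S1_bad", True, gained=["21"])
        rows.append(("S1_bad", "S1", "ad", False, bad_call))
        summary = sp.build_cohort_summary(_cells_table(rows))
        pooled = summary.pooled.iloc[0]
        assert pooled["n_cells"] == 10
        assert pooled["n_aneuploid"] == 1

    def test_empty_sample_excluded_with_warning(self):
        rows = make_cells("S1", "ad", 5)
        failed_call = sp.AneuploidyCall("S2_0", False)
        rows.append(("S2_0", "S2", "ad", False, failed_call))
        with pytest.warns(UserWarning, match="no QC-passing cells"):
            summary = sp.build_cohort_summary(_cells_table(rows))
        assert list(summary.per_sample["sample"]) == ["S1"]

    def test_missing_cohort_label_rejected(self):
        rows = make_cells("S1", None, 3)
        with pytest.raises(ValueError, match="cohort"):
            sp.build_cohort_summary(_cells_table(rows))


class TestClopperPearsonCoverage:
    def test_empirical_coverage_at_study_prevalence(self):
        """Exact interval covers p = 0.007 in >= 95 % of 2000 draws at n = 589."""
        rng = np.random.default_rng(42)
        p_true, n = 0.007, 589
        covered = 0
        draws = rng.binomial(n, p_true, size=2000)
        for x in np.unique(draws):
            _, lo, hi = sp.aneuploidy_prevalence((int(x), n))
            inside = lo <= 100 * p_true <= hi
            covered += inside * np.sum(draws == x)
        assert covered / 2000 >= 0.95


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_per_sample_counts_match_truth(self, seed):
        """Simulated cohort -> full pipeline -> summary equals programmed truth."""
        grid = sp.simulate_grch37_grid(seed=seed)
        config = sp.SimulationConfig(seed=seed)
        spec = [
            ("S1", 8, sp.KaryotypeSpec.euploid("XY")),
            ("S2", 8, [(6 / 8, sp.KaryotypeSpec.euploid("XX")),
                       (2 / 8, sp.KaryotypeSpec.trisomy("18", "XX"))]),
            ("S3", 8, sp.KaryotypeSpec.euploid("XX")),
        ]
        cells, truth = sp.simulate_cohort(grid, spec, config)
        truth = truth.set_index("cell_id")
        rows = []
        for cell in cells:
            fit = sp.fit_copy_number_hmm(
                sp.gc_correct(cell, grid).observable(), grid
            )
            karyo = sp.call_chromosomes(fit, grid, cell_id=cell.cell_id, sex=cell.sex)
            call = sp.classify_aneuploid(karyo)
            rows.append((cell.cell_id, cell.sample, "cohort", True, call))
            # the decoded whole-chromosome karyotype equals the programmed one
            expected_aneuploid = bool(truth.loc[cell.cell_id, "cn_18"] == 3)
            assert call.is_aneuploid == expected_aneuploid
        summary = sp.build_cohort_summary(_cells_table(rows))
        per_sample = summary.per_sample.set_index("sample")
        truth_counts = (
            truth.reset_index()
            .assign(aneu=lambda d: d["cn_18"] == 3)
            .groupby("sample")["aneu"].sum()
        )
        for sample in ("S1", "S2", "S3"):
            assert per_sample.loc[sample, "n_aneuploid"] == truth_counts[sample]
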