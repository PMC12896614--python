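"""Consensus peak construction, weighted counts, TMM, voom, outliers, annotation."""

import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_consensus, brute_force_tmm
from clonediff.atac import (
    CALL_COLUMNS,
    ConsensusPeak,
    InsufficientReplicationError,
    annotate_peaks,
    build_consensus,
    detect_outlier_peaks,
    filter_low_counts,
    tmm_factors,
    voom_transform,
    weighted_counts,
)


def _calls(rows_by_clone: dict[str, list[tuple]]) -> dict[str, pd.DataFrame]:
    """rows are (chrom, start, end, name, score, count)."""
    return {
        clone: pd.DataFrame(rows, columns=CALL_COLUMNS)
        for clone, rows in rows_by_clone.items()
    }



class TestBuildConsensus:
    def test_single_clone_peak_dropped(self):
        calls = _calls({
            "A": [("chr1", 100, 200, "a1", 5.0, 30)],
            "B": [("chr1", 900, 1000, "b1", 5.0, 30)],
        })
        assert build_consensus(calls) == []

    def test_highest_spm_member_wins(self):
        # one cluster; equal per-clone totals so spm ranks like raw score
        calls = _calls({
            "A": [("chr1", 100, 200, "a1", 5.0, 10)],
            "B": [("chr1", 150, 260, "b1", 10.0, 10)],
            "C": [("chr1", 180, 240, "c1", 7.0, 10)],
        })
        peaks = build_consensus(calls, min_score_per_million=0.0)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end, peaks[0].source_clone) == (150, 260, "B")
        assert peaks[0].supporting_clones == frozenset("ABC")

    def test_chained_overlap_forms_single_cluster(self):
        # A and C disjoint but both overlap B -> one cluster of 3
        calls = _calls({
            "A": [("chr1", 100, 200, "a1", 5.0, 10)],
            "B": [("chr1", 190, 310, "b1", 5.0, 10)],
            "C": [("chr1", 300, 400, "c1", 5.0, 10)],
        })
        peaks = build_consensus(calls, min_score_per_million=0.0)
        assert len(peaks) == 1
        assert peaks[0].supporting_clones == frozenset("ABC")

    def test_clone_order_invariance(self, atac_sim):
        _, calls = atac_sim
        fwd = build_consensus(calls)
        rev = build_consensus(dict(reversed(list(calls.items()))))
        assert [(p.chrom, p.start, p.end, p.source_clone) for p in fwd] == [
            (p.chrom, p.start, p.end, p.source_clone) for p in rev
        ]

    @pytest.mark.parametrize("seed", range(20))
    def test_random_configs_match_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_clones = rng.integers(2, 6)
        calls = {}
        for c in range(n_clones):
            n_peaks = rng.integers(1, 21)
            starts = np.sort(rng.choice(5000, n_peaks, replace=False)) * 3
            widths = rng.integers(10, 200, n_peaks)
            # enforce within-clone non-overlap by capping width at the gap
            gaps = np.diff(np.append(starts, starts[-1] + 10_000))
            widths = np.minimum(widths, np.maximum(gaps - 1, 1))
            rows = [
                ("chr1", int(s), int(s + w), f"c{c}p{i}",
                 float(rng.integers(1, 100)), int(rng.integers(1, 500)))
                for i, (s, w) in enumerate(zip(starts, widths))
            ]
            calls[f"clone{c}"] = pd.DataFrame(rows, columns=CALL_COLUMNS)
        mine = build_consensus(calls, min_clones=2, min_score_per_million=1.0)
        oracle = brute_force_consensus(calls, min_clones=2, min_spm=1.0)
        assert len(mine) == len(oracle)
        oracle_sorted = sorted(oracle, key=lambda t: (t[0]["chrom"], t[0]["start"], t[0]["end"]))
        mine_sorted = sorted(mine, key=lambda p: (p.chrom, p.start, p.end))
        for got, (best, names, clones) in zip(mine_sorted, oracle_sorted):
            assert (got.chrom, got.start, got.end) == (best["chrom"], best["start"], best["end"])
            assert got.source_clone == best["clone"]
            assert got.supporting_clones == clones
            assert got.source_score_per_million == pytest.approx(best["spm"])


class TestWeightedCounts:
    def _one_peak(self):
        return [ConsensusPeak("p", "chr1", 150, 250, "A", 10.0, frozenset("AB"))]

    def test_identical_interval_full_count(self):
        calls = _calls({"A": [("chr1", 150, 250, "a", 5.0, 40)]})
        m = weighted_counts(self._one_peak(), calls)
        assert m.iloc[0, 0] == pytest.approx(40.0)

    def test_half_overlap_half_count(self):
        calls = _calls({"A": [("chr1", 100, 200, "a", 5.0, 40)]})
        m = weighted_counts(self._one_peak(), calls)
        assert m.iloc[0, 0] == pytest.approx(20.0)

    def test_no_overlap_zero(self):
        calls = _calls({"A": [("chr1", 300, 400, "a", 5.0, 40)]})
        m = weighted_counts(self._one_peak(), calls)
        assert m.iloc[0, 0] == 0.0

    def test_never_exceeds_raw_clone_total(self, atac_sim):
        _, calls = atac_sim
        consensus = build_consensus(calls)
        m = weighted_counts(consensus, calls)
        for clone in m.columns:
            assert m[clone].sum() <= calls[clone]["count"].sum() + 1e-9


class TestFilterLowCounts:
    @pytest.mark.parametrize(
        "counts,kept",
        [([12, 15, 11, 13], True), ([9, 9, 12, 15], False), ([10, 10, 10, 10], True)],
    )
    def test_boundary_rule(self, counts, kept):
        m = pd.DataFrame([counts], index=["p"], dtype=float)
        out = filter_low_counts(m)
        assert ("p" in out.index) == kept



class TestTMM:
    def test_identical_columns_unit_factors(self):
        m = pd.DataFrame({"A": [10.0, 50, 100, 20], "B": [10.0, 50, 100, 20]})
        assert np.allclose(tmm_factors(m), 1.0)

    def test_pure_depth_scaling_leaves_factors_at_one(self):
        rng = np.random.default_rng(7)
        base = rng.integers(10, 1000, 50).astype(float)
        m = pd.DataFrame({"A": base, "B": base * 3.0, "C": base})
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_straight_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 2000, (20, 4)).astype(float))
        m.iloc[:, 0] *= 2.5  # composition shift so trimming is exercised
        got = tmm_factors(m).to_numpy()
        want = brute_force_tmm(m.to_numpy())
        assert np.allclose(got, want, atol=1e-10)

    def test_geometric_mean_one(self, atac_sim):
        _, calls = atac_sim
        counts = weighted_counts(build_consensus(calls), calls)
        f = tmm_factors(filter_low_counts(counts))
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)


class TestVoom:
    def test_log_cpm_formula_for_zero_count(self):
        # column sums of 1e6 with a zero entry in the first row
        m = pd.DataFrame({"A": [0.0, 1e6], "B": [0.0, 1e6]})
        log_cpm, _ = voom_transform(m, pd.Series({"A": 1.0, "B": 1.0}))
        assert log_cpm.iloc[0, 0] == pytest.approx(np.log2(0.5 / (1e6 + 1) * 1e6))
        assert log_cpm.iloc[0, 0] == pytest.approx(-1.0000014, abs=1e-6)

    def test_constant_matrix_equal_weights(self):
        m = pd.DataFrame(np.full((5, 4), 100.0))
        _, w = voom_transform(m, pd.Series(1.0, index=m.columns))
        assert np.allclose(w, w.iloc[0, 0])

    def test_planted_trend_gives_decreasing_weights(self):
        """With residual variance rising in the mean, precision weights fall."""
        rng = np.random.default_rng(8)
        n_rows, n_cols = 200, 10
        mean_level = np.linspace(4, 12, n_rows)
        noise_sd = np.linspace(0.05, 1.0, n_rows)
        log_counts = mean_level[:, None] + rng.normal(0, 1, (n_rows, n_cols)) * noise_sd[:, None]
        m = pd.DataFrame(2.0 ** log_counts)
        _, w = voom_transform(m, pd.Series(1.0, index=m.columns))
        from scipy.stats import spearmanr

        rho = spearmanr(mean_level, w.mean(axis=1)).statistic
        assert rho < -0.95

    def test_rejects_single_sample(self):
        with pytest.raises(InsufficientReplicationError):
            voom_transform(pd.DataFrame({"A": [1.0]}), pd.Series({"A": 1.0}))


class TestOutlierDetection:
    def test_single_extreme_sample_flagged_and_excluded(self):
        m = pd.DataFrame([[10.0, 11, 9, 10, 100]], index=["p"])
        flags, excluded = detect_outlier_peaks(m)
        assert flags.loc["p"].tolist() == [False, False, False, False, True]
        assert excluded == ["p"]

    def test_constant_row_not_flagged(self):
        m = pd.DataFrame([[5.0, 5, 5, 5]], index=["p"])
        flags, excluded = detect_outlier_peaks(m)
        assert not flags.to_numpy().any() and excluded == []

    def test_two_high_samples_not_a_singleton(self):
        m = pd.DataFrame([[10.0, 11, 100, 110]], index=["p"])
        flags, excluded = detect_outlier_peaks(m)
        assert not flags.to_numpy().any() and excluded == []

    def test_low_singleton_also_flagged(self):
        m = pd.DataFrame([[100.0, 101, 99, 100, 1]], index=["p"])
        flags, excluded = detect_outlier_peaks(m)
        assert flags.loc["p"].tolist() == [False, False, False, False, True]


class TestAnnotatePeaks:
    GENES = pd.DataFrame(
        [("G1", "chr1", 10_000, 12_000, "+")],
        columns=["gene", "chrom", "start", "end", "strand"],
    )

    def _peak(self, start, end, chrom="chr1"):
        return ConsensusPeak("p", chrom, start, end, "A", 10.0, frozenset("AB"))

    def test_within_window_upstream_is_genic(self):
        out = annotate_peaks([self._peak(8_000, 8_500)], self.GENES)
        assert out.loc[0, "category"] == "genic"
        assert out.loc[0, "distance"] == 1_500

    def test_far_peak_is_intergenic(self):
        out = annotate_peaks([self._peak(17_000, 17_500)], self.GENES)
        assert out.loc[0, "category"] == "intergenic"

    def test_exact_window_boundary_is_genic(self):
        out = annotate_peaks([self._peak(7_500, 8_000)], self.GENES)
        assert out.loc[0, "distance"] == 2_000
        assert out.loc[0, "category"] == "genic"

    def test_overlapping_peak_distance_zero(self):
        out = annotate_peaks([self._peak(11_000, 11_500)], self.GENES)
        assert out.loc[0, "distance"] == 0

    def test_missing_chromosome_warns_intergenic(self):
        with pytest.warns(UserWarning):
            out = annotate_peaks([self._peak(100, 200, chrom="chrX")], self.GENES)
        assert out.loc[0, "category"] == "intergenic"
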