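"""Detection rules, two-pass reduction, and upper-quartile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonediff.expression import (
    CoverageMatrix,
    DegenerateLibraryError,
    EmptyInputError,
    ExpressionMatrix,
    FeatureCatalog,
    InvalidFeatureError,
    MappingError,
    compute_apn,
    flag_detected_features,
    flag_detected_transcripts,
    gene_expressed,
    reduce_transcriptome,
    second_pass,
    upper_quartile_log,
)


@pytest.mark.parametrize(
    "depth,length,expected",
    [(300, 150, 2.0), (0, 100, 0.0), (137, 261, 137 / 261)],
)
def test_compute_apn(depth, length, expected):
    assert compute_apn(depth, length) == pytest.approx(expected)


def test_compute_apn_rejects_bad_length():
    with pytest.raises(InvalidFeatureError):
        compute_apn(10, 0)


def _coverage(support: np.ndarray) -> CoverageMatrix:
    df = pd.DataFrame(support,
                      index=[f"F{i}" for i in range(support.shape[0])],
                      columns=[f"C{j}" for j in range(support.shape[1])])
    return CoverageMatrix(apn=df.astype(float), read_support=df)


class TestFeatureDetection:
    def test_boundary_half_of_clones_is_detected(self):
        cov = _coverage(np.array([[1, 1, 0, 0], [1, 0, 0, 0]]))
        flags = flag_detected_features(cov)
        assert flags.tolist() == [True, False]

    def test_empty_matrix_rejected(self):
        cov = _coverage(np.empty((0, 0), dtype=int))
        with pytest.raises(EmptyInputError):
            flag_detected_features(cov)

    def test_random_matrix_matches_row_scan_oracle(self):
        rng = np.random.default_rng(0)
        support = rng.integers(0, 3, (20, 6))
        flags = flag_detected_features(_coverage(support))
        for i in range(20):
            expected = sum(1 for v in support[i] if v >= 1) / 6 >= 0.5
            assert flags.iloc[i] == expected


def _catalog(memberships: dict[str, list[str]], genes: dict[str, str]) -> FeatureCatalog:
    rows = []
    feat_members: dict[str, list[str]] = {}
    for t, feats in memberships.items():
        for f in feats:
            feat_members.setdefault(f, []).append(t)
    for f, ts in feat_members.items():
        rows.append((f, "exonic_fragment", 100, tuple(ts)))
    tab = pd.DataFrame(rows, columns=["feature", "kind", "length", "transcripts"])
    return FeatureCatalog(tab.set_index("feature"), pd.Series(genes, name="gene"))


class TestReduceTranscriptome:
    def test_fully_detected_transcript_retained(self):
        cat = _catalog({"T1": [f"F{i}" for i in range(5)]}, {"T1": "G1"})
        flags = pd.Series(True, index=cat.features.index)
        assert reduce_transcriptome(cat, flags).transcripts == ["T1"]

    def test_one_undetected_feature_drops_transcript(self):
        cat = _catalog({"T1": [f"F{i}" for i in range(5)]}, {"T1": "G1"})
        flags = pd.Series([True] * 4 + [False], index=cat.features.index)
        assert reduce_transcriptome(cat, flags).transcripts == []

    def test_random_catalog_matches_all_oracle(self):
        rng = np.random.default_rng(1)
        memberships = {
            f"T{i}": [f"F{j}" for j in rng.choice(30, rng.integers(1, 6), replace=False)]
            for i in range(50)
        }
        genes = {t: f"G{i % 10}" for i, t in enumerate(memberships)}
        cat = _catalog(memberships, genes)
        flags = pd.Series(rng.random(len(cat.features)) < 0.7, index=cat.features.index)
        kept = set(reduce_transcriptome(cat, flags).transcripts)
        for t, feats in memberships.items():
            assert (t in kept) == all(flags[f] for f in feats)

    @given(extra=st.sets(st.integers(0, 29), max_size=10))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_detected_features(self, extra):
        """Turning additional features detected never removes a retained transcript."""
        rng = np.random.default_rng(2)
        memberships = {
            f"T{i}": [f"F{j}" for j in rng.choice(30, rng.integers(1, 5), replace=False)]
            for i in range(25)
        }
        genes = {t: f"G{i % 5}" for i, t in enumerate(memberships)}
        cat = _catalog(memberships, genes)
        base = pd.Series(rng.random(len(cat.features)) < 0.5, index=cat.features.index)
        more = base.copy()
        for j in extra:
            fid = f"F{j}"
            if fid in more.index:
                more[fid] = True
        before = set(reduce_transcriptome(cat, base).transcripts)
        after = set(reduce_transcriptome(cat, more).transcripts)
        assert before <= after


class TestTranscriptDetection:
    def test_boundary_and_zero_rows(self):
        tpm = pd.DataFrame(
            [[1.0] * 12 + [0.0] * 12, [0.0] * 24],
            index=["T1", "T2"], columns=[f"C{i}" for i in range(24)],
        )
        flags = flag_detected_transcripts(ExpressionMatrix(tpm))
        assert flags.tolist() == [True, False]

    def test_random_matrix_matches_positive_count_oracle(self):
        rng = np.random.default_rng(3)
        tpm = pd.DataFrame(rng.random((15, 7)) * (rng.random((15, 7)) < 0.5))
        flags = flag_detected_transcripts(ExpressionMatrix(tpm))
        for i in range(15):
            assert flags.iloc[i] == ((tpm.iloc[i] > 0).sum() / 7 >= 0.5)

    def test_invariant_to_clone_order(self):
        rng = np.random.default_rng(4)
        tpm = pd.DataFrame(rng.random((10, 6)) * (rng.random((10, 6)) < 0.6),
                           columns=[f"C{i}" for i in range(6)])
        a = flag_detected_transcripts(ExpressionMatrix(tpm))
        b = flag_detected_transcripts(ExpressionMatrix(tpm[tpm.columns[::-1]]))
        assert a.equals(b)


class TestGeneExpressed:
    def test_any_detected_transcript_marks_gene(self):
        flags = pd.Series({"T1": True, "T2": False, "T3": False, "T4": False})
        t2g = pd.Series({"T1": "G1", "T2": "G1", "T3": "G1", "T4": "G2"})
        out = gene_expressed(flags, t2g)
        assert out["G1"] and not out["G2"]

    def test_orphan_transcript_rejected(self):
        with pytest.raises(MappingError):
            gene_expressed(pd.Series({"T9": True}), pd.Series({"T1": "G1"}))

    def test_random_assignment_matches_union_oracle(self):
        rng = np.random.default_rng(5)
        t2g = pd.Series({f"T{i}": f"G{i % 8}" for i in range(40)})
        flags = pd.Series(rng.random(40) < 0.3, index=t2g.index)
        out = gene_expressed(flags, t2g)
        for g in out.index:
            assert out[g] == any(flags[t] for t in t2g.index[t2g == g])


class TestSecondPass:
    def _small(self):
        tpm = pd.DataFrame(
            {"C1": [10.0, 20.0, 5.0], "C2": [12.0, 18.0, 6.0]},
            index=["T1", "T2", "T3"],
        )
        cat = _catalog({"T1": ["F1"], "T2": ["F2"], "T3": ["F3"]},
                       {"T1": "G1", "T2": "G1", "T3": "G2"})
        return ExpressionMatrix(tpm), cat

    def test_identity_when_nothing_removed(self):
        expr, cat = self._small()
        out = second_pass(expr, cat)
        pd.testing.assert_frame_equal(out.transcripts.tpm, expr.tpm)
        assert out.genes.tpm.loc["G1"].tolist() == [30.0, 30.0]

    def test_removed_transcript_subtracts_from_gene(self):
        expr, cat = self._small()
        flags = pd.Series({"F1": True, "F2": False, "F3": True})
        reduced = reduce_transcriptome(cat, flags)
        out = second_pass(expr, reduced)
        # G1 loses exactly T2's TPM
        assert out.genes.tpm.loc["G1"].tolist() == [10.0, 12.0]

    def test_gene_absent_when_all_transcripts_removed(self):
        expr, cat = self._small()
        flags = pd.Series({"F1": True, "F2": True, "F3": False})
        out = second_pass(expr, reduce_transcriptome(cat, flags))
        assert "G2" not in out.genes.tpm.index

    def test_idempotent(self, expression_sim):
        cov, cat = expression_sim.coverage, expression_sim.catalog
        reduced = reduce_transcriptome(cat, flag_detected_features(cov))
        once = second_pass(expression_sim.expression, reduced)
        twice = second_pass(once.transcripts, reduced)
        pd.testing.assert_frame_equal(once.transcripts.tpm, twice.transcripts.tpm)
        pd.testing.assert_frame_equal(once.genes.tpm, twice.genes.tpm)

    def test_gene_tpm_is_exact_transcript_sum(self, expression_sim):
        cat = expression_sim.catalog
        out = second_pass(expression_sim.expression, cat)
        manual = expression_sim.expression.tpm.groupby(
            cat.transcript_to_gene.loc[expression_sim.expression.tpm.index]
        ).sum()
        pd.testing.assert_frame_equal(
            out.genes.tpm.sort_index(), manual.sort_index(), check_names=False
        )


class TestUpperQuartileLog:
    def test_identical_clones_reduce_to_log2_plus_one(self):
        tpm = pd.DataFrame({"C1": [4.0, 8.0, 0.0], "C2": [4.0, 8.0, 0.0]})
        out = upper_quartile_log(ExpressionMatrix(tpm))
        assert np.allclose(out.scale_factors, 1.0)
        assert np.allclose(out.normalized_log, np.log2(tpm + 1.0))

    def test_doubled_clone_has_doubled_factor(self):
        rng = np.random.default_rng(6)
        base = rng.random(30) * 100
        tpm = pd.DataFrame({"C1": base, "C2": 2 * base})
        out = upper_quartile_log(ExpressionMatrix(tpm))
        assert out.scale_factors["C2"] == pytest.approx(2 * out.scale_factors["C1"])

    def test_single_clone_factor_is_one(self):
        tpm = pd.DataFrame({"C1": [1.0, 5.0, 9.0, 13.0]})
        out = upper_quartile_log(ExpressionMatrix(tpm))
        assert out.scale_factors["C1"] == pytest.approx(1.0)

    def test_all_zero_clone_rejected(self):
        tpm = pd.DataFrame({"C1": [1.0, 2.0], "C2": [0.0, 0.0]})
        with pytest.raises(DegenerateLibraryError):
            upper_quartile_log(ExpressionMatrix(tpm))
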