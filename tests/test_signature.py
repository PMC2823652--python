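"""Signature extraction, projection, scoring and centroid correlation."""

import numpy as np
import pandas as pd
import pytest

from stromasig import (
    GeneSignature,
    ValidationError,
    centroid_correlation,
    continuous_score,
    extract_signature_foldchange,
    extract_signature_from_sam,
    label_cluster_groups,
    make_expression_matrix,
    project_signature,
)
from stromasig.simulate import CohortSimConfig, simulate_cohort
from stromasig.signature import ScoreResult


def _stim_matrix(values, symbols=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    half = m // 2
    return make_expression_matrix(
        values,
        [f"P{i}" for i in range(n)],
        [f"x{j}" for j in range(m)],
        gene_symbols=symbols or [f"G{i}" for i in range(n)],
        treatments=["unstimulated"] * half + ["stimulated"] * (m - half),
        pair_ids=[f"p{j % half}" for j in range(m)],
        cell_types=["f"] * m,
    )


class TestFoldChangeExtraction:
    def test_mean_fold_2_35_included(self):
        # log2(2.35) = 1.233 > log2(1.5): the study's mean induction passes
        m = _stim_matrix([[0.0, 0.0, np.log2(2.35), np.log2(2.35)]])
        sig = extract_signature_foldchange(m)
        assert sig.genes == ["G0"]

    def test_exact_threshold_excluded(self):
        m = _stim_matrix([[0.0, 0.0, np.log2(1.5), np.log2(1.5)]])
        sig = extract_signature_foldchange(m)
        assert sig.genes == []

    def test_planted_genes_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 100
        values = np.zeros((n, 6))
        induced = rng.choice(n, 30, replace=False)
        values[induced, 3:] = 1.2  # ~2.3-fold induction
        m = _stim_matrix(values)
        sig = extract_signature_foldchange(m)
        assert set(sig.genes) == {f"G{i}" for i in sorted(induced)}

    def test_ordered_by_induction_descending(self):
        values = np.zeros((3, 4))
        values[:, 2:] = np.array([[1.0], [3.0], [2.0]])
        m = _stim_matrix(values)
        sig = extract_signature_foldchange(m)
        assert sig.genes == ["G1", "G2", "G0"]

    def test_no_stimulated_samples_error(self):
        m = make_expression_matrix(
            [[1.0]], ["P1"], ["s1"], treatments=["unstimulated"], pair_ids=["p"]
        )
        with pytest.raises(ValidationError):
            extract_signature_foldchange(m)


class TestSamExtraction:
    class FakeResults:
        delta, fdr, s0 = 1.0, 0.0, 0.1

        class config:
            seed = 1

        def __init__(self, up):
            self.up_called = up
            self.down_called = []

    def test_empty_call_set_gives_empty_signature(self):
        sig = extract_signature_from_sam(self.FakeResults([]))
        assert len(sig) == 0

    def test_twelve_up_genes(self):
        sig = extract_signature_from_sam(
            self.FakeResults([f"G{i}" for i in range(12)])
        )
        assert len(sig) == 12

    def test_duplicate_clones_collapse_to_one_entry(self):
        m = _stim_matrix(np.zeros((3, 4)), symbols=["GA", "GA", "GB"])
        sig = extract_signature_from_sam(
            self.FakeResults(["P0", "P1", "P2"]), matrix=m
        )
        assert sig.genes == ["GA", "GB"]


class TestProjection:
    def _cohort(self, values, symbols):
        values = np.asarray(values, dtype=float)
        return make_expression_matrix(
            values,
            [f"C{i}" for i in range(values.shape[0])],
            [f"t{j}" for j in range(values.shape[1])],
            gene_symbols=symbols,
        )

    def test_full_presence_rows_centred(self):
        rng = np.random.default_rng(1)
        cohort = self._cohort(rng.normal(size=(4, 5)), ["GA", "GB", "GC", "GD"])
        sig = GeneSignature("s", ["GA", "GB", "GC"])
        projected, report = project_signature(sig, cohort)
        assert projected.n_genes == 3
        assert np.abs(np.nanmean(projected.values, axis=1)).max() < 1e-12
        assert report.missing == []

    def test_low_presence_gene_dropped(self):
        # 79% present (19 of 24) is not > 80%
        values = np.ones((2, 24))
        values[0, :5] = np.nan
        cohort = self._cohort(values, ["GA", "GB"])
        values2 = values.copy()
        sig = GeneSignature("s", ["GA", "GB"])
        projected, report = project_signature(sig, cohort)
        assert report.dropped_low_presence == ["GA"]
        assert projected.n_genes == 1

    def test_duplicate_probes_averaged(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(3, 4))
        cohort = self._cohort(values, ["GA", "GA", "GB"])
        sig = GeneSignature("s", ["GA"])
        projected, _ = project_signature(sig, cohort)
        oracle = values[:2].mean(axis=0)
        assert np.allclose(projected.values[0], oracle - oracle.mean())

    def test_unigene_fallback(self):
        cohort = make_expression_matrix(
            np.ones((1, 3)) * np.arange(3), ["C0"], ["t0", "t1", "t2"],
            gene_symbols=[""], unigene_ids=["HS.77"],
        )
        sig = GeneSignature("s", ["HS.77"])
        projected, report = project_signature(sig, cohort)
        assert report.found == ["HS.77"]

    def test_no_match_error(self):
        cohort = self._cohort(np.ones((1, 3)), ["GA"])
        with pytest.raises(ValidationError, match="matched"):
            project_signature(GeneSignature("s", ["ZZZ"]), cohort)


class TestContinuousScore:
    def _projected(self, values):
        values = np.asarray(values, dtype=float)
        return make_expression_matrix(
            values,
            [f"G{i}" for i in range(values.shape[0])],
            [f"t{j}" for j in range(values.shape[1])],
        )

    def test_constant_gene_values_give_that_score(self):
        res = continuous_score(self._projected([[2.5], [2.5], [2.5]]))
        assert res.scores.iloc[0] == pytest.approx(2.5)

    def test_median_tie_goes_low(self):
        res = continuous_score(self._projected([[1.0, 2.0, 3.0]]))
        assert res.low == ["t0", "t1"]
        assert res.high == ["t2"]

    def test_missing_aware_mean_oracle(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(3, 4))
        values[1, 2] = np.nan
        res = continuous_score(self._projected(values))
        for j in range(4):
            assert res.scores.iloc[j] == pytest.approx(np.nanmean(values[:, j]))

    def test_all_missing_sample_excluded(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan]])
        res = continuous_score(self._projected(values))
        assert np.isnan(res.scores["t1"])
        assert "t1" not in res.groups.index

    def test_score_invariant_to_gene_order_and_duplicates(self):
        rng = np.random.default_rng(4)
        cohort = make_expression_matrix(
            rng.normal(size=(5, 6)),
            [f"C{i}" for i in range(5)],
            [f"t{j}" for j in range(6)],
            gene_symbols=["GA", "GB", "GC", "GD", "GE"],
        )
        s1 = GeneSignature("a", ["GA", "GB", "GC"])
        s2 = GeneSignature("b", ["GC", "ga", "GB", "GA"])  # reordered + dup
        p1, _ = project_signature(s1, cohort)
        p2, _ = project_signature(s2, cohort)
        r1, r2 = continuous_score(p1), continuous_score(p2)
        assert np.allclose(
            r1.scores.to_numpy(), r2.scores.to_numpy(), atol=1e-12
        )

    def test_per_gene_shift_invariance_after_centring(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(4, 6))
        cohort = make_expression_matrix(
            values, [f"C{i}" for i in range(4)], [f"t{j}" for j in range(6)],
            gene_symbols=["GA", "GB", "GC", "GD"],
        )
        shifted = make_expression_matrix(
            values + rng.normal(size=(4, 1)),  # per-gene constant shifts
            [f"C{i}" for i in range(4)], [f"t{j}" for j in range(6)],
            gene_symbols=["GA", "GB", "GC", "GD"],
        )
        sig = GeneSignature("s", ["GA", "GB", "GC", "GD"])
        r1 = continuous_score(project_signature(sig, cohort)[0])
        r2 = continuous_score(project_signature(sig, shifted)[0])
        assert np.allclose(r1.scores.to_numpy(), r2.scores.to_numpy(), atol=1e-12)


class TestCentroidCorrelation:
    def _scores(self, vals):
        return pd.Series(vals, index=[f"t{i}" for i in range(len(vals))])

    def test_identical_vectors_r_one(self):
        s = self._scores([1.0, 2.0, 3.0, 4.0])
        cmp = centroid_correlation(s, s.copy())
        assert cmp.r == pytest.approx(1.0)

    def test_negated_vector_r_minus_one(self):
        s = self._scores([1.0, 2.0, 3.0, 4.0])
        cmp = centroid_correlation(s, -s)
        assert cmp.r == pytest.approx(-1.0)

    def test_toy_vectors_match_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        cmp = centroid_correlation(self._scores(x), self._scores(y))
        xc, yc = x - x.mean(), y - y.mean()
        r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert cmp.r == pytest.approx(r, abs=1e-12)
        assert -1.0 <= cmp.r <= 1.0

    def test_constant_vector_error(self):
        with pytest.raises(ValidationError, match="constant"):
            centroid_correlation(
                self._scores([1.0, 1.0, 1.0]), self._scores([1.0, 2.0, 3.0])
            )


class TestLabelClusterGroups:
    def _projected(self, values):
        values = np.asarray(values, dtype=float)
        return make_expression_matrix(
            values,
            [f"G{i}" for i in range(values.shape[0])],
            [f"t{j}" for j in range(values.shape[1])],
        )

    def test_higher_mean_group_is_high(self):
        proj = self._projected([[0.5, 0.5, -0.5, -0.5]])
        out = label_cluster_groups(["t0", "t1"], ["t2", "t3"], proj)
        assert out["high"] == ["t0", "t1"]

    def test_tie_broken_toward_larger_group(self):
        proj = self._projected([[1.0, 1.0, 1.0]])
        out = label_cluster_groups(["t0"], ["t1", "t2"], proj)
        assert out["high"] == ["t1", "t2"]

    def test_labelling_matches_planted_activity_sign(self):
        hits = 0
        for seed in range(10):
            cfg = CohortSimConfig(
                n_samples=40, n_genes=50, signature_size=25,
                activity_dist="bimodal", noise_sd=0.4, seed=seed,
            )
            matrix, _, sig, truth = simulate_cohort(cfg)
            from stromasig import cluster_axis, cut_two_groups

            projected, _ = project_signature(sig, matrix)
            ga, gb = cut_two_groups(cluster_axis(projected, axis="samples"))
            out = label_cluster_groups(ga, gb, projected)
            high_activity = truth.activity[out["high"]].mean()
            low_activity = truth.activity[out["low"]].mean()
            hits += high_activity > low_activity
        assert hits >= 9
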