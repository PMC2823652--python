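"""Paired SAM: statistic, fudge factor, permutation null, calling, FDR.

The brute-force oracle used here re-implements every quantity with
plain loops and explicit enumeration of all sign-flip vectors, entirely
independently of the package code paths.
"""

import itertools
import math

import numpy as np
import pytest

from stromasig import PairedSAM, SamConfig, ValidationError
from stromasig.sam import (
    call_significant,
    choose_delta_for_fdr,
    choose_s0,
    estimate_pi0,
    paired_d_statistics,
    permutation_null,
    sign_flip_vectors,
)
from stromasig.simulate import StimulationSimConfig, simulate_stimulation_experiment


# --------------------------------------------------- brute-force oracle
def oracle_d(z_row, s0):
    z = [v for v in z_row if not math.isnan(v)]
    m = len(z)
    zbar = sum(z) / m
    s = math.sqrt(sum((v - zbar) ** 2 for v in z) / (m * (m - 1)))
    return zbar / (s + s0)


def oracle_null(z, s0):
    """All sign flips, each row of d sorted; returns (dbar, null_sorted)."""
    n, m = z.shape
    rows = []
    for eps in itertools.product([1.0, -1.0], repeat=m):
        d = sorted(oracle_d(z[i] * np.array(eps), s0) for i in range(n))
        rows.append(d)
    arr = np.array(rows)
    return arr.mean(axis=0), arr


# ------------------------------------------------------------ statistic
class TestPairedD:
    def test_zero_differences_give_zero(self):
        z = np.zeros((1, 4))
        assert paired_d_statistics(z, 0.5)[0] == 0.0

    def test_constant_differences_exact_value(self):
        z = np.array([[2.0, 2.0, 2.0, 2.0]])
        # s = 0, so d = 2 / 0.5
        assert paired_d_statistics(z, 0.5)[0] == pytest.approx(4.0)

    def test_random_rows_match_formula_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(20, 5))
        d = paired_d_statistics(z, 0.3)
        for i in range(20):
            assert d[i] == pytest.approx(oracle_d(z[i], 0.3), abs=1e-12)

    def test_negative_s0_rejected(self):
        with pytest.raises(ValidationError):
            paired_d_statistics(np.ones((2, 3)), -0.1)


class TestChooseS0:
    def test_identical_scatter_returns_it(self):
        rng = np.random.default_rng(2)
        # all rows are permutations of the same values: identical s
        base = np.array([-1.0, 0.0, 1.0, 2.0])
        z = np.array([rng.permutation(base) for _ in range(30)])
        assert choose_s0(z) == pytest.approx(
            math.sqrt(sum((v - 0.5) ** 2 for v in base) / 12)
        )

    def test_all_zero_scatter_floor(self):
        z = np.tile(np.array([[1.0, 1.0, 1.0]]), (12, 1)) * np.arange(1, 13)[:, None]
        # every row constant -> s = 0 everywhere
        assert choose_s0(z) == pytest.approx(1e-8)

    def test_grid_search_matches_exhaustive_oracle(self):
        from scipy.stats import median_abs_deviation

        rng = np.random.default_rng(3)
        z = rng.normal(size=(500, 4)) * rng.uniform(0.2, 2.0, size=(500, 1))
        got = choose_s0(z)
        # oracle: same documented grid and binning, written independently
        zbar = z.mean(axis=1)
        s = np.sqrt(((z - zbar[:, None]) ** 2).sum(axis=1) / (4 * 3))
        edges = np.quantile(s, np.linspace(0, 1, 11))
        bins = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
        best, best_cv = None, np.inf
        for cand in np.percentile(s, np.arange(0, 101, 5)):
            d = zbar / (s + cand)
            mads = [
                median_abs_deviation(d[bins == b], scale="normal")
                for b in range(10)
                if (bins == b).sum() >= 2
            ]
            cv = np.std(mads) / np.mean(mads)
            if cv < best_cv - 1e-15:
                best, best_cv = cand, cv
        assert got == pytest.approx(best)


# ----------------------------------------------------------------- null
class TestPermutationNull:
    def test_m3_enumerates_eight_vectors(self):
        flips, enumerated = sign_flip_vectors(3)
        assert enumerated
        assert flips.shape == (8, 3)
        assert len({tuple(row) for row in flips}) == 8

    def test_enumeration_antisymmetric_order_stats(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(15, 3))
        dbar, _, _ = permutation_null(z, 0.2)
        assert np.allclose(dbar, -dbar[::-1], atol=1e-12)

    def test_m4_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(12, 4))
        dbar, null_sorted, enumerated = permutation_null(z, 0.25)
        assert enumerated and null_sorted.shape == (16, 12)
        o_dbar, o_null = oracle_null(z, 0.25)
        assert np.allclose(dbar, o_dbar, atol=1e-12)
        assert np.allclose(np.sort(null_sorted, axis=0), np.sort(o_null, axis=0))

    def test_single_pair_rejected(self):
        with pytest.raises(ValidationError):
            sign_flip_vectors(1)


# -------------------------------------------------------------- calling
class TestCalling:
    @pytest.fixture
    def planted(self):
        rng = np.random.default_rng(6)
        z = rng.normal(0, 0.3, size=(200, 4))
        z[:20] += 2.0  # 20 true up-regulated genes
        d = paired_d_statistics(z, 0.2)
        dbar, null_sorted, _ = permutation_null(z, 0.2)
        return z, d, dbar, null_sorted

    def test_huge_delta_calls_nothing(self, planted):
        _, d, dbar, null_sorted = planted
        big = np.max(np.abs(np.sort(d) - dbar)) + 1.0
        up, down, fdr, _ = call_significant(d, dbar, big, null_sorted)
        assert up.sum() == 0 and down.sum() == 0 and fdr == 0.0

    def test_zero_delta_calls_everything_beyond_crossing(self, planted):
        _, d, dbar, null_sorted = planted
        up, down, _, cuts = call_significant(d, dbar, 0.0, null_sorted)
        # with delta = 0 the cut points sit at the crossing itself
        assert up.sum() + down.sum() > 0
        assert np.all(d[up] >= cuts[1]) and np.all(d[down] <= cuts[0])

    def test_calls_and_fdr_match_literal_rewalk_oracle(self, planted):
        _, d, dbar, null_sorted = planted
        pi0 = estimate_pi0(d, null_sorted)
        for delta in (0.3, 0.8, 1.5):
            up, down, fdr, cuts = call_significant(d, dbar, delta, null_sorted, pi0)
            # oracle: literal re-walk of the sorted arrays
            ds = np.sort(d)
            diff = ds - dbar
            centre = next(i for i in range(len(ds)) if ds[i] >= 0)
            iu = next((i for i in range(centre, len(ds)) if diff[i] >= delta), None)
            idn = next((i for i in range(centre - 1, -1, -1) if -diff[i] >= delta), None)
            cut_up = ds[iu] if iu is not None else np.inf
            cut_lo = ds[idn] if idn is not None else -np.inf
            exp_up = d >= cut_up
            exp_down = d <= cut_lo
            assert np.array_equal(up, exp_up)
            assert np.array_equal(down, exp_down)
            n_called = exp_up.sum() + exp_down.sum()
            counts = [
                int(((row >= cut_up) | (row <= cut_lo)).sum()) for row in null_sorted
            ]
            exp_fdr = min(1.0, pi0 * float(np.median(counts)) / max(1, n_called))
            if n_called == 0:
                exp_fdr = 0.0
            assert fdr == pytest.approx(exp_fdr)

    def test_negative_delta_rejected(self, planted):
        _, d, dbar, null_sorted = planted
        with pytest.raises(ValidationError):
            call_significant(d, dbar, -0.1, null_sorted)


class TestPi0:
    def test_pure_null_near_one(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=(400, 4))
        d = paired_d_statistics(z, 0.2)
        _, null_sorted, _ = permutation_null(z, 0.2)
        assert estimate_pi0(d, null_sorted) > 0.85

    def test_half_shifted_conservative_estimate(self):
        """With half the genes strongly shifted the quartile estimator
        tracks the true null fraction (0.5) from above: sign-flipped
        alternatives widen the pooled-null quartiles, a documented
        conservative bias of this estimator."""
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z = rng.normal(0, 0.2, size=(400, 5))
            z[:200] += 2.0
            d = paired_d_statistics(z, 0.1)
            _, null_sorted, _ = permutation_null(z, 0.1)
            vals.append(estimate_pi0(d, null_sorted))
        assert 0.5 <= np.mean(vals) <= 0.7

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            z = rng.normal(size=(50, 3)) + rng.normal(0, 2)
            d = paired_d_statistics(z, 0.1)
            _, null_sorted, _ = permutation_null(z, 0.1)
            assert 0.0 <= estimate_pi0(d, null_sorted) <= 1.0


class TestDeltaSearch:
    def test_permissive_target_gives_zero_delta(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=(100, 4))
        d = paired_d_statistics(z, 0.2)
        dbar, null_sorted, _ = permutation_null(z, 0.2)
        delta = choose_delta_for_fdr(d, dbar, null_sorted, 1.0, target_fdr=0.999)
        assert delta == 0.0

    def test_null_only_calls_stay_rare(self):
        """Under a pure null at target FDR 0.05% the call sets are
        small: the median-exceedance FDR estimate reaches zero once
        more than half the permutations have no exceedances, so a few
        observed-tail genes can slip through, but never many."""
        call_fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=(300, 5))
            res = PairedSAM.from_differences(z, config=SamConfig(seed=seed)).fit()
            call_fracs.append(
                (len(res.up_called) + len(res.down_called)) / 300
            )
            assert res.fdr <= res.config.target_fdr  # search postcondition
        assert np.mean(call_fracs) <= 0.02

    def test_chosen_delta_meets_target_with_planted_signal(self):
        rng = np.random.default_rng(11)
        z = rng.normal(0, 0.3, size=(500, 5))
        z[:50] += 1.5
        res = PairedSAM.from_differences(z, config=SamConfig(seed=11)).fit()
        assert res.fdr <= res.config.target_fdr
        assert len(res.up_called) > 0


# ----------------------------------------------------------- invariants
class TestInvariants:
    def test_antisymmetry_swaps_up_and_down(self):
        rng = np.random.default_rng(12)
        z = rng.normal(size=(150, 4))
        z[:15] += 1.8
        res_pos = PairedSAM.from_differences(z, config=SamConfig(seed=0)).fit(delta=0.7)
        res_neg = PairedSAM.from_differences(-z, config=SamConfig(seed=0)).fit(delta=0.7)
        assert set(res_pos.up_called) == set(res_neg.down_called)
        assert set(res_pos.down_called) == set(res_neg.up_called)

    def test_full_enumeration_is_deterministic_across_seeds(self):
        rng = np.random.default_rng(13)
        z = rng.normal(size=(60, 4))
        r1 = PairedSAM.from_differences(z, config=SamConfig(seed=1)).fit()
        r2 = PairedSAM.from_differences(z, config=SamConfig(seed=999)).fit()
        assert np.array_equal(r1.d, r2.d)
        assert r1.delta == r2.delta
        assert r1.up_called == r2.up_called

    def test_small_problem_matches_full_oracle(self):
        """n <= 50 genes, m = 4: every quantity equals brute force."""
        rng = np.random.default_rng(14)
        z = rng.normal(size=(50, 4))
        z[:5] += 2.5
        s0 = choose_s0(z)
        d = paired_d_statistics(z, s0)
        dbar, null_sorted, _ = permutation_null(z, s0)
        for i in range(50):
            assert d[i] == pytest.approx(oracle_d(z[i], s0), abs=1e-12)
        o_dbar, _ = oracle_null(z, s0)
        assert np.allclose(dbar, o_dbar, atol=1e-12)

    def test_genes_with_too_few_pairs_excluded(self):
        z = np.array([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]])
        res = PairedSAM.from_differences(z, gene_ids=["a", "b"]).fit(delta=10.0)
        assert res.gene_ids == ["b"]
        assert res.n_excluded == 1


class TestPairing:
    def test_unpaired_sample_error(self, paired_matrix):
        bad = paired_matrix.copy()
        bad.samples.loc[0, "pair_id"] = "c"
        with pytest.raises(ValidationError, match="unpaired|pair"):
            PairedSAM(bad)

    def test_pair_differences_built_correctly(self, paired_matrix):
        model = PairedSAM(paired_matrix)
        v = paired_matrix.values
        # pairs sorted by id: a = (u1, s1), b = (u2, s2)
        assert np.allclose(model.z[:, 0], v[:, 2] - v[:, 0])
        assert np.allclose(model.z[:, 1], v[:, 3] - v[:, 1])


def test_recovery_on_paper_scale_experiment():
    """Planted induction at 2.35-fold mean: SAM at 0.05% FDR recovers
    the induced set with high sensitivity and few false calls."""
    sens, fdrs = [], []
    for seed in (1, 2, 3):
        matrix, _, truth = simulate_stimulation_experiment(
            StimulationSimConfig(n_genes=1500, frac_induced=0.04, seed=seed)
        )
        res = PairedSAM(matrix, SamConfig(seed=seed)).fit()
        sym = dict(zip(matrix.probe_ids, matrix.features["gene_symbol"]))
        up = {sym[g] for g in res.up_called}
        true_set = set(truth.induced_genes)
        sens.append(len(up & true_set) / len(true_set))
        fdrs.append(len(up - true_set) / max(1, len(up)))
    assert np.mean(sens) >= 0.9
    assert np.mean(fdrs) <= 0.05
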