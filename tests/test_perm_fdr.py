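import itertools
import math

import numpy as np
import pytest

from countperm import perm_fdr
from countperm.datatypes import DirectionalCounts
from tests.conftest import make_expr


class TestPermutationPlan:
    @pytest.mark.parametrize(
        "nc,nt,expected",
        [(5, 5, 252), (4, 4, 70), (1, 1, 2), (3, 3, 20), (6, 6, 924)],
    )
    def test_exhaustive_plan_size(self, nc, nt, expected):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small designs warn; sizes still hold
            plan = perm_fdr.make_permutation_plan(nc, nt)
        assert plan.exhaustive
        assert plan.n_permutations == expected == math.comb(nc + nt, nt)
        # distinct partitions, observed labelling included
        tuples = {tuple(a) for a in plan.assignments}
        assert len(tuples) == expected
        assert tuple(range(nc, nc + nt)) in tuples

    def test_small_group_warning(self):
        with pytest.warns(UserWarning, match="too few"):
            perm_fdr.make_permutation_plan(4, 4)

    def test_sampled_plan_distinct_and_deterministic(self):
        a = perm_fdr.make_permutation_plan(10, 10, max_exhaustive=500, seed=9)
        b = perm_fdr.make_permutation_plan(10, 10, max_exhaustive=500, seed=9)
        assert not a.exhaustive
        assert a.n_permutations == 500
        assert len({tuple(x) for x in a.assignments}) == 500
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_invalid_group_sizes(self):
        with pytest.raises(ValueError):
            perm_fdr.make_permutation_plan(0, 5)


class TestCellsFromCounts:
    def test_dominant_direction_and_cell(self):
        t, j, d, ni = perm_fdr.cells_from_counts(
            np.array([1, 0, 2, 0]),
            np.array([0, 2, 0, 1]),
            np.array([4, 1, 2, 0]),
            np.array([0, 3, 2, 0]),
        )
        np.testing.assert_array_equal(j, [4, 3, 0, 0])
        # the non-interpretable probe's t is irrelevant downstream; it falls
        # through to the larger control count
        np.testing.assert_array_equal(t, [5, 5, 2, 1])
        np.testing.assert_array_equal(d, [1, -1, 0, 0])
        np.testing.assert_array_equal(ni, [False, False, True, False])


def brute_force_null(X, nc, nt, theta_r=0.097, theta_p=0.1, p_mode="disabled"):
    """Independent oracle: pure-python loop over all label partitions,
    recomputing pool means, ratios and flags per partition."""
    n = nc + nt
    n_probes = X.shape[0]
    shape = (n, nt + 1)
    hist = np.zeros(shape)
    partitions = list(itertools.combinations(range(n), nt))
    for trt in partitions:
        ctrl = [s for s in range(n) if s not in trt]
        for i in range(n_probes):
            pool = sum(X[i, s] for s in ctrl) / nc
            if pool <= 0:
                continue
            lr = [math.log10(max(X[i, s] / pool, 1e-12)) for s in range(n)]
            if p_mode == "disabled":
                p = [0.0] * n
            else:
                raise NotImplementedError
            up = [s for s in range(n) if lr[s] >= theta_r and p[s] <= theta_p]
            dn = [s for s in range(n) if lr[s] <= -theta_r and p[s] <= theta_p]
            S_c = len([s for s in up if s in ctrl])
            S_t = len([s for s in up if s in trt])
            R_c = len([s for s in dn if s in ctrl])
            R_t = len([s for s in dn if s in trt])
            if S_t == R_t and S_t > 0:
                continue
            if S_t > R_t:
                t, j = S_t + S_c, S_t
            elif R_t > S_t:
                t, j = R_t + R_c, R_t
            else:
                t, j = max(S_c, R_c), 0
            hist[t, j] += 1
    return hist / len(partitions)


class TestNullCellCounts:
    def test_constant_probe_lands_in_origin_cell(self):
        expr = make_expr([[7.0] * 10], 5, 5)
        plan = perm_fdr.make_permutation_plan(5, 5)
        null = perm_fdr.null_cell_counts(expr, plan, p_mode="disabled")
        assert null[0, 0] == pytest.approx(1.0)
        assert null.sum() == pytest.approx(1.0)

    def test_single_probe_matches_brute_force_over_252_relabelings(self):
        X = np.array([[1.0, 1, 1, 1, 1, 2, 2, 2, 2, 2]])
        expr = make_expr(X, 5, 5)
        plan = perm_fdr.make_permutation_plan(5, 5)
        null = perm_fdr.null_cell_counts(expr, plan, p_mode="disabled")
        oracle = brute_force_null(X, 5, 5)
        np.testing.assert_allclose(null, oracle, atol=1e-12)
        # sanity: the oracle itself is non-trivial
        assert oracle[5, 5] > 0

    def test_two_probe_four_sample_matches_brute_force(self):
        X = np.array([[1.0, 3.0, 2.0, 6.0], [5.0, 5.0, 5.0, 5.0]])
        expr = make_expr(X, 2, 2)
        with pytest.warns(UserWarning):
            plan = perm_fdr.make_permutation_plan(2, 2)
        null = perm_fdr.null_cell_counts(expr, plan, p_mode="disabled")
        oracle = brute_force_null(X, 2, 2)
        np.testing.assert_allclose(null, oracle, atol=1e-12)

    def test_random_matrix_matches_brute_force(self):
        rng = np.random.default_rng(21)
        X = rng.lognormal(1, 0.3, size=(8, 6))
        expr = make_expr(X, 3, 3)
        with pytest.warns(UserWarning):
            plan = perm_fdr.make_permutation_plan(3, 3)
        null = perm_fdr.null_cell_counts(expr, plan, p_mode="disabled")
        oracle = brute_force_null(X, 3, 3)
        np.testing.assert_allclose(null, oracle, atol=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.lognormal(2, 0.4, size=(30, 10))
        plan = perm_fdr.make_permutation_plan(5, 5)
        a = perm_fdr.null_cell_counts(make_expr(X, 5, 5), plan, p_mode="disabled")
        perm = rng.permutation(10)
        b = perm_fdr.null_cell_counts(make_expr(X[:, perm], 5, 5), plan, p_mode="disabled")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_label_shuffle_mode_runs(self, five_five_expr):
        plan = perm_fdr.make_permutation_plan(5, 5)
        null = perm_fdr.null_cell_counts(
            five_five_expr, plan, p_mode="disabled", null_mode="label-shuffle"
        )
        assert null.sum() == pytest.approx(1.0)


class TestFDRMatrix:
    def _grid(self, obs_val, null_val):
        obs = np.zeros((10, 6))
        null = np.zeros((10, 6))
        obs[5, 5], null[5, 5] = obs_val, null_val
        return obs, null

    @pytest.mark.parametrize(
        "obs,null,expected",
        [(17, 0.0, 0.0), (4, 3.2, 0.8), (4, 9.0, 1.0)],
    )
    def test_cell_values(self, obs, null, expected):
        o, n = self._grid(obs, null)
        fdrm = perm_fdr.fdr_matrix(o, n)
        assert fdrm.fdr[5, 5] == pytest.approx(expected)

    def test_empty_observed_cells_get_one(self):
        o, n = self._grid(1, 0.5)
        fdrm = perm_fdr.fdr_matrix(o, n)
        assert fdrm.fdr[3, 2] == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            perm_fdr.fdr_matrix(np.zeros((10, 6)), np.zeros((9, 6)))

    def test_duplicating_probes_leaves_fdr_unchanged(self):
        rng = np.random.default_rng(8)
        X = rng.lognormal(2, 0.3, size=(40, 10))
        X[:10, 5:] *= 2.5
        expr1 = make_expr(X, 5, 5)
        expr2 = make_expr(np.vstack([X, X]), 5, 5)
        plan = perm_fdr.make_permutation_plan(5, 5)

        def grid(expr):
            from countperm import flag_counter, ratio_engine
            rt = ratio_engine.ratio_table(expr, p_mode="disabled")
            counts = flag_counter.count_directional(flag_counter.flag_samples(rt))
            obs = perm_fdr.observed_cell_counts(counts)
            null = perm_fdr.null_cell_counts(expr, plan, p_mode="disabled")
            return perm_fdr.fdr_matrix(obs, null)

        f1, f2 = grid(expr1), grid(expr2)
        np.testing.assert_allclose(f1.fdr, f2.fdr, atol=1e-12)
        np.testing.assert_allclose(f2.observed_counts, 2 * f1.observed_counts)

    def test_monotone_variant_non_increasing_in_j(self):
        rng = np.random.default_rng(4)
        fdr = rng.random((10, 6))
        fdrm = perm_fdr.FDRMatrix(fdr, np.ones((10, 6)), fdr, 5, 5)
        mono = fdrm.monotone()
        assert np.all(np.diff(mono.fdr, axis=1) <= 1e-12)
        assert np.all(mono.fdr <= fdr + 1e-12)


class TestCallSignificant:
    def _fdrm(self, values):
        fdr = np.ones((10, 6))
        for (t, j), v in values.items():
            fdr[t, j] = v
        return perm_fdr.FDRMatrix(fdr, np.ones((10, 6)), fdr, 5, 5)

    def _counts(self, S_c, R_c, S_t, R_t):
        return DirectionalCounts(
            probe_ids=[f"p{i}" for i in range(len(S_c))],
            S_control=np.array(S_c),
            R_control=np.array(R_c),
            S_treated=np.array(S_t),
            R_treated=np.array(R_t),
            n_control=5,
            n_treated=5,
        )

    def test_all_responder_probe_significant(self):
        counts = self._counts([0], [0], [5], [0])
        fdrm = self._fdrm({(5, 5): 0.0})
        calls = perm_fdr.call_significant(counts, fdrm, np.array([2.0]))
        assert calls[0].significant and calls[0].direction == "up"
        assert (calls[0].t, calls[0].j) == (5, 5)

    def test_high_fdr_cell_not_significant(self):
        counts = self._counts([2], [0], [2], [0])
        fdrm = self._fdrm({(4, 2): 0.781})
        calls = perm_fdr.call_significant(counts, fdrm, np.array([1.5]))
        assert not calls[0].significant
        assert calls[0].fdr == pytest.approx(0.781)

    def test_noninterpretable_never_significant(self):
        counts = self._counts([0], [0], [2], [2])
        fdrm = self._fdrm({(2, 2): 0.0, (4, 2): 0.0})
        calls = perm_fdr.call_significant(counts, fdrm, np.array([1.5]))
        assert calls[0].non_interpretable and not calls[0].significant

    def test_treated_majority_required(self):
        # j = 2, t = 4: two controls moved with the treated samples
        counts = self._counts([2], [0], [2], [0])
        fdrm = self._fdrm({(4, 2): 0.0})
        calls = perm_fdr.call_significant(counts, fdrm, np.array([1.5]))
        assert not calls[0].significant


class TestNullCalibrationSmall:
    def test_exchangeable_data_rarely_called(self):
        """On a pure-null matrix the caller should stay near silent."""
        from countperm import synthetic
        expr = synthetic.generate_null(n_probes=400, noise_sd=0.05, seed=17)
        from countperm.perm_fdr import differential_expression
        calls, _ = differential_expression(expr, seed=17)
        frac = sum(c.significant for c in calls) / len(calls)
        assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 400)
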