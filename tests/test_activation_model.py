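"""Activation-model tests: DoF assignment, robust g, median pooling."""

import itertools

import numpy as np
import pytest

from mukin.activation_model import (
    DoFAssignment,
    GFunction,
    assign_dof,
    combine_median,
    compute_activations,
    estimate_alpha,
    fit_g,
    neural_feature_matrix,
)
from mukin.errors import (
    DegenerateInputError,
    EmptyPoolError,
    InsufficientDataError,
    InvalidInputError,
)
from mukin.types import FeatureMatrix


def _dsc(values, uids=None):
    values = np.asarray(values, dtype=float)
    uids = uids or list(range(values.shape[1]))
    return FeatureMatrix(
        values=values,
        window_end_sample=np.arange(values.shape[0]),
        labels=[f"unit{u}" for u in uids],
    )


class TestAssignDoF:
    def test_proportional_counts_assign_with_sign(self, rng):
        r = 200
        angles = np.zeros((3, r))
        angles[0] = np.sin(np.linspace(0, 6, r))
        angles[1] = np.cos(np.linspace(0, 5, r))
        counts = np.stack([2 * angles[0] + 5, -3 * angles[1] + 9], axis=1)
        res = assign_dof(_dsc(counts), angles)
        assert res.assignments[0][0] == 0
        assert res.assignments[0][1] == pytest.approx(1.0)
        assert res.assignments[1][0] == 1
        assert res.assignments[1][1] == pytest.approx(-1.0)

    def test_argmax_over_dofs(self, rng):
        r = 300
        angles = rng.normal(size=(3, r))
        x = 0.9 * angles[0] + 0.1 * rng.normal(size=r)
        res = assign_dof(_dsc(x[:, None]), angles)
        assert res.assignments[0][0] == 0

    def test_zero_variance_unit_excluded(self):
        angles = np.zeros((3, 50))
        angles[0] = np.linspace(-1, 1, 50)
        res = assign_dof(_dsc(np.ones((50, 1))), angles)
        assert 0 not in res.assignments
        assert "zero-variance" in res.excluded[0]

    def test_weakly_correlated_unit_excluded(self, rng):
        angles = np.zeros((3, 400))
        angles[0] = np.sin(np.linspace(0, 10, 400))
        noise = rng.normal(size=(400, 1))
        res = assign_dof(_dsc(noise), angles, min_abs_corr=0.2)
        assert 0 not in res.assignments


class TestFitG:
    def test_noiseless_recovery(self):
        counts = np.tile(np.arange(10.0), 5)
        angles = 3.0 * counts + 1.0
        g = fit_g(counts, angles)
        assert g.slope == pytest.approx(3.0, abs=1e-8)
        assert g.intercept == pytest.approx(1.0, abs=1e-8)
        assert g.converged

    def test_outliers_hurt_bisquare_less_than_ols(self, rng):
        wins = 0
        for trial in range(30):
            r = np.random.default_rng(trial)
            counts = r.uniform(0, 4, size=200)
            angles = 12.0 * counts - 5.0 + r.normal(0, 2.0, size=200)
            out = r.choice(200, size=20, replace=False)
            angles[out] = 500.0
            g = fit_g(counts, angles)
            X = np.column_stack([np.ones_like(counts), counts])
            ols = np.linalg.lstsq(X, angles, rcond=None)[0]
            err_bi = abs(g.slope - 12.0) + abs(g.intercept + 5.0)
            err_ols = abs(ols[1] - 12.0) + abs(ols[0] + 5.0)
            wins += err_bi < err_ols
        assert wins >= 28

    def test_matches_statsmodels_rlm(self, rng):
        # independent oracle: statsmodels RLM with Tukey biweight
        sm = pytest.importorskip("statsmodels.api")
        counts = rng.uniform(0, 5, size=300)
        angles = 7.0 * counts + 2.0 + rng.normal(0, 1.5, size=300)
        angles[rng.choice(300, 20, replace=False)] += 80.0
        g = fit_g(counts, angles)
        X = sm.add_constant(counts)
        rlm = sm.RLM(angles, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
            scale_est="mad"
        )
        assert g.intercept == pytest.approx(rlm.params[0], abs=0.05)
        assert g.slope == pytest.approx(rlm.params[1], abs=0.05)

    def test_degenerate_and_short_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_g(np.ones(50), np.arange(50.0))
        with pytest.raises(InsufficientDataError):
            fit_g(np.arange(5.0), np.arange(5.0))

    def test_alpha_evaluation(self):
        g = GFunction(unit_id=0, slope=3.0, intercept=1.0)
        assert estimate_alpha(g, np.array([2.0]))[0] == 7.0
        flat = GFunction(unit_id=0, slope=0.0, intercept=4.0)
        assert np.all(estimate_alpha(flat, np.arange(10.0)) == 4.0)


class TestCombineMedian:
    def test_hand_computed_cases(self):
        # alphas (2, 3, 10) with previous value 3 -> median of 4 values = 3
        out = combine_median(np.array([[2.0], [3.0], [10.0]]), a0=3.0)
        assert out[0] == 3.0
        # single unit: median of (5, prev=1) = 3 (mean of central pair)
        assert combine_median(np.array([[5.0]]), a0=1.0)[0] == 3.0

    def test_constant_inputs_lock_in_from_second_step(self):
        alphas = np.full((3, 4), 7.0)
        out = combine_median(alphas, a0=0.0)
        assert out[0] == 7.0  # median(7,7,7,0) = 7 for n = 3
        assert np.all(out[1:] == 7.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(EmptyPoolError):
            combine_median(np.zeros((0, 5)))

    def test_boundedness_and_monotonicity_exhaustive_small_cases(self):
        # exhaustive enumeration over a value grid for n <= 4
        grid = [-1.0, 0.0, 2.0]
        for n in (1, 2, 3, 4):
            for vals in itertools.product(grid, repeat=n):
                for a0 in grid:
                    base = combine_median(np.array(vals)[:, None], a0=a0)[0]
                    lo, hi = min(list(vals) + [a0]), max(list(vals) + [a0])
                    assert lo <= base <= hi
                    # raising any single alpha never decreases the output
                    for j in range(n):
                        bumped = list(vals)
                        bumped[j] += 1.5
                        out2 = combine_median(np.array(bumped)[:, None], a0=a0)[0]
                        assert out2 >= base - 1e-12

    def test_recursion_term_promotes_smoothness_exhaustive(self):
        # |a_r - a_{r-1}| with the recursion term never exceeds the same
        # median computed without it (n <= 4, small value grid)
        grid = [-1.0, 0.5, 3.0]
        for n in (2, 3, 4):
            for vals in itertools.product(grid, repeat=n):
                for a_prev in grid:
                    with_term = np.median(np.array(list(vals) + [a_prev]))
                    without = np.median(np.array(vals))
                    assert abs(with_term - a_prev) <= abs(without - a_prev) + 1e-12

    def test_outlier_robustness_randomized(self, rng):
        # corrupting floor((n-1)/2) series at one window moves the output
        # by no more than the clean value spread
        for n in (5, 11, 20, 40):
            clean = rng.normal(10.0, 1.0, size=(n, 1))
            base = combine_median(clean, a0=10.0)[0]
            k = (n - 1) // 2
            corrupted = clean.copy()
            corrupted[rng.choice(n, size=k, replace=False), 0] = rng.choice(
                [-1e6, 1e6], size=k
            )
            out = combine_median(corrupted, a0=10.0)[0]
            spread = clean.max() - clean.min()
            assert abs(out - base) <= spread + 1e-9

    def test_identical_series_conserved(self, rng):
        series = rng.normal(size=30)
        alphas = np.tile(series, (5, 1))
        out = combine_median(alphas, a0=0.0)
        assert np.allclose(out, series)  # n=5 >= 3: a0 never the median


class TestComputeActivations:
    def test_exact_linear_composition_recovers_angles(self, rng):
        r = 400
        angles = np.zeros((3, r))
        angles[0] = 30 * np.sin(np.linspace(0, 8, r))
        angles[1] = 20 * np.cos(np.linspace(0, 5, r))
        angles[2] = 10 * np.sin(np.linspace(0, 3, r))
        cols, uids, gfuncs, assigns = [], [], {}, {}
        uid = 0
        for dof in range(3):
            for _ in range(3):
                slope = rng.uniform(0.5, 2.0)
                icept = rng.uniform(-5, 5)
                cols.append((angles[dof] - icept) / slope)
                gfuncs[uid] = GFunction(unit_id=uid, slope=slope, intercept=icept)
                assigns[uid] = (dof, 1.0)
                uids.append(uid)
                uid += 1
        dsc = _dsc(np.stack(cols, axis=1), uids)
        acts, warn = compute_activations(dsc, DoFAssignment(assigns), gfuncs, a0=0.0)
        assert not warn
        for dof in range(3):
            # n=3 equal alphas dominate the recursion term from step 2 on
            assert np.allclose(acts[dof].values[1:], angles[dof][1:], atol=1e-6)

    def test_single_gross_outlier_unit_ignored(self, rng):
        r = 100
        angles = np.zeros((3, r))
        angles[0] = np.linspace(-30, 30, r)
        gfuncs, assigns, cols, uids = {}, {}, [], []
        for uid in range(9):
            gfuncs[uid] = GFunction(unit_id=uid, slope=1.0, intercept=0.0)
            assigns[uid] = (0, 1.0)
            cols.append(angles[0])
            uids.append(uid)
        dsc_clean = _dsc(np.stack(cols, axis=1), uids)
        broken = np.stack(cols, axis=1)
        broken[:, 4] = 1000.0
        dsc_broken = _dsc(broken, uids)
        a_clean, _ = compute_activations(dsc_clean, DoFAssignment(dict(assigns)), gfuncs)
        a_broken, _ = compute_activations(dsc_broken, DoFAssignment(dict(assigns)), gfuncs)
        assert np.allclose(a_clean[0].values, a_broken[0].values, atol=1e-9)

    def test_empty_dof_pool_emits_constant_with_warning(self):
        angles = np.zeros((3, 50))
        angles[0] = np.linspace(-1, 1, 50)
        gfuncs = {0: GFunction(unit_id=0, slope=1.0, intercept=0.0)}
        assigns = DoFAssignment({0: (0, 1.0)})
        acts, warn = compute_activations(_dsc(angles[0][:, None]), assigns, gfuncs, a0=0.0)
        assert any("DoF 2" in w for w in warn)
        assert acts[2].empty_pool
        assert np.all(acts[2].values == 0.0)

    def test_all_pools_empty_rejected(self):
        with pytest.raises(EmptyPoolError):
            compute_activations(_dsc(np.ones((20, 1))), DoFAssignment({}), {})


class TestNeuralFeatureMatrix:
    def _acts(self, r):
        from mukin.activation_model import PoolActivation

        return [PoolActivation(dof=d, values=np.full(r, float(d))) for d in range(3)]

    def test_column_layout(self, rng):
        res = FeatureMatrix(values=rng.normal(size=(50, 20)), window_end_sample=np.arange(50))
        fm = neural_feature_matrix(self._acts(50), res)
        assert fm.n_features == 23
        assert fm.labels[:3] == ["activation_dof1", "activation_dof2", "activation_dof3"]

    def test_window_mismatch_rejected(self, rng):
        res = FeatureMatrix(values=rng.normal(size=(49, 4)), window_end_sample=np.arange(49))
        with pytest.raises(InvalidInputError):
            neural_feature_matrix(self._acts(50), res)
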