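"""Candidate fits, PRESS leave-one-out shortcut, and the weight QP."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathjma.groups import GeneGroups, groups_sequential
from pathjma.model import (
    DegenerateFitError,
    GroupedDesign,
    JMARegressor,
    fit_candidate,
    fit_jma,
    jackknife_matrix,
    load_model,
    save_model,
    solve_weights,
)
from pathjma.simulate import SimulationSpec, make_dataset

from conftest import grid_search_weights, loo_refit_oracle


def _design(X, y, sizes=None):
    p = X.shape[1]
    if sizes is None:
        groups = groups_sequential(p, 1)
    else:
        idx, members = 0, []
        for s in sizes:
            members.append(np.arange(idx, idx + s))
            idx += s
        groups = GeneGroups([f"g{i}" for i in range(len(sizes))], members, p)
    return GroupedDesign(X, y, groups)


class TestFitCandidate:
    def test_mean_model_closed_form(self):
        """A constant single-gene column fits the sample mean; h_ii = 1/3."""
        d = _design(np.ones((3, 1)), np.array([1.0, 2.0, 3.0]))
        f = fit_candidate(d, 0, delta=0.0)
        assert f.beta_hat == pytest.approx([2.0])
        assert f.fitted == pytest.approx([2.0, 2.0, 2.0])
        assert f.hat_diag == pytest.approx([1 / 3] * 3)
        # LOO of the mean model: ytilde_i = mean of the other two values
        assert f.loo_pred == pytest.approx([2.5, 2.0, 1.5])

    def test_saturated_identity_design_is_degenerate(self):
        d = _design(np.eye(4), np.array([1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(DegenerateFitError, match="delta"):
            fit_candidate(d, 0, delta=0.0)

    def test_singular_normal_matrix_requires_positive_delta(self, rng):
        X = rng.standard_normal((5, 8))  # more genes than samples
        d = _design(X, rng.standard_normal(5))
        with pytest.raises(np.linalg.LinAlgError, match="delta"):
            fit_candidate(d, 0, delta=0.0)
        fit_candidate(d, 0, delta=1.0)  # stabilized fit succeeds

    def test_negative_delta_rejected(self, rng):
        d = _design(rng.standard_normal((6, 2)), rng.standard_normal(6))
        with pytest.raises(ValueError):
            fit_candidate(d, 0, delta=-0.5)

    @pytest.mark.parametrize(
        "n, m, delta",
        [(8, 5, 1.0), (20, 6, 0.0), (15, 25, 0.1), (30, 60, 10.0), (50, 49, 1.0)],
    )
    def test_press_shortcut_matches_explicit_refits(self, rng, n, m, delta):
        """The hat-diagonal shortcut reproduces n explicit LOO refits."""
        G = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        d = _design(G, y)
        f = fit_candidate(d, 0, delta=delta)
        np.testing.assert_allclose(f.loo_pred, loo_refit_oracle(G, y, delta),
                                   atol=1e-8)

    def test_dual_and_primal_forms_agree(self, rng):
        """m>n dual-form fit matches the m x m normal-equation solution."""
        G = rng.standard_normal((12, 30))
        y = rng.standard_normal(12)
        d = _design(G, y)
        f = fit_candidate(d, 0, delta=2.0)
        beta_primal = np.linalg.solve(G.T @ G + 2.0 * np.eye(30), G.T @ y)
        np.testing.assert_allclose(f.beta_hat, beta_primal, atol=1e-10)


class TestJackknifeMatrix:
    def test_single_candidate(self, rng):
        d = _design(rng.standard_normal((10, 3)), rng.standard_normal(10))
        f = fit_candidate(d, 0, delta=1.0)
        Yt = jackknife_matrix([f])
        np.testing.assert_array_equal(Yt[:, 0], f.loo_pred)

    def test_duplicate_groups_give_identical_columns(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        groups = GeneGroups(["a", "b"], [np.arange(4), np.arange(4)], 4,
                            allow_overlap=True)
        d = GroupedDesign(X, y, groups)
        Yt = jackknife_matrix([fit_candidate(d, 0, 1.0), fit_candidate(d, 1, 1.0)])
        np.testing.assert_array_equal(Yt[:, 0], Yt[:, 1])

    def test_inconsistent_n_rejected(self, rng):
        d1 = _design(rng.standard_normal((10, 2)), rng.standard_normal(10))
        d2 = _design(rng.standard_normal((11, 2)), rng.standard_normal(11))
        fits = [fit_candidate(d1, 0, 1.0), fit_candidate(d2, 0, 1.0)]
        with pytest.raises(ValueError, match="inconsistent"):
            jackknife_matrix(fits)

    def test_columns_reproduce_press_values(self, rng):
        """||y - column_j||^2 equals candidate j's sum of squared LOO residuals."""
        X = rng.standard_normal((25, 10))
        y = rng.standard_normal(25)
        d = _design(X, y, sizes=[6, 4])
        fits = [fit_candidate(d, j, 1.0) for j in range(2)]
        Yt = jackknife_matrix(fits)
        for j, idx in enumerate(d.groups.members):
            oracle = loo_refit_oracle(X[:, idx], y, 1.0)
            assert np.sum((y - Yt[:, j]) ** 2) == pytest.approx(
                np.sum((y - oracle) ** 2)
            )


class TestSolveWeights:
    def test_perfect_candidate_gets_weight_one(self, rng):
        y = rng.standard_normal(20)
        sol = solve_weights(y[:, None], y)
        assert sol.weights == pytest.approx([1.0])
        assert sol.criterion_value == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_candidates_get_zero_weights(self, rng):
        y = rng.standard_normal(40)
        Yt = rng.standard_normal((40, 3))
        Yt -= np.outer(y, y @ Yt) / (y @ y)  # make every column orthogonal to y
        sol = solve_weights(Yt, y)
        assert sol.weights == pytest.approx(np.zeros(3), abs=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        """Criterion at the solver optimum matches exhaustive 0.01-grid search
        to within the grid's own resolution."""
        Yt = rng.standard_normal((30, 3))
        y = 0.5 * Yt[:, 0] + 0.2 * Yt[:, 2] + rng.standard_normal(30)
        sol = solve_weights(Yt, y)
        _, crit_grid = grid_search_weights(Yt, y, step=0.01)
        lam_max = np.linalg.eigvalsh(Yt.T @ Yt).max()
        resolution = lam_max * 3 * (0.01 / 2) ** 2
        assert sol.criterion_value <= crit_grid + 1e-8
        assert crit_grid - sol.criterion_value <= resolution

    def test_kkt_conditions_hold(self, rng):
        Yt = rng.standard_normal((50, 6))
        y = Yt @ rng.uniform(-0.5, 1.5, 6) + rng.standard_normal(50)
        sol = solve_weights(Yt, y)
        A, b = Yt.T @ Yt, Yt.T @ y
        grad = 2 * (A @ sol.weights - b)
        tol = 1e-6 * max(1.0, np.abs(b).max())
        for wj, gj in zip(sol.weights, grad):
            if wj <= 1e-10:
                assert gj >= -tol  # pushing below the lower bound
            elif wj >= 1 - 1e-10:
                assert gj <= tol  # pushing above the upper bound
            else:
                assert abs(gj) <= tol

    def test_beats_equal_weights_and_singletons(self, rng):
        Yt = rng.standard_normal((40, 5))
        y = Yt[:, 1] + 0.3 * rng.standard_normal(40)
        sol = solve_weights(Yt, y)
        K = 5
        for w in [np.full(K, 1.0 / K), *np.eye(K)]:
            assert sol.criterion_value <= np.sum((y - Yt @ w) ** 2) + 1e-9

    def test_wider_box_never_hurts(self, rng):
        Yt = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        narrow = solve_weights(Yt, y, 0.0, 1.0)
        wide = solve_weights(Yt, y, -1.0, 1.0)
        assert wide.criterion_value <= narrow.criterion_value + 1e-9
        assert wide.weights.min() >= -1.0 and wide.weights.max() <= 1.0

    @settings(deadline=None, max_examples=25)
    @given(c=st.floats(0.05, 20.0), seed=st.integers(0, 10_000))
    def test_scaling_equivariance(self, c, seed):
        """Scaling y and Ytilde by c>0 keeps w and scales the criterion by c^2."""
        r = np.random.default_rng(seed)
        Yt = r.standard_normal((25, 3))
        y = Yt @ r.uniform(0, 1, 3) + r.standard_normal(25)
        s1 = solve_weights(Yt, y)
        s2 = solve_weights(c * Yt, c * y)
        np.testing.assert_allclose(s2.weights, s1.weights, atol=1e-6)
        assert s2.criterion_value == pytest.approx(
            c**2 * s1.criterion_value, rel=1e-6, abs=1e-9
        )

    def test_bad_inputs(self, rng):
        y = rng.standard_normal(10)
        with pytest.raises(ValueError, match="finite"):
            solve_weights(np.full((10, 2), np.nan), y)
        with pytest.raises(ValueError, match="lower"):
            solve_weights(rng.standard_normal((10, 2)), y, lower=1.0, upper=0.0)


class TestJMARegressor:
    def test_single_good_candidate_weight_near_one(self, rng):
        X = rng.standard_normal((100, 5))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0, 0.2]) + 0.05 * rng.standard_normal(100)
        model = fit_jma(X, y, groups=1)
        assert model.weights_.shape == (1,)
        assert model.weights_[0] == pytest.approx(1.0, abs=0.05)

    def test_zero_weights_predict_the_training_mean(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30) + 7.0
        model = JMARegressor(groups=2).fit(X, y)
        model.weights_ = np.zeros(2)
        np.testing.assert_allclose(model.predict(X), np.full(30, model.y_mean_))

    def test_training_prediction_is_weighted_fitted_sum(self, rng):
        X = rng.standard_normal((60, 12))
        y = X[:, 0] - X[:, 7] + rng.standard_normal(60)
        model = JMARegressor(groups=3).fit(X, y)
        expected = np.zeros(60)
        for w, f in zip(model.weights_, model.candidate_fits_):
            expected += w * f.fitted
        np.testing.assert_allclose(
            model.predict(X), model.y_mean_ + model.y_scale_ * expected, atol=1e-10
        )

    def test_column_count_mismatch_rejected(self, rng):
        X = rng.standard_normal((30, 4))
        model = JMARegressor(groups=2).fit(X, rng.standard_normal(30))
        with pytest.raises(ValueError, match="columns"):
            model.predict(X[:, :3])

    def test_sklearn_params_round_trip(self):
        model = JMARegressor(delta=2.0, upper=0.5)
        assert JMARegressor(**model.get_params()).get_params() == model.get_params()

    def test_active_groups_outweigh_null_groups(self):
        """On group-structured data, weight mass concentrates on the groups
        that truly carry signal; null groups are zeroed far more often."""
        ds = make_dataset(SimulationSpec(
            n=300, p=500, partition="sequential-25", scenario="I", pve=0.6, seed=11
        ))
        model = JMARegressor(groups=ds.groups).fit(ds.X, ds.y)
        active = np.zeros(25, dtype=bool)
        active[ds.active_groups] = True
        assert model.weights_[active].mean() > model.weights_[~active].mean()
        assert (model.weights_[~active] == 0).mean() > (model.weights_[active] == 0).mean()

    def test_delta_robustness_of_test_correlation(self):
        """Prediction accuracy is insensitive to the ridge constant over two
        orders of magnitude."""
        ds = make_dataset(SimulationSpec(
            n=400, p=400, partition="sequential-20", scenario="I", pve=0.5, seed=21
        ))
        tr, te = np.arange(300), np.arange(300, 400)
        rs = []
        for delta in (0.1, 1.0, 10.0):
            m = JMARegressor(groups=ds.groups, delta=delta).fit(ds.X[tr], ds.y[tr])
            rs.append(np.corrcoef(m.predict(ds.X[te]), ds.y[te])[0, 1])
        assert max(rs) - min(rs) < 0.05

    def test_equal_weight_strategy(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        m = JMARegressor(groups=3, weight_strategy="equal").fit(X, y)
        np.testing.assert_allclose(m.weights_, np.full(3, 1 / 3))

    def test_archive_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((50, 8))
        y = X[:, 0] + rng.standard_normal(50)
        model = JMARegressor(groups=4).fit(X, y)
        path = tmp_path / "model.json"
        save_model(model, path, gene_ids=[f"g{i}" for i in range(8)])
        loaded, gene_ids = load_model(path)
        assert gene_ids == [f"g{i}" for i in range(8)]
        X_new = rng.standard_normal((7, 8))
        np.testing.assert_allclose(loaded.predict(X_new), model.predict(X_new),
                                   atol=1e-12)
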