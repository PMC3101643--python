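import numpy as np
import pytest

import densvar as dv
from densvar.density import GridRegion, density_map, fragment_box
from densvar.sparse import (
    RegressionProblem,
    build_problem,
    average_weight,
    classify_ensemble,
    coef_significance,
    cv_lambda,
    default_lambda_grid,
    fragment_profile,
    kkt_violation,
    lasso_fit,
    lasso_objective,
    regularization_path,
    windowed_profile,
)


def random_problem(seed, n_members=3, n_rows=40, noise=0.05):
    """Small random problem with unit-norm columns and coefficients in [-1, 1]."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_rows, n_members))
    X /= np.linalg.norm(X, axis=0)
    w_true = rng.uniform(-1, 1, size=n_members)
    y = X @ w_true + noise * rng.normal(size=n_rows)
    return RegressionProblem(y=y, X=X, member_labels=[f"m{i}" for i in range(n_members)])


def grid_search_lasso(y, X, lam, span=2.0, coarse=0.05, fine=1e-3):
    """Exhaustive minimization of the L1 objective on a coordinate grid.

    Coarse scan over [-span, span]^k followed by local refinement; exact at
    the fine resolution because the objective is convex.
    """
    k = X.shape[1]
    gram = X.T @ X
    xty = X.T @ y
    yty = y @ y

    def objective_on(mesh):
        quad = np.einsum("ni,ij,nj->n", mesh, gram, mesh)
        return yty - 2 * mesh @ xty + quad + lam * np.abs(mesh).sum(axis=1)

    def scan(center, width, step):
        axes = [
            np.arange(c - width, c + width + step / 2, step) for c in center
        ]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, k)
        vals = objective_on(mesh)
        return mesh[int(np.argmin(vals))]

    best = scan(np.zeros(k), span, coarse)
    for width, step in [(2 * coarse, coarse / 5), (2 * coarse / 5, fine)]:
        best = scan(best, width, step)
    return best


class TestBuildProblem:
    def test_identity_feature(self, standard_fixture):
        sf = standard_fixture
        p = build_problem(sf.base_map, [sf.base_map], sf.region)
        np.testing.assert_array_equal(p.X[:, 0], p.y)

    def test_full_grid_rows(self, standard_fixture):
        sf = standard_fixture
        p = build_problem(sf.base_map, sf.member_maps)
        assert p.X.shape[0] == np.prod(sf.base_map.shape)

    def test_permutation_contract(self, standard_fixture):
        sf = standard_fixture
        labels = ["a", "b", "c", "d"]
        p1 = build_problem(sf.base_map, sf.member_maps, sf.region, labels)
        perm = [2, 0, 3, 1]
        p2 = build_problem(
            sf.base_map, [sf.member_maps[i] for i in perm], sf.region,
            [labels[i] for i in perm],
        )
        for new_col, old_col in enumerate(perm):
            np.testing.assert_array_equal(p2.X[:, new_col], p1.X[:, old_col])
            assert p2.member_labels[new_col] == labels[old_col]

    def test_layout_mismatch(self, standard_fixture):
        sf = standard_fixture
        other = density_map(sf.crystal.base, sf.crystal.cell, sf.crystal.spacing * 2)
        with pytest.raises(ValueError):
            build_problem(sf.base_map, [other])

    def test_zero_column_dropped_with_record(self):
        y = np.ones(10)
        X = np.column_stack([np.ones(10), np.zeros(10)])
        p = RegressionProblem(y=y, X=X, member_labels=["live", "dead"])
        assert p.member_labels == ["live"]
        assert p.dropped_labels == ["dead"]


class TestLassoFit:
    def test_lambda_max_gives_all_zero(self, standard_fixture):
        sf = standard_fixture
        p = build_problem(sf.base_map, sf.member_maps, sf.region)
        fit = lasso_fit(p, p.lambda_max())
        np.testing.assert_array_equal(fit.weights_scaled, 0.0)

    def test_lambda_zero_orthogonal_closed_form(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        y = rng.normal(size=30)
        p = RegressionProblem(y=y, X=Q, member_labels=["a", "b", "c"])
        fit = lasso_fit(p, 0.0)
        np.testing.assert_allclose(fit.weights_scaled, Q.T @ y, atol=1e-10)

    def test_lambda_zero_matches_least_squares(self):
        p = random_problem(3, n_members=3)
        fit = lasso_fit(p, 0.0)
        ls, *_ = np.linalg.lstsq(p.scaled_X(), p.y, rcond=None)
        np.testing.assert_allclose(fit.weights_scaled, ls, atol=1e-8)

    def test_two_member_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 2))
        X /= np.linalg.norm(X, axis=0)
        y = X @ np.array([0.8, -0.5]) + 0.1 * rng.normal(size=25)
        p = RegressionProblem(y=y, X=X, member_labels=["a", "b"])
        lam = 0.3 * p.lambda_max()
        fit = lasso_fit(p, lam)
        w_grid = grid_search_lasso(p.y, p.scaled_X(), lam, fine=1e-3)
        np.testing.assert_allclose(fit.weights_scaled, w_grid, atol=2e-3)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("nonneg", [False, True])
    def test_kkt_certified(self, seed, nonneg):
        p = random_problem(seed)
        for frac in (0.5, 0.1, 0.01):
            fit = lasso_fit(p, frac * p.lambda_max(), nonneg=nonneg)
            assert fit.converged
            assert kkt_violation(p, fit, nonneg=nonneg) < 1e-6

    def test_objective_monotone_over_sweeps(self):
        p = random_problem(5, n_members=3, n_rows=60)
        history = []
        lasso_fit(p, 0.2 * p.lambda_max(), objective_history=history)
        assert len(history) >= 1
        diffs = np.diff(history)
        assert np.all(diffs <= 1e-12)

    def test_nonneg_constraint_respected(self):
        p = random_problem(2)
        fit = lasso_fit(p, 0.05 * p.lambda_max(), nonneg=True)
        assert np.all(fit.weights_scaled >= 0)

    def test_negative_lambda_rejected(self):
        p = random_problem(0)
        with pytest.raises(ValueError):
            lasso_fit(p, -1.0)

    def test_weights_reported_on_original_scale(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2)) * np.array([1.0, 10.0])
        y = X @ np.array([0.5, 0.05])
        p = RegressionProblem(y=y, X=X, member_labels=["a", "b"])
        fit = lasso_fit(p, 1e-10 * p.lambda_max())
        np.testing.assert_allclose(p.X @ fit.weights, y, atol=1e-6)


class TestRegularizationPath:
    def test_first_point_at_lambda_max(self):
        p = random_problem(0)
        grid = default_lambda_grid(p)
        path = regularization_path(p, grid)
        assert path.l1_ratio[0] == pytest.approx(0.0, abs=1e-10)

    def test_l1_ratio_monotone_and_bounded(self):
        p = random_problem(1)
        path = regularization_path(p)
        assert np.all(path.l1_ratio >= 0) and np.all(path.l1_ratio <= 1)
        assert np.all(np.diff(path.l1_ratio) >= -1e-9)

    def test_warm_start_consistency_oracle(self):
        # path values must match cold-started fits at every grid point
        p = random_problem(2)
        grid = default_lambda_grid(p, n=10)
        path = regularization_path(p, grid)
        for i, lam in enumerate(grid):
            cold = lasso_fit(p, lam, tol=1e-10)
            np.testing.assert_allclose(path.weight_matrix[i], cold.weights, atol=1e-6)

    def test_bad_grid_rejected(self):
        p = random_problem(0)
        with pytest.raises(ValueError):
            regularization_path(p, np.array([1.0, 2.0]))


class TestCvLambda:
    def test_pure_noise_selects_large_lambda(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        X /= np.linalg.norm(X, axis=0)
        y = rng.normal(size=200)  # members carry no signal
        p = RegressionProblem(y=y, X=X, member_labels=["a", "b", "c"])
        grid = default_lambda_grid(p)
        lam = cv_lambda(p, lam_grid=grid, seed=1)
        assert lam >= grid[5]  # at or near the top of the grid

    def test_single_member_recovery(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        X /= np.linalg.norm(X, axis=0)
        y = 3.0 * X[:, 1]
        p = RegressionProblem(y=y, X=X, member_labels=["a", "b", "c"])
        lam = cv_lambda(p, seed=0)
        fit = lasso_fit(p, lam)
        assert abs(fit.weights_scaled[1] - 3.0) <= 0.3
        assert np.argmax(np.abs(fit.weights_scaled)) == 1

    def test_deterministic_under_seed(self, standard_fixture):
        sf = standard_fixture
        p = build_problem(sf.base_map, sf.member_maps, sf.region)
        assert cv_lambda(p, seed=7) == cv_lambda(p, seed=7)

    def test_too_many_folds(self):
        p = random_problem(0, n_rows=4)
        with pytest.raises(ValueError):
            cv_lambda(p, k=10)


class TestCoefSignificance:
    def test_overwhelming_signal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 3.0 * x + 1e-4 * rng.normal(size=50)
        p = RegressionProblem(y=y, X=x[:, None], member_labels=["a"])
        t, pv, r2 = coef_significance(p, np.array([True]))
        assert pv[0] < 1e-6
        assert r2 > 0.999

    def test_empty_support(self):
        p = random_problem(0)
        t, pv, r2 = coef_significance(p, np.zeros(3, dtype=bool))
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(pv, 1.0)
        assert r2 == 0.0

    def test_normal_equations_oracle(self):
        # 5-row, 2-column textbook OLS: beta = (X'X)^-1 X'y,
        # se_i = sqrt(sigma2 * [(X'X)^-1]_ii), t = beta/se
        from scipy import stats as sps

        X = np.array([[1.0, 2.0], [2.0, 0.5], [3.0, 1.5], [4.0, 3.0], [5.0, 2.5]])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        p = RegressionProblem(y=y, X=X, member_labels=["a", "b"])
        Xs = p.scaled_X()
        xtx_inv = np.linalg.inv(Xs.T @ Xs)
        beta = xtx_inv @ Xs.T @ y
        resid = y - Xs @ beta
        sigma2 = resid @ resid / (5 - 2)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        t_exp = beta / se
        p_exp = 2 * sps.t.sf(np.abs(t_exp), 3)
        t, pv, _ = coef_significance(p, np.array([True, True]))
        np.testing.assert_allclose(t, t_exp, atol=1e-8)
        np.testing.assert_allclose(pv, p_exp, atol=1e-10)

    def test_collinear_columns_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        y = x.copy()
        p = RegressionProblem(y=y, X=X, member_labels=["a", "b"])
        t, pv, r2 = coef_significance(p, np.array([True, True]))
        assert np.isfinite(t).all()
        assert (pv < 1).sum() == 1  # one of the twins dropped


class TestClassifyEnsemble:
    def test_two_conformer_fixture_base_regression(self, standard_fixture):
        sf = standard_fixture
        rep = classify_ensemble(sf.base_map, sf.member_maps, sf.region, lam="cv", seed=0)
        predicted = [
            "noise" if lab == "noise_variant" else "variable" for lab in rep.labels
        ]
        assert predicted == sf.ensemble.truth_labels

    def test_two_conformer_fixture_alternate_regression(self, standard_fixture):
        sf = standard_fixture
        rep = classify_ensemble(sf.alt_map, sf.member_maps, sf.region, lam="cv", seed=0)
        variable_idx = [
            i for i, t in enumerate(sf.ensemble.truth_labels) if t == "variable"
        ]
        for i in variable_idx:
            assert rep.labels[i] == "noise_variant"  # significant ω vs the alternate
            assert rep.weights[i] > 0
            assert rep.p_values[i] <= 0.05

    def test_self_representation(self, standard_fixture):
        sf = standard_fixture
        rep = classify_ensemble(sf.base_map, [sf.base_map], sf.region, lam="cv", seed=0)
        assert rep.labels == ["noise_variant"]
        assert rep.weights[0] == pytest.approx(1.0, abs=1e-3)

    def test_report_partition_invariant(self, standard_fixture):
        sf = standard_fixture
        rep = classify_ensemble(sf.base_map, sf.member_maps, sf.region, lam="cv", seed=0)
        assert len(rep.labels) == len(sf.member_maps)
        assert set(rep.labels) <= {"noise_variant", "truly_variable"}
        assert np.all((rep.p_values >= 0) & (rep.p_values <= 1))

    def test_invalid_alpha(self, standard_fixture):
        sf = standard_fixture
        with pytest.raises(ValueError):
            classify_ensemble(sf.base_map, sf.member_maps, sf.region, alpha=1.5)


class TestWindowedProfile:
    def test_whole_chain_window_equals_global_fit(self, standard_fixture):
        sf = standard_fixture
        lam = 10.0
        prof = windowed_profile(
            sf.crystal.base, sf.base_map, sf.member_maps, window=99, margin=2.0, lam=lam
        )
        residues = sf.crystal.base.residue_indices
        region = fragment_box(
            sf.crystal.base, (int(residues.min()), int(residues.max())), 2.0, sf.base_map
        )
        p = build_problem(sf.base_map, sf.member_maps, region)
        global_fit = lasso_fit(p, lam)
        for row in prof.weights:
            np.testing.assert_allclose(row, global_fit.weights, atol=1e-8)

    def test_even_window_rejected(self, standard_fixture):
        sf = standard_fixture
        with pytest.raises(ValueError):
            windowed_profile(sf.crystal.base, sf.base_map, sf.member_maps, window=4)

    def test_window_one_equals_fragment_size_one(self, standard_fixture):
        sf = standard_fixture
        w1 = windowed_profile(
            sf.crystal.base, sf.base_map, sf.member_maps, window=1, margin=2.0, lam=10.0
        )
        f1 = fragment_profile(
            sf.crystal.base, sf.base_map, sf.member_maps, fragment_size=1,
            margin=2.0, lam=10.0,
        )
        np.testing.assert_allclose(w1.weights, f1.weights, atol=1e-10)

    def test_localized_perturbation_contrast(self):
        # two members: one a faithful (lightly noisy) copy, one displaced only
        # in residues 9-12; inside that stretch the displaced member's weight
        # collapses while the faithful member keeps representing the base.
        # Windows at the far chain start (spatially remote in the helix) see
        # two near-identical predictors and share the weight.
        base = dv.make_toy_protein(16, "helix", seed=3)
        rng = np.random.default_rng(0)
        faithful = base.with_coords(base.coords + rng.normal(0, 0.1, (len(base), 3)))
        coords = base.coords.copy()
        ridx = base.residue_indices
        inside = (ridx >= 9) & (ridx <= 12)
        coords[inside] += np.array([1.2, 0.6, -0.8])
        displaced = base.with_coords(coords + rng.normal(0, 0.1, (len(base), 3)))
        fx = dv.make_two_conformer_crystal(base, displaced, d_min=2.0)
        shape = fx.mixed_map.shape
        base_map = density_map(fx.base, fx.cell, fx.spacing, shape=shape)
        shift = fx.base.coords[0] - base.coords[0]
        maps = [
            density_map(faithful.translated(shift), fx.cell, fx.spacing, shape=shape),
            density_map(fx.alternate, fx.cell, fx.spacing, shape=shape),
        ]
        prof = windowed_profile(base_conf=fx.base, base_map=base_map,
                                member_maps=maps, window=3, margin=2.0, lam=10.0)
        rows_in = np.isin(prof.residues, np.arange(10, 12))
        rows_out = prof.residues <= 3
        diff = prof.weights[:, 0] - prof.weights[:, 1]
        # designed separation inside; contrast ratio > 2 vs remote windows
        assert diff[rows_in].mean() > 2 * abs(diff[rows_out].mean()) + 0.1
        # displaced member fully dropped where it departs from the base
        assert np.all(prof.weights[rows_in, 1] < 0.01)
        # remote windows: weight shared, displaced member still represents
        assert prof.weights[rows_out, 1].mean() > 0.2

    def test_dropped_member_weight_zero(self):
        # member map empty over a remote window gets weight 0, not an error
        base = dv.make_toy_protein(4, "helix", seed=0)
        cell, shift = __import__("densvar").density.auto_cell([base])
        conf = base.translated(shift)
        grid = density_map(conf, cell, 0.7)
        empty = dv.DensityGrid(cell, np.zeros(grid.shape))
        prof = windowed_profile(conf, grid, [grid, empty], window=1, lam=1.0)
        np.testing.assert_array_equal(prof.weights[:, 1], 0.0)


class TestAverageWeight:
    def test_constant_rows(self, standard_fixture):
        sf = standard_fixture
        prof = windowed_profile(
            sf.crystal.base, sf.base_map, sf.member_maps, window=99, lam=10.0
        )
        np.testing.assert_allclose(average_weight(prof), prof.weights[0], atol=1e-12)

    def test_permutation_invariance(self, standard_fixture):
        sf = standard_fixture
        prof = windowed_profile(
            sf.crystal.base, sf.base_map, sf.member_maps, window=3, lam=10.0
        )
        avg = average_weight(prof)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(prof.residues))
        prof.weights = prof.weights[perm]
        np.testing.assert_allclose(average_weight(prof), avg, atol=1e-15)

    def test_noise_members_rank_above_variable(self, standard_fixture):
        sf = standard_fixture
        prof = windowed_profile(
            sf.crystal.base, sf.base_map, sf.member_maps, window=3, lam=10.0
        )
        avg = average_weight(prof)
        truth = sf.ensemble.truth_labels
        worst_noise = min(avg[i] for i, t in enumerate(truth) if t == "noise")
        best_variable = max(avg[i] for i, t in enumerate(truth) if t == "variable")
        assert worst_noise > best_variable
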