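import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from litnet.models import (
    LabeledPairTable,
    CaseWeights,
    WKLRModel,
    WLRModel,
    bootstrap_tune,
    build_kernel_matrix,
    classify,
    compute_weights,
    fit_wklr,
    fit_wlr,
    gene_persistence,
    load_model,
    predict_proba,
    rbf_kernel,
    save_model,
    threshold_persistence,
    wklr_loglik,
    wlr_gradient,
    wlr_loglik,
)


def make_table(X, y):
    return LabeledPairTable(pairs=[(f"a{i}", f"b{i}") for i in range(len(y))], X=X, y=y)


def random_table(rng, n=80, d=4, sep=2.0):
    X = rng.normal(size=(n, d))
    eta = sep * X[:, 0] - 0.5
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    if y.min() == y.max():  # ensure both classes
        y[0], y[1] = 0, 1
    return make_table(X, y)


class TestWeights:
    def test_balanced_classes_give_unit_weights(self):
        w = compute_weights(np.array([0, 1, 0, 1]))
        assert w.w == pytest.approx([1, 1, 1, 1])

    def test_rare_event_arithmetic(self):
        y = np.array([1, 1] + [0] * 8)
        w = compute_weights(y)
        assert w.w[:2] == pytest.approx([2.5, 2.5])
        assert w.w[2:] == pytest.approx([0.625] * 8)
        assert w.w.sum() == pytest.approx(10)

    def test_tau_equal_to_sample_rate_is_identity(self):
        y = np.array([1, 0, 0, 0])
        w = compute_weights(y, tau=0.25)
        assert w.w == pytest.approx([1, 1, 1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_weights(np.zeros(5))


class TestWLRObjective:
    def test_loglik_at_zero_is_minus_n_log2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 3))
        y = np.array([0, 1, 0, 1, 1, 0, 0], dtype=float)
        val = wlr_loglik(np.zeros(4), X, y, np.ones(7), 0.0)
        assert val == pytest.approx(-7 * np.log(2))

    def test_numerically_stable_at_extreme_linear_predictor(self):
        X = np.array([[100.0], [-100.0]])
        y = np.array([1.0, 0.0])
        val = wlr_loglik(np.array([0.0, 5.0]), X, y, np.ones(2), 0.0)
        assert np.isfinite(val)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        y = (rng.random(12) < 0.4).astype(float)
        w = rng.uniform(0.5, 2.0, size=12)
        beta = rng.normal(scale=0.5, size=4)
        lam = 0.7
        grad = wlr_gradient(beta, X, y, w, lam)
        eps = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            fd = (wlr_loglik(beta + e, X, y, w, lam) - wlr_loglik(beta - e, X, y, w, lam)) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-6)


class TestFitWLR:
    def test_gradient_vanishes_at_solution(self):
        rng = np.random.default_rng(2)
        table = random_table(rng)
        w = compute_weights(table.y)
        model = fit_wlr(table, w, 0.5)
        assert model.converged
        g = wlr_gradient(model.beta, table.X, table.y, w.w, 0.5)
        assert np.max(np.abs(g)) <= 1e-6

    def test_one_dimensional_fit_matches_dense_grid_search(self):
        X = np.array([[-1.0], [0.0], [0.5], [1.0]])
        y = np.array([0, 1, 0, 1])
        w = np.ones(4)
        lam = 0.1
        model = fit_wlr(make_table(X, y), CaseWeights(w=w), lam)
        b0s = np.linspace(-2, 2, 801)
        b1s = np.linspace(-2, 2, 801)
        B0, B1 = np.meshgrid(b0s, b1s, indexing="ij")
        eta = B0[..., None] + B1[..., None] * X[:, 0]
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(-1) - lam / 2 * B1**2
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert model.beta == pytest.approx([b0s[i], b1s[j]], abs=1e-2 + 1e-3)

    def test_matches_sklearn_ridge_logistic(self):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(3)
        for seed in range(3):
            table = random_table(np.random.default_rng(seed), n=120, d=5)
            lam = 1.3
            model = fit_wlr(table, CaseWeights(w=np.ones(table.n)), lam)
            ref = sklearn_lm.LogisticRegression(
                C=1.0 / lam, tol=1e-12, max_iter=5000
            ).fit(table.X, table.y)
            assert model.beta[0] == pytest.approx(ref.intercept_[0], abs=1e-4)
            assert model.beta[1:] == pytest.approx(ref.coef_[0], abs=1e-4)

    def test_duplicating_rows_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, n=40)
        w = CaseWeights(w=np.ones(table.n))
        m1 = fit_wlr(table, w, 0.3)
        doubled = make_table(np.vstack([table.X, table.X]), np.concatenate([table.y, table.y]))
        m2 = fit_wlr(doubled, CaseWeights(w=np.ones(doubled.n)), 0.6)
        assert m1.beta == pytest.approx(m2.beta, abs=1e-6)

    def test_huge_penalty_shrinks_slopes_to_weighted_log_odds_intercept(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=60)
        w = CaseWeights(w=np.ones(table.n))
        model = fit_wlr(table, w, 1e9)
        assert np.max(np.abs(model.beta[1:])) < 1e-6
        ybar = table.y.mean()
        assert model.beta[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)


class TestRBF:
    def test_identical_points_give_unit_kernel(self):
        x = np.array([0.3, 0.7])
        assert rbf_kernel(x, x, 0.5) == 1.0

    def test_distance_sigma_sqrt2_gives_inverse_e(self):
        x = np.zeros(2)
        y = np.array([1.0, 1.0])  # ||x-y|| = sqrt(2) = sigma*sqrt(2) at sigma=1
        assert rbf_kernel(x, y, 1.0) == pytest.approx(np.exp(-1))

    def test_kernel_matrix_psd_and_symmetric(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(size=(5, 9))
        K = build_kernel_matrix(X, 0.8)
        assert K == pytest.approx(K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-9

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(2), np.ones(2), 0.0)
        with pytest.raises(ValueError):
            build_kernel_matrix(np.zeros((2, 2)), -1.0)


class TestFitWKLR:
    def test_matches_generic_optimizer(self):
        rng = np.random.default_rng(7)
        n = 30
        X = rng.uniform(size=(n, 3))
        y = (rng.random(n) < 0.4).astype(int)
        table = make_table(X, y)
        w = compute_weights(table.y)
        lam, sigma = 0.05, 0.7
        model = fit_wklr(table, w, lam, sigma)
        K = build_kernel_matrix(X, sigma)

        def neg_grad(a):
            p = 1 / (1 + np.exp(-(K @ a)))
            return -(K @ (w.w * (table.y - p)) - lam * (K @ a))

        ref = minimize(
            lambda a: -wklr_loglik(a, K, table.y, w.w, lam),
            np.zeros(n),
            jac=neg_grad,
            method="L-BFGS-B",
            options={"maxiter": 50000, "ftol": 1e-15, "gtol": 1e-12},
        )
        p_model = predict_proba(model, X)
        p_ref = 1 / (1 + np.exp(-build_kernel_matrix(X, sigma, Y=X) @ ref.x))
        assert p_model == pytest.approx(p_ref, abs=1e-4)

    def test_label_flip_mirrors_probabilities(self):
        rng = np.random.default_rng(8)
        n = 25
        X = rng.uniform(size=(n, 2))
        y = (rng.random(n) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        w = CaseWeights(w=np.ones(n))
        m1 = fit_wklr(make_table(X, y), w, 0.1, 0.5)
        m2 = fit_wklr(make_table(X, 1 - y), w, 0.1, 0.5)
        assert predict_proba(m1, X) == pytest.approx(1 - predict_proba(m2, X), abs=1e-6)

    def test_flat_kernel_limit_is_constant_rate(self):
        rng = np.random.default_rng(9)
        n = 40
        X = rng.normal(size=(n, 3))
        X -= X.mean(axis=0)
        y = (rng.random(n) < 0.3).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        w = np.ones(n)
        lam = 0.01
        model = fit_wklr(make_table(X, y), CaseWeights(w=w), lam, sigma=1e4)
        # with K ~ all-ones, eta is a constant s maximizing the 1-D objective
        ref = minimize_scalar(
            lambda s: -(np.sum(w * (y * s - np.logaddexp(0.0, s))) - lam / 2 * s**2),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        p_const = 1 / (1 + np.exp(-ref.x))
        assert predict_proba(model, X) == pytest.approx(np.full(n, p_const), abs=0.02)


class TestPredictClassify:
    def test_zero_eta_gives_half(self):
        model = WLRModel(beta=np.zeros(3), lam=0.0, converged=True, iterations=0)
        assert predict_proba(model, np.ones((1, 2)))[0] == pytest.approx(0.5)

    def test_wlr_closed_form(self):
        model = WLRModel(beta=np.array([0.0, 1.0, 0.0]), lam=0.0, converged=True, iterations=0)
        p = predict_proba(model, np.array([[np.log(3), 5.0]]))
        assert p[0] == pytest.approx(0.75)

    def test_wklr_lone_training_point(self):
        model = WKLRModel(
            alpha=np.array([2.0]),
            sigma=1.0,
            lam=0.0,
            train_x=np.array([[0.2, 0.4]]),
            converged=True,
            iterations=0,
        )
        p = predict_proba(model, np.array([[0.2, 0.4]]))
        assert p[0] == pytest.approx(1 / (1 + np.exp(-2)))

    def test_dimension_mismatch_rejected(self):
        model = WLRModel(beta=np.zeros(3), lam=0.0, converged=True, iterations=0)
        with pytest.raises(ValueError):
            predict_proba(model, np.ones((1, 5)))

    def test_boundary_probability_assigned_to_class_zero(self):
        assert classify(np.array([0.5]), 0.5)[0] == 0
        assert classify(np.array([0.5000001]), 0.5)[0] == 1

    def test_all_below_threshold_gives_zeros(self):
        assert classify(np.array([0.1, 0.2, 0.3]), 0.5).sum() == 0


class TestThresholdPersistence:
    def test_examples(self):
        model = WLRModel(beta=np.array([0.0, 1.0]), lam=0.0, converged=True, iterations=0)
        # eta = x -> p = sigmoid(x); choose x so p = 0.85, 0.55, 0.2
        xs = [np.log(p / (1 - p)) for p in (0.85, 0.55, 0.2)]
        table = LabeledPairTable(
            pairs=[("A", "B"), ("A", "C"), ("B", "C")],
            X=np.array(xs)[:, None],
            y=np.zeros(3, dtype=int),
        )
        pers = threshold_persistence(model, table, (0.5, 0.6, 0.7, 0.8))
        assert pers[("A", "B")] == pytest.approx(0.8)
        assert pers[("A", "C")] == pytest.approx(0.5)
        assert pers[("B", "C")] is None
        genes = gene_persistence(pers)
        assert genes["A"] == pytest.approx(0.8)
        assert genes["C"] == pytest.approx(0.5)

    def test_monotone_in_probability(self):
        model = WLRModel(beta=np.array([0.0, 1.0]), lam=0.0, converged=True, iterations=0)
        thresholds = (0.5, 0.6, 0.7, 0.8)
        grid = np.linspace(0.01, 0.99, 197)
        etas = np.log(grid / (1 - grid))
        table = LabeledPairTable(
            pairs=[(f"g{i}", f"h{i}") for i in range(len(grid))],
            X=etas[:, None],
            y=np.zeros(len(grid), dtype=int),
        )
        pers = threshold_persistence(model, table, thresholds)
        vals = [pers[p] if pers[p] is not None else 0.0 for p in table.pairs]
        assert vals == sorted(vals)

    def test_unsorted_thresholds_rejected(self):
        model = WLRModel(beta=np.zeros(2), lam=0.0, converged=True, iterations=0)
        table = make_table(np.zeros((1, 1)), np.array([0]))
        with pytest.raises(ValueError):
            threshold_persistence(model, table, (0.8, 0.5))


class TestBootstrapTune:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(10)
        table = random_table(rng, n=50, d=2)
        res = bootstrap_tune(table, [0.5], B=3, seed=0)
        assert res.best == (0.5,)
        assert len(res.grid) == 1 and res.rounds == 3

    def test_same_seed_is_deterministic(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, n=60, d=3)
        a = bootstrap_tune(table, [0.01, 1.0, 100.0], B=5, seed=42)
        b = bootstrap_tune(table, [0.01, 1.0, 100.0], B=5, seed=42)
        assert a.best == b.best and a.scores == b.scores

    def test_noisier_data_selects_at_least_as_much_shrinkage(self):
        lambdas = [1e-3, 1e-1, 10.0, 1000.0]
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n, d = 150, 4
            X = rng.normal(size=(n, d))
            beta = np.array([3.0, -2.0, 1.5, 0.5])
            strong = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
            weak = (rng.random(n) < 1 / (1 + np.exp(-(0.1 * X @ beta)))).astype(int)
            for y in (strong, weak):
                if y.min() == y.max():
                    y[0] = 1 - y[0]
            best_strong = bootstrap_tune(make_table(X, strong), lambdas, B=10, seed=seed).best[0]
            best_weak = bootstrap_tune(make_table(X, weak), lambdas, B=10, seed=seed).best[0]
            if best_weak >= best_strong:
                wins += 1
        assert wins > 5

    def test_kernel_model_beats_linear_on_xor_data(self):
        from litnet.evaluation import auc, roc_curve

        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            n = 160
            X = rng.uniform(-1, 1, size=(n, 9))
            y = ((X[:, 0] * X[:, 1]) > 0).astype(int)  # XOR-style rule
            flip = rng.random(n) < 0.05
            y[flip] = 1 - y[flip]
            table = make_table(X, y)
            w = compute_weights(table.y)
            lin = fit_wlr(table, w, 0.1)
            ker = fit_wklr(table, w, 0.01, 0.5)
            auc_lin = auc(roc_curve(predict_proba(lin, X), y))
            auc_ker = auc(roc_curve(predict_proba(ker, X), y))
            if auc_ker >= auc_lin:
                wins += 1
        assert wins > 5


class TestModelIO:
    def test_wlr_round_trip(self, tmp_path):
        model = WLRModel(beta=np.array([0.1, -2.0, 3.5]), lam=0.7, converged=True, iterations=9)
        path = tmp_path / "m.yaml"
        save_model(model, path)
        loaded = load_model(path)
        assert isinstance(loaded, WLRModel)
        assert loaded.beta == pytest.approx(model.beta)
        assert loaded.lam == model.lam

    def test_wklr_round_trip_with_checksum(self, tmp_path):
        rng = np.random.default_rng(12)
        model = WKLRModel(
            alpha=rng.normal(size=4),
            sigma=0.5,
            lam=0.01,
            train_x=rng.uniform(size=(4, 3)),
            converged=True,
            iterations=3,
        )
        path = tmp_path / "m.yaml"
        save_model(model, path)
        loaded = load_model(path)
        assert isinstance(loaded, WKLRModel)
        assert loaded.alpha == pytest.approx(model.alpha)
        assert loaded.train_x == pytest.approx(model.train_x)
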