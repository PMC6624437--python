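import copy
import math

import numpy as np
import pytest

from embryopt import anfis
from embryopt.anfis import (
    AnfisModel,
    FuzzyRule,
    GaussianMF,
    TrainConfig,
    fit,
    init_rules_grid,
    init_rules_subtractive,
    membership,
    normalize_strengths,
    premise_gradient_step,
    solve_consequents,
)
from tests.conftest import random_anfis


def forward_oracle(model, x):
    """Independent five-layer evaluation with plain Python loops."""
    xs = []
    for j in range(model.dim):
        lo, hi = model.input_ranges[j]
        span = hi - lo if hi > lo else 1.0
        xs.append((x[j] - lo) / span)
    # layer 1-2: membership grades and product firing strengths
    w = []
    for rule in model.rules:
        prod = 1.0
        for j in range(model.dim):
            prod *= math.exp(
                -((xs[j] - rule.centers[j]) ** 2) / (2.0 * rule.sigmas[j] ** 2)
            )
        w.append(prod)
    # layer 3: normalization (with the documented floor fallback)
    total = sum(w)
    if total < anfis.STRENGTH_FLOOR:
        wbar = [1.0 / len(w)] * len(w)
    else:
        wbar = [wi / total for wi in w]
    # layers 4-5: weighted first-order consequents, summed
    out = 0.0
    for rule, wb in zip(model.rules, wbar):
        z = rule.consequent[-1]
        for j in range(model.dim):
            z += rule.consequent[j] * xs[j]
        out += wb * z
    return out


class TestMembership:
    def test_peak_at_center(self):
        assert membership(GaussianMF(2.0, 0.5), 2.0) == 1.0

    def test_one_sigma_away(self):
        assert membership(GaussianMF(0.0, 1.0), 1.0) == pytest.approx(math.exp(-0.5))

    def test_symmetry(self):
        mf = GaussianMF(1.0, 0.3)
        assert membership(mf, 1.7) == pytest.approx(membership(mf, 0.3))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            GaussianMF(0.0, 0.0)


class TestFiringStrengths:
    def test_single_rule_at_center(self):
        model = AnfisModel(
            [FuzzyRule([0.5, 0.5], [1.0, 1.0], [0, 0, 0])],
            ["a", "b"],
            "y",
            np.array([[0, 1], [0, 1]]),
        )
        assert model.firing_strengths(np.array([0.5, 0.5]))[0] == pytest.approx(1.0)

    def test_product_of_grades(self):
        # choose sigma so grades are exactly 0.5 and 0.4 at x = (1, 1), scaled space
        s1 = math.sqrt(-1.0 / (2 * math.log(0.5)))
        s2 = math.sqrt(-1.0 / (2 * math.log(0.4)))
        model = AnfisModel(
            [FuzzyRule([0.0, 0.0], [s1, s2], [0, 0, 0])],
            ["a", "b"],
            "y",
            np.array([[0, 1], [0, 1]]),
        )
        w = model.firing_strengths(np.array([1.0, 1.0]))
        assert w[0] == pytest.approx(0.2, rel=1e-12)

    def test_matches_per_factor_product_oracle(self, rng):
        model = random_anfis(rng, n_rules=5, dim=4)
        for _ in range(20):
            x = rng.uniform(0, 1, 4)
            w = model.firing_strengths(x)
            for k, rule in enumerate(model.rules):
                expected = 1.0
                for j in range(4):
                    expected *= membership(
                        GaussianMF(rule.centers[j], rule.sigmas[j]), x[j]
                    )
                assert w[k] == pytest.approx(expected, rel=1e-12)


class TestNormalizeStrengths:
    def test_equal_weights(self):
        wbar, floored = normalize_strengths(np.array([[0.2, 0.2]]))
        assert np.allclose(wbar, [0.5, 0.5]) and not floored.any()

    def test_single_rule(self):
        wbar, _ = normalize_strengths(np.array([[0.7]]))
        assert wbar[0, 0] == 1.0

    def test_sums_to_one(self, rng):
        W = rng.uniform(0, 1, size=(50, 6))
        wbar, _ = normalize_strengths(W)
        assert np.allclose(wbar.sum(axis=1), 1.0)

    def test_underflow_floor_gives_uniform_and_flags(self):
        wbar, floored = normalize_strengths(np.array([[1e-20, 1e-20, 1e-20]]))
        assert floored[0]
        assert np.allclose(wbar, 1 / 3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_strengths(np.array([[-0.1, 0.5]]))


class TestPredict:
    def test_single_rule_is_its_consequent(self):
        model = AnfisModel(
            [FuzzyRule([0.0], [1.0], [2.0, 1.0])],  # z = 2x + 1 (scaled x)
            ["x"],
            "y",
            np.array([[0.0, 1.0]]),
        )
        for x in [0.0, 0.25, 1.0]:
            assert model.predict(np.array([x])) == pytest.approx(2 * x + 1)

    def test_identical_consequents_dominate_premises(self, rng):
        rules = [
            FuzzyRule(rng.uniform(0, 1, 2), rng.uniform(0.1, 1, 2), [1.0, -2.0, 0.5])
            for _ in range(4)
        ]
        model = AnfisModel(rules, ["a", "b"], "y", np.array([[0, 1], [0, 1]]))
        x = rng.uniform(0, 1, 2)
        assert model.predict(x) == pytest.approx(x[0] - 2 * x[1] + 0.5)

    def test_forward_pass_matches_oracle_1000_cases(self, rng):
        for _ in range(100):
            model = random_anfis(rng, n_rules=int(rng.integers(1, 6)), dim=3)
            X = rng.uniform(-0.5, 1.5, size=(10, 3))
            pred = model.predict(X)
            for i in range(10):
                assert pred[i] == pytest.approx(forward_oracle(model, X[i]), abs=1e-12)

    def test_prediction_is_convex_combination_of_consequents(self, rng):
        model = random_anfis(rng, n_rules=5, dim=3)
        Xs = rng.uniform(0, 1, size=(200, 3))
        from embryopt.anfis import _consequent_values

        Z = _consequent_values(Xs, model.rules)
        pred = model.predict(Xs)
        assert np.all(pred <= Z.max(axis=1) + 1e-9)
        assert np.all(pred >= Z.min(axis=1) - 1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        model = random_anfis(rng, dim=3)
        with pytest.raises(ValueError):
            model.predict(np.zeros(5))


class TestGridInit:
    def test_two_inputs_three_mfs(self, rng):
        X = rng.uniform(0, 1, size=(20, 2))
        assert len(init_rules_grid(X, 3)) == 9

    def test_one_input_five_mfs_centers_span_range(self, rng):
        X = rng.uniform(2.0, 8.0, size=(30, 1))
        rules = init_rules_grid(X, 5)
        assert len(rules) == 5
        centers = sorted(r.centers[0] for r in rules)
        assert centers[0] == pytest.approx(X.min())
        assert centers[-1] == pytest.approx(X.max())

    def test_eight_inputs_rejected(self, rng):
        X = rng.uniform(0, 1, size=(20, 8))
        with pytest.raises(ValueError, match="6561"):
            init_rules_grid(X, 3)


class TestSubtractiveInit:
    def test_two_separated_clouds_give_two_rules(self, rng):
        a = rng.normal(0.15, 0.02, size=(25, 2))
        b = rng.normal(0.85, 0.02, size=(25, 2))
        X = np.clip(np.vstack([a, b]), 0, 1)
        rules = init_rules_subtractive(X, cluster_radius=0.5)
        assert len(rules) == 2
        centers = np.array(sorted(r.centers.tolist() for r in rules))
        assert np.allclose(centers[0], 0.15, atol=0.07)
        assert np.allclose(centers[1], 0.85, atol=0.07)
        # brute-force potential maximum equals the first accepted center
        sq = ((X[:, None] - X[None]) ** 2).sum(-1)
        pot = np.exp(-4 / 0.5**2 * sq).sum(1)
        best = X[np.argmax(pot)]
        assert any(np.allclose(r.centers, best) for r in rules)

    def test_single_duplicated_row_gives_one_rule(self):
        X = np.tile([0.3, 0.7], (40, 1))
        assert len(init_rules_subtractive(X, 0.5)) == 1

    def test_rule_count_clamped_at_30(self, rng):
        X = rng.uniform(0, 1, size=(200, 3))
        assert len(init_rules_subtractive(X, 0.05)) <= 30


class TestSolveConsequents:
    def test_exact_linear_recovery_single_rule(self, rng):
        X = rng.uniform(0, 10, size=(40, 2))
        y = 3.0 * X[:, 0] - 1.5 * X[:, 1] + 2.0
        model = AnfisModel(
            [FuzzyRule([0.5, 0.5], [5.0, 5.0], np.zeros(3))],
            ["a", "b"],
            "y",
            np.stack([X.min(0), X.max(0)], axis=1),
        )
        solve_consequents(model, X, y, ridge_lambda=1e-12)
        assert np.allclose(model.predict(X), y, atol=1e-6)

    def test_large_lambda_shrinks_slopes(self, rng):
        X = rng.uniform(0, 1, size=(60, 2))
        y = 5 * X[:, 0] + rng.normal(0, 0.1, 60)
        model = random_anfis(rng, n_rules=3, dim=2)
        model.input_names = ["a", "b"]
        solve_consequents(model, X, y, ridge_lambda=1e-6)
        small = max(np.abs(r.consequent[:-1]).max() for r in model.rules)
        solve_consequents(model, X, y, ridge_lambda=1e6)
        big = max(np.abs(r.consequent[:-1]).max() for r in model.rules)
        assert big < 1e-3 * small

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.uniform(0, 1, size=(30, 2))
        y = rng.normal(size=30)
        model = random_anfis(rng, n_rules=3, dim=2)
        lam, intf = 0.05, 1e-6
        solve_consequents(model, X, y, lam, intf)
        # independent oracle: explicit penalized normal equations on the
        # mean-centered targets
        from embryopt.anfis import _design_matrix

        A = _design_matrix(model._scale(X), model.rules)
        D = np.diag(np.tile(np.r_[1.0, 1.0, intf], 3))
        theta = np.linalg.inv(A.T @ A + lam * D) @ A.T @ (y - y.mean())
        for i, rule in enumerate(model.rules):
            expected = theta[3 * i : 3 * i + 3].copy()
            expected[-1] += y.mean()
            assert np.allclose(rule.consequent, expected, atol=1e-8)

    def test_nonfinite_rejected(self, rng):
        model = random_anfis(rng, dim=2)
        with pytest.raises(ValueError):
            solve_consequents(model, np.array([[np.nan, 0.0]]), np.array([1.0]))


class TestPremiseGradientStep:
    def test_zero_error_leaves_parameters_unchanged(self, rng):
        # single rule -> prediction equals the consequent; fit it exactly
        X = rng.uniform(0, 1, size=(30, 2))
        model = AnfisModel(
            [FuzzyRule([0.5, 0.5], [0.4, 0.4], [1.0, 2.0, 0.0])],
            ["a", "b"],
            "y",
            np.array([[0, 1], [0, 1]], dtype=float),
        )
        y = model.predict(X)
        before = copy.deepcopy(model.rules)
        premise_gradient_step(model, X, y, learning_rate=0.1)
        assert np.allclose(model.rules[0].centers, before[0].centers)
        assert np.allclose(model.rules[0].sigmas, before[0].sigmas)

    def test_zero_learning_rate_is_identity(self, rng):
        model = random_anfis(rng, n_rules=3, dim=2)
        X = rng.uniform(0, 1, size=(20, 2))
        y = rng.normal(size=20)
        before = copy.deepcopy(model.rules)
        premise_gradient_step(model, X, y, learning_rate=0.0)
        for b, a in zip(before, model.rules):
            assert np.allclose(b.centers, a.centers)
            assert np.allclose(b.sigmas, a.sigmas)

    def test_gradient_matches_finite_differences(self, rng):
        model = random_anfis(rng, n_rules=3, dim=2)
        X = rng.uniform(0, 1, size=(25, 2))
        y = rng.normal(size=25)

        def mse(m):
            return float(np.mean((m.predict(X) - y) ** 2))

        lr = 1e-6  # small enough that the sigma floor never clamps the step
        stepped = copy.deepcopy(model)
        premise_gradient_step(stepped, X, y, learning_rate=lr)
        eps = 1e-6
        for i in range(3):
            for j in range(2):
                for attr in ("centers", "sigmas"):
                    up = copy.deepcopy(model)
                    dn = copy.deepcopy(model)
                    getattr(up.rules[i], attr)[j] += eps
                    getattr(dn.rules[i], attr)[j] -= eps
                    fd = (mse(up) - mse(dn)) / (2 * eps)
                    analytic = (
                        getattr(model.rules[i], attr)[j]
                        - getattr(stepped.rules[i], attr)[j]
                    ) / lr
                    assert analytic == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestFit:
    def test_linear_target_noise_free_near_zero_rmse(self, rng):
        X = rng.uniform(0, 5, size=(50, 1))
        y = 2.0 * X[:, 0] + 1.0
        cfg = TrainConfig(rule_init="grid", mfs_per_input=3, n_epochs=3, ridge_lambda=1e-10)
        model, trace = fit(X, y, cfg)
        assert trace[0] < 1e-6

    def test_retained_loss_non_increasing(self, default_split):
        train, _ = default_split
        X = train[["d24", "bap", "glu"]].to_numpy()
        model, trace = fit(X, train["ef"].to_numpy(), TrainConfig(n_epochs=10))
        best_so_far = np.minimum.accumulate(trace)
        assert (np.diff(best_so_far) <= 1e-12).all()
        assert min(trace) == pytest.approx(best_so_far[-1])

    def test_recovers_known_small_anfis_function(self, rng):
        truth = random_anfis(rng, n_rules=4, dim=2)
        X = rng.uniform(0, 1, size=(300, 2))
        y = truth.predict(X)
        model, _ = fit(
            X, y, TrainConfig(rule_init="grid", mfs_per_input=3, ridge_lambda=1e-8)
        )
        resid = model.predict(X) - y
        assert np.sqrt(np.mean(resid**2)) < 0.05 * y.std()

    def test_deterministic(self, default_split):
        train, _ = default_split
        X = train[["d24", "bap"]].to_numpy()
        y = train["ef"].to_numpy()
        m1, t1 = fit(X, y)
        m2, t2 = fit(X, y)
        assert t1 == t2
        assert m1.to_dict() == m2.to_dict()

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit(rng.uniform(size=(5, 2)), rng.uniform(size=5))


def test_serialization_round_trip_lossless(tmp_path, rng):
    model = random_anfis(rng, n_rules=4, dim=5)
    path = tmp_path / "model.json"
    model.save_json(path)
    back = AnfisModel.load_json(path)
    for r1, r2 in zip(model.rules, back.rules):
        assert (r1.centers == r2.centers).all()
        assert (r1.sigmas == r2.sigmas).all()
        assert (r1.consequent == r2.consequent).all()
    assert (model.input_ranges == back.input_ranges).all()
    assert back.input_names == model.input_names
    X = rng.uniform(0, 1, size=(20, 5))
    assert np.array_equal(model.predict(X), back.predict(X))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(n_epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(mfs_per_input=6)
    with pytest.raises(ValueError):
        TrainConfig(cluster_radius=0.0)
    with pytest.raises(ValueError):
        TrainConfig(rule_init="random")
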