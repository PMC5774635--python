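import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from popadjust import (
    CovariateSpec,
    CovariateSummary,
    IPDTrial,
    MAICWeighter,
    build_moment_matrix,
    effective_sample_size,
    fit_entropy_weights,
    fit_maic_weights,
    weight_summary,
    weighted_arm_estimates,
)
from popadjust.maic import SupportError

from conftest import make_random_trial, random_targets


# -- moment matrix ----------------------------------------------------

def test_mean_column_is_centered(toy_binary_trial):
    Z = build_moment_matrix(toy_binary_trial, [CovariateSummary("x", 0.75)])
    np.testing.assert_allclose(Z.Z[:, 0], [-0.75, -0.75, 0.25, 0.25])


def test_variance_column_uses_second_raw_moment():
    rng = np.random.default_rng(0)
    x = rng.normal(60, 8, 100)
    df = pd.DataFrame({"arm": ["A"] * 50 + ["B"] * 50, "outcome": 0.0, "age": x})
    trial = IPDTrial(
        "AB", df, [CovariateSpec("age", match_moments="mean_and_variance")]
    )
    Z = build_moment_matrix(trial, [CovariateSummary("age", 60, 8)])
    # E[X^2] target = 60^2 + 8^2 = 3664
    np.testing.assert_allclose(Z.Z[:, 1], x**2 - 3664.0)
    assert Z.column_labels == ["age:mean", "age:second_moment"]


def test_target_outside_support_raises(toy_binary_trial):
    with pytest.raises(SupportError, match="support"):
        build_moment_matrix(toy_binary_trial, [CovariateSummary("x", 2.0)])


def test_degenerate_binary_covariate_with_different_target():
    df = pd.DataFrame(
        {"arm": ["A", "A", "B", "B"], "outcome": [0.0] * 4, "x": [1.0] * 4}
    )
    trial = IPDTrial("AB", df, [CovariateSpec("x", kind="binary")])
    with pytest.raises(SupportError):
        build_moment_matrix(trial, [CovariateSummary("x", 0.5)])


def test_collinear_columns_dropped_with_warning():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 40)
    df = pd.DataFrame(
        {"arm": ["A"] * 20 + ["B"] * 20, "outcome": 0.0, "x1": x, "x2": 2 * x}
    )
    trial = IPDTrial("AB", df, [CovariateSpec("x1"), CovariateSpec("x2")])
    with pytest.warns(UserWarning, match="collinear"):
        Z = build_moment_matrix(
            trial, [CovariateSummary("x1", 0.1), CovariateSummary("x2", 0.2)]
        )
    assert Z.k == 1


# -- weight fitting ---------------------------------------------------

def test_closed_form_toy_weights(toy_binary_trial):
    """Balancing x={0,0,1,1} to mean 0.75 requires odds exp(alpha) = 3."""
    Z = build_moment_matrix(toy_binary_trial, [CovariateSummary("x", 0.75)])
    sol = fit_maic_weights(Z)
    assert sol.alpha[0] == pytest.approx(np.log(3), abs=1e-8)
    np.testing.assert_allclose(sol.weights, [0.5, 0.5, 1.5, 1.5], atol=1e-8)
    assert sol.ess == pytest.approx(3.2, abs=1e-8)
    assert sol.converged


def test_null_target_gives_uniform_weights():
    rng = np.random.default_rng(3)
    trial = make_random_trial(rng)
    cov_means = {
        s.name: float(trial.data[s.name].mean()) for s in trial.spec
    }
    targets = [
        CovariateSummary(
            s.name,
            cov_means[s.name],
            None
            if s.match_moments == "mean_only"
            else float(np.sqrt(np.mean(trial.data[s.name] ** 2) - cov_means[s.name] ** 2)),
        )
        for s in trial.spec
    ]
    Z = build_moment_matrix(trial, targets)
    sol = fit_maic_weights(Z)
    np.testing.assert_allclose(sol.alpha, 0.0, atol=1e-6)
    np.testing.assert_allclose(sol.weights, 1.0, atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_moment_balance_random_instances(seed):
    """Weighted means of every matched moment hit the target to 1e-8."""
    rng = np.random.default_rng(seed)
    trial = make_random_trial(rng)
    targets = random_targets(rng, trial)
    Z = build_moment_matrix(trial, targets)
    sol = fit_maic_weights(Z)
    assert sol.converged
    balance = Z.Z.T @ sol.weights / sol.weights.sum()
    assert np.abs(balance).max() < 1e-8
    # raw-moment form of the same identity
    for j, lab in enumerate(Z.column_labels):
        wmean = np.average(Z.raw_columns[:, j], weights=sol.weights)
        assert wmean == pytest.approx(Z.targets[lab], abs=1e-7)


def test_entropy_equals_moments(toy_binary_trial):
    Z = build_moment_matrix(toy_binary_trial, [CovariateSummary("x", 0.75)])
    np.testing.assert_allclose(
        fit_entropy_weights(Z).weights, [0.5, 0.5, 1.5, 1.5], atol=1e-8
    )


def test_entropy_uniform_when_target_feasible_at_uniform():
    rng = np.random.default_rng(11)
    trial = make_random_trial(rng)
    targets = [
        CovariateSummary(s.name, float(trial.data[s.name].mean()))
        for s in trial.spec
        if s.match_moments == "mean_only"
    ]
    spec = [s for s in trial.spec if s.match_moments == "mean_only"]
    Z = build_moment_matrix(trial, targets, spec=spec)
    np.testing.assert_allclose(fit_entropy_weights(Z).weights, 1.0, atol=1e-8)


def test_entropy_matches_primal_constrained_optimizer():
    """Independent oracle: minimise sum w log w subject to the moment
    constraints directly (SLSQP on the primal)."""
    rng = np.random.default_rng(5)
    trial = make_random_trial(rng, n=40)
    targets = random_targets(rng, trial)
    Z = build_moment_matrix(trial, targets)
    n = Z.n

    def neg_entropy(w):
        return float(np.sum(w * np.log(np.maximum(w, 1e-300))))

    cons = [
        {"type": "eq", "fun": lambda w: w.sum() - 1.0},
        {"type": "eq", "fun": lambda w, Zm=Z.Z: Zm.T @ w},
    ]
    res = scipy.optimize.minimize(
        neg_entropy,
        np.full(n, 1.0 / n),
        constraints=cons,
        bounds=[(1e-12, 1.0)] * n,
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success
    sol = fit_entropy_weights(Z)
    np.testing.assert_allclose(sol.weights / n, res.x, atol=5e-6)


def test_fit_raises_on_unknown_method():
    with pytest.raises(ValueError, match="unknown method"):
        MAICWeighter(method="ipw").fit(np.zeros((4, 1)))


def test_sklearn_param_interface():
    est = MAICWeighter(method="entropy", tol=1e-9)
    assert est.get_params()["method"] == "entropy"
    est.set_params(method="moments")
    assert est.method == "moments"


# -- weighted estimates, ESS, diagnostics -----------------------------

def test_weighted_arm_estimates(toy_binary_trial):
    Z = build_moment_matrix(toy_binary_trial, [CovariateSummary("x", 0.75)])
    sol = fit_maic_weights(Z)
    est = weighted_arm_estimates(toy_binary_trial, sol)
    # arm B outcomes (1,1) with weights (1.5,1.5): weighted mean 1
    assert est["B"].ybar == pytest.approx(1.0)
    assert est["A"].ybar == pytest.approx(0.0)


def test_weighted_estimates_uniform_weights_equal_unweighted():
    rng = np.random.default_rng(2)
    trial = make_random_trial(rng)
    from popadjust.maic import WeightSolution

    sol = WeightSolution(
        alpha=np.zeros(1),
        weights=np.ones(trial.n),
        ess=trial.n,
        converged=True,
        gradient_norm=0.0,
        method="moments",
    )
    est = weighted_arm_estimates(trial, sol)
    for arm in trial.arms:
        mask = trial.arm_mask(arm)
        assert est[arm].ybar == pytest.approx(trial.outcomes[mask].mean())


@pytest.mark.parametrize(
    "weights,expected",
    [
        (np.ones(10), 10.0),
        (np.array([1.0, 1.0, 3.0, 3.0]), 3.2),
        (np.array([1.0, 1.0, 2.0]), 16 / 6),
    ],
)
def test_effective_sample_size_values(weights, expected):
    assert effective_sample_size(weights) == pytest.approx(expected)


def test_ess_invariant_to_rescaling_and_bounded():
    rng = np.random.default_rng(4)
    w = rng.gamma(2.0, 1.0, 100)
    ess = effective_sample_size(w)
    assert ess == pytest.approx(effective_sample_size(17.3 * w))
    assert 1 <= ess <= len(w)


def test_ess_rejects_degenerate_weights():
    with pytest.raises(ValueError):
        effective_sample_size(np.zeros(5))
    with pytest.raises(ValueError):
        effective_sample_size(np.array([1.0, -0.5]))


def test_weight_summary_diagnostics(toy_binary_trial):
    Z = build_moment_matrix(toy_binary_trial, [CovariateSummary("x", 0.75)])
    rep = weight_summary(fit_maic_weights(Z))
    assert rep["max"] == pytest.approx(1.5)
    assert rep["top5_shares"][0] == pytest.approx(0.375)
    assert rep["ess"] == pytest.approx(3.2)
    assert "underestimation" in rep["caveat"]


def test_weight_summary_flags_dominant_weight():
    from popadjust.maic import WeightSolution

    w = np.ones(101)
    w[0] = 100.0
    sol = WeightSolution(
        alpha=np.zeros(1),
        weights=w,
        ess=effective_sample_size(w),
        converged=True,
        gradient_norm=0.0,
        method="moments",
    )
    rep = weight_summary(sol)
    assert rep["ess"] == pytest.approx(200**2 / 10100)
    assert "ESS < 10% of N" in rep["flags"]
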