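"""Attribution: kernel Shapley values, substitution SHAP, SHAP_P."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wbcbt import shap_explain
from wbcbt.shap_explain import (
    dominant_direction,
    kernel_shap,
    mean_substitution_shap,
    rank_predictors,
    shap_p,
    summarize,
    whole_model_shap,
)


def brute_force_shapley(f, x, reference):
    """Shapley values by direct averaging over all feature orderings."""
    p = len(x)
    phi = np.zeros(p)
    for order in itertools.permutations(range(p)):
        current = reference.copy()
        prev = f(current[None, :])[0]
        for j in order:
            current[j] = x[j]
            nxt = f(current[None, :])[0]
            phi[j] += nxt - prev
            prev = nxt
    return phi / math.factorial(p)


def _linear(beta):
    beta = np.asarray(beta, dtype=float)
    return lambda X: np.asarray(X, dtype=float) @ beta


def test_linear_model_closed_form_attributions():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 2))
    f = _linear([2.0, 3.0])
    shap = kernel_shap(f, X)
    means = X.mean(axis=0)
    np.testing.assert_allclose(
        shap.values.to_numpy()[:, 0], 2.0 * (X[:, 0] - means[0]), atol=1e-8
    )
    np.testing.assert_allclose(
        shap.values.to_numpy()[:, 1], 3.0 * (X[:, 1] - means[1]), atol=1e-8
    )


def test_kernel_shap_matches_brute_force_permutation_shapley():
    """Exact enumeration equals order-averaged Shapley on models with
    interactions, up to 4 features."""
    rng = np.random.default_rng(1)

    def f3(X):
        X = np.asarray(X, dtype=float)
        return X[:, 0] * X[:, 1] + 2.0 * X[:, 2] + 0.5 * X[:, 0] ** 2

    def f4(X):
        X = np.asarray(X, dtype=float)
        return X[:, 0] * X[:, 1] * X[:, 2] - X[:, 3] + np.sin(X[:, 0])

    for p, f in ((3, f3), (4, f4)):
        X = rng.standard_normal((12, p))
        reference = X.mean(axis=0)
        shap = kernel_shap(f, X, reference=reference)
        for i in range(len(X)):
            expected = brute_force_shapley(f, X[i].copy(), reference.copy())
            np.testing.assert_allclose(
                shap.values.to_numpy()[i], expected, atol=1e-8
            )


def test_local_accuracy_under_exact_enumeration():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((40, 6))

    def f(Xm):
        Xm = np.asarray(Xm, dtype=float)
        return np.exp(0.3 * Xm[:, 0]) + Xm[:, 1] * Xm[:, 2] - Xm[:, 4] ** 2

    shap = kernel_shap(f, X)
    assert np.abs(shap.local_accuracy_residuals()).max() < 1e-6


def test_local_accuracy_holds_exactly_under_sampling():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((20, 15))  # p > 12 forces coalition sampling
    beta = rng.standard_normal(15)
    f = _linear(beta)
    shap = kernel_shap(f, X, coalition_budget=600, seed=0)
    # the constraint keeps the attribution sum exact even when sampled
    assert np.abs(shap.local_accuracy_residuals()).max() < 1e-8
    means = X.mean(axis=0)
    # sampled linear attributions still approximate the closed form
    approx = shap.values.to_numpy()
    exact = (X - means) * beta
    assert np.abs(approx - exact).max() < 1e-2 * max(1, np.abs(exact).max())


def test_constant_model_gives_all_zero_attributions():
    X = np.ones((10, 3)) * np.arange(3)
    shap = kernel_shap(lambda Xm: np.full(len(Xm), 7.0), X)
    assert np.allclose(shap.values.to_numpy(), 0.0)


def test_single_feature_attribution_is_the_prediction_shift():
    X = np.linspace(0, 1, 9)[:, None]
    f = _linear([4.0])
    shap = kernel_shap(f, X)
    np.testing.assert_allclose(
        shap.values.to_numpy()[:, 0], 4.0 * (X[:, 0] - X.mean()), atol=1e-10
    )


# ---------------------------------------------------------------------------
# mean-substitution SHAP and SHAP_P


def test_mean_substitution_closed_form_for_linear_models():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((60, 3))
    beta = np.array([1.5, -2.0, 0.0])
    vals = mean_substitution_shap(_linear(beta), X)
    means = X.mean(axis=0)
    for j in range(3):
        expected = abs(beta[j]) * np.mean(np.abs(X[:, j] - means[j]))
        assert vals.iloc[j] == pytest.approx(expected, abs=1e-10)
    assert vals.iloc[2] == 0.0  # unused feature


def test_mean_substitution_on_a_hand_worked_tree_model():
    """2-feature threshold model on 4 rows, enumerated by hand.

    f = 10 if x0 > 0.5 else 0, plus 1 if x1 > 0.5 else 0.
    X rows: (0,0), (0,1), (1,0), (1,1); column means are (0.5, 0.5);
    substituting the mean sends each indicator to its 'else' branch:
    f(x0=0.5) drops the 10 for rows 3-4 and adds nothing for rows 1-2,
    so value_0 = mean(|0-0|,|0-0|,|10|,|10|) = 5; value_1 = 0.5.
    """

    def tree(X):
        X = np.asarray(X, dtype=float)
        return 10.0 * (X[:, 0] > 0.5) + 1.0 * (X[:, 1] > 0.5)

    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    vals = mean_substitution_shap(tree, X)
    assert vals.iloc[0] == pytest.approx(5.0)
    assert vals.iloc[1] == pytest.approx(0.5)


def test_shap_p_single_feature_is_100_percent():
    X = np.linspace(-1, 1, 20)[:, None]
    assert shap_p(_linear([3.0]), X).iloc[0] == pytest.approx(100.0)


def test_shap_p_symmetric_features_equal_and_sum_above_100():
    """Two orthogonal balanced binary features with symmetric effects:
    each feature's substitution value equals the whole-model value's
    components, and the two SHAP_P values sum above 100%."""
    X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    f = _linear([2.0, 2.0])
    vals = shap_p(f, X)
    assert vals.iloc[0] == pytest.approx(vals.iloc[1])
    assert vals.sum() > 100.0


def test_shap_p_is_scale_equivariant():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((30, 3))

    def f(Xm):
        Xm = np.asarray(Xm, dtype=float)
        return Xm[:, 0] ** 2 + Xm[:, 1]

    base = shap_p(f, X)
    scaled = shap_p(lambda Xm: 37.0 * f(Xm), X)
    pd.testing.assert_series_equal(base, scaled)


def test_shap_p_rejects_constant_models():
    X = np.random.default_rng(6).standard_normal((10, 2))
    with pytest.raises(ValueError, match="constant"):
        shap_p(lambda Xm: np.zeros(len(Xm)), X)


def test_unused_feature_has_zero_shap_p():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((25, 2))
    vals = shap_p(_linear([1.0, 0.0]), X)
    assert vals.iloc[1] == 0.0


# ---------------------------------------------------------------------------
# directions and ranking


def test_dominant_directions_follow_coefficient_signs():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((60, 3))
    shap = kernel_shap(_linear([2.0, -3.0, 0.0]), X)
    d = dominant_direction(shap, X)
    assert d.iloc[0] == "positive"
    assert d.iloc[1] == "negative"
    assert d.iloc[2] == "indeterminate"  # constant zero attribution


def test_symmetric_u_shape_is_flagged_indeterminate():
    x = np.linspace(-2, 2, 81)
    X = x[:, None]
    shap = kernel_shap(lambda Xm: np.asarray(Xm)[:, 0] ** 2, X)
    d = dominant_direction(shap, X)
    assert d.iloc[0] == "indeterminate"


def _summary_frame(values, domains):
    return pd.DataFrame({
        "feature": [f"f{i}" for i in range(len(values))],
        "kernel_mean_abs_shap": values,
        "domain": domains,
    })


def test_rank_predictors_floor_and_per_domain_cap():
    # everything below the floor: empty report
    low = _summary_frame([0.005, 0.003], ["a", "a"])
    assert rank_predictors(low).empty
    # six qualifying features in one domain: five reported
    six = _summary_frame([0.5, 0.4, 0.3, 0.2, 0.1, 0.05], ["a"] * 6)
    ranked = rank_predictors(six)
    assert len(ranked) == 5
    assert ranked["feature"].tolist() == ["f0", "f1", "f2", "f3", "f4"]


def test_rank_predictors_breaks_ties_alphabetically():
    tied = pd.DataFrame({
        "feature": ["zeta", "alpha", "mid"],
        "kernel_mean_abs_shap": [0.2, 0.2, 0.2],
        "domain": ["a", "a", "a"],
    })
    ranked = rank_predictors(tied)
    assert ranked["feature"].tolist() == ["alpha", "mid", "zeta"]


def test_summary_table_over_an_ensemble_like_model():
    rng = np.random.default_rng(9)
    X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
    f = _linear([1.0, -1.0, 0.0])
    table = summarize(f, X, domain_map={"a": "d1", "b": "d1", "c": "d2"})
    assert set(table["feature"]) == {"a", "b", "c"}
    assert table.set_index("feature").loc["c", "shap_p_pct"] == 0.0
    assert whole_model_shap(f, X) > 0
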