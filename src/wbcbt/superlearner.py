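"""Cross-validated stacking ensemble ("super learner") for compliance.

The compliance model predicts the post-guidance usage target
(log1p total minutes, weeks 13-52) from baseline covariates in the
self-guided arm.  A library of base learners is combined with
simplex-constrained weights chosen to minimize V-fold cross-validated
squared error; *nested* cross-validation (an outer loop whose held-out
fold never enters base-learner fitting or weight estimation) yields
honest out-of-fold predictions and an unbiased CV R^2.  Scores for
participants in the other arms come from the ensemble refit on the full
training arm, so every trial participant receives a predicted-compliance
score generated from pre-randomization information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .codebook import COVARIATE_NAMES


@dataclass(frozen=True)
class LearnerSpec:
    """A named base learner (an unfitted scikit-learn regressor)."""

    name: str
    estimator: object

    def make(self):
        return clone(self.estimator)


def default_library() -> list[LearnerSpec]:
    """Mean-only, linear, ridge, lasso, shallow boosted trees, k-NN.

    The mean-only learner guards against negative-signal overfitting:
    when the covariates carry no information the ensemble can always
    fall back to predicting the training mean.
    """
    return [
        LearnerSpec("mean", DummyRegressor(strategy="mean")),
        LearnerSpec("linear", LinearRegression()),
        LearnerSpec("ridge", make_pipeline(StandardScaler(), Ridge(alpha=100.0))),
        LearnerSpec("lasso", make_pipeline(StandardScaler(),
                                           Lasso(alpha=0.03, max_iter=5000))),
        LearnerSpec("gbt", GradientBoostingRegressor(
            n_estimators=60, max_depth=2, learning_rate=0.1, subsample=0.8,
            random_state=0)),
        LearnerSpec("knn", make_pipeline(StandardScaler(),
                                         KNeighborsRegressor(n_neighbors=25))),
    ]


def linear_library() -> list[LearnerSpec]:
    """A small, fast library for simulation studies.

    The weak, diffuse compliance signal at a few hundred observations is
    lost to overfit by plain least squares, so the small library carries
    a strongly regularized (standardized) ridge alongside it.
    """
    return [
        LearnerSpec("mean", DummyRegressor(strategy="mean")),
        LearnerSpec("linear", LinearRegression()),
        LearnerSpec("ridge", make_pipeline(StandardScaler(), Ridge(alpha=100.0))),
    ]


@dataclass
class EnsembleModel:
    """Simplex-weighted combination of base learners fit on one dataset."""

    learners: list[LearnerSpec]
    weights: np.ndarray            # nonnegative, sums to one
    fits: list[object]             # fitted estimators, aligned with learners
    cv_risks: np.ndarray           # per-learner V-fold CV squared error
    ensemble_cv_risk: float
    feature_names: tuple[str, ...]
    folds: int
    seed: int

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xm = _as_matrix(X, self.feature_names)
        preds = np.column_stack([f.predict(Xm) for f in self.fits])
        return preds @ self.weights


@dataclass
class PredictedCompliance:
    """Per-participant compliance scores with their provenance."""

    scores: pd.Series               # indexed by participant_id
    provenance: pd.Series           # 'out-of-fold' or 'full-model'


def _as_matrix(X, feature_names: tuple[str, ...] | None = None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"covariate schema mismatch; missing columns: {missing}")
            X = X[list(feature_names)]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _fold_assignments(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    for f, part in enumerate(np.array_split(idx, folds)):
        assign[part] = f
    return assign


def _simplex_weights(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Weights on the simplex minimizing ||Z w - y||^2.

    Initialized at normalized non-negative least squares, polished with
    SLSQP under the simplex constraints, and guarded by comparison with
    every vertex so the ensemble CV risk never exceeds the best single
    learner's CV risk.
    """
    n, k = Z.shape
    risks = np.mean((Z - y[:, None]) ** 2, axis=0)
    w0, _ = optimize.nnls(Z, y)
    w0 = w0 / w0.sum() if w0.sum() > 0 else np.full(k, 1.0 / k)

    def risk(w: np.ndarray) -> float:
        return float(np.mean((Z @ w - y) ** 2))

    res = optimize.minimize(
        risk, w0, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None) if res.success else w0
    s = w.sum()
    w = w / s if s > 0 else np.full(k, 1.0 / k)
    best = int(np.argmin(risks))
    if risk(w) > risks[best]:
        w = np.zeros(k)
        w[best] = 1.0
    return w, risk(w)


def fit_superlearner(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    learners: list[LearnerSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the stacking ensemble on one dataset.

    V-fold cross-validated predictions of each base learner form the
    meta-level design; simplex weights minimize the CV squared error;
    base learners are then refit on the full data.  A constant target
    puts all weight on the mean-only learner.
    """
    learners = learners if learners is not None else default_library()
    if len(learners) < 1:
        raise ValueError("the learner library is empty")
    y = np.asarray(y, dtype=float)
    feature_names = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = _as_matrix(X)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} is smaller than the number of folds ({folds})")
    rng = np.random.default_rng(seed)
    assign = _fold_assignments(n, folds, rng)

    if np.ptp(y) == 0:
        # constant target: mean-only (or the first learner) gets weight 1
        weights = np.zeros(len(learners))
        mean_idx = next(
            (i for i, ls in enumerate(learners) if ls.name == "mean"), 0
        )
        weights[mean_idx] = 1.0
        fits = [ls.make().fit(Xm, y) for ls in learners]
        risks = np.zeros(len(learners))
        return EnsembleModel(learners, weights, fits, risks, 0.0,
                             feature_names, folds, seed)

    Z = np.empty((n, len(learners)))
    for j, ls in enumerate(learners):
        for f in range(folds):
            tr, te = assign != f, assign == f
            if te.sum() == 0 or tr.sum() < 2:
                raise ValueError("a cross-validation fold has too few observations")
            model = ls.make().fit(Xm[tr], y[tr])
            Z[te, j] = model.predict(Xm[te])
    if len(learners) == 1:
        weights = np.array([1.0])
        ens_risk = float(np.mean((Z[:, 0] - y) ** 2))
    else:
        weights, ens_risk = _simplex_weights(Z, y)
    risks = np.mean((Z - y[:, None]) ** 2, axis=0)
    fits = [ls.make().fit(Xm, y) for ls in learners]
    return EnsembleModel(learners, weights, fits, risks, ens_risk,
                         feature_names, folds, seed)


def r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST (may be negative)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    if len(observed) < 2:
        raise ValueError("r2 requires at least two observations")
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values are constant; R^2 undefined")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst


@dataclass
class NestedCVResult:
    predictions: pd.Series          # out-of-fold ensemble predictions
    cv_r2: float
    cv_r2_se: float
    fold_assignments: pd.Series


def nested_cv_score(
    X: pd.DataFrame,
    y: np.ndarray,
    learners: list[LearnerSpec] | None = None,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> NestedCVResult:
    """Honest out-of-fold compliance predictions with CV R^2 and SE.

    Every participant's score comes from an ensemble whose base-learner
    fits *and* weight estimation excluded that participant (the inner
    cross-validation runs entirely inside each outer training split).
    The SE of the CV R^2 is a leave-one-fold-out jackknife.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * outer_folds:
        raise ValueError("too few observations for the outer fold count")
    rng = np.random.default_rng(seed)
    assign = _fold_assignments(n, outer_folds, rng)
    preds = np.empty(n)
    for f in range(outer_folds):
        tr, te = assign != f, assign == f
        model = fit_superlearner(
            X.iloc[tr] if isinstance(X, pd.DataFrame) else X[tr],
            y[tr], learners=learners, folds=inner_folds,
            seed=int(rng.integers(2**31)),
        )
        preds[te] = model.predict(X.iloc[te] if isinstance(X, pd.DataFrame) else X[te])

    cv_r2 = r2(y, preds)
    # fold-wise jackknife on R^2
    loo = []
    for f in range(outer_folds):
        keep = assign != f
        if np.ptp(y[keep]) == 0:
            continue
        loo.append(r2(y[keep], preds[keep]))
    loo = np.array(loo)
    V = len(loo)
    se = float(np.sqrt((V - 1) / V * np.sum((loo - loo.mean()) ** 2))) if V > 1 else float("nan")
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)
    return NestedCVResult(
        pd.Series(preds, index=index, name="score"),
        float(cv_r2), se,
        pd.Series(assign, index=index, name="outer_fold"),
    )


def score_all(
    baseline: pd.DataFrame,
    arms: pd.DataFrame,
    y_train: pd.Series,
    train_arm: str = "self-guided",
    learners: list[LearnerSpec] | None = None,
    covariates: tuple[str, ...] = COVARIATE_NAMES,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> tuple[PredictedCompliance, NestedCVResult, EnsembleModel]:
    """Score every trial participant's predicted compliance.

    Participants in the training arm receive nested out-of-fold scores
    (their own data never influenced the model that scored them); all
    other participants are scored by the ensemble refit on the full
    training arm.  ``y_train`` is the compliance target indexed by
    participant_id for the training arm.
    """
    df = baseline.merge(arms[["participant_id", "arm"]], on="participant_id")
    df = df.set_index("participant_id")
    X = df[list(covariates)]
    in_train = df["arm"] == train_arm
    X_train = X[in_train]
    y = y_train.reindex(X_train.index)
    if y.isna().any():
        raise ValueError("compliance target missing for some training-arm rows")

    nested = nested_cv_score(
        X_train, y.to_numpy(), learners=learners,
        outer_folds=outer_folds, inner_folds=inner_folds, seed=seed,
    )
    full = fit_superlearner(
        X_train, y.to_numpy(), learners=learners, folds=inner_folds, seed=seed
    )
    scores = pd.Series(index=X.index, dtype=float, name="score")
    prov = pd.Series(index=X.index, dtype=object, name="provenance")
    scores[in_train] = nested.predictions
    prov[in_train] = "out-of-fold"
    scores[~in_train] = full.predict(X[~in_train])
    prov[~in_train] = "full-model"
    return PredictedCompliance(scores, prov), nested, full
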