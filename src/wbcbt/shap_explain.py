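"""Attribution of the compliance model.

Two attribution constructions are provided side by side:

* **Kernel Shapley values** — for each participant, per-feature additive
  attributions solving the Shapley-kernel-weighted least squares problem
  over feature coalitions, with missing features replaced by the sample
  reference (covariate means; one-hot encoded categoricals thereby
  receive level-frequency-weighted references).  Exact enumeration of
  all 2^p coalitions is used for p <= 12 features, weighted coalition
  sampling above that.  Local accuracy (attributions sum to the
  prediction minus the reference prediction) holds to numerical
  precision under enumeration.
* **Mean-substitution values** — for feature j, the mean over
  participants of |f(x_i) - f(x_i with feature j set to its sample
  mean)|, and the proportional value SHAP_P: that quantity divided by
  the whole-model value mean_i |f(x_i) - f(xbar)|, in percent.  SHAP_P
  values of individual predictors can sum above 100% because most
  participants sit above the mean on some predictors and below it on
  others.

Feature directions are read off the kernel values (sign of the
correlation between feature values and their attributions), mirroring a
beeswarm-plot reading.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

EXACT_ENUMERATION_MAX = 12


@dataclass
class ShapMatrix:
    """Per-participant, per-feature attributions plus the base value."""

    values: pd.DataFrame      # n x p attribution matrix
    base_value: float         # prediction at the reference point
    predictions: np.ndarray   # f(x_i)

    def local_accuracy_residuals(self) -> np.ndarray:
        return self.predictions - self.base_value - self.values.sum(axis=1).to_numpy()


def _predict_fn(model):
    if callable(model) and not hasattr(model, "predict"):
        return model
    return model.predict


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _kernel_weight(p: int, s: int) -> float:
    return (p - 1) / (math.comb(p, s) * s * (p - s))


def kernel_shap(
    model,
    X,
    reference: np.ndarray | None = None,
    coalition_budget: int = 2048,
    seed: int = 0,
) -> ShapMatrix:
    """Kernel Shapley attributions of ``model`` over the rows of ``X``.

    ``reference`` defaults to the column means of ``X``.  For p <= 12
    all coalitions are enumerated (local accuracy then holds to ~1e-12);
    for larger p, ``coalition_budget`` coalitions are sampled from the
    Shapley kernel size distribution and the attribution solve keeps the
    local-accuracy constraint exact while the values themselves carry
    sampling error.
    """
    Xf = _as_frame(X)
    f = _predict_fn(model)
    cols = list(Xf.columns)
    p = len(cols)
    Xm = Xf.to_numpy(dtype=float)
    n = len(Xm)
    if reference is None:
        reference = Xm.mean(axis=0)
    reference = np.asarray(reference, dtype=float)

    base = float(np.asarray(f(reference[None, :])).ravel()[0])
    fx = np.asarray(f(Xm), dtype=float).ravel()

    if p == 1:
        values = (fx - base)[:, None]
        return ShapMatrix(pd.DataFrame(values, columns=cols, index=Xf.index),
                          base, fx)

    if p <= EXACT_ENUMERATION_MAX:
        masks = [np.array(bits, dtype=bool)
                 for bits in itertools.product((0, 1), repeat=p)
                 if 0 < sum(bits) < p]
        weights = np.array([_kernel_weight(p, int(m.sum())) for m in masks])
    else:
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, p)
        size_w = np.array([(p - 1) / (s * (p - s)) for s in sizes])
        size_w = size_w / size_w.sum()
        masks = []
        for _ in range(coalition_budget // 2):
            s = int(rng.choice(sizes, p=size_w))
            idx = rng.choice(p, size=s, replace=False)
            m = np.zeros(p, dtype=bool)
            m[idx] = True
            masks.append(m)
            masks.append(~m)  # paired complements reduce variance
        weights = np.ones(len(masks))

    Z = np.array(masks, dtype=float)                      # (c, p)
    # evaluate v(S) for every row of X: masked entries take the reference
    c = len(masks)
    vals = np.empty((c, n))
    for i, m in enumerate(masks):
        pts = np.where(m[None, :], Xm, reference[None, :])
        vals[i] = np.asarray(f(pts), dtype=float).ravel()

    # constrained weighted least squares: sum_j phi_j = f(x) - base.
    # eliminate the last coefficient, solve, and back-substitute.
    A = Z[:, :-1] - Z[:, -1:]                             # (c, p-1)
    sw = np.sqrt(weights)[:, None]
    Aw = A * sw
    gram = Aw.T @ Aw
    total = fx - base                                     # (n,)
    B = vals - base - np.outer(Z[:, -1], total)           # (c, n)
    rhs = Aw.T @ (B * sw)
    phi_head = np.linalg.lstsq(gram, rhs, rcond=None)[0]  # (p-1, n)
    phi_last = total - phi_head.sum(axis=0)
    values = np.vstack([phi_head, phi_last[None, :]]).T   # (n, p)
    return ShapMatrix(pd.DataFrame(values, columns=cols, index=Xf.index), base, fx)


def mean_substitution_shap(model, X) -> pd.Series:
    """Mean absolute prediction change when one feature is set to its mean.

    ``value_j = mean_i |f(x_i) - f(x_i with feature j -> xbar_j)|``.
    """
    Xf = _as_frame(X)
    f = _predict_fn(model)
    Xm = Xf.to_numpy(dtype=float)
    means = Xm.mean(axis=0)
    fx = np.asarray(f(Xm), dtype=float).ravel()
    out = {}
    for j, col in enumerate(Xf.columns):
        Xs = Xm.copy()
        Xs[:, j] = means[j]
        out[col] = float(np.mean(np.abs(fx - np.asarray(f(Xs), dtype=float).ravel())))
    return pd.Series(out, name="mean_substitution_shap")


def whole_model_shap(model, X) -> float:
    """Whole-model value: mean_i |f(x_i) - f(xbar)| (all features to mean)."""
    Xf = _as_frame(X)
    f = _predict_fn(model)
    Xm = Xf.to_numpy(dtype=float)
    fbar = float(np.asarray(f(Xm.mean(axis=0)[None, :])).ravel()[0])
    fx = np.asarray(f(Xm), dtype=float).ravel()
    return float(np.mean(np.abs(fx - fbar)))


def shap_p(model, X) -> pd.Series:
    """Proportional SHAP: per-feature substitution value over the
    whole-model value, in percent.  Values may sum above 100%."""
    denom = whole_model_shap(model, X)
    if denom == 0:
        raise ValueError("constant model: whole-model SHAP value is zero")
    return (100.0 * mean_substitution_shap(model, X) / denom).rename("shap_p_pct")


def dominant_direction(shap: ShapMatrix, X, tol: float = 1e-8) -> pd.Series:
    """Sign of the association between feature values and attributions.

    Positive/negative per the Pearson correlation of x_ij with phi_ij;
    a constant feature or a (numerically) zero correlation — e.g. a
    symmetric U-shaped dependence — is flagged 'indeterminate'.
    """
    Xf = _as_frame(X)
    out = {}
    for col in Xf.columns:
        x = Xf[col].to_numpy(dtype=float)
        phi = shap.values[col].to_numpy()
        scale = max(1.0, float(np.abs(shap.predictions).max()))
        if np.std(x) == 0 or np.abs(phi).max() < 1e-10 * scale:
            out[col] = "indeterminate"
            continue
        r = float(np.corrcoef(x, phi)[0, 1])
        if abs(r) < max(tol, 0.05):
            out[col] = "indeterminate"
        elif r > 0:
            out[col] = "positive"
        else:
            out[col] = "negative"
    return pd.Series(out, name="dominant_direction")


def summarize(
    model, X, domain_map: dict[str, str] | None = None,
    coalition_budget: int = 2048, seed: int = 0,
) -> pd.DataFrame:
    """Per-feature attribution summary table.

    Columns: kernel mean |SHAP|, mean-substitution value, SHAP_P (%),
    dominant direction, domain tag.
    """
    shap = kernel_shap(model, X, coalition_budget=coalition_budget, seed=seed)
    kernel_mean = shap.values.abs().mean(axis=0)
    msub = mean_substitution_shap(model, X)
    try:
        prop = shap_p(model, X)
    except ValueError:
        prop = pd.Series(np.nan, index=msub.index)
    direction = dominant_direction(shap, X)
    df = pd.DataFrame({
        "kernel_mean_abs_shap": kernel_mean,
        "mean_substitution_shap": msub,
        "shap_p_pct": prop,
        "dominant_direction": direction,
    })
    df.index.name = "feature"
    df["domain"] = (
        pd.Series(domain_map).reindex(df.index) if domain_map else "unassigned"
    )
    return df.reset_index()


def rank_predictors(
    summary: pd.DataFrame,
    k: int = 5,
    floor: float = 0.01,
    value_column: str = "kernel_mean_abs_shap",
) -> pd.DataFrame:
    """Top-k predictors per domain with mean |SHAP| at or above ``floor``.

    Sort is stable: by attribution value descending, ties broken
    alphabetically by feature name.  A global rank over all qualifying
    features is included.
    """
    df = summary[summary[value_column] >= floor].copy()
    if df.empty:
        return df.assign(domain_rank=pd.Series(dtype=int),
                         global_rank=pd.Series(dtype=int))
    df = df.sort_values(
        ["feature"], kind="stable"
    ).sort_values([value_column], ascending=False, kind="stable")
    df["global_rank"] = np.arange(1, len(df) + 1)
    df["domain_rank"] = df.groupby("domain")["global_rank"].rank(method="first").astype(int)
    df = df[df["domain_rank"] <= k]
    return df.reset_index(drop=True)
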