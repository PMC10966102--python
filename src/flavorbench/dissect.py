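"""Model dissection: importance rankings, Shapley attributions, partial
dependence, and the importance-vs-correlation comparison.

A fitted tree ensemble encodes which chemical properties drive its
predictions; this module extracts that structure three ways:

* impurity importance (mean decrease in impurity) — fast, global, but
  split-frequency biased;
* exact per-sample Shapley attributions — additive decompositions of each
  prediction, aggregated into an importance score as the mean absolute
  attribution per feature;
* partial dependence — the expected prediction as one or two features are
  swept over their observed quantiles, revealing thresholds, saturation
  and pairwise interaction shapes.

The overlap operation contrasts the Shapley ranking with a plain
rank-correlation screen against the target: features that act through
interactions or nonlinear thresholds rank high in attribution yet low in
marginal correlation, which is the methodological argument for dissecting
models instead of reading correlation tables.  High attribution is still
no proof of causation: co-correlated compounds share credit, so validation
experiments remain necessary (reports carry this warning).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from ._treeshap import brute_force_tree_shap, ensemble_shap_values

__all__ = [
    "CAUSAL_CAVEAT",
    "mdi_ranking",
    "shapley_attributions",
    "partial_dependence",
    "importance_correlation_overlap",
]

_SKLEARN_TREES = (DecisionTreeRegressor, RandomForestRegressor,
                  ExtraTreesRegressor, GradientBoostingRegressor)

CAUSAL_CAVEAT = (
    "High importance identifies predictive, not necessarily causal, "
    "properties: co-correlated compounds share attribution credit. "
    "Validate candidate drivers experimentally."
)


def _unwrap(model):
    """Accept fitted bundles from the bench module as well as bare estimators.

    Only unwraps bench bundles (sklearn ensembles also expose an
    ``estimator`` attribute, the unfitted base template — leave those alone).
    """
    if hasattr(model, "spec") and hasattr(model, "estimator"):
        return model.estimator
    return model


def mdi_ranking(model, feature_names: list | None = None) -> pd.Series:
    """Normalized impurity-based importance, descending, name tie-break."""
    model = _unwrap(model)
    if not isinstance(model, _SKLEARN_TREES + (XGBRegressor,)):
        raise TypeError(
            f"impurity importance needs a tree model, got {type(model).__name__}")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    if feature_names is None:
        feature_names = getattr(model, "feature_names_in_",
                                [f"x{i}" for i in range(len(imp))])
    s = pd.Series(imp, index=list(feature_names))
    return s.sort_values(ascending=False, kind="stable") \
            .sort_index(kind="stable").sort_values(ascending=False, kind="stable")


def shapley_attributions(model, X: pd.DataFrame,
                         aggregate: str = "mean_abs") -> dict:
    """Exact tree-Shapley attributions for every sample in X.

    Returns a dict with per-sample ``values`` (samples × features), the
    ``base`` value (expectation of the model over its training
    distribution), the ``aggregate`` importance per feature (mean absolute
    attribution by default, max absolute with aggregate='max_abs'), and the
    reconstructed ``prediction`` = base + row sums (local accuracy).
    """
    model = _unwrap(model)
    arr = np.asarray(X, dtype=float)
    if isinstance(model, XGBRegressor):
        booster = model.get_booster()
        import xgboost as xgb

        dmat = xgb.DMatrix(arr, feature_names=booster.feature_names)
        contrib = booster.predict(dmat, pred_contribs=True)
        phi, base = contrib[:, :-1], float(contrib[0, -1])
    else:
        phi, base = ensemble_shap_values(model, arr)
    values = pd.DataFrame(phi, index=X.index, columns=X.columns)
    if aggregate == "mean_abs":
        agg = values.abs().mean(axis=0)
    elif aggregate == "max_abs":
        agg = values.abs().max(axis=0)
    else:
        raise ValueError(f"unknown aggregate '{aggregate}'")
    agg = agg.sort_values(ascending=False, kind="stable")
    return {
        "values": values,
        "base": base,
        "aggregate": agg,
        "prediction": base + values.sum(axis=1),
        "caveat": CAUSAL_CAVEAT,
    }


def exhaustive_shapley(tree_model, x: np.ndarray) -> np.ndarray:
    """Brute-force Shapley enumeration over feature subsets (small p only);
    the independent oracle for the recursive algorithm."""
    return brute_force_tree_shap(_unwrap(tree_model), x)


def partial_dependence(model, X: pd.DataFrame, features, grid: int = 20):
    """Partial dependence over quantile grids of the observed features.

    PD(v) = mean over samples of the prediction with the feature(s) clamped
    to v.  One feature → (grid values, PD curve); a pair → two grids and a
    PD surface.  Grid points are equally spaced quantiles, robust to the
    long right tails of concentration data.  A constant feature collapses
    to a single-point grid with a warning.
    """
    if isinstance(features, (str, int)):
        features = (features,)
    if len(features) not in (1, 2):
        raise ValueError("features must be one name or a pair")
    if grid < 2:
        raise ValueError("grid must have at least 2 points")
    for f in features:
        if f not in X.columns:
            raise KeyError(f"unknown feature '{f}'")

    def axis(f):
        vals = np.unique(np.quantile(X[f].to_numpy(), np.linspace(0, 1, grid)))
        if len(vals) == 1:
            warnings.warn(f"feature '{f}' is constant: single-point curve")
        return vals

    predict = model.predict if hasattr(model, "predict") else model
    if len(features) == 1:
        f = features[0]
        g = axis(f)
        pd_vals = np.empty(len(g))
        work = X.copy()
        for i, v in enumerate(g):
            work[f] = v
            pd_vals[i] = float(np.mean(predict(work)))
        return {"features": (f,), "grid": (g,), "values": pd_vals}
    f1, f2 = features
    g1, g2 = axis(f1), axis(f2)
    surface = np.empty((len(g1), len(g2)))
    work = X.copy()
    for i, v1 in enumerate(g1):
        work[f1] = v1
        for j, v2 in enumerate(g2):
            work[f2] = v2
            surface[i, j] = float(np.mean(predict(work)))
        work[f2] = X[f2]
    return {"features": (f1, f2), "grid": (g1, g2), "values": surface}


def importance_correlation_overlap(
    shap_rank: pd.Series, rho_vs_target: pd.Series, k: int
) -> tuple[int, pd.DataFrame]:
    """Compare the attribution top-k with the |rank correlation| top-k.

    ``shap_rank`` is the aggregate attribution per feature; ``rho_vs_target``
    the Spearman rho of each feature against the predicted target.  Returns
    the overlap size and a side-by-side table (attribution, rho, rho-rank)
    for the attribution top-k.  Ties break lexicographically.
    """
    shared = shap_rank.index.intersection(rho_vs_target.index)
    if k > len(shared):
        raise ValueError(f"k={k} exceeds the {len(shared)} shared features")
    if k == 0:
        return 0, pd.DataFrame(columns=["attribution", "rho", "rho_rank"])
    shap_s = shap_rank.loc[shared]
    rho_s = rho_vs_target.loc[shared]

    def topk(s: pd.Series) -> list:
        order = sorted(s.index, key=lambda f: (-s[f], f))
        return order[:k]

    top_shap = topk(shap_s)
    top_rho = topk(rho_s.abs())
    overlap = len(set(top_shap) & set(top_rho))
    rho_rank_all = rho_s.abs().rank(ascending=False, method="min")
    table = pd.DataFrame({
        "attribution": shap_s.loc[top_shap],
        "rho": rho_s.loc[top_shap],
        "rho_rank": rho_rank_all.loc[top_shap].astype(int),
    })
    table.index.name = "feature"
    return overlap, table
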