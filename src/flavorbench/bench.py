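"""Benchmark of regression families for sensory prediction.

Ten model families are trained to predict sensory targets (panel z-scores
or consumer appreciation) from the standardized chemistry matrix: three
linear (LR and Lasso with first-order interaction terms, PLSR), five tree
ensembles (AdaBoost, Extra Trees, Gradient Boosting, Random Forest,
XGBoost), an RBF support-vector regressor and a multilayer perceptron.
Hyperparameters are tuned by 5-fold cross-validated grid search on R²
(budgeted random search for the MLP); each family yields both a
multi-output model (aggregate R² = uniform average over descriptors) and
per-descriptor models, which are ranked per descriptor (midranks on ties)
and averaged into the family's rank — the two complementary views of a
model comparison table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import GridSearchCV, KFold, ParameterSampler
from sklearn.multioutput import MultiOutputRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from . import chemprep

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FamilyFit",
    "BenchResult",
    "default_grids",
    "fast_specs",
    "build_features",
    "make_estimator",
    "fit_model",
    "fit_family",
    "evaluate_suite",
    "stability_runs",
    "augmented_experiments",
]

FAMILIES = ("LR", "Lasso", "PLSR", "ABR", "ET", "GBR", "RF", "XGBR", "SVR", "ANN")

_LINEAR_FAMILIES = {"LR", "Lasso"}
_TREE_FAMILIES = {"ABR", "ET", "GBR", "RF", "XGBR"}
#: families whose sklearn estimator does not natively fit multiple targets
_NEEDS_WRAPPER = {"ABR", "GBR", "SVR", "XGBR"}


@dataclass
class ModelSpec:
    """One model family with its hyperparameter search space."""

    family: str
    grid: dict = field(default_factory=dict)
    interactions: bool = False
    multi_output: bool = True
    seed: int = 0
    search: str = "grid"  # 'grid' | 'random' (random only meaningful for ANN)
    n_iter: int = 10  # budget of the random search

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family '{self.family}'")
        if self.interactions and self.family not in _LINEAR_FAMILIES:
            raise ValueError("interaction terms are only for LR/Lasso")
        if self.grid is None or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")


def default_grids() -> dict:
    """Pinned default search spaces per family."""
    tree = {"n_estimators": [100, 300], "max_depth": [3, 6, None]}
    boosted = {"n_estimators": [100, 300], "max_depth": [3, 6],
               "learning_rate": [0.05, 0.1]}
    return {
        "LR": {},
        "Lasso": {"alpha": list(np.logspace(-3, 1, 5))},
        "PLSR": {"n_components": list(range(2, 21, 3))},
        "ABR": {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1]},
        "ET": dict(tree),
        "GBR": dict(boosted),
        "RF": dict(tree),
        "XGBR": dict(boosted),
        "SVR": {"C": list(np.logspace(-1, 2, 4)),
                "gamma": list(np.logspace(-3, -1, 3))},
        "ANN": {"hidden_layer_sizes": [(32,), (64,), (128,), (64, 32), (128, 64)],
                "alpha": list(np.logspace(-4, -1, 4))},
    }


def fast_specs(families=FAMILIES, seed: int = 0) -> dict:
    """Single-point specs (no search) at sensible defaults — the scale used
    for quick experiments and smoke runs."""
    single = {
        "LR": {},
        "Lasso": {"alpha": [0.05]},
        "PLSR": {"n_components": [8]},
        "ABR": {"n_estimators": [100], "learning_rate": [0.1]},
        "ET": {"n_estimators": [100], "max_depth": [None]},
        "GBR": {"n_estimators": [100], "max_depth": [3], "learning_rate": [0.1]},
        "RF": {"n_estimators": [100], "max_depth": [None]},
        "XGBR": {"n_estimators": [100], "max_depth": [3], "learning_rate": [0.1]},
        "SVR": {"C": [10.0], "gamma": [0.01]},
        "ANN": {"hidden_layer_sizes": [(64,)], "alpha": [1e-3]},
    }
    return {f: ModelSpec(family=f, grid=single[f],
                         interactions=f in _LINEAR_FAMILIES, seed=seed)
            for f in families}


def build_features(X: pd.DataFrame, interactions: bool) -> pd.DataFrame:
    """Optionally append all pairwise products x_i·x_j (i < j), named 'a×b'.

    No squared terms; inputs are assumed standardized and the products are
    left unscaled so they stay interpretable.
    """
    if not interactions:
        return X
    cols = list(X.columns)
    arr = X.to_numpy()
    names, prods = [], []
    for i in range(len(cols)):
        block = arr[:, i:i + 1] * arr[:, i + 1:]
        prods.append(block)
        names.extend(f"{cols[i]}×{cols[j]}" for j in range(i + 1, len(cols)))
    if not names:
        return X
    inter = pd.DataFrame(np.hstack(prods), index=X.index, columns=names)
    return pd.concat([X, inter], axis=1)


def make_estimator(family: str, params: dict, seed: int = 0,
                   multi_output: bool = False):
    """Instantiate one estimator of a family with explicit hyperparameters."""
    if family == "LR":
        est = LinearRegression()
    elif family == "Lasso":
        est = Lasso(max_iter=10000, random_state=seed, **params)
    elif family == "PLSR":
        est = PLSRegression(**params)
    elif family == "ABR":
        est = AdaBoostRegressor(random_state=seed, **params)
    elif family == "ET":
        est = ExtraTreesRegressor(random_state=seed, n_jobs=1, **params)
    elif family == "GBR":
        est = GradientBoostingRegressor(random_state=seed, **params)
    elif family == "RF":
        est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    elif family == "XGBR":
        est = XGBRegressor(random_state=seed, n_jobs=1, verbosity=0,
                           tree_method="hist", **params)
    elif family == "SVR":
        est = SVR(kernel="rbf", **params)
    elif family == "ANN":
        est = MLPRegressor(max_iter=800, random_state=seed, **params)
    else:
        raise ValueError(f"unknown model family '{family}'")
    if multi_output and family in _NEEDS_WRAPPER:
        est = MultiOutputRegressor(est, n_jobs=1)
    return est


def _grid_size(grid: dict) -> int:
    n = 1
    for v in grid.values():
        n *= len(v)
    return n


def fit_model(spec: ModelSpec, X: pd.DataFrame, Y):
    """Fit one family on the training block with 5-fold CV model selection.

    The grid search maximizes mean CV R² and refits on the full training
    data; a single-point grid skips the search.  The ANN may use a budgeted
    random search over its space instead of the full grid.  Constant
    targets are rejected by name — R² is undefined for them.
    """
    Y_frame = Y.to_frame() if isinstance(Y, pd.Series) else Y
    const = Y_frame.columns[Y_frame.std(ddof=0) == 0].tolist()
    if const:
        raise ValueError(f"constant target descriptor(s): {const}")
    if len(X) < 10:
        raise ValueError("need at least 10 training rows")
    multi = isinstance(Y, pd.DataFrame) and Y.shape[1] > 1
    y_fit = Y if multi else np.ravel(Y_frame)

    Xd = build_features(X, spec.interactions)
    if _grid_size(spec.grid) == 1:
        params = {k: v[0] for k, v in spec.grid.items()}
        est = make_estimator(spec.family, params, seed=spec.seed, multi_output=multi)
        est.fit(Xd, y_fit)
        return _FittedBundle(spec, est, list(Xd.columns))
    cv = KFold(n_splits=5, shuffle=True, random_state=spec.seed)
    base = make_estimator(spec.family, {}, seed=spec.seed, multi_output=multi)
    grid = spec.grid
    if isinstance(base, MultiOutputRegressor):
        grid = {f"estimator__{k}": v for k, v in grid.items()}
    if spec.search == "random":
        best_score, best_params = -np.inf, None
        for params in ParameterSampler(grid, n_iter=min(spec.n_iter, _grid_size(grid)),
                                       random_state=spec.seed):
            est = clone(base).set_params(**params)
            scores = []
            for tr, va in cv.split(Xd):
                e = clone(est)
                e.fit(Xd.iloc[tr], y_fit[tr] if not multi else y_fit.iloc[tr])
                scores.append(r2_score(
                    Y_frame.iloc[va], _as2d(e.predict(Xd.iloc[va]))))
            score = float(np.mean(scores))
            if score > best_score:
                best_score, best_params = score, params
        est = clone(base).set_params(**best_params)
        est.fit(Xd, y_fit)
        return _FittedBundle(spec, est, list(Xd.columns))
    gs = GridSearchCV(base, grid, cv=cv, scoring="r2", n_jobs=1, refit=True)
    gs.fit(Xd, y_fit)
    return _FittedBundle(spec, gs.best_estimator_, list(Xd.columns))


def _as2d(a):
    a = np.asarray(a)
    return a.reshape(-1, 1) if a.ndim == 1 else a


@dataclass
class _FittedBundle:
    spec: ModelSpec
    estimator: object
    feature_names: list

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = build_features(X, self.spec.interactions)
        return np.asarray(self.estimator.predict(Xd[self.feature_names]))


@dataclass
class FamilyFit:
    """Multi-output model plus per-descriptor models for one family."""

    spec: ModelSpec
    multi: _FittedBundle
    per_descriptor: dict  # descriptor -> _FittedBundle
    descriptors: list


def fit_family(spec: ModelSpec, X: pd.DataFrame, Y: pd.DataFrame) -> FamilyFit:
    """Fit the multi-output model and one model per descriptor."""
    multi = fit_model(spec, X, Y)
    per = {d: fit_model(spec, X, Y[d]) for d in Y.columns}
    return FamilyFit(spec=spec, multi=multi, per_descriptor=per,
                     descriptors=list(Y.columns))


@dataclass
class BenchResult:
    """Benchmark table: per-descriptor R², aggregate R², average rank."""

    per_descriptor_r2: pd.DataFrame  # models × descriptors (per-descriptor models)
    multi_r2: pd.Series  # per model, uniform average over descriptors
    avg_rank: pd.Series  # per model, midranks
    train_r2: pd.Series | None = None  # multi-output model, training block

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"R2": self.multi_r2, "rank": self.avg_rank})
        if self.train_r2 is not None:
            out["train_R2"] = self.train_r2
        return out.sort_values("rank")


def evaluate_suite(
    fits: dict, X_test: pd.DataFrame, Y_test: pd.DataFrame,
    X_train: pd.DataFrame | None = None, Y_train: pd.DataFrame | None = None,
) -> BenchResult:
    """Evaluate fitted families on the shared held-out split.

    Aggregate R² comes from each family's multi-output model (uniform
    average over descriptors; may be negative).  Per-descriptor models are
    ranked 1..M per descriptor — midranks on ties — and averaged per family.
    """
    names = list(fits)
    per = pd.DataFrame(index=names, columns=Y_test.columns, dtype=float)
    multi = pd.Series(index=names, dtype=float)
    train = pd.Series(index=names, dtype=float)
    for name, fit in fits.items():
        pred = _as2d(fit.multi.predict(X_test))
        multi[name] = r2_score(Y_test, pred)
        if X_train is not None and Y_train is not None:
            train[name] = r2_score(Y_train, _as2d(fit.multi.predict(X_train)))
        for d in Y_test.columns:
            pred_d = np.ravel(fit.per_descriptor[d].predict(X_test))
            per.loc[name, d] = r2_score(Y_test[d], pred_d)
    # rank 1 = best R² per descriptor; midranks conserve sum M(M+1)/2
    ranks = pd.DataFrame(index=per.index, columns=per.columns, dtype=float)
    for d in per.columns:
        ranks[d] = stats.rankdata(-per[d].to_numpy(), method="average")
    avg_rank = ranks.mean(axis=1)
    return BenchResult(
        per_descriptor_r2=per, multi_r2=multi, avg_rank=avg_rank,
        train_r2=train if X_train is not None else None,
    )


def stability_runs(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: pd.Series,
    styles: pd.Series,
    n_iter: int = 100,
    k_top: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    importance: str = "shap",
    shap_sample: int = 60,
) -> dict:
    """Repeat split → standardize → fit → dissect with distinct seeds.

    Reports, per feature, how often it lands in the top-k aggregate
    importance (Shapley mean-|value| by default, or impurity importance),
    plus the distribution of test R² across iterations.
    """
    from . import dissect  # deferred: dissect depends on bench being importable

    if n_iter < 2:
        raise ValueError("need at least 2 iterations")
    rng = np.random.default_rng(seed)
    top_counts = pd.Series(0, index=X.columns, dtype=int)
    r2s = []
    matrix = chemprep.CompoundMatrix(
        values=X.copy(), meta=pd.DataFrame({"style": styles}, index=X.index))
    for it in range(n_iter):
        it_seed = int(rng.integers(2**31 - 1))
        train_ids, test_ids = chemprep.split_stratified(
            matrix, train_frac=train_frac, seed=it_seed)
        Xtr, state = chemprep.standardize(X.loc[train_ids])
        Xte, _ = chemprep.standardize(X.loc[test_ids], state)
        it_spec = ModelSpec(family=spec.family, grid=spec.grid,
                            interactions=spec.interactions, seed=it_seed,
                            search=spec.search, n_iter=spec.n_iter)
        fit = fit_model(it_spec, Xtr, y.loc[train_ids])
        r2s.append(r2_score(y.loc[test_ids], np.ravel(fit.predict(Xte))))
        if importance == "shap":
            sample = Xtr.iloc[:shap_sample]
            report = dissect.shapley_attributions(fit.estimator, sample)
            agg = report["aggregate"]
        else:
            agg = dissect.mdi_ranking(fit.estimator, feature_names=list(X.columns))
        top = agg.sort_values(ascending=False).index[:k_top]
        top_counts[top] += 1
    return {
        "top_k_frequency": top_counts / n_iter,
        "top_k_counts": top_counts,
        "r2": pd.Series(r2s),
        "k_top": k_top,
        "n_iter": n_iter,
    }


def augmented_experiments(
    datasets: dict,
    mode: str,
    styles: pd.Series | None = None,
    spec: ModelSpec | None = None,
    train_frac: float = 0.7,
    seed: int = 0,
) -> dict:
    """Combined-dataset and style-feature experiments.

    ``datasets`` maps source name -> (X, y) with a shared predictor space.
    mode 'combined' stacks the two sources; 'combined+identifier' adds a
    binary source column; 'style_onehot' augments the single dataset 'A'
    with one-hot style columns.  Returns test R² and the impurity
    importance of every feature, with the added features called out.
    """
    spec = spec or ModelSpec(family="GBR",
                             grid={"n_estimators": [100], "max_depth": [3],
                                   "learning_rate": [0.1]}, seed=seed)
    from . import dissect

    if mode in ("combined", "combined+identifier"):
        (name_a, (X_a, y_a)), (name_b, (X_b, y_b)) = sorted(datasets.items())
        if list(X_a.columns) != list(X_b.columns):
            raise ValueError("datasets have mismatched predictor spaces")
        X_a, X_b = X_a.copy(), X_b.copy()
        added = []
        if mode == "combined+identifier":
            X_a["dataset_id"] = 0.0
            X_b["dataset_id"] = 1.0
            added = ["dataset_id"]
        X = pd.concat([X_a, X_b], axis=0, ignore_index=True)
        y = pd.concat([pd.Series(np.ravel(y_a)), pd.Series(np.ravel(y_b))],
                      ignore_index=True)
    elif mode == "style_onehot":
        X_a, y_a = datasets["A"]
        if styles is None:
            raise ValueError("style_onehot mode needs per-beer styles")
        onehot = pd.get_dummies(styles.loc[X_a.index], prefix="style").astype(float)
        added = list(onehot.columns)
        X = pd.concat([X_a, onehot], axis=1)
        y = pd.Series(np.ravel(y_a), index=X.index)
    else:
        raise ValueError(f"unknown mode '{mode}'")

    rng = np.random.default_rng(seed)
    idx = np.arange(len(X))
    rng.shuffle(idx)
    n_train = int(round(train_frac * len(X)))
    tr, te = idx[:n_train], idx[n_train:]
    fit = fit_model(spec, X.iloc[tr], pd.Series(np.asarray(y)[tr]))
    r2 = r2_score(np.asarray(y)[te], np.ravel(fit.predict(X.iloc[te])))
    imp = dissect.mdi_ranking(fit.estimator, feature_names=list(X.columns))
    ranks = imp.rank(ascending=False, method="min")
    return {
        "r2": float(r2),
        "importance": imp,
        "added_features": added,
        "added_importance": imp[added] if added else imp.iloc[0:0],
        "added_rank": ranks[added] if added else ranks.iloc[0:0],
    }
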