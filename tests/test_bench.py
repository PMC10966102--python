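"""Model benchmark: features, fitting, evaluation, stability, ablations."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import r2_score

from flavorbench import bench
from flavorbench.bench import FamilyFit, ModelSpec, _FittedBundle


def _toy_data(rng, n=120, p=4):
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"x{i}" for i in range(p)])
    return X


class TestBuildFeatures:
    def test_pairwise_products_counted(self, rng):
        X = _toy_data(rng, 10, 3)
        out = bench.build_features(X, interactions=True)
        assert out.shape[1] == 3 + 3  # C(3,2) products, no squares
        assert "x0×x1" in out.columns
        assert np.allclose(out["x0×x1"], X["x0"] * X["x1"])

    def test_p231_column_count(self):
        X = pd.DataFrame(np.zeros((2, 231)),
                         columns=[f"c{i}" for i in range(231)])
        out = bench.build_features(X, interactions=True)
        assert out.shape[1] == 231 + 231 * 230 // 2  # 26,565 interactions

    def test_off_is_identity(self, rng):
        X = _toy_data(rng)
        assert bench.build_features(X, interactions=False) is X


class TestFitModel:
    def test_noiseless_linear_recovered_exactly(self, rng):
        X = _toy_data(rng)
        y = pd.Series(2 * X["x0"] + 1, index=X.index)
        fit = bench.fit_model(ModelSpec("LR"), X, y)
        assert r2_score(y, fit.predict(X)) == pytest.approx(1.0)

    def test_interaction_target_favors_trees_over_plain_linear(self, rng):
        X = _toy_data(rng, n=500)
        y = pd.Series(X["x0"] * X["x1"] + 0.05 * rng.standard_normal(500),
                      index=X.index)
        tr, te = X.index[:350], X.index[350:]
        gbr = bench.fit_model(
            ModelSpec("GBR", {"n_estimators": [200], "max_depth": [3],
                              "learning_rate": [0.1]}), X.loc[tr], y.loc[tr])
        lr = bench.fit_model(ModelSpec("LR"), X.loc[tr], y.loc[tr])
        r2_gbr = r2_score(y.loc[te], gbr.predict(X.loc[te]))
        r2_lr = r2_score(y.loc[te], lr.predict(X.loc[te]))
        assert r2_gbr > r2_lr + 0.3

    def test_same_spec_seed_data_is_deterministic(self, rng):
        X = _toy_data(rng)
        y = pd.Series(X["x0"] + 0.2 * rng.standard_normal(len(X)), index=X.index)
        spec = ModelSpec("RF", {"n_estimators": [30, 50]}, seed=5)
        a = bench.fit_model(spec, X, y).predict(X)
        b = bench.fit_model(spec, X, y).predict(X)
        assert np.array_equal(a, b)

    def test_constant_target_rejected_by_name(self, rng):
        X = _toy_data(rng)
        Y = pd.DataFrame({"ok": X["x0"], "flat": 1.0})
        with pytest.raises(ValueError, match="flat"):
            bench.fit_model(ModelSpec("GBR", {"n_estimators": [10]}), X, Y)

    def test_interactions_only_for_linear_families(self):
        with pytest.raises(ValueError, match="LR/Lasso"):
            ModelSpec("GBR", {"n_estimators": [10]}, interactions=True)

    def test_grid_search_selects_on_cv_r2(self, rng):
        X = _toy_data(rng, n=150)
        y = pd.Series(X["x0"] + 0.1 * rng.standard_normal(150), index=X.index)
        fit = bench.fit_model(
            ModelSpec("Lasso", {"alpha": [0.001, 100.0]}, seed=0), X, y)
        # a huge alpha zeroes everything; CV must pick the small one
        assert fit.estimator.alpha == 0.001


class _Fixed:
    """Stub estimator with fixed predictions, for arithmetic checks."""

    def __init__(self, pred):
        self._pred = np.asarray(pred)

    def predict(self, X):
        return self._pred[: len(X)]


def _stub_family(spec, pred_multi, pred_per):
    bundle = _FittedBundle(spec, _Fixed(pred_multi), ["x0"])
    per = {d: _FittedBundle(spec, _Fixed(p), ["x0"])
           for d, p in pred_per.items()}
    return FamilyFit(spec=spec, multi=bundle, per_descriptor=per,
                     descriptors=list(pred_per))


class TestEvaluateSuite:
    def _setup(self):
        X = pd.DataFrame({"x0": [0.0, 1.0, 2.0, 3.0]})
        Y = pd.DataFrame({"d1": [1.0, 2.0, 3.0, 4.0],
                          "d2": [4.0, 3.0, 2.0, 1.0]})
        return X, Y

    def test_hand_computed_aggregate_r2(self):
        X, Y = self._setup()
        spec = ModelSpec("GBR", {"n_estimators": [1]})
        pred = np.array([[1.0, 4.0], [2.0, 3.0], [3.0, 2.0], [5.0, 1.0]])
        fits = {"M": _stub_family(spec, pred,
                                  {"d1": pred[:, 0], "d2": pred[:, 1]})}
        res = bench.evaluate_suite(fits, X, Y)
        # d1: SSE=1, SST=5 -> R2=0.8 ; d2 perfect -> 1.0 ; average 0.9
        assert res.multi_r2["M"] == pytest.approx(0.9)
        assert res.per_descriptor_r2.loc["M", "d1"] == pytest.approx(0.8)

    def test_strict_dominance_gives_ranks_1_and_2(self):
        X, Y = self._setup()
        spec = ModelSpec("GBR", {"n_estimators": [1]})
        perfect = {"d1": Y["d1"].to_numpy(), "d2": Y["d2"].to_numpy()}
        off = {"d1": Y["d1"].to_numpy() + 1.0, "d2": Y["d2"].to_numpy() + 1.0}
        fits = {"good": _stub_family(spec, np.column_stack(list(perfect.values())),
                                     perfect),
                "bad": _stub_family(spec, np.column_stack(list(off.values())),
                                    off)}
        res = bench.evaluate_suite(fits, X, Y)
        assert res.avg_rank["good"] == 1.0
        assert res.avg_rank["bad"] == 2.0

    def test_exact_tie_gives_midrank(self):
        X, Y = self._setup()
        spec = ModelSpec("GBR", {"n_estimators": [1]})
        same = {"d1": Y["d1"].to_numpy(), "d2": Y["d2"].to_numpy()}
        fits = {"a": _stub_family(spec, np.column_stack(list(same.values())), same),
                "b": _stub_family(spec, np.column_stack(list(same.values())), same)}
        res = bench.evaluate_suite(fits, X, Y)
        assert res.avg_rank["a"] == res.avg_rank["b"] == 1.5

    def test_midrank_conservation(self, rng):
        # ranks of M models sum to M(M+1)/2 per descriptor
        X = _toy_data(rng, 60, 3)
        Y = pd.DataFrame({"d1": X["x0"] + 0.3 * rng.standard_normal(60),
                          "d2": X["x1"] + 0.3 * rng.standard_normal(60)},
                         index=X.index)
        specs = bench.fast_specs(("LR", "Lasso", "RF"), seed=0)
        tr, te = X.index[:45], X.index[45:]
        fits = {f: bench.fit_family(s, X.loc[tr], Y.loc[tr])
                for f, s in specs.items()}
        res = bench.evaluate_suite(fits, X.loc[te], Y.loc[te])
        per = res.per_descriptor_r2
        from scipy.stats import rankdata

        for d in per.columns:
            assert rankdata(-per[d]).sum() == pytest.approx(3 * 4 / 2)


class TestStability:
    def test_single_iteration_count_rejected(self, bundle, appreciation):
        spec = ModelSpec("GBR", {"n_estimators": [10]})
        with pytest.raises(ValueError, match="at least 2"):
            bench.stability_runs(spec, bundle.chemistry.values, appreciation,
                                 bundle.chemistry.meta["style"], n_iter=1)

    def test_planted_drivers_dominate_top5(self, bundle, appreciation):
        spec = ModelSpec("GBR", {"n_estimators": [100], "max_depth": [3],
                                 "learning_rate": [0.1]})
        res = bench.stability_runs(
            spec, bundle.chemistry.values, appreciation,
            bundle.chemistry.meta["style"], n_iter=8, k_top=5, seed=21)
        freq = res["top_k_frequency"]
        assert freq["ethyl_acetate"] >= 0.9
        assert freq["lactic_acid"] >= 0.9

    def test_r2_distribution_varies_across_splits(self, bundle, appreciation):
        spec = ModelSpec("GBR", {"n_estimators": [50], "max_depth": [3],
                                 "learning_rate": [0.1]})
        res = bench.stability_runs(
            spec, bundle.chemistry.values, appreciation,
            bundle.chemistry.meta["style"], n_iter=4, seed=3,
            importance="mdi")
        assert res["r2"].std() > 0


class TestAugmented:
    def _xy(self, rng, n=150):
        X = _toy_data(rng, n, 5)
        y = pd.Series(X["x0"] + 0.5 * X["x1"] + 0.2 * rng.standard_normal(n),
                      index=X.index)
        return X, y

    def test_identical_copies_make_identifier_uninformative(self, rng):
        X, y = self._xy(rng)
        out = bench.augmented_experiments(
            {"A": (X, y), "B": (X.copy(), y.copy())}, "combined+identifier",
            seed=1)
        assert out["added_importance"]["dataset_id"] == pytest.approx(0.0, abs=0.02)

    def test_constant_offset_makes_identifier_top_feature(self, rng):
        X, y = self._xy(rng)
        out = bench.augmented_experiments(
            {"A": (X, y), "B": (X.copy(), y + 5.0)}, "combined+identifier",
            seed=1)
        assert out["added_rank"]["dataset_id"] == 1
        assert out["importance"].index[0] == "dataset_id"

    def test_style_onehot_uninformative_on_balanced_target(self, rng):
        X, y = self._xy(rng, 200)
        styles = pd.Series(["s1", "s2"] * 100, index=X.index)
        out = bench.augmented_experiments({"A": (X, y)}, "style_onehot",
                                          styles=styles, seed=2)
        assert (out["added_importance"] < 0.05).all()

    def test_mismatched_predictors_rejected(self, rng):
        X, y = self._xy(rng)
        X2 = X.rename(columns={"x0": "other"})
        with pytest.raises(ValueError, match="mismatched"):
            bench.augmented_experiments({"A": (X, y), "B": (X2, y)}, "combined")


class TestOverfitInvariant:
    def test_lr_with_interactions_overfits_when_n_below_p(self, rng):
        # n = 60 rows, p = 12 -> 78 columns with interactions: exact fit
        X = _toy_data(rng, 60, 12)
        y = pd.Series(rng.standard_normal(60), index=X.index)
        fit = bench.fit_model(ModelSpec("LR", interactions=True), X, y)
        assert r2_score(y, fit.predict(X)) == pytest.approx(1.0, abs=1e-6)
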