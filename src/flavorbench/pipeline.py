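"""End-to-end orchestration of a chemistry-to-flavor study.

One configured, seeded run chains every stage — synthetic data generation
(or loading of user-supplied tables), chemical preprocessing and
correlation analysis, panel normalization and consistency, review mining,
the model benchmark, dissection of the best tree model, and a spiking
plan — and writes each result as CSV with a JSON schema sidecar plus a
machine-readable manifest (seed, config hash, declared artifacts).  The
global seed fans out to per-stage seeds through a NumPy seed sequence, so
stages are individually reproducible and the whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bench, chemprep, dissect, panel, reviews, spike, synthdata

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration (YAML-friendly)."""

    seed: int
    output_dir: str
    synth: dict | None = None
    inputs: dict | None = None
    train_frac: float = 0.7
    families: tuple = ("GBR", "RF", "Lasso")
    bench_mode: str = "fast"  # 'fast' (pinned points) | 'grid' (full search)
    dissect_family: str = "GBR"
    k_top: int = 15
    shap_sample: int = 60
    spike_cfg: dict = field(default_factory=dict)
    min_reviews: int = 5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if (self.synth is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synth' or 'inputs' must be given")
        unknown = set(self.families) - set(bench.FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        return cls(
            seed=raw.get("seed"),
            output_dir=raw.get("output_dir", "flavorbench_out"),
            synth=raw.get("synth"),
            inputs=raw.get("inputs"),
            train_frac=raw.get("split", {}).get("train_frac", 0.7),
            families=tuple(raw.get("bench", {}).get("families",
                                                    ("GBR", "RF", "Lasso"))),
            bench_mode=raw.get("bench", {}).get("mode", "fast"),
            dissect_family=raw.get("dissect", {}).get("family", "GBR"),
            k_top=raw.get("dissect", {}).get("k_top", 15),
            shap_sample=raw.get("dissect", {}).get("shap_sample", 60),
            spike_cfg=raw.get("spike", {}),
            min_reviews=raw.get("reviews", {}).get("min_reviews", 5),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "output_dir": self.output_dir,
            "synth": self.synth, "inputs": self.inputs,
            "train_frac": self.train_frac, "families": list(self.families),
            "bench_mode": self.bench_mode, "dissect_family": self.dissect_family,
            "k_top": self.k_top, "shap_sample": self.shap_sample,
            "spike_cfg": self.spike_cfg, "min_reviews": self.min_reviews,
        }


def _config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, artifacts: list, index: bool = True):
    df.to_csv(path, index=index, float_format="%.10g")
    schema = {"columns": [str(c) for c in df.columns],
              "index": df.index.name or "index", "rows": int(len(df))}
    side = path.with_suffix(path.suffix + ".schema.json")
    side.write_text(json.dumps(schema, indent=1))
    artifacts.extend([path.name, side.name])


def _stage_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full study; returns {'manifest': ..., 'outputs': {...}}."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    seeds = _stage_seeds(cfg.seed, 6)
    results: dict = {}

    # ---- stage 1: data -------------------------------------------------
    stage = "data"
    try:
        if cfg.synth is not None:
            syn = dict(cfg.synth)
            rc = synthdata.ReviewConfig(
                reviews_per_beer_mean=syn.get("reviews_per_beer_mean", 40.0),
                reviews_per_beer_min=syn.get("reviews_per_beer_min", 5),
                n_raters=syn.get("n_raters", 160),
                nonenglish_frac=syn.get("nonenglish_frac", 0.05),
                low_activity_frac=syn.get("low_activity_frac", 0.10),
            )
            bundle = synthdata.generate_bundle(
                seed=seeds[0],
                n_compounds=syn.get("n_compounds", 100),
                n_tasters=syn.get("n_tasters", 16),
                review_cfg=rc,
            )
            chem, pan, revs = bundle.chemistry, bundle.panel, bundle.reviews
            truth_path = out / "truth.json"
            synthdata.truth_ledger(bundle).to_json(truth_path)
            artifacts.append(truth_path.name)
        else:
            chem = chemprep.load_chemistry(cfg.inputs["chemistry"])
            pan = panel.PanelScores.from_csv(cfg.inputs["panel"])
            revs = reviews.ReviewSet.from_jsonl(cfg.inputs["reviews"])
        chem_out = pd.concat([chem.meta, chem.values], axis=1)
        _write_csv(chem_out, out / "chemistry.csv", artifacts)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 2: chemistry preprocessing + correlations ---------------
    stage = "prep"
    try:
        chem_t, log_flags, _ = chemprep.log_transform_matrix(chem)
        chem_i, _ = chemprep.impute_missing(chem_t)
        chem_corr = chemprep.spearman_matrix(chem_i.values)
        _write_csv(chem_corr.to_long(), out / "chem_correlations.csv",
                   artifacts, index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 3: panel -------------------------------------------------
    stage = "panel"
    try:
        pan_z = panel.taster_zscore(pan)
        profile = panel.beer_attribute_means(pan_z)
        repeated = [b for b in pan.records["beer_id"].unique()
                    if pan.records.loc[pan.records.beer_id == b,
                                       "session_id"].nunique() > 1]
        if repeated:
            frac, cons_table = panel.panel_consistency(pan_z, repeated)
            results["panel_consistency"] = frac
            _write_csv(cons_table, out / "panel_consistency.csv",
                       artifacts, index=False)
        _write_csv(profile.values, out / "panel_profile.csv", artifacts)
        sens_corr = chemprep.spearman_matrix(profile.values.dropna(axis=1, how="any"))
        _write_csv(sens_corr.to_long(), out / "sensory_correlations.csv",
                   artifacts, index=False)
        cross = chemprep.spearman_matrix(chem_i.values, profile.values)
        _write_csv(cross.to_long(), out / "chem_sensory_correlations.csv",
                   artifacts, index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 4: reviews ----------------------------------------------
    stage = "reviews"
    try:
        filtered, filt_report = reviews.filter_reviews(revs, cfg.min_reviews)
        results["review_filter"] = filt_report
        per_beer = reviews.rater_center_scores(filtered)
        _write_csv(per_beer, out / "review_scores.csv", artifacts)
        lex = reviews.default_lexicon()
        sents, labels = synthdata.gen_labeled_sentences(40, seed=seeds[1])
        clf = reviews.train_aspect_classifier(sents, labels, lex)
        enrich, _ = reviews.tfidf_enrichment(filtered, clf, lex)
        _write_csv(enrich, out / "tfidf_enrichment.csv", artifacts)
        amap = {t: a for t, a in lex.sensory_vocab.items()
                if t in enrich.columns and a in profile.values.columns}
        if "appreciation" in profile.values.columns:
            agree_scores = reviews.review_panel_agreement(
                per_beer, profile.values, {"overall": "appreciation"})
            _write_csv(agree_scores.to_long(), out / "agreement_scores.csv",
                       artifacts, index=False)
        if amap:
            agree_terms = reviews.review_panel_agreement(
                enrich, profile.values, amap)
            _write_csv(agree_terms.to_long(), out / "agreement_terms.csv",
                       artifacts, index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 5: benchmark --------------------------------------------
    stage = "bench"
    try:
        train_ids, test_ids = chemprep.split_stratified(
            chem, cfg.train_frac, seed=seeds[2])
        chem_model, state = _fit_preprocess(chem, train_ids)
        Xtr, Xte = chem_model.loc[train_ids], chem_model.loc[test_ids]
        Y = profile.values.dropna(axis=1, how="any")
        if "overall" in per_beer.columns:
            appr = per_beer["overall"].reindex(chem.values.index)
            Y = Y.assign(consumer_appreciation=appr).dropna(axis=0, how="any")
        Ytr = Y.reindex(train_ids).dropna()
        Yte = Y.reindex(test_ids).dropna()
        Xtr, Xte = Xtr.loc[Ytr.index], Xte.loc[Yte.index]
        if cfg.bench_mode == "fast":
            specs = bench.fast_specs(cfg.families, seed=seeds[3])
        else:
            grids = bench.default_grids()
            specs = {f: bench.ModelSpec(
                family=f, grid=grids[f], interactions=f in ("LR", "Lasso"),
                seed=seeds[3], search="random" if f == "ANN" else "grid")
                for f in cfg.families}
        fits = {f: bench.fit_family(spec, Xtr, Ytr)
                for f, spec in specs.items()}
        result = bench.evaluate_suite(fits, Xte, Yte, Xtr, Ytr)
        _write_csv(result.table(), out / "benchmark.csv", artifacts)
        _write_csv(result.per_descriptor_r2, out / "benchmark_per_descriptor.csv",
                   artifacts)
        results["benchmark"] = result
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 6: dissection -------------------------------------------
    stage = "dissect"
    try:
        target = ("consumer_appreciation" if "consumer_appreciation" in Ytr
                  else Ytr.columns[0])
        fam = cfg.dissect_family if cfg.dissect_family in fits else "GBR"
        best = fits[fam].per_descriptor[target]
        mdi = dissect.mdi_ranking(best.estimator, feature_names=list(Xtr.columns))
        _write_csv(mdi.rename("mdi").to_frame(), out / "mdi_importance.csv",
                   artifacts)
        shap_report = dissect.shapley_attributions(
            best.estimator, Xtr.iloc[:cfg.shap_sample])
        _write_csv(shap_report["values"], out / "shap_values.csv", artifacts)
        _write_csv(shap_report["aggregate"].rename("mean_abs_shap").to_frame(),
                   out / "shap_importance.csv", artifacts)
        rho_target = chemprep.spearman_matrix(
            chem_model, Y[[target]]).rho[target]
        k = min(cfg.k_top, len(rho_target))
        overlap, ov_table = dissect.importance_correlation_overlap(
            shap_report["aggregate"], rho_target, k)
        results["overlap"] = overlap
        _write_csv(ov_table, out / "importance_vs_correlation.csv", artifacts)
        top_feats = list(shap_report["aggregate"].index[:3])
        pdp_rows = []
        for f in top_feats:
            curve = dissect.partial_dependence(best, chem_model[Xtr.columns], f)
            for v, y in zip(curve["grid"][0], curve["values"]):
                pdp_rows.append({"feature": f, "value": v, "pd": y})
        _write_csv(pd.DataFrame(pdp_rows), out / "pdp_curves.csv",
                   artifacts, index=False)
        results["shap_aggregate"] = shap_report["aggregate"]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 7: spiking plan -----------------------------------------
    stage = "spike"
    try:
        sp = dict(cfg.spike_cfg)
        style = sp.get("style") or chem.meta["style"].mode().iloc[0]
        statistic = sp.get("statistic", "p95")
        exclude = sp.get("exclude", [])
        compounds = sp.get("compounds")
        if compounds is None:
            compounds = [f for f in results["shap_aggregate"].index
                         if f in chem.values.columns][:7]
        in_style = chem.meta.index[chem.meta["style"] == style]
        base_id = sp.get("base_beer") or str(in_style[0])
        targets = spike.style_targets(chem, style, compounds, statistic)
        plan = spike.spiking_plan(chem, base_id, targets,
                                  statistic=statistic, style=style,
                                  exclude=exclude)
        plan.predicted_uplift = spike.predict_uplift(best, chem, plan, state)
        plan_out = plan.table.copy()
        plan_out.attrs = {}
        _write_csv(plan_out, out / "spiking_plan.csv", artifacts)
        results["spiking_plan"] = plan
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- manifest -------------------------------------------------------
    manifest = {
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "artifacts": sorted(set(artifacts)),
        "note": dissect.CAUSAL_CAVEAT,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    results["output_dir"] = str(out)
    return results


def _fit_preprocess(chem: chemprep.CompoundMatrix, train_ids: list):
    """Fit log/impute/standardize on the training block, apply to all beers.

    Returns (preprocessed full matrix, TransformState).
    """
    values = chem.values
    train = values.loc[train_ids]
    flags, epss = {}, {}
    work = values.copy()
    for col in values.columns:
        flag, _, eps = chemprep.select_log_transform(train[col].to_numpy())
        flags[col], epss[col] = flag, eps
        if flag:
            work[col] = np.log(values[col] + eps)
    train_w = work.loc[train_ids]
    imput = train_w.mean(axis=0)
    work = work.fillna(imput)
    std_train, state = chemprep.standardize(work.loc[train_ids])
    state.log_flags = pd.Series(flags)
    state.log_eps = pd.Series(epss)
    state.imputed_means = imput
    full_std, _ = chemprep.standardize(work, state)
    return full_std, state
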