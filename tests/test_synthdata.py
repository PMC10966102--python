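"""Synthetic-study generator: determinism, copula fidelity, planted effects."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flavorbench import chemprep, reviews, synthdata


@pytest.fixture(scope="module")
def two_style_setup():
    styles = synthdata.default_styles(n_compounds=40)[:2]
    truth = synthdata.default_truth(n_compounds=40)
    return styles, truth


class TestChemistry:
    def test_seed_reproducibility_is_byte_identical(self, two_style_setup):
        styles, truth = two_style_setup
        a = synthdata.gen_chemistry(styles, truth, seed=7)
        b = synthdata.gen_chemistry(styles, truth, seed=7)
        assert a.values.to_csv() == b.values.to_csv()
        assert a.meta.to_csv() == b.meta.to_csv()

    def test_concentrations_strictly_positive(self, two_style_setup):
        styles, truth = two_style_setup
        chem = synthdata.gen_chemistry(styles, truth, seed=1)
        assert (chem.values.to_numpy() > 0).all()

    def test_target_rank_correlation_recovered_at_n_1000(self):
        # two yeast esters at target rho 0.6, 1000 beers in one style
        labels = ["ester_a", "ester_b"]
        target = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]], index=labels, columns=labels)
        rng = np.random.default_rng(11)
        sample = synthdata.gaussian_copula_sample(target, 1000, rng)
        rho = stats.spearmanr(sample["ester_a"], sample["ester_b"]).statistic
        assert abs(rho - 0.6) < 0.1

    def test_log_median_matches_location_without_shifts(self):
        truth = synthdata.default_truth(n_compounds=40)
        style = synthdata.default_styles(n_compounds=40)[0]
        style.signature_shifts = {}
        style.n_beers = 2000
        chem = synthdata.gen_chemistry([style], truth, seed=5)
        log_med = np.log(chem.values.median(axis=0))
        # Monte-Carlo CI on the median of a normal: ~1.25 * sd / sqrt(n)
        half_width = 4 * 1.25 * style.compound_scale / np.sqrt(2000)
        within = (log_med - style.compound_location).abs() < half_width
        assert within.all()

    def test_signature_shift_moves_per_style_median(self, bundle):
        chem = bundle.chemistry
        styles = chem.meta["style"]
        ipa = chem.values.loc[styles == "IPA", "iso_alpha_acids"].median()
        lager = chem.values.loc[styles == "Lager", "iso_alpha_acids"].median()
        assert ipa > lager

    def test_non_psd_block_rejected_by_name(self):
        labels = ["a", "b", "c"]
        bad = pd.DataFrame([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]],
                           index=labels, columns=labels)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="positive semi-definite"):
            synthdata.gaussian_copula_sample(bad, 10, rng)

    def test_default_study_composition(self, bundle):
        styles = bundle.chemistry.meta["style"]
        assert len(styles) == 250
        assert styles.nunique() == 22
        assert "Low/No-alcohol" in set(styles)


class TestPanel:
    def test_zero_noise_single_taster_equals_response_surface(self):
        styles = synthdata.default_styles(n_compounds=40)[:1]
        truth = synthdata.default_truth(n_compounds=40)
        truth.noise_sd["taster"] = 0.0
        chem = synthdata.gen_chemistry(styles, truth, seed=2)
        pan = synthdata.gen_panel(chem, truth, n_tasters=1, seed=0,
                                  taster_bias_sd=0.0, taster_scale_sd=0.0,
                                  attendance=1.0, n_repeated=0)
        surface = synthdata.panel_response_surface(chem, truth)
        obs = pan.records.pivot_table(index="beer_id", columns="attribute",
                                      values="score")
        clipped = surface.clip(1.0, 7.0).loc[obs.index, obs.columns]
        pd.testing.assert_frame_equal(obs, clipped, check_names=False)

    def test_masking_pair_anticorrelated(self, bundle):
        from flavorbench import panel as panelmod

        z = panelmod.taster_zscore(bundle.panel)
        profile = panelmod.beer_attribute_means(z)
        rho = stats.spearmanr(profile.values["sweetness"],
                              profile.values["bitterness"]).statistic
        assert rho < 0

    def test_all_scores_within_scale(self, bundle):
        s = bundle.panel.records["score"]
        assert s.between(1.0, 7.0).all()

    def test_unknown_driver_compound_rejected(self, two_style_setup):
        styles, _ = two_style_setup
        truth = synthdata.default_truth(n_compounds=40)
        truth.driver_set.append(
            synthdata.Driver("weird", "unobtainium", "linear", 1.0))
        chem = synthdata.gen_chemistry(styles, synthdata.default_truth(40), seed=0)
        with pytest.raises(ValueError, match="unobtainium"):
            synthdata.gen_panel(chem, truth, n_tasters=2, seed=0)


class TestReviews:
    def test_disabled_price_bias_kills_price_correlation(self):
        styles = synthdata.default_styles(n_compounds=40)
        truth = synthdata.default_truth(n_compounds=40)
        truth.noise_sd["review"] = 0.3
        chem = synthdata.gen_chemistry(styles, truth, seed=4)
        # decouple price from chemistry so the planted bias is the only link
        rng = np.random.default_rng(99)
        chem.meta["price_per_l"] = rng.uniform(2.0, 10.0, len(chem.meta))
        cfg = synthdata.ReviewConfig(price_bias=0.0, style_bias={},
                                     reviews_per_beer_mean=20,
                                     nonenglish_frac=0.0, low_activity_frac=0.0)
        revs = synthdata.gen_reviews(chem, truth, cfg, seed=4)
        mean_overall = revs.records.groupby("beer_id")["overall"].mean()
        price = chem.meta["price_per_l"].reindex(mean_overall.index)
        rho = stats.spearmanr(price, mean_overall).statistic
        assert abs(rho) < 0.15
        # with the bias enabled on the same decoupled prices, rho shows up
        cfg_b = synthdata.ReviewConfig(price_bias=0.6, style_bias={},
                                       reviews_per_beer_mean=20,
                                       nonenglish_frac=0.0, low_activity_frac=0.0)
        revs_b = synthdata.gen_reviews(chem, truth, cfg_b, seed=4)
        mean_b = revs_b.records.groupby("beer_id")["overall"].mean()
        rho_b = stats.spearmanr(price.reindex(mean_b.index), mean_b).statistic
        assert rho_b > rho + 0.2

    def test_planted_appreciation_driver_positively_correlated(self, bundle):
        mean_overall = bundle.reviews.records.groupby("beer_id")["overall"].mean()
        conc = bundle.chemistry.values["ethyl_acetate"].reindex(mean_overall.index)
        rho = stats.spearmanr(conc, mean_overall).statistic
        assert rho > 0.2

    def test_nonenglish_fraction_is_filtered_out(self):
        styles = synthdata.default_styles(n_compounds=40)[:3]
        truth = synthdata.default_truth(n_compounds=40)
        cfg = synthdata.ReviewConfig(nonenglish_frac=0.1, low_activity_frac=0.0,
                                     reviews_per_beer_mean=30)
        revs = synthdata.gen_reviews(chem=synthdata.gen_chemistry(styles, truth, 0),
                                     truth=truth, cfg=cfg, seed=9)
        _, report = reviews.filter_reviews(revs, min_reviews=1)
        frac_removed = report["non_english"] / report["input"]
        assert frac_removed == pytest.approx(0.1, abs=0.03)

    def test_negative_review_count_support_rejected(self):
        with pytest.raises(ValueError, match="negative support"):
            synthdata.ReviewConfig(reviews_per_beer_min=-1)

    def test_term_usage_tracks_latent_attribute(self, bundle):
        # beers with high bitterness latent should mention 'bitter' more often
        lat = synthdata.latent_attributes(bundle.chemistry, bundle.truth)
        texts = bundle.reviews.records.groupby("beer_id")["text"].apply(" ".join)
        rate = texts.str.lower().str.count("bitter") / texts.str.len().clip(lower=1)
        rho = stats.spearmanr(lat["bitterness"].reindex(rate.index), rate).statistic
        assert rho > 0.3


class TestTruthLedger:
    def test_each_planted_driver_listed_once(self, bundle):
        ledger = synthdata.truth_ledger(bundle)
        drivers = ledger.appreciation_drivers
        assert len(drivers) == len(set(drivers)) == 3

    def test_json_round_trip_unchanged(self, bundle, tmp_path):
        path = tmp_path / "truth.json"
        bundle.truth.to_json(path)
        back = synthdata.GroundTruth.from_json(path)
        assert back.to_json_dict() == bundle.truth.to_json_dict()
        # and the file itself is valid JSON
        json.loads(path.read_text())

    def test_regenerated_bundle_same_seed_identical_ledger(self, bundle):
        again = synthdata.generate_bundle(seed=3)
        assert (synthdata.truth_ledger(again).to_json_dict()
                == synthdata.truth_ledger(bundle).to_json_dict())
        pd.testing.assert_frame_equal(again.chemistry.values,
                                      bundle.chemistry.values)
        pd.testing.assert_frame_equal(again.reviews.records,
                                      bundle.reviews.records)
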