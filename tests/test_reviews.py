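"""Review filtering, rater normalization, text mining and TFIDF."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flavorbench import panel as panelmod
from flavorbench import reviews, synthdata


def _review_set(rows):
    df = pd.DataFrame(rows)
    for c in reviews.SUBSCORES:
        if c not in df:
            df[c] = 10.0
    return reviews.ReviewSet(df)


class TestFilter:
    def test_detector_disagreement_drops_record(self):
        rs = _review_set([
            {"beer_id": "b1", "rater_id": "r1", "lang_a": "en", "lang_b": "fr",
             "text": "x"},
            {"beer_id": "b1", "rater_id": "r1", "lang_a": "en", "lang_b": "en",
             "text": "x"},
        ])
        out, report = reviews.filter_reviews(rs, min_reviews=1)
        assert len(out) == 1
        assert report["non_english"] == 1

    def test_rater_activity_boundary(self):
        rows = [{"beer_id": f"b{i}", "rater_id": "r99", "lang_a": "en",
                 "lang_b": "en", "text": "x"} for i in range(99)]
        rows += [{"beer_id": f"b{i}", "rater_id": "r100", "lang_a": "en",
                  "lang_b": "en", "text": "x"} for i in range(100)]
        out, report = reviews.filter_reviews(_review_set(rows), min_reviews=100)
        assert set(out.records["rater_id"]) == {"r100"}
        assert report["low_activity_rater"] == 99

    def test_empty_input(self):
        out, report = reviews.filter_reviews(
            reviews.ReviewSet(pd.DataFrame(
                columns=["beer_id", "rater_id", *reviews.SUBSCORES, "text"])),
            min_reviews=1)
        assert len(out) == 0 and report["kept"] == 0

    def test_filtering_is_idempotent(self, bundle):
        once, _ = reviews.filter_reviews(bundle.reviews, min_reviews=5)
        twice, report = reviews.filter_reviews(once, min_reviews=5)
        assert len(twice) == len(once)
        assert report["non_english"] == 0

    def test_builtin_detectors_separate_languages(self):
        en = "The aroma of this beer is hoppy and it has a nice head."
        fr = "Cette bière est très bonne et la mousse est belle."
        assert reviews.detect_language_stopwords(en) == "en"
        assert reviews.detect_language_stopwords(fr) != "en"
        assert reviews.detect_language_charprofile(en) == "en"
        assert reviews.detect_language_charprofile(fr) != "en"


class TestRaterCentering:
    def test_two_review_rater_forced_values(self):
        rs = _review_set([
            {"beer_id": "b1", "rater_id": "r1", "overall": 10.0},
            {"beer_id": "b2", "rater_id": "r1", "overall": 20.0},
        ])
        per_beer = reviews.rater_center_scores(rs)
        assert per_beer.loc["b1", "overall"] == pytest.approx(-1 / math.sqrt(2))
        assert per_beer.loc["b2", "overall"] == pytest.approx(+1 / math.sqrt(2))

    def test_single_review_rater_contributes_zero(self):
        rs = _review_set([{"beer_id": "b1", "rater_id": "solo", "overall": 19.0}])
        with pytest.warns(UserWarning, match="single review"):
            per_beer = reviews.rater_center_scores(rs)
        assert per_beer.loc["b1", "overall"] == 0.0

    def test_opposite_biases_same_ranking_agree_after_normalization(self):
        # harsh rater scores {4, 8}, generous rater {14, 18}; same ordering
        rs = _review_set([
            {"beer_id": "b1", "rater_id": "harsh", "overall": 4.0},
            {"beer_id": "b2", "rater_id": "harsh", "overall": 8.0},
            {"beer_id": "b1", "rater_id": "generous", "overall": 14.0},
            {"beer_id": "b2", "rater_id": "generous", "overall": 18.0},
        ])
        per_beer = reviews.rater_center_scores(rs)
        # hand calculation: both raters standardize to ∓1/sqrt(2)
        assert per_beer.loc["b1", "overall"] == pytest.approx(-1 / math.sqrt(2))
        assert per_beer.loc["b2", "overall"] == pytest.approx(+1 / math.sqrt(2))

    def test_standardized_scores_mean_zero_per_rater(self, bundle):
        filtered, _ = reviews.filter_reviews(bundle.reviews, min_reviews=5)
        rec = filtered.records
        mu = rec.groupby("rater_id")["overall"].transform("mean")
        sd = rec.groupby("rater_id")["overall"].transform(lambda s: s.std(ddof=1))
        z = (rec["overall"] - mu) / sd
        by_rater = z.groupby(rec["rater_id"]).mean()
        assert np.allclose(by_rater, 0, atol=1e-10)


class TestNormalizeText:
    def test_synonyms_collapse_to_canonical(self):
        lex = reviews.default_lexicon()
        a = reviews.normalize_text("Floral notes all over.", lex)
        b = reviews.normalize_text("A flowery aroma here!", lex)
        assert "floral" in a and "floral" in b

    def test_protected_term_survives_numbers_and_punctuation(self):
        lex = reviews.default_lexicon()
        toks = reviews.normalize_text("Lambic 75cl!!", lex)
        assert toks == ["Lambic"]

    def test_empty_string(self):
        assert reviews.normalize_text("", reviews.default_lexicon()) == []

    def test_lemma_like_suffixes_merge(self):
        lex = reviews.default_lexicon()
        assert (reviews.normalize_text("acid", lex)
                == reviews.normalize_text("acidity", lex))


class TestAspectClassifier:
    @pytest.fixture(scope="class")
    def trained(self):
        sents, labels = synthdata.gen_labeled_sentences(40, seed=0)
        clf = reviews.train_aspect_classifier(sents, labels)
        return clf, sents, labels

    def test_training_accuracy_on_separable_templates(self, trained):
        clf, sents, labels = trained
        pred = reviews.classify_sentences(clf, sents)
        acc = np.mean(np.array(pred) == np.array(labels))
        assert acc >= 0.9

    def test_held_out_accuracy(self, trained):
        clf, _, _ = trained
        sents, labels = synthdata.gen_labeled_sentences(25, seed=123)
        pred = reviews.classify_sentences(clf, sents)
        acc = np.mean(np.array(pred) == np.array(labels))
        assert acc >= 0.8

    def test_unseen_vocabulary_still_classified(self, trained):
        clf, _, _ = trained
        out = reviews.classify_sentences(clf, ["zzz qqq xxyy"])
        assert out[0] in reviews.ASPECTS

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            reviews.train_aspect_classifier(["a b", "c d"], ["aroma", "aroma"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown aspect"):
            reviews.train_aspect_classifier(["a", "b"], ["aroma", "bouquet"])


class TestTfidf:
    @pytest.fixture(scope="class")
    def clf(self):
        sents, labels = synthdata.gen_labeled_sentences(40, seed=0)
        return reviews.train_aspect_classifier(sents, labels)

    def test_two_beer_corpus_matches_hand_computation(self):
        # force both texts through as 'taste' sentences via a stub classifier
        class Stub:
            def predict(self, sentences):
                return ["taste"] * len(sentences)

        lex = reviews.Lexicon(sensory_vocab={"hoppy": "hop", "malty": "malt"})
        rs = _review_set([
            {"beer_id": "A", "rater_id": "r", "text": "hoppy hoppy malty"},
            {"beer_id": "B", "rater_id": "r", "text": "malty"},
        ])
        scores, empty = reviews.tfidf_enrichment(rs, Stub(), lex)
        idf = math.log((1 + 2) / (1 + 1)) + 1  # df=1 ('hoppy'), N=2
        idf_both = math.log((1 + 2) / (1 + 2)) + 1  # df=2 ('malty')
        assert scores.loc["A", "hoppy"] == pytest.approx((2 / 3) * idf)
        assert scores.loc["A", "malty"] == pytest.approx((1 / 3) * idf_both)
        assert scores.loc["B", "malty"] == pytest.approx(1.0 * idf_both)
        assert scores.loc["B", "hoppy"] == 0.0
        assert not empty

    def test_scores_nonnegative_and_zero_iff_absent(self, bundle, clf):
        filtered, _ = reviews.filter_reviews(bundle.reviews, min_reviews=5)
        sub = reviews.ReviewSet(filtered.records.iloc[:400].copy())
        scores, _ = reviews.tfidf_enrichment(sub, clf)
        assert (scores.to_numpy() >= 0).all()

    def test_globally_absent_term_has_no_column(self):
        class Stub:
            def predict(self, sentences):
                return ["taste"] * len(sentences)

        lex = reviews.Lexicon(sensory_vocab={"hoppy": "hop", "ghostterm": "x"})
        rs = _review_set([{"beer_id": "A", "rater_id": "r", "text": "hoppy"}])
        scores, _ = reviews.tfidf_enrichment(rs, Stub(), lex)
        assert "ghostterm" not in scores.columns


class TestAgreement:
    def test_profile_against_itself_is_diagonal_one(self, bundle):
        z = panelmod.taster_zscore(bundle.panel)
        profile = panelmod.beer_attribute_means(z).values
        amap = {c: c for c in profile.columns[:3]}
        corr = reviews.review_panel_agreement(profile, profile, amap)
        for c in amap:
            assert corr.rho.loc[c, c] == pytest.approx(1.0)

    def test_synthetic_reviews_agree_with_panel_appreciation(self, bundle,
                                                             appreciation):
        z = panelmod.taster_zscore(bundle.panel)
        profile = panelmod.beer_attribute_means(z).values
        corr = reviews.review_panel_agreement(
            appreciation.to_frame("overall"), profile,
            {"overall": "appreciation"})
        assert corr.rho.loc["overall", "appreciation"] > 0.3

    def test_unmapped_pairs_excluded(self, bundle):
        z = panelmod.taster_zscore(bundle.panel)
        profile = panelmod.beer_attribute_means(z).values
        corr = reviews.review_panel_agreement(
            profile, profile, {"sweetness": "sweetness"})
        assert list(corr.rho.index) == ["sweetness"]

    def test_no_shared_beers_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        b = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["d", "e", "f"])
        with pytest.raises(ValueError, match="shared beers"):
            reviews.review_panel_agreement(a, b, {"x": "x"})
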