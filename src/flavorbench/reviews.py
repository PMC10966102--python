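"""Consumer-review mining: filtering, score normalization and text analysis.

Consumer platforms provide, per review, five numeric sub-scores (appearance,
aroma, taste, palate, overall) and an optional free text.  Such corpora are
large but noisy: raters use score scales idiosyncratically, casual raters
add little signal, and texts are multilingual.  The processing chain here:

1. keep reviews written in English according to *two* independent language
   detectors, and drop raters below an activity threshold;
2. center/scale sub-scores per rater, then average per beer;
3. normalize texts (slang, synonyms, lemmas, stems; protected beer terms
   survive untouched), classify sentences by the beer aspect they describe,
   and compute per-beer TFIDF enrichment of sensory vocabulary over the
   aroma/taste sentences;
4. compare the mined signals against trained-panel profiles with Spearman
   correlations.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from . import chemprep

__all__ = [
    "ReviewSet",
    "Lexicon",
    "default_lexicon",
    "detect_language_stopwords",
    "detect_language_charprofile",
    "filter_reviews",
    "rater_center_scores",
    "normalize_text",
    "split_sentences",
    "train_aspect_classifier",
    "classify_sentences",
    "tfidf_enrichment",
    "review_panel_agreement",
]

SUBSCORES = ("appearance", "aroma", "taste", "palate", "overall")
ASPECTS = ("appearance", "aroma", "taste", "palate", "overall", "irrelevant")


@dataclass
class ReviewSet:
    """Consumer review records; one row per review."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("beer_id", "rater_id", *SUBSCORES)
                   if c not in self.records.columns]
        if missing:
            raise ValueError(f"review records missing columns: {missing}")
        if "text" not in self.records.columns:
            self.records["text"] = ""
        self.records["text"] = self.records["text"].fillna("")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_jsonl(cls, path) -> "ReviewSet":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        return cls(pd.DataFrame(rows))

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.records.to_dict(orient="records"):
                fh.write(json.dumps(row) + "\n")


@dataclass
class Lexicon:
    """Text-normalization resources.

    ``synonym_groups`` maps a canonical term to its variants ('floral' covers
    'flower', 'flowery', ...); ``sensory_vocab`` maps canonical sensory terms
    to the panel attribute they describe.  ``protected_terms`` (beer names,
    style names) are never rewritten.
    """

    slang_map: dict = field(default_factory=dict)
    protected_terms: set = field(default_factory=set)
    synonym_groups: dict = field(default_factory=dict)
    sensory_vocab: dict = field(default_factory=dict)
    lemma_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._variant_to_canonical = {}
        for canonical, variants in self.synonym_groups.items():
            for v in variants:
                self._variant_to_canonical[v] = canonical
            self._variant_to_canonical.setdefault(canonical, canonical)

    @classmethod
    def from_yaml(cls, path) -> "Lexicon":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            slang_map=raw.get("slang_map", {}),
            protected_terms=set(raw.get("protected_terms", [])),
            synonym_groups={k: set(v) for k, v in raw.get("synonym_groups", {}).items()},
            sensory_vocab=raw.get("sensory_vocab", {}),
            lemma_map=raw.get("lemma_map", {}),
        )


def default_lexicon() -> Lexicon:
    """Illustrative default lexicon; the vocabulary real studies use is
    panel-specific and should be supplied via configuration."""
    return Lexicon(
        slang_map={
            "hophead": "hoppy", "brewski": "beer", "quaffable": "drinkable",
            "gorgeus": "gorgeous", "awsome": "awesome", "carb": "carbonation",
        },
        protected_terms={"Chimay", "Lambic", "Tripel", "Dubbel", "Saison", "Kriek"},
        synonym_groups={
            "floral": {"flower", "flowery", "blossom"},
            "hoppy": {"hop", "hops", "hopped"},
            "malty": {"malt", "malts", "maltiness"},
            "fruity": {"fruit", "fruits", "fruitiness"},
            "sour": {"sourness", "tart", "tartness"},
            "bitter": {"bitterness", "bittering"},
            "sweet": {"sweetness", "sugary"},
            "acidic": {"acid", "acidity"},
            "estery": {"ester", "esters", "solvent"},
            "alcoholic": {"alcohol", "boozy", "booze"},
            "full": {"fullness", "thick", "heavy"},
            "caramel": {"caramelized", "toffee"},
            "citrus": {"citrusy", "lemon", "grapefruit"},
            "roasted": {"roast", "roasty", "toasted"},
        },
        sensory_vocab={
            "hoppy": "hop_aroma", "floral": "hop_aroma", "citrus": "hop_aroma",
            "bitter": "bitterness", "sweet": "sweetness", "sour": "acidity",
            "acidic": "acidity", "malty": "malt_taste", "roasted": "malt_taste",
            "fruity": "ester_aroma", "estery": "ester_aroma",
            "alcoholic": "alcohol", "full": "body", "caramel": "malt_taste",
        },
    )


# --- language detection -------------------------------------------------

_STOPWORDS = {
    "en": {"the", "a", "an", "and", "with", "of", "this", "is", "it", "very",
           "but", "has", "was", "not", "nice", "good", "beer", "on", "in"},
    "fr": {"le", "la", "les", "et", "un", "une", "avec", "est", "ce", "cette",
           "tres", "très", "mais", "bonne", "bière", "biere", "de", "du"},
    "nl": {"de", "het", "een", "en", "met", "is", "dit", "erg", "maar",
           "heeft", "lekker", "bier", "niet", "deze", "van"},
}

_CHAR_PROFILES = {
    # characteristic letters / digraph frequencies per language
    "en": {"th": 3.0, "wh": 1.5, "gh": 1.0, "ee": 1.0, "oo": 1.0},
    "fr": {"é": 3.0, "è": 2.0, "ç": 2.0, "ou": 1.0, "eu": 1.0, "au": 1.0},
    "nl": {"ij": 3.0, "aa": 1.5, "ee": 1.0, "oe": 1.5, "kk": 1.0},
}


def _words(text: str) -> list[str]:
    return re.findall(r"[^\W\d_]+", text.lower(), flags=re.UNICODE)


def detect_language_stopwords(text: str) -> str:
    """Stopword-overlap detector; returns a language code or 'unknown'."""
    words = set(_words(text))
    if not words:
        return "unknown"
    scores = {lang: len(words & sw) for lang, sw in _STOPWORDS.items()}
    best = max(scores, key=lambda k: (scores[k], k == "en"))
    return best if scores[best] > 0 else "unknown"


def detect_language_charprofile(text: str) -> str:
    """Character-profile detector, independent of the stopword lists."""
    low = text.lower()
    if not low.strip():
        return "unknown"
    scores = {}
    for lang, profile in _CHAR_PROFILES.items():
        scores[lang] = sum(w * low.count(pat) for pat, w in profile.items())
    best = max(scores, key=lambda k: (scores[k], k == "en"))
    return best if scores[best] > 0 else "unknown"


DEFAULT_DETECTORS = (detect_language_stopwords, detect_language_charprofile)


def filter_reviews(
    review_set: ReviewSet,
    min_reviews: int = 100,
    detectors=DEFAULT_DETECTORS,
) -> tuple[ReviewSet, dict]:
    """Consensus language filter + rater activity filter.

    A review is kept iff *both* detectors classify its text as English and
    its rater has at least ``min_reviews`` reviews in the corpus.  Records
    already carrying ``lang_a``/``lang_b`` columns are trusted; otherwise
    the pluggable detectors are applied.  Returns the filtered set and a
    report of counts removed per rule.
    """
    rec = review_set.records.copy()
    if len(rec) == 0:
        return ReviewSet(rec), {"input": 0, "non_english": 0,
                                "low_activity_rater": 0, "kept": 0}
    if "lang_a" not in rec.columns or "lang_b" not in rec.columns:
        det_a, det_b = detectors
        rec["lang_a"] = rec["text"].map(det_a)
        rec["lang_b"] = rec["text"].map(det_b)
    english = (rec["lang_a"] == "en") & (rec["lang_b"] == "en")
    rater_counts = rec.groupby("rater_id")["beer_id"].transform("size")
    active = rater_counts >= min_reviews
    keep = english & active
    report = {
        "input": int(len(rec)),
        "non_english": int((~english).sum()),
        "low_activity_rater": int((english & ~active).sum()),
        "kept": int(keep.sum()),
    }
    return ReviewSet(rec[keep].reset_index(drop=True)), report


def rater_center_scores(review_set: ReviewSet) -> pd.DataFrame:
    """Per-rater standardization of the five sub-scores, then per-beer means.

    Each sub-score is centered by the rater's mean and scaled by the rater's
    sample sd (n−1).  A rater with a single review or zero spread on a
    sub-score contributes 0 for that sub-score (warning): one observation
    carries no ranking information.
    """
    rec = review_set.records
    out = {}
    degenerate = False
    for col in SUBSCORES:
        grp = rec.groupby("rater_id")[col]
        mu = grp.transform("mean")
        sd = grp.transform(lambda s: s.std(ddof=1))
        flat = sd.isna() | (sd == 0)
        if flat.any():
            degenerate = True
            sd = sd.mask(flat, np.inf)
        out[col] = (rec[col] - mu) / sd
    if degenerate:
        warnings.warn("rater(s) with a single review or zero spread contribute 0")
    std = pd.DataFrame(out)
    std["beer_id"] = rec["beer_id"].to_numpy()
    return std.groupby("beer_id").mean()


# --- text normalization -------------------------------------------------

_SUFFIX_RULES = (
    ("iness", "y"), ("ness", ""), ("ities", "ity"), ("ity", ""),
    ("ingly", ""), ("edly", ""), ("fully", "ful"),
    ("ies", "y"), ("ing", ""), ("ed", ""), ("es", ""), ("ly", ""), ("s", ""),
)


def _stem(word: str) -> str:
    """Light rule-based suffix stripper (post-lemmatization cleanup)."""
    if len(word) <= 3:
        return word
    for suffix, repl in _SUFFIX_RULES:
        if word.endswith(suffix) and len(word) - len(suffix) + len(repl) >= 3:
            stemmed = word[: -len(suffix)] + repl
            # undo consonant doubling: hopp -> hop
            if len(stemmed) >= 4 and stemmed[-1] == stemmed[-2] and stemmed[-1] not in "aeiouls":
                stemmed = stemmed[:-1]
            return stemmed
    return word


def normalize_text(text: str, lexicon: Lexicon) -> list[str]:
    """Normalize a review text to a canonical token list.

    Pipeline order: lowercase → protect protected terms → slang correction →
    tokenize → drop numbers/punctuation → synonym collapse → lemmatize →
    stem.  Protected terms pass through verbatim (original casing).
    """
    if not text:
        return []
    protected = {}
    work = text
    for i, term in enumerate(sorted(lexicon.protected_terms, key=len, reverse=True)):
        token = "xprotectedx" + "".join(
            chr(ord("a") + int(d)) for d in str(i)) + "x"
        pattern = re.compile(re.escape(term), flags=re.IGNORECASE)
        if pattern.search(work):
            work = pattern.sub(token, work)
            protected[token] = term
    work = work.lower()
    # whitespace tokens containing digits ('75cl', '2023') are dropped whole;
    # from the rest, keep letter runs (strips punctuation)
    raw_tokens = []
    for chunk in work.split():
        if any(ch.isdigit() for ch in chunk):
            continue
        raw_tokens.extend(re.findall(r"[^\W\d_]+", chunk, flags=re.UNICODE))
    out = []
    for tok in raw_tokens:
        if tok in protected:
            out.append(protected[tok])
            continue
        tok = lexicon.slang_map.get(tok, tok)
        tok = lexicon._variant_to_canonical.get(tok, tok)
        tok = lexicon.lemma_map.get(tok, tok)
        tok = _stem(tok)
        # a stem may land on another variant of a synonym group
        tok = lexicon._variant_to_canonical.get(tok, tok)
        out.append(tok)
    return out


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    return [s.strip() for s in _SENTENCE_SPLIT.split(text) if s.strip()]


# --- aspect classification ----------------------------------------------

def train_aspect_classifier(sentences: list[str], labels: list[str],
                            lexicon: Lexicon | None = None) -> Pipeline:
    """Train a linear bag-of-words classifier over normalized tokens.

    Labels must come from the six-aspect vocabulary (five review aspects
    plus 'irrelevant').  At least two classes are required.
    """
    bad = set(labels) - set(ASPECTS)
    if bad:
        raise ValueError(f"unknown aspect label(s): {sorted(bad)}")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 distinct aspect classes to train")
    lexicon = lexicon or default_lexicon()
    clf = Pipeline([
        ("bow", CountVectorizer(
            analyzer=lambda text: normalize_text(text, lexicon))),
        ("linear", LogisticRegression(max_iter=2000, random_state=0)),
    ])
    clf.fit(sentences, labels)
    return clf


def classify_sentences(classifier: Pipeline, sentences: list[str]) -> list[str]:
    """Deterministic aspect labels; sentences with no known vocabulary fall
    back to the class prior (intercept) rather than failing."""
    if not sentences:
        return []
    return list(classifier.predict(sentences))


# --- TFIDF enrichment ---------------------------------------------------

def tfidf_enrichment(
    review_set: ReviewSet,
    classifier: Pipeline,
    lexicon: Lexicon | None = None,
    aspects_kept: set = frozenset({"aroma", "taste"}),
) -> tuple[pd.DataFrame, list]:
    """Per-beer TFIDF enrichment of sensory terms over kept-aspect sentences.

    Each beer's document is the concatenation of its sentences classified
    into ``aspects_kept``.  tf = term count / document length; smoothed
    idf = ln((1+N)/(1+df)) + 1; the score is tf·idf restricted to the
    lexicon's sensory vocabulary.  Terms absent from every document yield
    no column.  Beers with no kept sentences get a zero row and are
    returned in the flagged list.
    """
    lexicon = lexicon or default_lexicon()
    docs: dict[str, list[str]] = {b: [] for b in review_set.records["beer_id"].unique()}
    for beer_id, text in zip(review_set.records["beer_id"], review_set.records["text"]):
        sentences = split_sentences(text)
        if not sentences:
            continue
        labels = classify_sentences(classifier, sentences)
        for sent, label in zip(sentences, labels):
            if label in aspects_kept:
                docs[beer_id].extend(normalize_text(sent, lexicon))
    beers = sorted(docs)
    vocab = sorted(set(lexicon.sensory_vocab))
    counts = pd.DataFrame(0.0, index=beers, columns=vocab)
    doc_len = pd.Series(0, index=beers, dtype=float)
    for beer in beers:
        tokens = docs[beer]
        doc_len[beer] = len(tokens)
        for tok in tokens:
            if tok in counts.columns:
                counts.loc[beer, tok] += 1
    empty = doc_len.index[doc_len == 0].tolist()
    if empty:
        warnings.warn(f"{len(empty)} beer(s) with no kept sentences: zero rows")
    tf = counts.div(doc_len.replace(0, np.inf), axis=0)
    n_docs = int((doc_len > 0).sum())
    df_count = (counts > 0).sum(axis=0)
    idf = np.log((1 + n_docs) / (1 + df_count)) + 1.0
    scores = tf * idf
    scores = scores.loc[:, (counts > 0).any(axis=0)]  # drop globally absent terms
    scores.index.name = "beer_id"
    return scores, empty


def review_panel_agreement(
    per_beer: pd.DataFrame,
    profile_values: pd.DataFrame,
    attribute_map: dict,
) -> chemprep.CorrMatrix:
    """Spearman agreement between review-derived signals and panel profiles.

    ``attribute_map`` maps a column of ``per_beer`` (mean sub-score or TFIDF
    term) to the panel attribute it measures; only mapped pairs enter the
    output.  Requires at least 3 shared beers.
    """
    cols_a = [c for c in attribute_map if c in per_beer.columns]
    cols_b = [attribute_map[c] for c in cols_a]
    missing = [b for b in cols_b if b not in profile_values.columns]
    if missing:
        raise ValueError(f"panel profile lacks attribute(s): {missing}")
    if not cols_a:
        raise ValueError("attribute_map matches no review columns")
    shared = per_beer.index.intersection(profile_values.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared beers between reviews and panel")
    return chemprep.spearman_matrix(
        per_beer.loc[shared, cols_a], profile_values.loc[shared, cols_b]
    )
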