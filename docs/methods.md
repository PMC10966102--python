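# Methods

This note documents the models and procedures implemented in `flavorbench`,
the defaults they ship with, and the design decisions behind them.

## Chemical preprocessing

Concentration data from targeted assays is strictly non-negative with long
right tails, and many volatiles sit below detection in some samples.
Preprocessing therefore works per property:

* **Log-transform decision.** A property enters the models on log scale when
  the Shapiro–Wilk test rejects normality of the raw values (p < 0.05) *and*
  does not reject on the logs — i.e. when the raw shape is log-normal rather
  than merely non-normal. Both thresholds are 0.05 and configurable. The log
  uses `log(x + ε)` with ε = half the smallest positive observed value, so
  below-detection zeros are tolerated without a hard floor. Constant
  properties are never transformed (the test is undefined) and warn.
* **Imputation.** Missing cells are replaced by the per-property mean of
  observed values — appropriate for the ~0.1 % missingness of a well-run
  assay panel, not for structured missingness. Fully missing properties are
  an error, not a silent zero column.
* **Aggregates.** Derived attributes (total esters, caloric value, …) are
  configured weighted sums of component properties, flagged as aggregates.
  No recipe is hard-coded: the shipped examples are placeholders, since such
  formulas are lab conventions, not constants.
* **Standardization.** Per-property centering/scaling is fit on the training
  block only and re-applied to held-out data; a constant training property
  gets scale 1 with a warning. Correlation analyses, by contrast, use
  pairwise-complete observations *before* imputation — imputing first would
  bias rank correlations toward zero.
* **Stratified split.** Train/test allocation is per style with
  largest-remainder rounding, so a 250-beer, 22-style design at 0.7 yields
  exactly 175/75 and every multi-beer style is represented in both halves;
  a singleton style goes to training (it cannot be in both).

Spearman correlations use midranks for ties; two-sided p-values come from
the t-approximation on n−2 degrees of freedom, accurate for the n ≥ 3
pairwise-complete samples the precondition requires.

## Panel model

Tasters use a bounded 7-point intensity scale idiosyncratically, so raw
scores are z-scored per taster over *all* of that taster's ratings (sample
sd) — the correction targets the taster's scale use, which is not
attribute-specific. Beer-level profiles are mean z-scores over available
(taster, session) ratings; absence of a taster only reduces n. Panel
reliability is assessed by re-serving beers across sessions and running a
one-way ANOVA per (repeated beer, attribute) with session as the factor;
the consistency fraction is the share of tests with p > 0.05. Under a true
null this fraction is ≈ 0.95 by construction of the test, which the suite
verifies by simulation (2000 tests, tolerance ±0.03).

## Review mining

Consumer corpora are filtered by consensus of two independent language
detectors (pluggable; the defaults are a stopword-overlap detector and a
character-profile detector, which are sufficient for the templated synthetic
corpus and for clearly English/French/Dutch text) and by rater activity
(default ≥ 100 reviews; the count is taken within the supplied corpus, the
only information available offline). Sub-scores are centered and scaled per
rater (single-review raters contribute 0), then averaged per beer.

Texts are normalized in a fixed order — lowercase, protect beer-specific
proper nouns, slang correction, tokenization, digit-token and punctuation
removal, synonym collapse, lemma mapping, rule-based suffix stemming — so
'floral'/'flowery' and 'acid'/'acidity' land on one canonical term. The
aspect classifier is a logistic regression on bag-of-words counts over
normalized tokens with a fixed six-label vocabulary (five review aspects +
irrelevant); any linear classifier would do, and predictions fall back to
the class prior for unseen vocabulary. TFIDF enrichment uses
tf = count / document length and smoothed idf = ln((1+N)/(1+df)) + 1,
restricted to the sensory vocabulary, with one document per beer built from
its aroma/taste sentences. The shipped lexicon is an illustrative default;
real studies should supply their own.

## Benchmark

Ten families cover the common linear, kernel, ensemble and neural choices.
Hyperparameters are tuned by 5-fold cross-validated grid search maximizing
R² and refit on the full training block; the MLP may instead use a seeded
budgeted random search over its space (grids over layer widths and L2 are
large, and a random budget explores them more evenly at fixed cost).
Single-point grids skip the search. Pinned default grids: trees
n_estimators {100, 300} × depth {3, 6, ∅} (× learning rate {0.05, 0.1} for
boosting), Lasso λ on a log grid 10⁻³…10, PLSR 2–20 components, SVR
RBF C/γ log grids, MLP 1–2 hidden layers × width {32, 64, 128}.

Interaction features for LR/Lasso are all pairwise products x_i·x_j (i < j,
no squares), built *after* standardization and left unscaled so the product
terms stay interpretable. Evaluation reports (a) the multi-output model's
aggregate R² — the uniform average of per-descriptor R², which can be
negative — and (b) the average rank of per-descriptor models, with midranks
on ties (so M models always share M(M+1)/2 rank mass per descriptor).
Stability analysis repeats split → standardize → fit → dissect with distinct
seeds and tallies per-feature top-k importance frequency. The
combined-dataset ablation stacks two target sources, optionally adding a
binary source identifier; the style ablation appends one-hot style columns.

## Dissection

Impurity importance (MDI) is read from the fitted ensembles and normalized.
Shapley attributions use the exact path-dependent tree recursion: the
coalition value function is the tree-traversal conditional expectation with
training-coverage weights at out-of-coalition splits. This is implemented
in-package for sklearn trees and ensembles (XGBoost models use the
booster's built-in exact contributions) and validated two ways in the test
suite: local accuracy (base + Σφ = prediction) to 1e−6 on every sample, and
agreement with an independent brute-force enumeration over all 2^p feature
coalitions at p ≤ 8. Aggregate importance is the mean absolute attribution
(max-|φ| available by configuration); ranking ties break lexicographically
for reproducibility. Note the aggregation sample (training block by
default, configurable) affects the ranking only mildly for the smooth
ensembles used here.

Partial dependence clamps one or two features to grid values and averages
predictions over the sample; grids are equally spaced *quantiles* of the
observed feature, which is robust to the long right tails of concentration
data (a uniform grid would spend most points beyond the data).

The importance-vs-correlation overlap contrasts the attribution top-k with
the |Spearman| top-k against the target. Features acting through
interactions or thresholds appear in the first list but not the second —
the core argument for dissecting models rather than reading correlation
tables. All dissection reports carry a caveat that high attribution is
predictive, not causal: co-correlated compounds share credit, and only
spiking experiments can separate them.

## Spiking and validation

Style-typical targets are computed on the ethanol-normalized scale
(mg/L per % ABV), statistic either the 95th percentile (linear
interpolation between order statistics) or the mean — both appear in
practice, so the statistic is an explicit, always-reported flag, default
p95. Normalization divides by max(ABV, 0.5 %): the floor makes the
operation well-defined for 0.0 % beers, which are legitimate spiking bases.
Additions are max(0, target − current): compounds are never removed.
Predicted uplift applies the trained preprocessing state to the base and
spiked rows and differences the model predictions. Tasting outcomes use the
exact two-sided binomial test at p₀ = ½ (sum of outcome probabilities ≤
P(k), which at ½ equals twice the smaller tail, capped at 1); with 13–20
tasters a normal approximation would be inappropriate.

## Synthetic studies: what they emulate and what they do not

The generator's default design is a 250-beer study across 22 styles (Blond
31 beers = 12.4 %, Tripel 28 = 11.2 %, down to Faro 2 ≈ 1 %), ~100 compounds
in five origin blocks, a 16-taster panel with 12 beers repeated across two
sessions, and ~40 reviews per beer from ~160 raters.

* **Chemistry.** A Gaussian copula with block-diagonal rank-correlation
  targets drives log-normal marginals, so concentrations are positive,
  right-tailed, and rank-correlated as specified (the Spearman→Pearson
  conversion 2·sin(πρ/6) makes the targets exact in population). Yeast
  metabolites are the most strongly coupled block (ethanol–ethyl acetate at
  ρ = 0.72, glycerol 0.65, others 0.5); style signatures are additive
  log-shifts (high iso-alpha in IPAs, lactic/acetic acid in sour styles,
  suppressed esters and glycerol in the low/no-alcohol style, which is
  always present so the ABV floor logic is exercised). ABV derives from the
  sampled ethanol; price tracks ABV plus style premiums.
* **Sensory map.** Latent attributes are sums of standardized Hill terms
  x^h/(K^h+x^h) (K at the compound median, h = 2) — the
  threshold-then-saturate shape of flavor perception — plus linear terms and
  pairwise Hill-product interactions; sweetness and bitterness are coupled
  antagonistically (−0.35). Panel scores add per-taster scale/bias and noise
  (sd 0.6) and clip to [1, 7]; review scores add style bias, price bias,
  rater effects and noise, and review texts draw sensory terms with
  probability increasing in the matching latent.
* **Planted truth.** Three appreciation drivers — ethyl acetate
  (saturating, 1.2), lactic acid (saturating, 1.0), ethyl phenyl acetate
  (linear, 0.9) — plus an ethanol×glycerol synergy (0.4). The ledger of all
  planted structure round-trips through JSON for use in tests.

Known, deliberate differences from real data: synthetic sensory targets are
*more predictable* than real panels or review corpora (held-out R² around
0.6–0.95 versus the 0.1–0.7 range typical of real studies), because the
generator omits inter-individual perception differences, context effects
and unmeasured compounds. Review texts are templated English, not prose.
Passing tests on bundles therefore demonstrates correctness of the
machinery and recoverability of planted effects at realistic sample sizes —
not real-world effect sizes. Effect sizes, noise scales and bias
coefficients are configuration, not claims.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run the full default design
(n = 250 beers, 100 compounds, 100 stability iterations with Shapley
aggregation over 50 training samples, 20 000-sample copula checks) in a few
minutes on one CPU. Every random draw flows from a single seed through a
NumPy seed sequence; regenerating any bundle, split, fit or report with the
same seed is byte-identical, and the pipeline manifest records seed, config
hash and all declared artifacts.
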