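"""Ingestion and preprocessing of the beer chemistry matrix.

The predictor space of the study is a beers × chemical-properties matrix
(concentrations in mg/L or assay units) with per-beer metadata (style, ABV,
optionally price).  This module covers the standard preprocessing chain used
before any modeling:

* log-transform of properties whose raw distribution looks log-normal
  (Shapiro–Wilk on raw scale rejects normality, on log scale does not),
* mean imputation of the sparse missingness typical of targeted assays,
* configurable aggregate properties (e.g. "total esters" as a weighted sum),
* style-stratified train/test splitting with largest-remainder rounding,
* per-property standardization fit on the training block only,
* pairwise-complete Spearman rank correlation (square or rectangular).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompoundMatrix",
    "TransformState",
    "CorrMatrix",
    "load_chemistry",
    "select_log_transform",
    "log_transform_matrix",
    "impute_missing",
    "derive_aggregates",
    "split_stratified",
    "standardize",
    "spearman_matrix",
]

#: metadata columns recognized in a chemistry CSV, in canonical order
META_COLUMNS = ("style", "abv", "price_per_l")


@dataclass
class CompoundMatrix:
    """Beers × chemical properties with per-beer and per-property metadata.

    ``values`` is indexed by beer_id with one column per property; missing
    measurements are NaN (never silently zero).  ``meta`` carries style, abv
    and optional price per beer; ``property_meta`` carries the origin class
    (malt/hops/yeast/wild/other) and an aggregate flag per property.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    property_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate beer_id(s): {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate property name(s): {dups}")
        if self.property_meta is None:
            self.property_meta = pd.DataFrame(
                {"origin": "other", "is_aggregate": False}, index=self.values.columns
            )

    @property
    def beer_ids(self) -> pd.Index:
        return self.values.index

    @property
    def properties(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "CompoundMatrix":
        return CompoundMatrix(
            self.values.copy(), self.meta.copy(), self.property_meta.copy()
        )


@dataclass
class TransformState:
    """Frozen preprocessing state, fit on training data only."""

    log_flags: pd.Series  # bool per property
    log_eps: pd.Series  # per-property epsilon used inside log(x + eps)
    imputed_means: pd.Series  # fill values on the (possibly logged) scale
    train_means: pd.Series
    train_sds: pd.Series

    def to_dict(self) -> dict:
        return {
            "log_flags": self.log_flags.astype(bool).to_dict(),
            "log_eps": self.log_eps.to_dict(),
            "imputed_means": self.imputed_means.to_dict(),
            "train_means": self.train_means.to_dict(),
            "train_sds": self.train_sds.to_dict(),
        }


@dataclass
class CorrMatrix:
    """Spearman correlations with two-sided p-values.

    Square (labels_b is labels_a) or rectangular when computed between two
    different variable sets.
    """

    rho: pd.DataFrame
    p: pd.DataFrame

    @property
    def labels_a(self) -> pd.Index:
        return self.rho.index

    @property
    def labels_b(self) -> pd.Index:
        return self.rho.columns

    def to_long(self) -> pd.DataFrame:
        rows = [
            {"prop_a": a, "prop_b": b,
             "rho": self.rho.at[a, b], "p": self.p.at[a, b]}
            for a in self.rho.index for b in self.rho.columns
        ]
        return pd.DataFrame(rows)


def load_chemistry(path) -> CompoundMatrix:
    """Read a chemistry CSV (beer_id, style, abv[, price_per_l], properties...).

    Empty cells become NaN and stay NaN; duplicate beer ids and non-numeric
    property cells raise with the offending row/column named.
    """
    df = pd.read_csv(path, dtype={"beer_id": str})
    if "beer_id" not in df.columns:
        raise ValueError("chemistry CSV must have a 'beer_id' column")
    dup = df["beer_id"][df["beer_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate beer_id(s): {sorted(dup.unique())}")
    df = df.set_index("beer_id")
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy()
    if "abv" in meta:
        meta["abv"] = pd.to_numeric(meta["abv"], errors="raise")
    values = df.drop(columns=meta_cols)
    for col in values.columns:
        try:
            values[col] = pd.to_numeric(values[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()
                             & values[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value in property '{col}' at beer '{row}'"
            ) from exc
    return CompoundMatrix(values.astype(float), meta)


def select_log_transform(
    x: np.ndarray, alpha: float = 0.05
) -> tuple[bool, np.ndarray, float]:
    """Decide whether a property should enter the models on log scale.

    Rule: Shapiro–Wilk rejects normality of the raw values (p < alpha) AND
    does not reject on log(x + eps), with eps = half the smallest positive
    observed value (tolerates below-detection zeros).  Returns
    (flag, transformed-or-raw values, eps used).  A constant vector is never
    transformed (the test is undefined) and triggers a warning.
    """
    x = np.asarray(x, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(obs) == 0:
        warnings.warn("constant property: normality test undefined, not transformed")
        return False, x, 0.0
    pos = obs[obs > 0]
    eps = 0.5 * pos.min() if pos.size else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000; W still usable
        p_raw = stats.shapiro(obs).pvalue
        logged = np.log(obs + eps)
        p_log = stats.shapiro(logged).pvalue if np.ptp(logged) > 0 else 0.0
    flag = (p_raw < alpha) and (p_log >= alpha)
    if flag:
        return True, np.log(x + eps), eps
    return False, x, eps


def log_transform_matrix(
    matrix: CompoundMatrix, alpha: float = 0.05
) -> tuple[CompoundMatrix, pd.Series, pd.Series]:
    """Apply :func:`select_log_transform` per property.

    Returns (transformed matrix, per-property bool flags, per-property eps).
    """
    out = matrix.copy()
    flags, epss = {}, {}
    for col in out.values.columns:
        flag, tx, eps = select_log_transform(out.values[col].to_numpy(), alpha=alpha)
        out.values[col] = tx
        flags[col] = flag
        epss[col] = eps
    return out, pd.Series(flags), pd.Series(epss)


def impute_missing(matrix: CompoundMatrix) -> tuple[CompoundMatrix, pd.Series]:
    """Replace missing cells with the per-property mean of observed values.

    Returns the imputed matrix and a per-property count of filled cells.
    A fully-missing property cannot be imputed and raises.
    """
    fully_missing = matrix.values.columns[matrix.values.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"fully-missing property(ies): {fully_missing.tolist()}")
    counts = matrix.values.isna().sum(axis=0)
    out = matrix.copy()
    out.values = out.values.fillna(out.values.mean(axis=0))
    return out, counts


def derive_aggregates(matrix: CompoundMatrix, recipes: dict) -> CompoundMatrix:
    """Append aggregate properties defined as weighted sums of components.

    ``recipes`` maps aggregate name -> {component property: weight}.  The
    study's derived attributes (caloric value, total acids, total esters,
    hop aroma, sulfur compounds) are weighted sums of individually measured
    compounds; the weights are configuration, not constants of nature.
    """
    if not recipes:
        return matrix
    out = matrix.copy()
    for name, comps in recipes.items():
        missing = [c for c in comps if c not in out.values.columns]
        if missing:
            raise ValueError(f"aggregate '{name}' references unknown properties: {missing}")
        col = sum(out.values[c] * w for c, w in comps.items())
        out.values[name] = col
        out.property_meta.loc[name] = {"origin": "other", "is_aggregate": True}
    return out


def split_stratified(
    matrix: CompoundMatrix, train_frac: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Style-stratified train/test split with largest-remainder rounding.

    Each style contributes round(n_style * train_frac) beers to the training
    set, with remainders resolved largest-first so the global train count is
    exactly round(n_total * train_frac).  A single-beer style goes to train.
    Deterministic given the seed.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    styles = matrix.meta["style"]
    n_total = len(styles)
    target_total = int(round(n_total * train_frac))

    groups = []
    for style in sorted(styles.unique()):
        ids = styles.index[styles == style].tolist()
        exact = len(ids) * train_frac
        if len(ids) == 1:
            # a singleton style cannot be represented in both halves; train wins
            groups.append({"ids": ids, "floor": 1, "rem": -1.0})
        else:
            groups.append(
                {"ids": ids, "floor": int(np.floor(exact)), "rem": exact - np.floor(exact)}
            )
    leftover = target_total - sum(g["floor"] for g in groups)
    # hand leftover seats to the largest fractional remainders (smaller styles
    # win ties so rare styles keep training representation); if singleton
    # styles over-allocated, reclaim seats from the smallest remainders
    order = sorted(groups, key=lambda g: (-g["rem"], len(g["ids"])))
    if leftover >= 0:
        for g in order[:leftover]:
            g["floor"] += 1
    else:
        for g in reversed(order):
            if leftover == 0:
                break
            if g["rem"] >= 0 and g["floor"] > 0:
                g["floor"] -= 1
                leftover += 1
    train_ids, test_ids = [], []
    for g in groups:
        ids = list(g["ids"])
        rng.shuffle(ids)
        train_ids.extend(ids[: g["floor"]])
        test_ids.extend(ids[g["floor"]:])
    return train_ids, test_ids


def standardize(
    values: pd.DataFrame, state: TransformState | None = None
) -> tuple[pd.DataFrame, TransformState]:
    """Center/scale per property; fit on train, re-apply to test.

    With ``state`` None the statistics are fit on ``values`` (the training
    block) and returned; otherwise the given training state is applied.
    A constant property is centered and its scale forced to 1 (warning).
    """
    if state is not None:
        if set(values.columns) != set(state.train_means.index):
            raise ValueError("property sets of data and transform state differ")
        mu = state.train_means.reindex(values.columns)
        sd = state.train_sds.reindex(values.columns)
        return (values - mu) / sd, state
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()]
    if len(bad):
        warnings.warn(f"constant property(ies) {bad.tolist()}: scale forced to 1")
        sd = sd.copy()
        sd[bad] = 1.0
    state = TransformState(
        log_flags=pd.Series(False, index=values.columns),
        log_eps=pd.Series(0.0, index=values.columns),
        imputed_means=mu.copy(),
        train_means=mu,
        train_sds=sd,
    )
    return (values - mu) / sd, state


def _rank_nan(col: np.ndarray) -> np.ndarray:
    """Midranks of a column, NaN-preserving."""
    out = np.full(col.shape, np.nan)
    mask = ~np.isnan(col)
    out[mask] = stats.rankdata(col[mask], method="average")
    return out


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        warnings.warn("fewer than 3 complete pairs: correlation undefined")
        return np.nan, np.nan
    rx = stats.rankdata(x[mask], method="average")
    ry = stats.rankdata(y[mask], method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return np.nan, np.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = _spearman_pvalue(rho, n)
    return rho, p


def _spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p via the t-approximation on n−2 degrees of freedom."""
    if np.isnan(rho) or n < 3:
        return np.nan
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def spearman_matrix(
    A: pd.DataFrame, B: pd.DataFrame | None = None
) -> CorrMatrix:
    """Pairwise-complete Spearman correlation with midrank tie handling.

    Square (A vs A) when B is None, else rectangular A-columns × B-columns
    over the shared row index.  Pairs with fewer than 3 complete observations
    get NaN with a warning.
    """
    square = B is None
    if square:
        B = A
    else:
        shared = A.index.intersection(B.index)
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared observations between A and B")
        A, B = A.loc[shared], B.loc[shared]

    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    n = a.shape[0]
    if not (np.isnan(a).any() or np.isnan(b).any()):
        ra = np.apply_along_axis(stats.rankdata, 0, a)
        rb = ra if square else np.apply_along_axis(stats.rankdata, 0, b)
        ra = (ra - ra.mean(axis=0)) / ra.std(axis=0, ddof=0)
        rb = ra if square else (rb - rb.mean(axis=0)) / rb.std(axis=0, ddof=0)
        rho = ra.T @ rb / n
        rho = np.clip(rho, -1.0, 1.0)
        p = np.vectorize(_spearman_pvalue)(rho, n)
    else:
        rho = np.empty((a.shape[1], b.shape[1]))
        p = np.empty_like(rho)
        for i in range(a.shape[1]):
            j0 = i if square else 0
            for j in range(j0, b.shape[1]):
                rho[i, j], p[i, j] = _spearman_pair(a[:, i], b[:, j])
                if square:
                    rho[j, i], p[j, i] = rho[i, j], p[i, j]
    if square:
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(p, 0.0)
    return CorrMatrix(
        rho=pd.DataFrame(rho, index=A.columns, columns=B.columns),
        p=pd.DataFrame(p, index=A.columns, columns=B.columns),
    )
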