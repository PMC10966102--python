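"""From model insight to intervention: compound spiking plans and their
sensory validation.

Given compounds identified as appreciation drivers, a base beer is brought
up to style-typical target concentrations.  Targets are defined on the
ethanol-normalized scale (mg/L per % ABV) so that stronger beers are
compared like-for-like, using either the 95th percentile or the mean of
the base beer's style group.  Additions are never negative — compounds
cannot be removed from a finished beer.  Tasting validation is a paired
directional difference test: each assessor picks the more intense (or
preferred) of spiked vs control, analyzed with the exact two-sided
binomial test at null proportion 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemprep import CompoundMatrix, TransformState

__all__ = [
    "SpikingPlan",
    "TastingOutcome",
    "ethanol_normalize",
    "style_targets",
    "spiking_plan",
    "apply_plan",
    "predict_uplift",
    "directional_binomial",
    "tasting_outcomes",
]

#: % ABV floor used when normalizing 0.0% beers (division by near-zero ABV
#: would make alcohol-free beers look impossibly concentrated)
ABV_FLOOR = 0.5


@dataclass
class SpikingPlan:
    """Non-negative additions bringing a base beer to style targets."""

    base_beer_id: str
    table: pd.DataFrame  # index compound: current_conc, target_conc, addition
    statistic: str  # 'p95' | 'mean'
    style: str
    reference_abv: float
    abv_floored: bool = False
    predicted_uplift: float | None = None

    def __post_init__(self) -> None:
        if (self.table["addition"] < 0).any():
            raise ValueError("additions must be non-negative")

    @property
    def compounds(self) -> list:
        return list(self.table.index)


@dataclass
class TastingOutcome:
    attribute: str
    n_tasters: int
    n_choosing_spiked: int
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_choosing_spiked <= self.n_tasters:
            raise ValueError("count must be within 0..n")
        self.p_value = directional_binomial(self.n_choosing_spiked, self.n_tasters)


def ethanol_normalize(conc, abv, abv_floor: float = ABV_FLOOR):
    """Concentration per % ABV: conc / max(abv, floor).

    The floor handles 0.0% beers, for which raw division is undefined in
    spirit (their compound load is not 'infinite per unit alcohol').
    Returns (normalized value(s), floored flag).
    """
    abv_arr = np.asarray(abv, dtype=float)
    if (abv_arr < 0).any():
        raise ValueError("ABV cannot be negative")
    floored = bool((abv_arr < abv_floor).any())
    denom = np.maximum(abv_arr, abv_floor)
    return np.asarray(conc, dtype=float) / denom, floored


def style_targets(
    chem: CompoundMatrix,
    style: str,
    compounds: list,
    statistic: str = "p95",
) -> pd.Series:
    """Per-compound target on the ethanol-normalized scale, within a style.

    statistic 'p95' = 95th percentile with linear interpolation between
    order statistics; 'mean' = within-style average.  Requires at least
    3 beers in the style.
    """
    if statistic not in ("p95", "mean"):
        raise ValueError(f"unknown statistic '{statistic}'")
    in_style = chem.meta.index[chem.meta["style"] == style]
    if len(in_style) == 0:
        raise ValueError(f"unknown style '{style}'")
    if len(in_style) < 3:
        raise ValueError(f"style '{style}' has fewer than 3 beers")
    missing = [c for c in compounds if c not in chem.values.columns]
    if missing:
        raise ValueError(f"unknown compound(s): {missing}")
    conc = chem.values.loc[in_style, compounds]
    abv = chem.meta.loc[in_style, "abv"]
    norm, _ = ethanol_normalize(conc.to_numpy(), abv.to_numpy()[:, None])
    norm = pd.DataFrame(norm, index=in_style, columns=compounds)
    if statistic == "mean":
        return norm.mean(axis=0)
    return norm.quantile(0.95, interpolation="linear")


def spiking_plan(
    chem: CompoundMatrix,
    base_beer_id: str,
    targets: pd.Series,
    statistic: str = "p95",
    style: str | None = None,
    exclude: list | None = None,
    abv_floor: float = ABV_FLOOR,
) -> SpikingPlan:
    """Build the non-negative addition plan for a base beer.

    Targets are in normalized units (mg/L per % ABV); they are de-normalized
    with the base beer's own ABV (floored for alcohol-free bases), then
    addition = max(0, target_conc − current).  Compounds on the exclusion
    list (typically ethanol itself) are dropped from the plan.
    """
    if base_beer_id not in chem.values.index:
        raise ValueError(f"unknown base beer '{base_beer_id}'")
    exclude = set(exclude or ())
    compounds = [c for c in targets.index if c not in exclude]
    current = chem.values.loc[base_beer_id, compounds]
    if current.isna().any():
        missing = current.index[current.isna()].tolist()
        raise ValueError(f"base beer lacks measurements for: {missing}")
    abv = float(chem.meta.loc[base_beer_id, "abv"])
    floored = abv < abv_floor
    ref_abv = max(abv, abv_floor)
    target_conc = targets.loc[compounds] * ref_abv
    addition = np.maximum(target_conc - current, 0.0)
    table = pd.DataFrame({
        "current_conc": current,
        "target_conc": target_conc,
        "addition": addition,
    })
    return SpikingPlan(
        base_beer_id=base_beer_id, table=table, statistic=statistic,
        style=style or str(chem.meta.loc[base_beer_id, "style"]),
        reference_abv=ref_abv, abv_floored=floored,
    )


def apply_plan(chem: CompoundMatrix, plan: SpikingPlan) -> pd.Series:
    """The spiked beer's raw concentration row (base + additions)."""
    row = chem.values.loc[plan.base_beer_id].copy()
    row.loc[plan.compounds] = row.loc[plan.compounds] + plan.table["addition"]
    return row


def predict_uplift(
    model,
    chem: CompoundMatrix,
    plan: SpikingPlan,
    state: TransformState,
) -> float:
    """Predicted appreciation delta of the spiked beer vs its base.

    Additions act on raw concentrations; both rows then pass through the
    *training* preprocessing state (log where flagged, mean-impute,
    standardize) before prediction, exactly as any new sample would.
    """
    base_raw = chem.values.loc[plan.base_beer_id]
    spiked_raw = apply_plan(chem, plan)
    X = pd.DataFrame([base_raw, spiked_raw], index=["base", "spiked"])
    missing = [c for c in state.train_means.index if c not in X.columns]
    if missing:
        raise ValueError(f"model features missing from chemistry: {missing}")
    X = X[state.train_means.index]
    for col in X.columns:
        if bool(state.log_flags.get(col, False)):
            X[col] = np.log(X[col] + float(state.log_eps.get(col, 0.0)))
        X[col] = X[col].fillna(float(state.imputed_means[col]))
    Xs = (X - state.train_means) / state.train_sds
    pred = np.ravel(model.predict(Xs))
    return float(pred[1] - pred[0])


def directional_binomial(k: int, n: int) -> float:
    """Exact two-sided binomial p at null proportion 0.5.

    The two-sided p is the total probability of outcomes at least as
    extreme as k (sum of point probabilities ≤ P(k)), capped at 1; under
    p0 = 0.5 this equals twice the smaller tail.  Exact, not a normal
    approximation: panel sizes are small (n ≈ 13–20).
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n >= 1")
    return float(stats.binomtest(k, n, p=0.5, alternative="two-sided").pvalue)


def tasting_outcomes(counts: pd.DataFrame) -> pd.DataFrame:
    """Vectorized tasting analysis: one exact binomial test per attribute.

    ``counts`` needs columns attribute, n_tasters, n_choosing_spiked.
    """
    rows = []
    for _, r in counts.iterrows():
        o = TastingOutcome(str(r["attribute"]), int(r["n_tasters"]),
                           int(r["n_choosing_spiked"]))
        rows.append({"attribute": o.attribute, "n_tasters": o.n_tasters,
                     "n_choosing_spiked": o.n_choosing_spiked,
                     "p_value": o.p_value,
                     "significant": o.p_value < 0.05})
    return pd.DataFrame(rows)
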