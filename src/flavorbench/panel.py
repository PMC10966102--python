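"""Trained-panel score normalization, aggregation and consistency checks.

A trained descriptive panel scores each beer for a fixed vocabulary of
attributes on a 7-point intensity scale.  Tasters use the scale differently
(individual offsets and spreads), so raw scores are converted to per-taster
z-scores before any aggregation; beer-level sensory profiles are then the
mean z-score over available (taster, session) ratings.  Panel reliability is
quantified by re-serving a subset of beers across sessions and testing for a
session effect with one-way ANOVA per (beer, attribute).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PanelScores",
    "SensoryProfile",
    "taster_zscore",
    "beer_attribute_means",
    "panel_consistency",
]

SCALE_MIN, SCALE_MAX = 1.0, 7.0

REQUIRED_COLUMNS = ("beer_id", "taster_id", "session_id", "attribute", "score")


@dataclass
class PanelScores:
    """Long-format panel ratings: one row per (beer, taster, session, attribute)."""

    records: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"panel records missing columns: {missing}")
        key = ["beer_id", "taster_id", "session_id", "attribute"]
        if self.records.duplicated(subset=key).any():
            raise ValueError("duplicate (beer, taster, session, attribute) records")
        if not self.normalized:
            s = self.records["score"]
            if (s < SCALE_MIN - 1e-9).any() or (s > SCALE_MAX + 1e-9).any():
                raise ValueError("raw scores outside the 7-point scale")

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "PanelScores":
        return cls(pd.read_csv(path, dtype={"beer_id": str, "taster_id": str}),
                   normalized=normalized)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


@dataclass
class SensoryProfile:
    """Beer × attribute matrix of mean z-scores, with per-cell rating counts."""

    values: pd.DataFrame
    n_ratings: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def taster_zscore(scores: PanelScores) -> PanelScores:
    """Scale by standard deviation and mean-center per taster.

    The z-score is computed over *all* of a taster's ratings (sample sd,
    n−1), not per attribute: the normalization corrects how an individual
    uses the scale, which is a property of the taster.  A taster with zero
    spread carries no ranking information; their centered values are set to
    0 with a warning.
    """
    if scores.normalized:
        return scores
    rec = scores.records.copy()
    grp = rec.groupby("taster_id")["score"]
    mu = grp.transform("mean")
    sd = grp.transform(lambda s: s.std(ddof=1))
    flat = sd.isna() | (sd == 0)
    if flat.any():
        tasters = rec.loc[flat, "taster_id"].unique().tolist()
        warnings.warn(f"taster(s) with zero score spread, set to 0: {tasters}")
        sd = sd.mask(flat, np.inf)
    rec["score"] = (rec["score"] - mu) / sd
    return PanelScores(rec, normalized=True)


def beer_attribute_means(scores: PanelScores) -> SensoryProfile:
    """Aggregate normalized scores to a beer × attribute mean-z matrix.

    Not every taster rates every beer; a missing rating simply reduces the
    per-cell n (no imputation).  A (beer, attribute) cell with no ratings at
    all stays missing, with a warning.
    """
    if not scores.normalized:
        raise ValueError("scores must be taster-normalized before aggregation")
    rec = scores.records
    values = rec.pivot_table(index="beer_id", columns="attribute",
                             values="score", aggfunc="mean")
    n = rec.pivot_table(index="beer_id", columns="attribute",
                        values="score", aggfunc="count").fillna(0).astype(int)
    if values.isna().any().any():
        warnings.warn("some (beer, attribute) cells have no ratings")
    return SensoryProfile(values=values, n_ratings=n)


def panel_consistency(
    scores: PanelScores, repeated_ids: list, alpha: float = 0.05
) -> tuple[float, pd.DataFrame]:
    """Session-effect ANOVA on beers served in more than one session.

    For each repeated beer and attribute, a one-way ANOVA with session as
    the factor; the panel is consistent for that cell when the session
    effect is not significant (p > alpha).  Returns the fraction of
    consistent tests and the full per-test table.  Cells with zero variance
    everywhere are reported consistent with a ``degenerate`` flag (identical
    scores across sessions cannot indicate a session effect).
    """
    rec = scores.records
    rows = []
    for beer in repeated_ids:
        sub = rec[rec["beer_id"] == beer]
        if sub["session_id"].nunique() < 2:
            raise ValueError(f"repeated beer '{beer}' has fewer than 2 sessions")
        for attr, block in sub.groupby("attribute"):
            groups = [g["score"].to_numpy()
                      for _, g in block.groupby("session_id") if len(g)]
            if len(groups) < 2:
                continue
            pooled = np.concatenate(groups)
            if np.ptp(pooled) == 0:
                # identical scores across sessions: no session effect possible
                rows.append({"beer_id": beer, "attribute": attr, "F": np.nan,
                             "p": 1.0, "consistent": True, "degenerate": True})
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*groups)
            rows.append({"beer_id": beer, "attribute": attr, "F": float(f),
                         "p": float(p), "consistent": bool(p > alpha),
                         "degenerate": False})
    table = pd.DataFrame(rows)
    frac = float(table["consistent"].mean()) if len(table) else float("nan")
    return frac, table
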