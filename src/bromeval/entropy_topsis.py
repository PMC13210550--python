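"""Entropy-weighted TOPSIS ranking of alternatives on mixed indicators.

The entropy weight method derives objective indicator weights from the data
itself: for each indicator j the column of the strictly positive decision
matrix is normalized to proportions p_ij = x_ij / sum_i x_ij, its Shannon
entropy e_j = -(1/ln n) * sum_i p_ij ln p_ij is computed (with 0 ln 0 = 0),
the dispersion is d_j = 1 - e_j, and the weight w_j = d_j / sum_j d_j.
Indicators whose values differ more across alternatives carry more weight.

TOPSIS then scores each alternative by closeness to an ideal / anti-ideal
pair built from the weighted proportion matrix v_ij = w_j * p_ij: the ideal
V+ takes the per-indicator maximum of v for benefit-type indicators and the
minimum for cost-type indicators (V- conversely), and the closeness
coefficient is C_i = D_i- / (D_i+ + D_i-) with Euclidean distances D_i+/-.
C_i lies in [0, 1]; larger is better, and rank 1 has the largest C_i.

Because proportions are quotients, multiplying any raw column by a positive
constant leaves p, e, w, v and C unchanged (scale invariance).  Note that
under entropy weighting, duplicating an indicator column changes the weight
vector (the duplicated information is counted twice); invariance to such
edits holds only when weights are supplied externally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from bromeval.synthetic_data import TraitSchema

__all__ = [
    "DecisionMatrix",
    "EntropyWeights",
    "TopsisResult",
    "proportion_normalize",
    "entropy_weights",
    "topsis_rank",
    "rescale_to_positive",
    "DegenerateWeightsError",
]


class DegenerateWeightsError(ValueError):
    """All indicator columns are uniform: entropy weights are undefined."""


@dataclass(frozen=True)
class DecisionMatrix:
    """Strictly positive alternatives x indicators matrix with directions.

    ``directions`` maps each indicator column to ``"benefit"`` (more is
    better) or ``"cost"`` (less is better).
    """

    values: pd.DataFrame
    directions: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least 2 alternatives")
        if self.values.shape[1] < 1:
            raise ValueError("need at least 1 indicator")
        if not (self.values.to_numpy(dtype=float) > 0).all():
            raise ValueError(
                "decision matrix must be strictly positive; rescale raw values "
                "first (see rescale_to_positive)"
            )
        for col in self.values.columns:
            if self.directions.get(col) not in ("benefit", "cost"):
                raise ValueError(f"missing/invalid direction for indicator {col!r}")

    @classmethod
    def from_schema(cls, values: pd.DataFrame, schema: TraitSchema) -> "DecisionMatrix":
        return cls(values=values[list(schema.indicators)], directions=dict(schema.directions))


@dataclass(frozen=True)
class EntropyWeights:
    p: pd.DataFrame  # proportion matrix, columns sum to 1
    e: pd.Series  # entropy per indicator, in [0, 1]
    d: pd.Series  # dispersion 1 - e
    w: pd.Series  # weights, nonnegative, sum to 1


@dataclass(frozen=True)
class TopsisResult:
    weights: EntropyWeights
    v: pd.DataFrame  # weighted proportion matrix
    ideal: pd.Series  # V+
    anti_ideal: pd.Series  # V-
    d_plus: pd.Series
    d_minus: pd.Series
    closeness: pd.Series  # C_i in [0, 1]
    ranks: pd.Series  # dense ranks, 1 = best


def proportion_normalize(X: pd.DataFrame) -> pd.DataFrame:
    """Column-stochastic normalization p_ij = x_ij / sum_i x_ij."""
    values = X.to_numpy(dtype=float)
    if not (values > 0).all():
        raise ValueError(
            "proportion normalization requires strictly positive entries; "
            "min-max rescale raw/standardized inputs first"
        )
    return X / X.sum(axis=0)


def entropy_weights(p: pd.DataFrame) -> EntropyWeights:
    """Entropy, dispersion and weights from a proportion matrix."""
    n = len(p)
    if n < 2:
        raise ValueError("need at least 2 alternatives")
    vals = p.to_numpy(dtype=float)
    if (vals < 0).any() or not np.allclose(vals.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("columns of a proportion matrix must be nonnegative and sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(vals > 0, vals * np.log(np.where(vals > 0, vals, 1.0)), 0.0)
    e = pd.Series(-plogp.sum(axis=0) / np.log(n), index=p.columns).clip(0.0, 1.0)
    d = 1.0 - e
    total = d.sum()
    if total <= 0:
        raise DegenerateWeightsError(
            "every indicator column is uniform across alternatives; "
            "entropy weights are undefined"
        )
    w = d / total
    return EntropyWeights(p=p, e=e, d=d, w=w)


def topsis_rank(
    X: DecisionMatrix, weights: pd.Series | None = None
) -> TopsisResult:
    """Rank alternatives by closeness to the entropy-weighted ideal solution.

    ``weights`` overrides the entropy weights (must be nonnegative, summing
    to 1, indexed like the indicator columns); cost-type indicators are
    handled by direction at the ideal-solution stage, not by transforming
    the data.  Ties in closeness share a dense rank.
    """
    p = proportion_normalize(X.values)
    if weights is None:
        ew = entropy_weights(p)
    else:
        w = weights.reindex(p.columns)
        if w.isna().any() or (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("external weights must be nonnegative and sum to 1")
        ew = EntropyWeights(p=p, e=pd.Series(np.nan, index=p.columns), d=pd.Series(np.nan, index=p.columns), w=w)
    v = p * ew.w

    benefit = [c for c in v.columns if X.directions[c] == "benefit"]
    cost = [c for c in v.columns if X.directions[c] == "cost"]
    ideal = pd.concat([v[benefit].max(), v[cost].min()]).reindex(v.columns)
    anti = pd.concat([v[benefit].min(), v[cost].max()]).reindex(v.columns)

    d_plus = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - anti) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if (denom == 0).any():
        raise ValueError(
            "identical alternatives: distances to ideal and anti-ideal are both "
            "zero, closeness undefined"
        )
    closeness = d_minus / denom
    ranks = closeness.rank(method="dense", ascending=False).astype(int)
    return TopsisResult(
        weights=ew,
        v=v,
        ideal=ideal,
        anti_ideal=anti,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=closeness,
        ranks=ranks,
    )


def rescale_to_positive(
    X: pd.DataFrame, lo: float = 0.05, hi: float = 1.0
) -> pd.DataFrame:
    """Min-max rescale each column to [lo, hi] (lo > 0).

    Documented preprocessing for inputs that are not strictly positive
    (z-scored traits, signed effects).  Constant columns map to ``hi``.
    """
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    mins, maxs = X.min(), X.max()
    span = (maxs - mins).replace(0, np.nan)
    out = lo + (X - mins) / span * (hi - lo)
    return out.fillna(hi)
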