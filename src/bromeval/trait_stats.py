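"""Trait statistics for balanced multi-year trials.

Assumption screening (Lilliefors normality with Monte-Carlo p, median-based
Levene), one-way and two-way fixed-effects ANOVA with partial eta-squared,
protected-LSD pairwise comparisons with compact letter displays, coefficient
of variation, and pooled two-sample t-tests.

The ANOVA routines implement the balanced-complete-factorial case only and
compute sums of squares directly from cell means (for a balanced design all
classical SS types coincide, and factor coding is irrelevant); unbalanced
input is rejected rather than silently reweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "lilliefors_ks",
    "levene_median",
    "oneway_anova",
    "twoway_anova",
    "lsd_pairwise",
    "cv",
    "two_sample_t",
    "screen_assumptions",
    "PairwiseLSD",
    "OneWayAnova",
]

# ---------------------------------------------------------------------------
# Normality / variance screening
# ---------------------------------------------------------------------------

_LILLIEFORS_SEED = 20240623
_null_tables: dict[tuple[int, int], np.ndarray] = {}


def _ks_normal_estimated(x: np.ndarray) -> float:
    """KS distance of ``x`` to the normal with estimated mean and SD."""
    n = x.shape[-1]
    z = np.sort(x, axis=-1)
    mean = z.mean(axis=-1, keepdims=True)
    sd = z.std(axis=-1, ddof=1, keepdims=True)
    cdf = stats.norm.cdf((z - mean) / sd)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_plus = (grid_hi - cdf).max(axis=-1)
    d_minus = (cdf - grid_lo).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def _lilliefors_null(n: int, n_sim: int) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic (memoized).

    The null is the same for every dataset of size ``n``, so the table is
    simulated once per (n, n_sim) with a fixed internal seed.
    """
    key = (n, n_sim)
    if key not in _null_tables:
        rng = np.random.default_rng(_LILLIEFORS_SEED + n)
        # Chunk to bound memory for large n * n_sim.
        chunk = max(1, int(5e6) // n)
        parts = []
        done = 0
        while done < n_sim:
            m = min(chunk, n_sim - done)
            parts.append(_ks_normal_estimated(rng.normal(size=(m, n))))
            done += m
        _null_tables[key] = np.sort(np.concatenate(parts))
    return _null_tables[key]


def lilliefors_ks(sample: Sequence[float], n_sim: int = 10_000) -> tuple[float, float]:
    """Lilliefors-corrected Kolmogorov-Smirnov normality test.

    The statistic is the KS distance to the normal distribution with mean and
    SD estimated from the sample; because parameters are estimated, the
    standard KS null does not apply and the p-value is obtained from a
    Monte-Carlo null of ``n_sim`` standard-normal samples of the same size
    (fixed internal seed; the p-value therefore carries simulation noise of
    roughly +/- 0.01 at the default ``n_sim``).
    """
    x = np.asarray(sample, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-D sample with n >= 4")
    if np.std(x, ddof=1) == 0:
        raise ValueError("constant sample: SD is zero, normality test undefined")
    d = float(_ks_normal_estimated(x))
    null = _lilliefors_null(x.size, n_sim)
    # +1 correction keeps p in (0, 1].
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (n_ge + 1) / (null.size + 1)
    return d, float(p)


def levene_median(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Levene's variance-homogeneity test on deviations from group medians.

    The median-centred (Brown-Forsythe) form is robust to non-normality.
    Degenerate all-equal deviations return statistic 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    devs = [np.abs(a - np.median(a)) for a in arrays]
    if all(np.ptp(d) == 0 for d in devs) and np.ptp([d.mean() for d in devs]) == 0:
        return 0.0, 1.0
    stat, p = stats.levene(*arrays, center="median")
    return float(stat), float(p)


def screen_assumptions(
    table: pd.DataFrame,
    response: str,
    by: Sequence[str] = ("genotype", "year"),
    alpha: float = 0.05,
    n_sim: int = 10_000,
) -> pd.DataFrame:
    """Per-group normality screen plus an across-group variance test.

    A group passes normality when its Lilliefors p >= alpha, or marginally
    (0.01 < p < alpha) with |skewness| < 2 and |excess kurtosis| < 7.
    Returns one row per group with the across-group median-Levene statistic
    repeated in columns ``levene_stat`` / ``levene_p``.
    """
    rows = []
    groups = []
    for key, sub in table.groupby(list(by), observed=True, sort=True):
        x = sub[response].to_numpy(dtype=float)
        groups.append(x)
        ks_stat, ks_p = lilliefors_ks(x, n_sim=n_sim)
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, bias=False))  # excess
        passes = bool(
            ks_p >= alpha or (0.01 < ks_p < alpha and abs(skew) < 2 and abs(kurt) < 7)
        )
        rows.append([*np.atleast_1d(key), ks_stat, ks_p, skew, kurt, passes])
    lev_stat, lev_p = levene_median(groups)
    out = pd.DataFrame(
        rows,
        columns=[*by, "ks_stat", "ks_p", "skewness", "kurtosis", "pass_normality"],
    )
    out["levene_stat"] = lev_stat
    out["levene_p"] = lev_p
    return out


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OneWayAnova:
    f: float
    p: float
    df_between: int
    df_error: int
    mse: float
    group_means: pd.Series
    n_per_group: int


def oneway_anova(table: pd.DataFrame, response: str, group: str) -> OneWayAnova:
    """Balanced one-way fixed-effects ANOVA (omnibus F plus LSD ingredients)."""
    sizes = table.groupby(group, observed=True)[response].size()
    if sizes.nunique() != 1:
        raise ValueError("unequal group sizes: balanced design required")
    y = table[response].to_numpy(dtype=float)
    means = table.groupby(group, observed=True)[response].mean()
    r = int(sizes.iloc[0])
    k = len(means)
    ss_between = r * float(((means - y.mean()) ** 2).sum())
    fitted = table[group].map(means).to_numpy(dtype=float)
    ss_error = float(((y - fitted) ** 2).sum())
    df_b, df_e = k - 1, y.size - k
    mse = ss_error / df_e
    f = (ss_between / df_b) / mse if mse > 0 else np.inf
    p = float(stats.f.sf(f, df_b, df_e))
    return OneWayAnova(float(f), p, df_b, df_e, mse, means, r)


def twoway_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str = "genotype",
    factor_b: str = "year",
) -> pd.DataFrame:
    """Two-way factorial fixed-effects ANOVA with partial eta-squared.

    Requires a balanced complete factorial with replication (every A x B cell
    present with the same count > 1).  Returns a tidy table with one row per
    term (factor_a, factor_b, interaction, residual) and columns
    ``ss, df, ms, F, p, partial_eta2`` where
    partial eta2 = SS_term / (SS_term + SS_error).
    """
    cells = table.groupby([factor_a, factor_b], observed=True)[response].agg(
        ["mean", "size"]
    )
    a_levels = table[factor_a].unique()
    b_levels = table[factor_b].unique()
    if len(cells) != len(a_levels) * len(b_levels) or cells["size"].nunique() != 1:
        raise ValueError("missing cells or unequal replication: balanced design required")
    r = int(cells["size"].iloc[0])
    if r < 2:
        raise ValueError("need replication (> 1 observation per cell)")
    y = table[response].to_numpy(dtype=float)
    grand = y.mean()
    a, b = len(a_levels), len(b_levels)

    mean_a = table.groupby(factor_a, observed=True)[response].mean()
    mean_b = table.groupby(factor_b, observed=True)[response].mean()
    cell_mean = cells["mean"]

    ss_a = b * r * float(((mean_a - grand) ** 2).sum())
    ss_b = a * r * float(((mean_b - grand) ** 2).sum())
    inter = (
        cell_mean
        - mean_a.reindex(cell_mean.index.get_level_values(0)).to_numpy()
        - mean_b.reindex(cell_mean.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ab = r * float((inter**2).sum())
    fitted = (
        table.set_index([factor_a, factor_b]).index.map(cell_mean).to_numpy(dtype=float)
    )
    ss_e = float(((y - fitted) ** 2).sum())

    terms = [
        (factor_a, ss_a, a - 1),
        (factor_b, ss_b, b - 1),
        (f"{factor_a}:{factor_b}", ss_ab, (a - 1) * (b - 1)),
    ]
    df_e = a * b * (r - 1)
    ms_e = ss_e / df_e
    rows = []
    for name, ss, df in terms:
        ms = ss / df
        f = ms / ms_e if ms_e > 0 else np.inf
        p = float(stats.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
        eta = ss / (ss + ss_e) if (ss + ss_e) > 0 else 0.0
        rows.append([name, ss, df, ms, f, p, eta])
    rows.append(["residual", ss_e, df_e, ms_e, np.nan, np.nan, np.nan])
    return pd.DataFrame(
        rows, columns=["term", "ss", "df", "ms", "F", "p", "partial_eta2"]
    ).set_index("term")


# ---------------------------------------------------------------------------
# LSD post hoc
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseLSD:
    """Protected-LSD pairwise comparison result.

    ``pairs`` has one row per unordered group pair with the mean difference,
    the LSD threshold and the significance flag; ``letters`` is the compact
    letter display (groups sharing a letter do not differ at ``alpha``).
    ``omnibus_p`` is the protecting one-way F-test p-value: when it exceeds
    ``alpha`` no pair is declared significant regardless of magnitude.
    """

    pairs: pd.DataFrame
    letters: pd.Series
    lsd: float
    omnibus_p: float
    alpha: float


def lsd_pairwise(
    table: pd.DataFrame,
    response: str,
    group: str,
    alpha: float = 0.05,
) -> PairwiseLSD:
    """Fisher's protected least-significant-difference comparisons.

    LSD = t_{1-alpha/2, df_error} * sqrt(2 * MSE / n_per_group) from the
    one-way ANOVA; a pair differs when |mean difference| exceeds the LSD and
    the omnibus F is itself significant (the "protected" variant).  Compact
    letters follow from sorted means: with a common threshold, groups within
    any maximal run of means spanning at most one LSD share a letter.  Ties
    in mean are broken by ascending group label for determinism.
    """
    aov = oneway_anova(table, response, group)
    t_crit = stats.t.ppf(1 - alpha / 2, aov.df_error)
    lsd = float(t_crit * np.sqrt(2 * aov.mse / aov.n_per_group))
    protected = aov.p < alpha

    means = aov.group_means.sort_values(kind="mergesort")  # stable: label-order ties
    names = list(means.index)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = float(aov.group_means[a] - aov.group_means[b])
            sig = protected and abs(diff) > lsd
            rows.append([a, b, diff, lsd, sig])
    pairs = pd.DataFrame(rows, columns=["a", "b", "diff", "lsd", "significant"])

    # Compact letters: maximal windows of the sorted means within one LSD.
    if not protected:
        letters = pd.Series("a", index=aov.group_means.index)
    else:
        vals = means.to_numpy()
        windows = []
        for s in range(len(names)):
            e = s
            while e + 1 < len(names) and vals[e + 1] - vals[s] <= lsd:
                e += 1
            windows.append((s, e))
        # Keep only maximal windows (not nested in another).
        maximal = sorted(
            {
                (s, e)
                for s, e in windows
                if not any(
                    (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in windows
                )
            }
        )
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        labels = {name: "" for name in names}
        for li, (s, e) in enumerate(maximal):
            for name in names[s : e + 1]:
                labels[name] += alphabet[li % len(alphabet)]
        letters = pd.Series(labels).reindex(aov.group_means.index)
    return PairwiseLSD(pairs, letters, lsd, aov.p, alpha)


# ---------------------------------------------------------------------------
# Simple descriptive / comparison statistics
# ---------------------------------------------------------------------------


def cv(sample: Sequence[float]) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    x = np.asarray(sample, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean is zero: CV undefined")
    return float(np.std(x, ddof=1) / mean)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Independent two-sample t-test (pooled-variance Student t by default).

    The pooled form matches the balanced-design LSD machinery; pass
    ``welch=True`` for the unequal-variance form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
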