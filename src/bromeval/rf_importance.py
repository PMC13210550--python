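"""Random-forest regression importance with permutation significance.

A regression forest predicts the terminal response (hay yield) from the
remaining trait indicators; variable importance is the percentage increase
in out-of-bag mean squared error (%IncMSE) when a predictor is permuted
among the out-of-bag samples of each tree.  Two permutation nulls give
significance: the model-level null permutes the response and refits,
comparing pseudo-R^2; the variable-level null permutes one predictor's
training values and refits, comparing that predictor's %IncMSE.  Both
p-values use the add-one correction, so they are never exactly 0.

The trees are grown by scikit-learn; the forest wrapper here only does the
bagging bookkeeping so that each tree's out-of-bag indices are available to
the permutation machinery (the backend is a thin contract — fit, per-tree
OOB prediction — and can be swapped).  Null refits may use a reduced tree
count (``null_ntree``) for desk-scale runs; a noisier null is conservative
under the null hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import sklearn
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "RFConfig",
    "ImportanceResult",
    "BaggedForest",
    "fit_importance",
    "model_significance",
    "variable_significance",
    "scaled_down",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest and permutation-protocol settings.

    Defaults follow the conventional regression-forest protocol: 1000 trees,
    ``mtry = floor(m / 3)`` candidate predictors per split, terminal node
    size 5, seed 123, and 1000 permutations for both nulls.  ``null_ntree``
    (when set) reduces the tree count of the permutation-null refits only.
    """

    ntree: int = 1000
    mtry: int | None = None
    nodesize: int = 5
    seed: int = 123
    n_perm_model: int = 1000
    n_perm_variable: int = 1000
    null_ntree: int | None = None

    def validate(self, m: int) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        mtry = self.resolved_mtry(m)
        if not 1 <= mtry <= m:
            raise ValueError(f"mtry must be in [1, {m}]")
        if min(self.n_perm_model, self.n_perm_variable) < 99:
            raise ValueError("permutation counts must be >= 99")

    def resolved_mtry(self, m: int) -> int:
        return self.mtry if self.mtry is not None else max(1, m // 3)


class BaggedForest:
    """Bootstrap-aggregated regression trees with explicit OOB indices."""

    def __init__(self, ntree: int, mtry: int, nodesize: int):
        self.ntree = ntree
        self.mtry = mtry
        self.nodesize = nodesize
        self.trees: list[DecisionTreeRegressor] = []
        self.oob: list[np.ndarray] = []

    @staticmethod
    def _as32(X: np.ndarray) -> np.ndarray:
        # Trees are queried with check_input=False, which requires
        # C-contiguous float32 input.
        return np.ascontiguousarray(X, dtype=np.float32)

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> "BaggedForest":
        X32 = self._as32(X)
        y = np.ascontiguousarray(y, dtype=np.float64)
        n = X32.shape[0]
        self.trees, self.oob = [], []
        # Inputs are prepared here once, so per-tree re-validation is skipped.
        with sklearn.config_context(skip_parameter_validation=True):
            for _ in range(self.ntree):
                idx = rng.integers(0, n, n)
                mask = np.ones(n, dtype=bool)
                mask[idx] = False
                tree = DecisionTreeRegressor(
                    max_features=self.mtry,
                    min_samples_leaf=self.nodesize,
                    random_state=int(rng.integers(2**31)),
                )
                tree.fit(np.ascontiguousarray(X32[idx]), y[idx], check_input=False)
                self.trees.append(tree)
                self.oob.append(np.flatnonzero(mask))
        return self

    def oob_prediction(self, X: np.ndarray) -> np.ndarray:
        """Ensemble prediction for each sample from trees where it is OOB."""
        X32 = self._as32(X)
        n = X32.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob):
            if oob.size == 0:
                continue
            total[oob] += tree.predict(X32[oob], check_input=False)
            count[oob] += 1
        pred = np.full(n, np.nan)
        seen = count > 0
        pred[seen] = total[seen] / count[seen]
        return pred

    def pseudo_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        """1 - OOB MSE / Var(y) ("% variance explained" / 100)."""
        pred = self.oob_prediction(X)
        seen = ~np.isnan(pred)
        mse = float(np.mean((y[seen] - pred[seen]) ** 2))
        return 1.0 - mse / float(np.var(y))

    def oob_permutation_importance(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
        predictors: Sequence[int] | None = None,
    ) -> np.ndarray:
        """%IncMSE per requested predictor column.

        For each tree, the predictor's values are shuffled among that tree's
        OOB samples and the per-tree OOB MSE increase is recorded; the
        reported figure is 100 x (mean increase over trees) / (mean OOB MSE),
        i.e. the percentage by which scrambling the predictor inflates
        out-of-bag error.
        """
        X32 = self._as32(X)
        cols = list(range(X32.shape[1])) if predictors is None else list(predictors)
        inc = np.zeros(len(cols))
        base = 0.0
        for tree, oob in zip(self.trees, self.oob):
            if oob.size < 2:
                continue
            Xo = np.ascontiguousarray(X32[oob])
            yo = y[oob]
            err = float(np.mean((tree.predict(Xo, check_input=False) - yo) ** 2))
            base += err
            for ci, j in enumerate(cols):
                Xp = Xo.copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                err_p = float(np.mean((tree.predict(Xp, check_input=False) - yo) ** 2))
                inc[ci] += err_p - err
        base /= len(self.trees)
        inc /= len(self.trees)
        if base <= 0:
            return np.zeros(len(cols))
        return 100.0 * inc / base


@dataclass(frozen=True)
class ImportanceResult:
    pct_inc_mse: pd.Series  # per predictor, sorted descending
    pct_inc_mse_normalized: pd.Series  # rescaled to sum to 100 (contribution %)
    pseudo_r2: float
    variance_explained_pct: float
    oob_mse: float


def _prepare(table: pd.DataFrame, response: str, cfg: RFConfig):
    predictors = [c for c in table.columns if c != response]
    if table[predictors + [response]].isna().any().any():
        raise ValueError("missing values are not supported")
    if len(table) < 20:
        raise ValueError("need at least 20 records")
    cfg.validate(len(predictors))
    X = table[predictors].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    return X, y, predictors


def _fit(X, y, cfg: RFConfig, rng: np.random.Generator, ntree: int | None = None) -> BaggedForest:
    forest = BaggedForest(
        ntree=ntree or cfg.ntree,
        mtry=cfg.resolved_mtry(X.shape[1]),
        nodesize=cfg.nodesize,
    )
    return forest.fit(X, y, rng)


def fit_importance(
    table: pd.DataFrame, response: str, cfg: RFConfig = RFConfig()
) -> ImportanceResult:
    """Fit the forest and compute %IncMSE for every predictor.

    Deterministic given ``cfg.seed``.  The normalized importances (summing to
    100, negative values floored at 0 before rescaling) give per-trait
    "contribution percentages"; the raw %IncMSE column is the primary figure.
    """
    X, y, predictors = _prepare(table, response, cfg)
    rng = np.random.default_rng(cfg.seed)
    forest = _fit(X, y, cfg, rng)
    imp = forest.oob_permutation_importance(X, y, rng)
    pred = forest.oob_prediction(X)
    seen = ~np.isnan(pred)
    oob_mse = float(np.mean((y[seen] - pred[seen]) ** 2))
    r2 = 1.0 - oob_mse / float(np.var(y))
    series = pd.Series(imp, index=predictors).sort_values(ascending=False)
    clipped = series.clip(lower=0.0)
    norm = (
        clipped / clipped.sum() * 100.0
        if clipped.sum() > 0
        else pd.Series(0.0, index=series.index)
    )
    return ImportanceResult(
        pct_inc_mse=series,
        pct_inc_mse_normalized=norm,
        pseudo_r2=r2,
        variance_explained_pct=100.0 * r2,
        oob_mse=oob_mse,
    )


def model_significance(
    table: pd.DataFrame, response: str, cfg: RFConfig = RFConfig()
) -> tuple[float, float]:
    """Permutation test of the whole model: observed vs response-permuted R^2.

    p = (#{null pseudo-R^2 >= observed} + 1) / (n_perm_model + 1).  When
    ``cfg.null_ntree`` is set, the observed statistic is computed from a
    forest of the same reduced size as the null refits: OOB R^2 rises
    systematically with tree count, so mixing tree counts between the
    observed and null sides would bias the test.  The whole protocol is
    scaled down together, keeping the comparison exchangeable under the
    null.
    """
    X, y, _ = _prepare(table, response, cfg)
    rng = np.random.default_rng(cfg.seed)
    observed = _fit(X, y, cfg, rng, ntree=cfg.null_ntree).pseudo_r2(X, y)
    count = 0
    for _ in range(cfg.n_perm_model):
        y_perm = y[rng.permutation(y.size)]
        null_r2 = _fit(X, y_perm, cfg, rng, ntree=cfg.null_ntree).pseudo_r2(X, y_perm)
        count += null_r2 >= observed
    p = (count + 1) / (cfg.n_perm_model + 1)
    return observed, float(p)


def variable_significance(
    table: pd.DataFrame,
    response: str,
    cfg: RFConfig = RFConfig(),
    predictors: Sequence[str] | None = None,
) -> pd.Series:
    """Per-predictor permutation p-values for %IncMSE.

    For each predictor, its training values are permuted and the forest
    refitted ``cfg.n_perm_variable`` times (with ``null_ntree`` trees when
    set), building a null distribution of that predictor's %IncMSE;
    p = (#{null >= observed} + 1) / (n_perm + 1).
    """
    X, y, all_predictors = _prepare(table, response, cfg)
    targets = list(predictors) if predictors is not None else all_predictors
    missing = set(targets) - set(all_predictors)
    if missing:
        raise ValueError(f"unknown predictors: {sorted(missing)}")
    rng = np.random.default_rng(cfg.seed)
    forest = _fit(X, y, cfg, rng)
    cols = [all_predictors.index(t) for t in targets]
    observed = forest.oob_permutation_importance(X, y, rng, predictors=cols)
    pvals = {}
    for t, j, obs in zip(targets, cols, observed):
        count = 0
        for _ in range(cfg.n_perm_variable):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            null_forest = _fit(Xp, y, cfg, rng, ntree=cfg.null_ntree)
            null_imp = null_forest.oob_permutation_importance(
                Xp, y, rng, predictors=[j]
            )[0]
            count += null_imp >= obs
        pvals[t] = (count + 1) / (cfg.n_perm_variable + 1)
    return pd.Series(pvals, name="permutation_p")


def scaled_down(cfg: RFConfig = RFConfig(), n_perm: int = 199, ntree: int = 200,
                null_ntree: int = 25) -> RFConfig:
    """Desk-scale protocol: same estimator, fewer trees and permutations."""
    return replace(
        cfg,
        ntree=ntree,
        n_perm_model=n_perm,
        n_perm_variable=n_perm,
        null_ntree=null_ntree,
    )
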