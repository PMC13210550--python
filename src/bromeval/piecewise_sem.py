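"""Piecewise structural equation modeling.

A path model is a DAG over observed variables; instead of fitting one global
covariance structure, each endogenous variable is regressed (OLS) on its
parents, and overall fit is judged through the d-separation claims the DAG
implies: for every non-adjacent variable pair, the model claims conditional
independence given the union of both variables' parents.  Each claim is
tested by regressing the topologically later variable on the other plus the
conditioning set; under a correctly specified model the claim p-values are
uniform and Fisher's C = -2 * sum(ln p_i) follows a chi-square distribution
with 2k degrees of freedom (k = number of claims).  A non-significant C
(p > 0.05) means the data show no evidence of missing paths.

Standardized path coefficients beta = b * SD(parent) / SD(child) put all
paths on a common scale; indirect effects are products of the standardized
coefficients along each directed mediation path, and total effects are
direct + indirect.

Categorical exogenous variables (e.g. genotype, year as factors) enter the
component fits as dummy blocks; their edge and claim p-values are partial-F
tests of the whole block, and no single standardized beta is reported for
them (NaN).  An interaction treated as its own derived variable keeps a
single path coefficient, matching common reporting practice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathModel",
    "Claim",
    "SemFit",
    "basis_set",
    "fit",
    "fishers_c",
    "decompose_effects",
]

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class PathModel:
    """Directed acyclic path model over named observed variables.

    ``edges`` are (parent, child) pairs; ``categorical`` names variables to
    be dummy-coded in fits.  Exogenous variables are those with no parents.
    """

    edges: tuple[tuple[str, str], ...]
    categorical: frozenset[str] = field(default_factory=frozenset)
    extra_variables: tuple[str, ...] = ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.extra_variables))
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model contains a cycle")
        return g

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.graph().nodes)

    def endogenous(self) -> tuple[str, ...]:
        g = self.graph()
        return tuple(v for v in g.nodes if g.in_degree(v) > 0)

    @classmethod
    def from_spec(cls, text: str, categorical: Sequence[str] = ()) -> "PathModel":
        """Parse one ``child ~ parent + parent`` line per endogenous variable."""
        edges = []
        for line in text.strip().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            child, rhs = (part.strip() for part in line.split("~", 1))
            for parent in (p.strip() for p in rhs.split("+")):
                if parent:
                    edges.append((parent, child))
        return cls(edges=tuple(edges), categorical=frozenset(categorical))


@dataclass(frozen=True)
class Claim:
    """Conditional-independence claim implied by a missing edge.

    The claim is that ``x`` and ``y`` (non-adjacent in the DAG) are
    independent given ``conditioning`` (union of both variables' parents);
    ``response`` is the topologically later of the two (ties broken
    lexicographically) and is the regression response when testing.
    """

    x: str
    y: str
    conditioning: tuple[str, ...]
    response: str

    @property
    def predictor(self) -> str:
        return self.y if self.response == self.x else self.x


def basis_set(model: PathModel) -> list[Claim]:
    """The union-conditioning d-separation basis set of the DAG.

    One claim per non-adjacent unordered pair, conditioned on the union of
    both variables' parent sets; deterministic order (sorted by response,
    then predictor), independent of variable declaration order.
    """
    g = model.graph()
    order = list(nx.lexicographical_topological_sort(g))
    rank = {v: i for i, v in enumerate(order)}
    claims = []
    for u, v in itertools.combinations(sorted(g.nodes), 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        later = u if rank[u] > rank[v] else v
        cond = (set(g.predecessors(u)) | set(g.predecessors(v))) - {u, v}
        claims.append(
            Claim(x=u, y=v, conditioning=tuple(sorted(cond)), response=later)
        )
    return sorted(claims, key=lambda c: (c.response, c.predictor))


def fishers_c(claim_p: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C over the basis-set p-values.

    C = -2 * sum(ln p_i), df = 2k, fit p from the chi-square upper tail.
    An empty claim list (saturated model) is C = 0, df = 0, p = 1 with a
    warning; p_i that underflow to 0 are floored at 1e-300 with a warning.
    """
    ps = np.asarray(list(claim_p), dtype=float)
    if ps.size == 0:
        warnings.warn("saturated model: no independence claims to test", UserWarning)
        return 0.0, 0, 1.0
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("claim p-values must lie in [0, 1]")
    if (ps == 0).any():
        warnings.warn(
            "claim p-value underflowed to 0; flooring at 1e-300", UserWarning
        )
        ps = np.maximum(ps, _P_FLOOR)
    c = float(-2.0 * np.log(ps).sum()) + 0.0  # +0.0 normalizes -0.0
    df = 2 * ps.size
    return c, df, float(stats.chi2.sf(c, df))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _design(
    data: pd.DataFrame, predictors: Sequence[str], categorical: frozenset[str]
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Design matrix with intercept; returns column blocks per predictor."""
    columns = [np.ones(len(data))]
    blocks: dict[str, list[int]] = {}
    pos = 1
    for p in predictors:
        if p in categorical:
            dummies = pd.get_dummies(
                data[p].astype("category"), drop_first=True, dtype=float
            )
            for c in dummies.columns:
                columns.append(dummies[c].to_numpy())
            blocks[p] = list(range(pos, pos + dummies.shape[1]))
            pos += dummies.shape[1]
        else:
            columns.append(data[p].to_numpy(dtype=float))
            blocks[p] = [pos]
            pos += 1
    X = np.column_stack(columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design: collinear predictors among {list(predictors)}")
    return X, blocks


@dataclass(frozen=True)
class _OLS:
    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df_resid: int
    sse: float


def _ols(X: np.ndarray, y: np.ndarray) -> _OLS:
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough observations for the number of parameters")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    df = n - k
    sigma2 = sse / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf)
    p = 2 * stats.t.sf(np.abs(t), df)
    return _OLS(coef=coef, se=se, p=p, df_resid=df, sse=sse)


def _term_p(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    term: str,
    categorical: frozenset[str],
) -> tuple[float, float]:
    """(coefficient b, p) of ``term`` in response ~ predictors.

    Continuous terms use the coefficient t-test; categorical terms use the
    partial-F test of the whole dummy block (b reported as NaN).
    """
    y = data[response].to_numpy(dtype=float)
    X, blocks = _design(data, predictors, categorical)
    full = _ols(X, y)
    cols = blocks[term]
    if term not in categorical and len(cols) == 1:
        j = cols[0]
        return float(full.coef[j]), float(full.p[j])
    keep = [c for c in range(X.shape[1]) if c not in cols]
    reduced = _ols(X[:, keep], y)
    q = len(cols)
    f = ((reduced.sse - full.sse) / q) / (full.sse / full.df_resid)
    return float("nan"), float(stats.f.sf(f, q, full.df_resid))


@dataclass(frozen=True)
class SemFit:
    """Fitted piecewise SEM: component paths, claims and global fit."""

    model: PathModel
    paths: pd.DataFrame  # child, parent, b, beta, p
    claims: pd.DataFrame  # x, y, response, conditioning, p
    fishers_c: float
    df: int
    p_value: float

    def beta(self, parent: str, child: str) -> float:
        sel = self.paths[(self.paths["parent"] == parent) & (self.paths["child"] == child)]
        if sel.empty:
            raise KeyError(f"no edge {parent} -> {child}")
        return float(sel["beta"].iloc[0])


def fit(model: PathModel, data: pd.DataFrame) -> SemFit:
    """Fit every component regression and evaluate the d-separation claims.

    Each endogenous variable is regressed on its parents by OLS; edge-level
    standardized coefficients use sample SDs (``beta = b * sd(parent) /
    sd(child)``, NaN for categorical parents whose evidence is the block-F
    p).  Claim p-values come from the basis-set regressions on the same
    data, and Fisher's C summarizes them.
    """
    g = model.graph()
    missing = set(g.nodes) - set(data.columns)
    if missing:
        raise ValueError(f"data lacks model variables: {sorted(missing)}")
    sds = {
        v: float(data[v].std(ddof=1))
        for v in g.nodes
        if v not in model.categorical
    }
    rows = []
    for child in model.endogenous():
        parents = sorted(g.predecessors(child))
        for parent in parents:
            b, p = _term_p(data, child, parents, parent, model.categorical)
            if parent in model.categorical or np.isnan(b):
                beta = float("nan")
            else:
                beta = b * sds[parent] / sds[child]
            rows.append([child, parent, b, beta, p])
    paths = pd.DataFrame(rows, columns=["child", "parent", "b", "beta", "p"])

    claim_rows = []
    for claim in basis_set(model):
        predictors = sorted({claim.predictor, *claim.conditioning})
        _, p = _term_p(
            data, claim.response, predictors, claim.predictor, model.categorical
        )
        claim_rows.append(
            [claim.x, claim.y, claim.response, "+".join(claim.conditioning), p]
        )
    claims = pd.DataFrame(claim_rows, columns=["x", "y", "response", "conditioning", "p"])
    if len(claims):
        c, df, p_val = fishers_c(claims["p"].to_numpy())
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c, df, p_val = fishers_c([])
    return SemFit(model=model, paths=paths, claims=claims, fishers_c=c, df=df, p_value=p_val)


def decompose_effects(sem_fit: SemFit) -> pd.DataFrame:
    """Direct / indirect / total standardized effects for all connected pairs.

    Indirect effects sum the products of standardized coefficients over every
    directed path of length >= 2 from source to target; total = direct +
    indirect.  Pairs whose paths traverse a categorical (block-coded) edge
    have no single standardized product and propagate NaN.
    """
    g = sem_fit.model.graph()
    beta = {
        (r["parent"], r["child"]): r["beta"] for _, r in sem_fit.paths.iterrows()
    }
    rows = []
    for source in g.nodes:
        for target in g.nodes:
            if source == target or not nx.has_path(g, source, target):
                continue
            direct = beta.get((source, target), 0.0)
            indirect = 0.0
            for path in nx.all_simple_paths(g, source, target):
                if len(path) < 3:
                    continue
                prod = 1.0
                for u, v in zip(path[:-1], path[1:]):
                    prod *= beta[(u, v)]
                indirect += prod
            rows.append([source, target, direct, indirect, direct + indirect])
    return pd.DataFrame(
        rows, columns=["source", "target", "direct", "indirect", "total"]
    )
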