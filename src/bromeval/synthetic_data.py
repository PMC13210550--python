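"""Synthetic multi-year trial and linear-Gaussian path-model generators.

The trial generator emulates a balanced cultivar trial — 5 genotypes x 3
years x 4 blocks by default — with additive genotype, year and block effects,
a genotype x year interaction, and Gaussian residual noise, over the 15
agronomic / yield / nutritional indicators used throughout the package.
Because every effect is planted, downstream estimators (ANOVA, clustering,
TOPSIS, random forest, SEM) can be validated against known ground truth
without any external data.

The SEM generator draws from an arbitrary linear-Gaussian DAG with
standardized path coefficients; residual variances are chosen (or checked)
so every variable has unit variance in expectation, which makes fitted
standardized coefficients directly comparable to the planted ones.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "COST_INDICATORS",
    "TraitSchema",
    "EffectSpec",
    "SemGroundTruth",
    "default_schema",
    "default_trial_spec",
    "effect_spec_from_mapping",
    "sem_truth_from_mapping",
    "yield_pathway_truth",
    "generate_trial",
    "generate_sem_dataset",
    "generate_decision_fixture",
]

#: The 15 evaluation indicators, in conventional reporting order.
INDICATORS: tuple[str, ...] = (
    "plant_height",
    "stem_diameter",
    "leaf_length",
    "leaf_width",
    "grass_height",
    "tiller_number",
    "dry_fresh_ratio",
    "hay_yield",
    "fresh_forage_yield",
    "ash",
    "cp",
    "adf",
    "ndf",
    "cf",
    "rfv",
)

#: Cost-type indicators (lower is better); all others are benefit-type.
COST_INDICATORS: frozenset[str] = frozenset({"adf", "ndf", "ash"})

_UNITS: dict[str, str] = {
    "plant_height": "cm",
    "stem_diameter": "mm",
    "leaf_length": "cm",
    "leaf_width": "cm",
    "grass_height": "cm",
    "tiller_number": "count",
    "dry_fresh_ratio": "ratio",
    "hay_yield": "kg/hm2",
    "fresh_forage_yield": "kg/hm2",
    "ash": "% DM",
    "cp": "% DM",
    "adf": "% DM",
    "ndf": "% DM",
    "cf": "% DM",
    "rfv": "index",
}


class InvalidSpecError(ValueError):
    """Raised when a generator specification violates its invariants."""


@dataclass(frozen=True)
class TraitSchema:
    """Ordered indicator set with per-indicator optimization direction.

    Parameters
    ----------
    indicators : ordered indicator names (unique).
    directions : map indicator -> ``"benefit"`` or ``"cost"``.
    units : map indicator -> unit string (informational).
    """

    indicators: tuple[str, ...]
    directions: Mapping[str, str]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.indicators)) != len(self.indicators):
            raise InvalidSpecError("indicator names must be unique")
        for ind in self.indicators:
            if self.directions.get(ind) not in ("benefit", "cost"):
                raise InvalidSpecError(
                    f"indicator {ind!r} needs a direction 'benefit' or 'cost'"
                )

    @property
    def benefit(self) -> tuple[str, ...]:
        return tuple(i for i in self.indicators if self.directions[i] == "benefit")

    @property
    def cost(self) -> tuple[str, ...]:
        return tuple(i for i in self.indicators if self.directions[i] == "cost")


def default_schema() -> TraitSchema:
    """The standard 15-indicator schema (ADF, NDF and ash are cost-type)."""
    directions = {
        ind: ("cost" if ind in COST_INDICATORS else "benefit") for ind in INDICATORS
    }
    return TraitSchema(indicators=INDICATORS, directions=directions, units=dict(_UNITS))


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effects for a balanced factorial trial.

    All effect maps are additive shifts on the indicator scale:
    ``E[value] = baseline + genotype + year + interaction``.  ``block_sd``
    is expressed in units of the indicator's residual SD (block effects are
    drawn once per block and indicator as ``N(0, block_sd * residual_sd)``),
    which keeps a single scalar meaningful across indicators measured in
    centimetres, ratios and thousands of kilograms alike.
    """

    baseline: Mapping[str, float]
    genotype_effects: Mapping[str, Mapping[str, float]]
    year_effects: Mapping[str, Mapping[str, float]]
    interaction_effects: Mapping[tuple[str, str], Mapping[str, float]]
    residual_sd: Mapping[str, float]
    block_sd: float = 0.5
    n_blocks: int = 4

    @property
    def genotypes(self) -> tuple[str, ...]:
        return tuple(self.genotype_effects)

    @property
    def years(self) -> tuple[str, ...]:
        return tuple(self.year_effects)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.baseline)

    def validate(self) -> None:
        if not self.genotype_effects or not self.year_effects:
            raise InvalidSpecError("genotype and year effect maps must be non-empty")
        if self.block_sd < 0:
            raise InvalidSpecError("block_sd must be nonnegative")
        if self.n_blocks < 1:
            raise InvalidSpecError("n_blocks must be >= 1")
        for ind, sd in self.residual_sd.items():
            if sd < 0:
                raise InvalidSpecError(f"residual_sd[{ind!r}] must be nonnegative")
        missing = set(self.baseline) - set(self.residual_sd)
        if missing:
            raise InvalidSpecError(f"residual_sd missing for indicators: {sorted(missing)}")
        grid = set(itertools.product(self.genotypes, self.years))
        if self.interaction_effects and set(self.interaction_effects) - grid:
            raise InvalidSpecError("interaction effects outside the factorial grid")


def _zero_effects(keys: Sequence, indicators: Sequence[str]) -> dict:
    return {k: {i: 0.0 for i in indicators} for k in keys}


def default_trial_spec(
    genotypes: Sequence[str] = ("WUSU", "1-10", "2-10", "3-12", "4-4"),
    years: Sequence[str] = ("year2", "year3", "year4"),
    n_blocks: int = 4,
) -> EffectSpec:
    """A realistic 5 x 3 x 4 trial with planted genotype, year and G x Y effects.

    Baselines and effect magnitudes are set to the orders of magnitude typical
    of perennial cool-season forage trials: plant heights around 100 cm, hay
    yields in the tens of thousands of kg/hm2, fiber fractions of 30-55 % DM.
    Genotype "4-4" is planted as the strong performer (taller, thicker stems,
    higher yield, more protein, less ADF) and the control "WUSU" as the weak
    one; year effects peak in the middle (third production) year.
    """
    baseline = {
        "plant_height": 100.0,
        "stem_diameter": 3.5,
        "leaf_length": 14.0,
        "leaf_width": 0.8,
        "grass_height": 48.0,
        "tiller_number": 170.0,
        "dry_fresh_ratio": 0.35,
        "hay_yield": 15000.0,
        "fresh_forage_yield": 45000.0,
        "ash": 8.0,
        "cp": 4.8,
        "adf": 45.0,
        "ndf": 37.0,
        "cf": 4.8,
        "rfv": 120.0,
    }
    residual_sd = {
        "plant_height": 5.0,
        "stem_diameter": 0.25,
        "leaf_length": 1.2,
        "leaf_width": 0.06,
        "grass_height": 3.0,
        "tiller_number": 15.0,
        "dry_fresh_ratio": 0.02,
        "hay_yield": 1200.0,
        "fresh_forage_yield": 3500.0,
        "ash": 0.4,
        "cp": 0.25,
        "adf": 2.0,
        "ndf": 1.8,
        "cf": 0.3,
        "rfv": 6.0,
    }
    # Genotype effects as multiples of the residual SD: planted contrasts a
    # trial of this size can detect, with "4-4" dominant and "WUSU" weakest.
    per_genotype_scale = {"WUSU": -1.5, "1-10": -0.8, "2-10": 0.0, "3-12": 0.8, "4-4": 1.8}
    genotype_effects = {
        g: {
            ind: scale * residual_sd[ind] * (-1.0 if ind in COST_INDICATORS else 1.0)
            for ind in baseline
        }
        for g, scale in per_genotype_scale.items()
    }
    per_year_scale = {"year2": -0.8, "year3": 1.2, "year4": -0.4}
    year_effects = {
        y: {ind: scale * residual_sd[ind] for ind in baseline}
        for y, scale in per_year_scale.items()
    }
    # G x Y wobble: the best genotype gains extra in the peak year and gives
    # some back afterwards, while "2-10" swings strongly between years.
    wobble = {
        ("4-4", "year3"): 2.0,
        ("4-4", "year4"): -1.5,
        ("2-10", "year2"): -2.0,
        ("2-10", "year3"): 1.8,
        ("WUSU", "year3"): -1.5,
    }
    interaction_effects = {
        (g, y): {
            ind: wobble.get((g, y), 0.0) * residual_sd[ind] for ind in baseline
        }
        for g in genotype_effects
        for y in year_effects
    }
    return EffectSpec(
        baseline=baseline,
        genotype_effects=genotype_effects,
        year_effects=year_effects,
        interaction_effects=interaction_effects,
        residual_sd=residual_sd,
        block_sd=0.5,
        n_blocks=n_blocks,
    )


def effect_spec_from_mapping(raw: Mapping) -> EffectSpec:
    """Build an :class:`EffectSpec` from a plain (YAML-loadable) mapping.

    Interaction keys are ``"genotype|year"`` strings, e.g.
    ``interaction_effects: {"4-4|year3": {hay_yield: 2400}}``.
    """
    interactions = {}
    for key, effects in (raw.get("interaction_effects") or {}).items():
        g, _, y = key.partition("|")
        if not y:
            raise InvalidSpecError(
                f"interaction key {key!r} must look like 'genotype|year'"
            )
        interactions[(g, y)] = dict(effects)
    return EffectSpec(
        baseline=dict(raw["baseline"]),
        genotype_effects={g: dict(e) for g, e in raw["genotype_effects"].items()},
        year_effects={y: dict(e) for y, e in raw["year_effects"].items()},
        interaction_effects=interactions,
        residual_sd=dict(raw["residual_sd"]),
        block_sd=float(raw.get("block_sd", 0.5)),
        n_blocks=int(raw.get("n_blocks", 4)),
    )


def sem_truth_from_mapping(raw: Mapping) -> SemGroundTruth:
    """Build a :class:`SemGroundTruth` from a plain mapping.

    Coefficient keys are ``"parent->child"`` strings, e.g.
    ``coefficients: {"gxy->stem_diameter": -0.52}``.
    """
    coefficients = {}
    for key, value in raw["coefficients"].items():
        parent, sep, child = key.partition("->")
        if not sep:
            raise InvalidSpecError(f"coefficient key {key!r} must look like 'parent->child'")
        coefficients[(parent.strip(), child.strip())] = float(value)
    return SemGroundTruth(
        coefficients=coefficients,
        residual_sd={k: float(v) for k, v in (raw.get("residual_sd") or {}).items()},
        extra_exogenous=tuple(raw.get("extra_exogenous") or ()),
    )


def generate_trial(spec: EffectSpec, seed: int) -> pd.DataFrame:
    """Generate a balanced plot-level trial table from planted effects.

    Draw order (fixed for reproducibility across versions): first the block
    effects, block-major then indicator-major; then the residuals in
    (genotype, year, block) row order, indicator-major within row.

    Returns a long-format frame with columns
    ``genotype, year, block, <indicator...>``; raises
    :class:`InvalidSpecError` if the spec is invalid and ``ValueError`` if
    any generated indicator value is non-positive (choose baselines well
    above the noise scale instead of relying on truncation).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    indicators = list(spec.indicators)
    genotypes, years = spec.genotypes, spec.years
    blocks = [f"B{b + 1}" for b in range(spec.n_blocks)]
    sd = np.array([spec.residual_sd[i] for i in indicators])

    block_eff = rng.normal(0.0, 1.0, size=(spec.n_blocks, len(indicators)))
    block_eff *= spec.block_sd * sd

    rows = []
    for g, y, b in itertools.product(genotypes, years, range(spec.n_blocks)):
        mean = np.array(
            [
                spec.baseline[i]
                + spec.genotype_effects[g].get(i, 0.0)
                + spec.year_effects[y].get(i, 0.0)
                + spec.interaction_effects.get((g, y), {}).get(i, 0.0)
                for i in indicators
            ]
        )
        value = mean + block_eff[b] + rng.normal(0.0, 1.0, size=len(indicators)) * sd
        rows.append([g, y, blocks[b], *value])

    table = pd.DataFrame(rows, columns=["genotype", "year", "block", *indicators])
    bad = (table[indicators] <= 0).any()
    if bad.any():
        raise ValueError(
            "generated non-positive values for indicators "
            f"{list(bad[bad].index)}; raise baselines or lower SDs"
        )
    return table


@dataclass(frozen=True)
class SemGroundTruth:
    """A linear-Gaussian DAG with standardized path coefficients.

    ``coefficients`` maps ``(parent, child)`` edges to standardized path
    coefficients; every variable is constructed to have unit variance, so
    ``residual_sd`` may be omitted per endogenous variable, in which case it
    is solved from the implied covariance (``1 - var_explained``).
    """

    coefficients: Mapping[tuple[str, str], float]
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    extra_exogenous: tuple[str, ...] = ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.extra_exogenous)
        g.add_edges_from(self.coefficients)
        return g

    def validate(self) -> nx.DiGraph:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise InvalidSpecError("path model must be acyclic")
        non_edges = set(self.residual_sd) - set(g.nodes)
        if non_edges:
            raise InvalidSpecError(f"residual_sd given for unknown variables {non_edges}")
        return g


#: Reference standardized coefficients of the genotype-by-year-mediated
#: yield-formation pathway: the interaction suppresses stem diameter and
#: raises ADF; plant height, stem diameter and (negatively) ADF drive hay
#: yield; plant height also drives total (cumulative) hay yield.
YIELD_PATHWAY_COEFFS: dict[tuple[str, str], float] = {
    ("gxy", "stem_diameter"): -0.52,
    ("gxy", "adf"): 0.70,
    ("genotype", "plant_height"): -0.24,
    ("plant_height", "hay_yield"): 0.54,
    ("stem_diameter", "hay_yield"): 0.29,
    ("adf", "hay_yield"): -0.29,
    ("plant_height", "total_hay_yield"): 0.79,
}


def yield_pathway_truth() -> SemGroundTruth:
    """Ground truth for the reference yield-formation path model."""
    return SemGroundTruth(coefficients=dict(YIELD_PATHWAY_COEFFS))


def implied_covariance(truth: SemGroundTruth) -> pd.DataFrame:
    """Model-implied covariance of all variables under unit-variance scaling."""
    g = truth.validate()
    order = list(nx.topological_sort(g))
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    sigma = np.zeros((n, n))
    for v in order:
        i = idx[v]
        parents = list(g.predecessors(v))
        if not parents:
            sigma[i, i] = 1.0
            continue
        beta = np.array([truth.coefficients[(p, v)] for p in parents])
        pidx = [idx[p] for p in parents]
        # cov(v, u) for previously placed u; then var(v) forced to 1.
        sigma[i, :] = beta @ sigma[np.ix_(pidx, range(n))]
        sigma[:, i] = sigma[i, :]
        explained = float(beta @ sigma[np.ix_(pidx, pidx)] @ beta)
        if v in truth.residual_sd:
            sigma[i, i] = explained + truth.residual_sd[v] ** 2
        else:
            if explained > 1.0 + 1e-12:
                raise InvalidSpecError(
                    f"variance explained for {v!r} exceeds 1; coefficients too large "
                    "for unit-variance construction"
                )
            sigma[i, i] = 1.0
    return pd.DataFrame(sigma, index=order, columns=order)


def generate_sem_dataset(truth: SemGroundTruth, n: int, seed: int) -> pd.DataFrame:
    """Simulate ``n`` draws from a linear-Gaussian path model.

    Exogenous variables are standard normal; each endogenous variable is the
    coefficient-weighted sum of its parents plus a Gaussian residual whose SD
    is taken from ``truth.residual_sd`` or, if absent, solved so the variable
    has unit variance in expectation.  Variables are generated in topological
    order; same (truth, n, seed) gives bit-identical output.
    """
    g = truth.validate()
    sigma = implied_covariance(truth)
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for v in nx.topological_sort(g):
        parents = list(g.predecessors(v))
        if not parents:
            data[v] = rng.normal(size=n)
            continue
        beta = np.array([truth.coefficients[(p, v)] for p in parents])
        explained = float(
            beta @ sigma.loc[parents, parents].to_numpy() @ beta
        )
        if v in truth.residual_sd:
            res_sd = truth.residual_sd[v]
        else:
            res_sd = float(np.sqrt(max(1.0 - explained, 0.0)))
        mean = np.column_stack([data[p] for p in parents]) @ beta
        data[v] = mean + rng.normal(size=n) * res_sd
    order = list(nx.topological_sort(g))
    return pd.DataFrame({v: data[v] for v in order})


def generate_decision_fixture(
    n_alternatives: int,
    schema: TraitSchema | None = None,
    dominant: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random strictly positive decision matrix (alternatives x indicators).

    When ``dominant`` names a row, that row is made strictly best on every
    benefit column and strictly lowest on every cost column, giving a known
    rank-1 alternative for end-to-end ranking tests.
    """
    if n_alternatives < 2:
        raise ValueError("need at least 2 alternatives")
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)
    names = [f"G{i + 1}" for i in range(n_alternatives)]
    if dominant is not None and dominant not in names:
        names[0] = dominant
    # Positive values on heterogeneous scales: per-indicator lognormal level.
    levels = np.exp(rng.uniform(0.0, 5.0, size=len(schema.indicators)))
    values = levels * rng.uniform(0.5, 1.5, size=(n_alternatives, len(schema.indicators)))
    df = pd.DataFrame(values, index=names, columns=list(schema.indicators))
    if dominant is not None:
        for ind in schema.indicators:
            others = df.loc[df.index != dominant, ind]
            if schema.directions[ind] == "benefit":
                df.loc[dominant, ind] = others.max() * 1.25
            else:
                df.loc[dominant, ind] = others.min() * 0.75
    return df
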