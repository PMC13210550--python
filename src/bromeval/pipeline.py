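"""End-to-end trial evaluation pipeline.

Runs the full analysis on a long-format trial table: assumption screening,
per-year one-way ANOVA with protected LSD, pooled two-way factorial ANOVA,
genotype clustering with k selection, entropy-TOPSIS ranking, random-forest
importance and (optionally) a piecewise SEM.  Every stage writes a CSV
artifact under the output directory and the run report records seeds,
warnings and stage status, so a rerun with the same config reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import bromeval
from bromeval import (
    association_clustering as ac,
    entropy_topsis as et,
    piecewise_sem as psem,
    rf_importance as rf,
    trait_stats as ts,
)
from bromeval.synthetic_data import TraitSchema, default_schema

__all__ = ["PipelineConfig", "RunReport", "validate_input", "run"]

KEY_COLUMNS = ("genotype", "year", "block")


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str
    output_dir: str
    response: str = "hay_yield"
    schema: TraitSchema = field(default_factory=default_schema)
    seed: int = 0
    k_min: int = 2
    k_max: int | None = None  # default: n_genotypes - 1
    topsis_rescale: bool = False
    rf_ntree: int = 200
    rf_n_perm: int = 199
    rf_null_ntree: int = 25
    assumption_n_sim: int = 2000
    sem_spec: str | None = None  # "child ~ parent + parent" lines
    sem_categorical: tuple[str, ...] = ()


@dataclass
class RunReport:
    config: PipelineConfig
    stages: dict = field(default_factory=dict)  # name -> "ok" | "skipped: reason"
    warnings: list = field(default_factory=list)
    artifacts: dict = field(default_factory=dict)
    topsis_ranks: pd.Series | None = None
    cluster_assignments: pd.Series | None = None
    sem_fit: psem.SemFit | None = None

    def to_json(self) -> str:
        payload = {
            "package_version": bromeval.__version__,
            "seed": self.config.seed,
            "input": self.config.input_path,
            "response": self.config.response,
            "stages": self.stages,
            "warnings": self.warnings,
            # file names only: the report must be reproducible byte-for-byte
            # regardless of where the output directory lives
            "artifacts": {k: Path(v).name for k, v in self.artifacts.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def validate_input(path: str | Path, schema: TraitSchema | None = None) -> pd.DataFrame:
    """Read and validate a long-format trial CSV.

    Requires columns ``genotype, year, block`` plus every schema indicator;
    indicator cells must parse as numbers (a stray thousands separator makes
    the column non-numeric and is reported, not coerced); duplicate
    (genotype, year, block) rows are rejected.
    """
    schema = schema or default_schema()
    path = Path(path)
    table = pd.read_csv(path, dtype={k: str for k in KEY_COLUMNS})
    missing = [c for c in (*KEY_COLUMNS, *schema.indicators) if c not in table.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    for col in schema.indicators:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any() or table[col].isna().any():
            row = int(np.flatnonzero(bad | table[col].isna())[0])
            raise ValueError(
                f"{path.name}: non-numeric or missing value in column {col!r} "
                f"at data row {row}"
            )
        table[col] = converted
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        keys = table.loc[dup, list(KEY_COLUMNS)].to_records(index=False).tolist()
        raise ValueError(f"duplicate (genotype, year, block) rows: {keys}")
    return table


def run(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; a stage failure aborts with its name."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)
    indicators = list(config.schema.indicators)

    def save(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        dest = out / f"{name}.csv"
        frame.to_csv(dest, index=index)
        report.artifacts[name] = dest

    def stage(name):
        def wrap(fn):
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    fn()
                for w in caught:
                    report.warnings.append(f"{name}: {w.message}")
                report.stages[name] = "ok"
            except Exception as exc:
                report.stages[name] = f"failed: {exc}"
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    table = validate_input(config.input_path, config.schema)
    report.stages["validate"] = "ok"

    @stage("assumptions")
    def _():
        frames = []
        for ind in indicators:
            rep = ts.screen_assumptions(table, ind, n_sim=config.assumption_n_sim)
            rep.insert(0, "indicator", ind)
            frames.append(rep)
        save("assumption_report", pd.concat(frames, ignore_index=True))

    @stage("anova")
    def _():
        two = []
        for ind in indicators:
            aov = ts.twoway_anova(table, ind).reset_index()
            aov.insert(0, "indicator", ind)
            two.append(aov)
        save("anova_twoway", pd.concat(two, ignore_index=True))
        ones, lsd_rows = [], []
        for year, sub in table.groupby("year", observed=True, sort=True):
            for ind in indicators:
                aov = ts.oneway_anova(sub, ind, "genotype")
                ones.append([year, ind, aov.f, aov.p])
                if aov.p < 0.05:
                    res = ts.lsd_pairwise(sub, ind, "genotype")
                    for g, letter in res.letters.items():
                        lsd_rows.append([year, ind, g, res.lsd, letter])
        save(
            "anova_oneway_by_year",
            pd.DataFrame(ones, columns=["year", "indicator", "F", "p"]),
        )
        save(
            "lsd_letters",
            pd.DataFrame(lsd_rows, columns=["year", "indicator", "genotype", "lsd", "letters"]),
        )

    profiles = ac.genotype_profiles(table, indicators)

    @stage("clustering")
    def _():
        z = ac.zscore(profiles)
        k_max = config.k_max or (len(profiles) - 1)
        k_best, wss, sil = ac.select_k(
            z, range(config.k_min, k_max + 1), seed=config.seed
        )
        result = ac.kmeans_fit(z, k_best, seed=config.seed)
        report.cluster_assignments = result.assignments
        save("cluster_assignments", result.assignments.reset_index())
        save(
            "cluster_selection",
            pd.DataFrame({"k": wss.index, "wss": wss.values, "silhouette": sil.values}),
        )
        scores, frac = ac.pca_project(z, n_components=min(2, len(profiles) - 1))
        scores["explained_fraction"] = list(frac) + [np.nan] * (len(scores) - len(frac))
        save("pca_scores", scores, index=True)

    @stage("topsis")
    def _():
        values = (
            et.rescale_to_positive(profiles) if config.topsis_rescale else profiles
        )
        dm = et.DecisionMatrix.from_schema(values, config.schema)
        result = et.topsis_rank(dm)
        report.topsis_ranks = result.ranks
        save(
            "topsis_result",
            pd.DataFrame(
                {
                    "d_plus": result.d_plus,
                    "d_minus": result.d_minus,
                    "closeness": result.closeness,
                    "rank": result.ranks,
                }
            ),
            index=True,
        )
        save(
            "topsis_weights",
            pd.DataFrame(
                {"entropy": result.weights.e, "dispersion": result.weights.d, "weight": result.weights.w}
            ),
            index=True,
        )

    @stage("importance")
    def _():
        cfg = rf.RFConfig(
            ntree=config.rf_ntree,
            seed=config.seed,
            n_perm_model=config.rf_n_perm,
            n_perm_variable=config.rf_n_perm,
            null_ntree=config.rf_null_ntree,
        )
        data = table[indicators]
        imp = rf.fit_importance(data, config.response, cfg)
        r2, p = rf.model_significance(data, config.response, cfg)
        frame = pd.DataFrame(
            {
                "pct_inc_mse": imp.pct_inc_mse,
                "contribution_pct": imp.pct_inc_mse_normalized,
            }
        )
        frame.attrs["pseudo_r2"] = r2
        save("rf_importance", frame, index=True)
        save(
            "rf_model_fit",
            pd.DataFrame(
                [[imp.pseudo_r2, imp.variance_explained_pct, p]],
                columns=["pseudo_r2", "variance_explained_pct", "model_p"],
            ),
        )

    if config.sem_spec:

        @stage("sem")
        def _():
            model = psem.PathModel.from_spec(
                config.sem_spec, categorical=config.sem_categorical
            )
            sem_fit = psem.fit(model, table)
            report.sem_fit = sem_fit
            save("sem_paths", sem_fit.paths)
            save("sem_claims", sem_fit.claims)
            save(
                "sem_fit",
                pd.DataFrame(
                    [[sem_fit.fishers_c, sem_fit.df, sem_fit.p_value]],
                    columns=["fishers_c", "df", "p"],
                ),
            )
            save("sem_effects", psem.decompose_effects(sem_fit))
    else:
        report.stages["sem"] = "skipped: no sem_spec in config"

    (out / "report.json").write_text(report.to_json())
    report.artifacts["report"] = out / "report.json"
    return report
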