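"""End-to-end pipeline orchestration.

One config object (YAML round-trippable) drives the full sequence:
design → simulate (or ingest real responses) → fit candidate models →
select finals → in-silico search → consensus clustering → cluster-medium
selection → baselines → confirmation on fresh test donors.  A single
master seed deterministically derives one named seed per stage, so a rerun
with the same config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines as bl
from . import clustering as cl
from . import design as dd
from . import models as mz
from . import search as sr
from . import simulate as sim
from .simulate import EXPANSION, VIABILITY

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RunManifest",
    "stage_seeds",
    "run_pipeline",
    "ingest_responses",
]

_STAGES = (
    "design", "population", "train_donors", "simulate", "fit",
    "search", "cluster", "baseline", "test_donors", "confirm",
)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; every random stage consumes a seed
    derived from ``seed``."""

    k: int = 12
    n_donors: int = 4
    n_test_donors: int = 4
    replicates: int = 3
    seed: int = 0
    scenario_type: str = "default"          # default | planted
    planted_optimum: list[float] | None = None
    planted_quad_strength: float = 3.0
    planted_donor_sd_scale: float = 1.0
    # modeling
    equations: list[str] = field(default_factory=lambda: list(mz.EQUATIONS))
    algorithms: list[str] = field(default_factory=lambda: list(mz.ALGORITHMS))
    folds: int = 10
    l1_grid: list[float] = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    n_lambda: int = 50
    rf_mtry_grid: list[float] = field(default_factory=lambda: [1 / 3, 1 / 2, 2 / 3, 1.0])
    rf_trees: int = 500
    # in-silico search
    n_formulations: int = 100_000
    n_top: int = 40
    constraints: list[str] = field(default_factory=lambda: ["c02=0"])
    # clustering
    k_clusters: int = 6
    n_restarts: int = 25
    hopkins_fraction: float = 0.1
    elbow_kmax: int = 10
    # selection / baselines
    n_select: int = 2
    n_baseline: int = 6
    baseline_separation: float = 0.5
    baseline_equation: str = "eq1"

    def scenario(self) -> sim.Scenario:
        if self.scenario_type == "planted":
            if self.planted_optimum is None:
                raise ValueError("planted scenario requires planted_optimum")
            return sim.planted_optimum_scenario(
                np.asarray(self.planted_optimum, dtype=float),
                k=self.k,
                quad_strength=self.planted_quad_strength,
                donor_sd_scale=self.planted_donor_sd_scale,
            )
        if self.scenario_type != "default":
            raise ValueError(f"unknown scenario_type {self.scenario_type!r}")
        return sim.default_scenario(self.k)

    def modeling(self, seed: int) -> mz.ModelingConfig:
        return mz.ModelingConfig(
            equations=tuple(self.equations),
            algorithms=tuple(self.algorithms),
            folds=self.folds,
            l1_grid=tuple(self.l1_grid),
            n_lambda=self.n_lambda,
            rf_mtry_grid=tuple(self.rf_mtry_grid),
            rf_trees=self.rf_trees,
            seed=seed,
        )

    def parsed_constraints(self) -> list[sr.Constraint]:
        return [sr.parse_constraint(c) for c in self.constraints]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def stage_seeds(master: int) -> dict[str, int]:
    """Named per-stage seeds derived deterministically from one master seed."""
    state = np.random.SeedSequence(master).generate_state(len(_STAGES)) % (2**31)
    return {stage: int(s) for stage, s in zip(_STAGES, state)}


@dataclass
class RunManifest:
    seed: int
    stage_seeds: dict[str, int]
    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> sha256
    diagnostics: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


@dataclass
class PipelineResult:
    config: PipelineConfig
    design: pd.DataFrame
    responses: pd.DataFrame
    candidates: list
    finals: dict
    pool: pd.DataFrame
    hopkins: float
    elbow: pd.DataFrame
    solution: cl.ClusterSolution
    composition: pd.DataFrame
    cluster_media: pd.DataFrame
    back_eval: pd.DataFrame
    selection: cl.SelectionResult
    pooled_model: mz.FittedModel
    baseline_media: pd.DataFrame
    naive_formulation: pd.Series
    naive_back_eval: pd.DataFrame
    confirmation_design: pd.DataFrame
    test_responses: pd.DataFrame
    evaluation: pd.DataFrame
    manifest: RunManifest


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, out_dir: Path, name: str, manifest: RunManifest) -> None:
    path = out_dir / name
    df.to_csv(path, index=False, float_format="%.10g")
    manifest.artifacts[name] = _hash_file(path)


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute every pipeline stage and (optionally) persist all artifacts."""
    seeds = stage_seeds(config.seed)
    scenario = config.scenario()
    manifest = RunManifest(seed=config.seed, stage_seeds=seeds, config=asdict(config))

    # --- design -----------------------------------------------------------
    dsd = dd.generate_dsd(config.k, seed=seeds["design"])
    donor_ids = [f"d{i + 1:02d}" for i in range(config.n_donors)]
    design = dd.assemble_study(dsd, donor_ids, seed=seeds["design"])

    # --- simulate ---------------------------------------------------------
    population = sim.sample_population(scenario, seeds["population"])
    train_profiles = sim.sample_donor_profiles(
        config.n_donors, scenario, seeds["train_donors"],
        population=population, donor_ids=donor_ids,
    )
    responses = sim.simulate_study(
        train_profiles, design, scenario, config.replicates, seeds["simulate"]
    )

    # --- fit & select -----------------------------------------------------
    candidates = mz.fit_candidates(design, responses, config.modeling(seeds["fit"]))
    finals = mz.rank_and_select(candidates)

    # --- in-silico search -------------------------------------------------
    factor_ids = dd.factor_columns(dsd)
    constraints = config.parsed_constraints()
    formulations = sr.sample_formulations(
        config.n_formulations, factor_ids, constraints, seeds["search"]
    )
    pool = sr.top_n_pool(finals, formulations, config.n_top)

    # --- consensus clustering --------------------------------------------
    factor_cols = sr.pool_factor_columns(pool)
    X_pool = pool[factor_cols].to_numpy(dtype=float)
    Xs, _ = cl.scale_points(X_pool)
    hop = cl.hopkins_statistic(Xs, config.hopkins_fraction, seeds["cluster"])
    elbow = cl.elbow_curve(
        X_pool, range(1, config.elbow_kmax + 1), config.n_restarts, seeds["cluster"]
    )
    solution = cl.kmeans_cluster(
        X_pool, config.k_clusters, config.n_restarts, seed=seeds["cluster"]
    )
    solution.hopkins = hop
    composition = cl.cluster_composition(pool, solution)
    cluster_media = cl.cluster_median_formulations(pool, solution)
    back_eval = cl.back_evaluate(cluster_media, finals)
    selection = cl.select_cluster_media(
        composition, back_eval, config.n_select, all_donors=tuple(donor_ids)
    )

    # --- baselines (pooled arm needs at least two donor blocks) -----------
    if config.n_donors >= 2:
        pooled = bl.fit_pooled_ols(
            design, responses, EXPANSION, config.baseline_equation,
            config.folds, seeds["baseline"],
        )
        baseline_media = bl.select_baseline_media(
            pooled, formulations, config.n_baseline, config.baseline_separation
        )
    else:
        pooled = None
        baseline_media = pd.DataFrame(
            columns=["formulation_id", *factor_ids, "predicted"]
        )
    naive = bl.naive_ensemble(pool, EXPANSION)
    naive_df = pd.DataFrame([{"cluster": 0, **naive.to_dict()}])
    naive_back_eval = cl.back_evaluate(naive_df, finals)

    # --- confirmation on fresh test donors --------------------------------
    selected_media = cluster_media[
        cluster_media["cluster"].isin(selection.selected_clusters)
    ].reset_index(drop=True)
    test_ids = [f"t{i + 1:02d}" for i in range(config.n_test_donors)]
    test_profiles = sim.sample_donor_profiles(
        config.n_test_donors, scenario, seeds["test_donors"],
        population=population, donor_ids=test_ids,
    )
    confirmation = bl.assemble_confirmation_design(
        selected_media, baseline_media, test_ids
    )
    test_responses = sim.simulate_study(
        test_profiles, confirmation, scenario, config.replicates, seeds["confirm"]
    )

    predictions = _prediction_table(
        selected_media, baseline_media, finals, pooled, back_eval
    )
    evaluation = bl.evaluate_on_test_set(predictions, test_responses)

    manifest.diagnostics = {
        "hopkins": hop,
        "avg_silhouette": solution.avg_silhouette,
        "n_candidate_models": float(len(candidates)),
        "n_final_models": float(len(finals)),
        "pool_size": float(len(pool)),
        "pooled_train_r2": pooled.train_r2 if pooled else float("nan"),
        "pooled_train_rmse": pooled.train_rmse if pooled else float("nan"),
    }

    result = PipelineResult(
        config=config, design=design, responses=responses,
        candidates=candidates, finals=finals, pool=pool,
        hopkins=hop, elbow=elbow, solution=solution,
        composition=composition, cluster_media=cluster_media,
        back_eval=back_eval, selection=selection,
        pooled_model=pooled, baseline_media=baseline_media,
        naive_formulation=naive, naive_back_eval=naive_back_eval,
        confirmation_design=confirmation, test_responses=test_responses,
        evaluation=evaluation, manifest=manifest,
    )
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _prediction_table(
    selected_media: pd.DataFrame,
    baseline_media: pd.DataFrame,
    finals: dict,
    pooled: mz.FittedModel,
    back_eval: pd.DataFrame,
) -> pd.DataFrame:
    """Predictions to confront with the confirmation experiment.

    Cluster media get the median (and IQR) across the four donor models;
    baseline media get the pooled model's single expansion prediction.
    """
    rows = []
    for _, m in selected_media.iterrows():
        cid = int(m["cluster"])
        for response in sorted({r for _, r in finals}):
            be = back_eval[
                (back_eval["cluster"] == cid) & (back_eval["response"] == response)
            ].iloc[0]
            rows.append(
                {
                    "formulation_id": f"cluster{cid}",
                    "response": response,
                    "predicted": be["predicted_median"],
                    "predicted_iqr": be["iqr"],
                    "arm": "individual_models",
                }
            )
    if pooled is None or baseline_media.empty:
        return pd.DataFrame(rows)
    factor_cols = [c for c in baseline_media.columns if c in pooled.factor_ids]
    preds = pooled.predict(baseline_media[factor_cols].to_numpy(dtype=float))
    for (_, m), p in zip(baseline_media.iterrows(), preds):
        rows.append(
            {
                "formulation_id": m["formulation_id"],
                "response": pooled.response,
                "predicted": float(p),
                "predicted_iqr": np.nan,
                "arm": "pooled_model",
            }
        )
    return pd.DataFrame(rows)


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = result.manifest
    dd.write_design(result.design, out_dir / "design.csv")
    manifest.artifacts["design.csv"] = _hash_file(out_dir / "design.csv")
    _write_csv(result.responses, out_dir, "responses.csv", manifest)
    _write_csv(mz.metrics_table(result.candidates), out_dir, "candidate_metrics.csv", manifest)
    _write_csv(mz.metrics_table(result.finals), out_dir, "final_metrics.csv", manifest)
    _write_csv(result.pool, out_dir, "pool.csv", manifest)
    assignments = result.pool.copy()
    assignments["cluster"] = result.solution.assignments
    _write_csv(assignments, out_dir, "assignments.csv", manifest)
    _write_csv(result.elbow, out_dir, "elbow.csv", manifest)
    comp = result.composition.copy()
    comp["donors"] = comp["donors"].map(lambda d: "|".join(d))
    _write_csv(comp, out_dir, "composition.csv", manifest)
    _write_csv(result.cluster_media, out_dir, "cluster_media.csv", manifest)
    _write_csv(result.back_eval, out_dir, "back_evaluation.csv", manifest)
    _write_csv(result.baseline_media, out_dir, "baseline_media.csv", manifest)
    _write_csv(result.evaluation, out_dir, "evaluation.csv", manifest)
    dd.write_design(result.confirmation_design, out_dir / "confirmation_design.csv")
    manifest.artifacts["confirmation_design.csv"] = _hash_file(out_dir / "confirmation_design.csv")
    _write_csv(result.test_responses, out_dir, "test_responses.csv", manifest)
    selection_report = {
        "selected_clusters": result.selection.selected_clusters,
        "eligible_clusters": result.selection.eligible_clusters,
        "rationale": result.selection.rationale,
        "warning": result.selection.warning,
    }
    (out_dir / "selection.json").write_text(json.dumps(selection_report, indent=2))
    manifest.artifacts["selection.json"] = _hash_file(out_dir / "selection.json")
    manifest.to_json(out_dir / "manifest.json")


def ingest_responses(path) -> pd.DataFrame:
    """Read and validate a long-form response table.

    Required columns: donor_id, run_id, replicate, response, value.
    Viability values must lie in [0, 100]; expansion must be non-negative.
    Schema violations are reported with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    required = ["donor_id", "run_id", "replicate", "response", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    problems = []
    values = pd.to_numeric(df["value"], errors="coerce")
    for i in np.flatnonzero(values.isna().to_numpy()):
        problems.append(f"row {i + 1}: non-numeric value {df['value'].iloc[i]!r}")
    df["value"] = values
    viab = df["response"] == VIABILITY
    bad = viab & ((df["value"] < 0) | (df["value"] > 100))
    for i in np.flatnonzero(bad.to_numpy()):
        problems.append(f"row {i + 1}: viability {df['value'].iloc[i]} outside [0, 100]")
    expn = df["response"] == EXPANSION
    bad = expn & (df["value"] < 0)
    for i in np.flatnonzero(bad.to_numpy()):
        problems.append(f"row {i + 1}: negative expansion {df['value'].iloc[i]}")
    if problems:
        raise ValueError("invalid response table:\n" + "\n".join(problems))
    present = set(df["response"].unique())
    expected = {VIABILITY, EXPANSION}
    if present < expected:
        import warnings

        warnings.warn(
            f"only {sorted(present)} present; models will be fit for those responses only",
            stacklevel=2,
        )
    return df
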