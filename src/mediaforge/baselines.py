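"""Comparison arms: pooled single-response OLS and the naive ensemble.

The traditional arm pools all donors' expansion data (donor identity
discarded) into one stepwise-AIC regression and picks a small set of
diverse high-predicted formulations from it.  The ablation arm skips the
clustering step entirely: it takes the component-wise median of the pooled
top candidates in one shot.  The evaluation harness compares predictions
from either arm against experimental medians on a fresh set of test
donors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import REFERENCE_RUN_ID, factor_columns
from .models import FittedModel, ModelingConfig, Scaler, build_features, fit_ols_stepwise, run_folds
from .search import pool_factor_columns
from .simulate import EXPANSION

__all__ = [
    "fit_pooled_ols",
    "select_baseline_media",
    "naive_ensemble",
    "evaluate_on_test_set",
    "assemble_confirmation_design",
]


def fit_pooled_ols(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    response: str = EXPANSION,
    equation: str = "eq1",
    folds: int = 10,
    seed: int | None = None,
) -> FittedModel:
    """Single stepwise-AIC OLS on all donors' pooled data for one response.

    The default main-effects equation is the traditional screening-stage
    analysis: the sequential workflow only reaches curvature terms in its
    second (optimization) round, which the one-shot comparison omits.
    """
    cols = factor_columns(design)
    dsd = design[design["run_role"] == "dsd_formulation"].drop_duplicates("run_id")
    sub = responses[responses["response"] == response]
    if sub["donor_id"].nunique() < 2:
        raise ValueError("pooled model requires blocks from at least 2 donors")
    merged = sub.merge(dsd[["run_id", *cols]], on="run_id", how="inner")
    X = merged[cols].to_numpy(dtype=float)
    y = merged["value"].to_numpy(dtype=float)
    # group replicates and donor repeats of the same run together
    groups = merged["run_id"].to_numpy()
    splits = run_folds(groups, folds, seed)
    F = build_features(X, equation)
    est, hp, cv_rmse, cv_r2 = fit_ols_stepwise(F, y, splits)
    scaler = Scaler().fit(F)
    model = FittedModel(
        model_id="pooled.ols",
        donor_id="pooled",
        response=response,
        algorithm="ols_stepwise",
        equation=equation,
        estimator=est,
        scaler=scaler,
        factor_ids=cols,
        hyperparams=hp,
        cv_rmse=cv_rmse,
        cv_r2=cv_r2,
        y_train_min=float(y.min()),
        y_train_max=float(y.max()),
    )
    pred = model.predict(X)
    model.train_rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    model.train_r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst if sst > 0 else np.nan
    return model


def select_baseline_media(
    model: FittedModel,
    candidates: pd.DataFrame,
    n: int = 6,
    min_separation: float = 0.5,
) -> pd.DataFrame:
    """Greedy top-predicted selection with a pairwise diversity rule.

    Candidates are scanned in descending predicted order; one is accepted
    when its L∞ distance to every already-accepted formulation is at least
    ``min_separation``.  If the rule cannot fill ``n`` slots it is relaxed
    with a warning so the requested number of media is always returned.
    """
    factor_cols = [c for c in candidates.columns if c in model.factor_ids]
    X = candidates[factor_cols].to_numpy(dtype=float)
    pred = model.predict(X)
    order = np.lexsort((np.arange(len(pred)), -pred))
    chosen: list[int] = []
    for idx in order:
        if len(chosen) == n:
            break
        if all(np.max(np.abs(X[idx] - X[c])) >= min_separation for c in chosen):
            chosen.append(idx)
    if len(chosen) < n:
        warnings.warn(
            f"diversity rule (L-inf >= {min_separation}) infeasible; relaxing",
            stacklevel=2,
        )
        for idx in order:
            if len(chosen) == n:
                break
            if idx not in chosen:
                chosen.append(idx)
    out = candidates.iloc[chosen].reset_index(drop=True).copy()
    out.insert(0, "formulation_id", [f"T{i + 1:02d}" for i in range(len(out))])
    out["predicted"] = pred[chosen]
    return out


def naive_ensemble(pool: pd.DataFrame, response: str | None = EXPANSION) -> pd.Series:
    """Component-wise median of the pooled top candidates, without clustering.

    By default only candidates pooled for the expansion response enter the
    median; pass ``response=None`` to ensemble across both responses.
    """
    df = pool if response is None else pool[pool["response"] == response]
    if df.empty:
        raise ValueError("candidate pool is empty after response filtering")
    return df[pool_factor_columns(pool)].median()


def evaluate_on_test_set(
    predictions: pd.DataFrame,
    test_responses: pd.DataFrame,
) -> pd.DataFrame:
    """Pair predicted values with experimental medians on test donors.

    ``predictions`` needs columns (formulation_id, response, predicted);
    experimental values are summarized per formulation by averaging
    replicates within each donor first, then taking the median and IQR
    across donors.  The absolute prediction error is reported per row.
    """
    required = {"formulation_id", "response", "predicted"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions table needs columns {sorted(required)}")
    gaps = []
    rows = []
    for _, p in predictions.iterrows():
        sub = test_responses[
            (test_responses["run_id"] == p["formulation_id"])
            & (test_responses["response"] == p["response"])
        ]
        if sub.empty:
            gaps.append((p["formulation_id"], p["response"]))
            continue
        per_donor = sub.groupby("donor_id")["value"].mean()
        q25, q50, q75 = np.percentile(per_donor.to_numpy(), [25, 50, 75])
        rows.append(
            {
                "formulation_id": p["formulation_id"],
                "response": p["response"],
                "predicted": float(p["predicted"]),
                "predicted_iqr": float(p.get("predicted_iqr", np.nan)),
                "experimental_median": float(q50),
                "experimental_iqr": float(q75 - q25),
                "abs_error": float(abs(p["predicted"] - q50)),
                "n_donors": int(per_donor.size),
            }
        )
    if gaps:
        raise ValueError(f"test responses missing for: {gaps}")
    return pd.DataFrame(rows)


def assemble_confirmation_design(
    cluster_media: pd.DataFrame,
    baseline_media: pd.DataFrame,
    donor_ids: list[str],
    include_reference: bool = True,
) -> pd.DataFrame:
    """Confirmation block design: every test formulation in every test donor.

    Formulations are the selected cluster media, the baseline test media
    and (optionally) the reference medium, run as randomized complete
    blocks over the test donors.  Two cluster media + six baseline media +
    reference over four donors gives 36 confirmation runs.
    """
    factor_cols = [c for c in cluster_media.columns if c != "cluster"]
    rows = []
    for _, m in cluster_media.iterrows():
        row = {c: m[c] for c in factor_cols}
        row.update(run_id=f"cluster{int(m['cluster'])}", run_role="cluster_medium")
        rows.append(row)
    for _, m in baseline_media.iterrows():
        row = {c: m[c] for c in factor_cols}
        row.update(run_id=m["formulation_id"], run_role="baseline_medium")
        rows.append(row)
    if include_reference:
        row = {c: np.nan for c in factor_cols}
        row.update(run_id=REFERENCE_RUN_ID, run_role="reference")
        rows.append(row)
    base = pd.DataFrame(rows)
    blocks = []
    for donor in donor_ids:
        block = base.copy()
        block["block_id"] = donor
        blocks.append(block)
    out = pd.concat(blocks, ignore_index=True)
    meta = ["run_id", "run_role", "block_id"]
    return out[meta + factor_cols]
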