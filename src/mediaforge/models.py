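"""Competitive per-donor response-surface modeling.

For every donor block and every response, nine candidate models are fit:
three algorithms (stepwise-AIC ordinary least squares, elastic net with a
tuned mixing/penalty grid, random forest with a tuned feature-subsampling
fraction) crossed with three nested model equations:

* ``eq1`` — main effects only (k terms)
* ``eq2`` — main effects + pure quadratics (2k terms)
* ``eq3`` — full second-order: mains, quadratics and all two-way
  interactions (2k + k(k−1)/2 terms; 90 for k = 12)

Hyperparameters are tuned by grouped k-fold cross-validation in which all
replicates of a run share a fold and feature scaling is re-fit inside each
training fold, so no information leaks from held-out runs.  Candidates are
ranked by cross-validated RMSE (R² breaks ties) and one winner per
(donor, response) is chosen among the regularized and forest models —
ordinary least squares competes but is excluded from the finals for its
weaker robustness to overfitting at screening sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge, enet_path

from .design import factor_columns

__all__ = [
    "EQUATIONS",
    "ALGORITHMS",
    "build_features",
    "feature_names",
    "Scaler",
    "FittedModel",
    "ModelingConfig",
    "run_folds",
    "stepwise_aic",
    "fit_ols_stepwise",
    "fit_elastic_net",
    "fit_random_forest",
    "cross_validate",
    "fit_candidates",
    "rank_and_select",
    "metrics_table",
]

EQUATIONS = ("eq1", "eq2", "eq3")
ALGORITHMS = ("ols_stepwise", "elastic_net", "random_forest")


def feature_names(factor_ids: list[str], equation: str) -> list[str]:
    names = list(factor_ids)
    if equation in ("eq2", "eq3"):
        names += [f"{f}^2" for f in factor_ids]
    if equation == "eq3":
        k = len(factor_ids)
        names += [
            f"{factor_ids[i]}:{factor_ids[j]}"
            for i in range(k)
            for j in range(i + 1, k)
        ]
    return names


def build_features(X: np.ndarray, equation: str) -> np.ndarray:
    """Expand coded formulations into the term set of a model equation.

    Column order: mains by factor index, quadratics by factor index,
    interactions lexicographic by (i, j).
    """
    if equation not in EQUATIONS:
        raise ValueError(f"unknown equation {equation!r}")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("coded entries must be finite")
    blocks = [X]
    if equation in ("eq2", "eq3"):
        blocks.append(X**2)
    if equation == "eq3":
        k = X.shape[1]
        inter = [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
        blocks.append(np.stack(inter, axis=1) if inter else np.empty((X.shape[0], 0)))
    F = np.hstack(blocks)
    return F[0] if single else F


@dataclass
class Scaler:
    """Column-wise centering and scaling with zero-variance columns dropped."""

    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None
    kept_: np.ndarray | None = None
    dropped_: list[int] = field(default_factory=list)

    def fit(self, F: np.ndarray) -> "Scaler":
        F = np.asarray(F, dtype=float)
        mean = F.mean(axis=0)
        sd = F.std(axis=0, ddof=1) if F.shape[0] > 1 else np.zeros(F.shape[1])
        keep = sd > 0
        self.kept_ = np.flatnonzero(keep)
        self.dropped_ = list(np.flatnonzero(~keep))
        self.mean_ = mean[keep]
        self.scale_ = sd[keep]
        return self

    def transform(self, F: np.ndarray) -> np.ndarray:
        if self.kept_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(F, dtype=float)[:, self.kept_] - self.mean_) / self.scale_

    def fit_transform(self, F: np.ndarray) -> np.ndarray:
        return self.fit(F).transform(F)

    def inverse_transform(self, Fs: np.ndarray) -> np.ndarray:
        return np.asarray(Fs) * self.scale_ + self.mean_


@dataclass
class FittedModel:
    """A trained per-donor predictor with its scaling state and CV metrics."""

    model_id: str
    donor_id: str
    response: str
    algorithm: str
    equation: str
    estimator: object
    scaler: Scaler
    factor_ids: list[str]
    hyperparams: dict = field(default_factory=dict)
    cv_rmse: float = np.nan
    cv_r2: float = np.nan
    train_rmse: float = np.nan
    train_r2: float = np.nan
    y_train_min: float = np.nan
    y_train_max: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict responses for coded formulations (n, k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.factor_ids):
            raise ValueError(
                f"expected {len(self.factor_ids)} components, got {X.shape[1]}"
            )
        F = build_features(X, self.equation)
        return np.asarray(self.estimator.predict(self.scaler.transform(F)), dtype=float)


@dataclass
class ModelingConfig:
    """Grids and CV settings for the candidate-model stage."""

    equations: tuple[str, ...] = EQUATIONS
    algorithms: tuple[str, ...] = ALGORITHMS
    folds: int = 10
    l1_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    rf_mtry_grid: tuple[float, ...] = (1 / 3, 1 / 2, 2 / 3, 1.0)
    rf_trees: int = 500
    seed: int = 0


def run_folds(groups: np.ndarray, n_folds: int, seed: int | None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Grouped k-fold splits: all observations of a group share a fold."""
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if n_folds > len(uniq):
        warnings.warn(
            f"folds={n_folds} exceeds {len(uniq)} groups; using leave-one-group-out",
            stacklevel=2,
        )
        n_folds = len(uniq)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    chunks = np.array_split(order, n_folds)
    splits = []
    for chunk in chunks:
        held = set(uniq[chunk])
        test = np.flatnonzero([g in held for g in groups])
        train = np.flatnonzero([g not in held for g in groups])
        splits.append((train, test))
    return splits


def _aic(rss: float, n: int, p: int) -> float:
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * p


def _ols_rss(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Least squares with intercept; None when the fit is rank deficient."""
    A = np.column_stack([np.ones(len(y)), F]) if F.size else np.ones((len(y), 1))
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        return None
    resid = y - A @ coef
    return coef, float(resid @ resid)


def stepwise_aic(F: np.ndarray, y: np.ndarray, max_steps: int | None = None) -> tuple[list[int], np.ndarray]:
    """Bidirectional stepwise selection minimizing AIC = n·ln(RSS/n) + 2p.

    Starts from the intercept-only model with the full column set as scope;
    at each step the single add or drop with the lowest AIC is taken, and
    the search stops when no move improves on the current model.  Moves
    producing rank-deficient fits are rejected.  Returns the selected
    column indices and the coefficient vector (intercept first).

    Add moves are scored in one pass by projecting all free columns onto
    the orthogonal complement of the current design, which gives every
    add's exact RSS without refitting; drops refit the (small) reduced
    model directly.
    """
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = F.shape
    if n <= 2:
        raise ValueError("stepwise selection needs more than 2 observations")
    if max_steps is None:
        max_steps = 2 * m + 10
    selected: list[int] = []
    Q = np.full((n, 1), 1.0 / np.sqrt(n))
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    current_aic = _aic(rss, n, 1)
    col_scale = np.maximum((F * F).sum(axis=0), 1.0)

    for _ in range(max_steps):
        best_aic = current_aic - 1e-10
        best_move: tuple[str, int] | None = None

        free = [j for j in range(m) if j not in selected]
        if free and len(selected) + 2 <= n:
            E = F[:, free] - Q @ (Q.T @ F[:, free])
            den = (E * E).sum(axis=0)
            ok = den > 1e-9 * col_scale[free]
            with np.errstate(divide="ignore", invalid="ignore"):
                rss_add = rss - (r @ E) ** 2 / den
            rss_add = np.maximum(rss_add, 1e-12)
            aic_add = n * np.log(rss_add / n) + 2 * (len(selected) + 2)
            aic_add[~ok] = np.inf
            j_best = int(np.argmin(aic_add))
            if aic_add[j_best] < best_aic:
                best_aic = float(aic_add[j_best])
                best_move = ("add", free[j_best])

        for s in selected:
            cand = [c for c in selected if c != s]
            res = _ols_rss(F[:, cand], y)
            if res is None:
                continue
            aic = _aic(res[1], n, len(cand) + 1)
            if aic < best_aic:
                best_aic = aic
                best_move = ("drop", s)

        if best_move is None:
            break
        kind, j = best_move
        if kind == "add":
            selected.append(j)
        else:
            selected.remove(j)
        A = np.column_stack([np.ones(n) / np.sqrt(n), F[:, selected]])
        Q, _ = np.linalg.qr(A)
        r = y - Q @ (Q.T @ y)
        rss = max(float(r @ r), 1e-12)
        current_aic = _aic(rss, n, len(selected) + 1)

    fit = _ols_rss(F[:, selected], y)
    assert fit is not None
    return selected, fit[0]


class _SparseOLS:
    """Predictor over a fixed feature layout with a stepwise-selected support."""

    def __init__(self, n_features: int, selected: list[int], coef: np.ndarray):
        self.selected = list(selected)
        self.intercept_ = float(coef[0])
        self.coef_ = np.zeros(n_features)
        for idx, j in enumerate(self.selected):
            self.coef_[j] = coef[idx + 1]

    def predict(self, Fs: np.ndarray) -> np.ndarray:
        return self.intercept_ + np.asarray(Fs) @ self.coef_


def _rmse(y: np.ndarray, pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan


def cross_validate(fit_fn, F: np.ndarray, y: np.ndarray,
                   splits: list[tuple[np.ndarray, np.ndarray]]) -> tuple[float, float]:
    """Pooled held-out RMSE and R² for an arbitrary fit procedure.

    ``fit_fn(Fs_train, y_train) -> predict`` receives features already
    scaled with a scaler fit on the training fold only.
    """
    preds = np.empty_like(y, dtype=float)
    for train, test in splits:
        scaler = Scaler().fit(F[train])
        predict = fit_fn(scaler.transform(F[train]), y[train])
        preds[test] = predict(scaler.transform(F[test]))
    return _rmse(y, preds), _r2(y, preds)


def _lambda_grid(Fs: np.ndarray, y: np.ndarray, l1: float, n_lambda: int,
                 min_ratio: float) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(Fs.T @ (y - y.mean()))) / (n * max(l1, 0.1))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * min_ratio), n_lambda)


def _enet_estimator(l1: float, lam: float, n: int):
    if lam == 0:
        return LinearRegression()
    if l1 == 0:
        # exact ridge limit of the elastic-net objective
        return Ridge(alpha=lam * n)
    return ElasticNet(alpha=lam, l1_ratio=l1, max_iter=20_000, tol=1e-6)


def _enet_path_predictions(
    Fs_tr: np.ndarray, y_tr: np.ndarray, Fs_te: np.ndarray,
    l1: float, lams: np.ndarray,
) -> np.ndarray:
    """Test-fold predictions along a penalty path, one row per lambda.

    Features arrive scaled; the intercept is the training mean of y once y
    is regressed on centered columns, so the whole path reduces to a single
    ``enet_path`` call (coordinate descent) for l1 > 0 and a closed-form
    SVD ridge path for the pure-L2 corner of the grid.
    """
    out = np.empty((len(lams), len(Fs_te)))
    y_mean = y_tr.mean()
    yc = y_tr - y_mean
    nonzero = lams > 0
    if l1 > 0:
        if nonzero.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    Fs_tr, yc, l1_ratio=l1, alphas=np.sort(lams[nonzero])[::-1],
                    max_iter=20_000, tol=1e-6,
                )
            # enet_path returns coefficients for descending alphas
            order = np.argsort(-lams[nonzero])
            preds = y_mean + Fs_te @ coefs
            out[np.flatnonzero(nonzero)[order]] = preds.T
    else:
        if nonzero.any():
            U, s, Vt = np.linalg.svd(Fs_tr, full_matrices=False)
            uty = U.T @ yc
            n = len(y_tr)
            for pos in np.flatnonzero(nonzero):
                shrink = s / (s**2 + lams[pos] * n)
                coef = Vt.T @ (shrink * uty)
                out[pos] = y_mean + Fs_te @ coef
    for pos in np.flatnonzero(~nonzero):
        est = LinearRegression().fit(Fs_tr, y_tr)
        out[pos] = est.predict(Fs_te)
    return out


def fit_elastic_net(
    F: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    l1_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-4,
) -> tuple[object, dict, float, float]:
    """Grid-tuned elastic net; returns (estimator, hyperparams, cv_rmse, cv_r2).

    The (mixing, penalty) pair minimizing mean held-out RMSE wins; ties go
    to the larger penalty, then the larger mixing (the sparser model).
    """
    if np.std(y) == 0:
        raise ValueError("response has zero variance; cannot tune an elastic net")
    full_scaler = Scaler().fit(F)
    Fs_full = full_scaler.transform(F)
    results = []  # (cv_rmse, lam, l1)
    for l1 in l1_grid:
        lams = (
            np.asarray(lambda_grid, dtype=float)
            if lambda_grid is not None
            else _lambda_grid(Fs_full, y, l1, n_lambda, lambda_min_ratio)
        )
        per_lam_preds = np.empty((len(lams), len(y)))
        for train, test in splits:
            scaler = Scaler().fit(F[train])
            per_lam_preds[:, test] = _enet_path_predictions(
                scaler.transform(F[train]), y[train],
                scaler.transform(F[test]), float(l1), lams,
            )
        for li, lam in enumerate(lams):
            rmse = _rmse(y, per_lam_preds[li])
            results.append((rmse, float(lam), float(l1), per_lam_preds[li].copy()))
    # primary: min rmse; ties: larger lambda then larger l1
    best = min(results, key=lambda t: (round(t[0], 12), -t[1], -t[2]))
    cv_rmse, lam, l1, preds = best
    cv_r2 = _r2(y, preds)
    est = _enet_estimator(l1, lam, len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Fs_full, y)
    return est, {"l1_ratio": l1, "lambda": lam}, cv_rmse, cv_r2


def fit_random_forest(
    F: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    mtry_grid: tuple[float, ...] = (1 / 3, 1 / 2, 2 / 3, 1.0),
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[object, dict, float, float]:
    """Random forest with the feature-subsampling fraction tuned by CV."""
    best = None
    for mtry in mtry_grid:
        def fit_fn(Fs, yt, mtry=mtry):
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
            )
            rf.fit(Fs, yt)
            return rf.predict
        cv_rmse, cv_r2 = cross_validate(fit_fn, F, y, splits)
        if best is None or cv_rmse < best[0] - 1e-12:
            best = (cv_rmse, cv_r2, mtry)
    cv_rmse, cv_r2, mtry = best
    scaler = Scaler().fit(F)
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=mtry, random_state=seed, n_jobs=1
    )
    rf.fit(scaler.transform(F), y)
    return rf, {"max_features": mtry, "n_trees": n_trees}, cv_rmse, cv_r2


def fit_ols_stepwise(
    F: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[object, dict, float, float]:
    """Stepwise-AIC OLS with per-fold reselection for honest CV metrics."""
    def fit_fn(Fs, yt):
        sel, coef = stepwise_aic(Fs, yt)
        return _SparseOLS(Fs.shape[1], sel, coef).predict
    cv_rmse, cv_r2 = cross_validate(fit_fn, F, y, splits)
    scaler = Scaler().fit(F)
    sel, coef = stepwise_aic(scaler.transform(F), y)
    est = _SparseOLS(len(scaler.kept_), sel, coef)
    return est, {"n_terms": len(sel)}, cv_rmse, cv_r2


def _fit_one(
    algorithm: str,
    F: np.ndarray,
    y: np.ndarray,
    splits,
    config: ModelingConfig,
    seed: int,
) -> tuple[object, dict, float, float]:
    if algorithm == "ols_stepwise":
        return fit_ols_stepwise(F, y, splits)
    if algorithm == "elastic_net":
        return fit_elastic_net(
            F, y, splits,
            l1_grid=config.l1_grid,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
    if algorithm == "random_forest":
        return fit_random_forest(
            F, y, splits, mtry_grid=config.rf_mtry_grid,
            n_trees=config.rf_trees, seed=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _response_suffix(response: str) -> str:
    return "e" if "expansion" in response else "v"


def fit_candidates(
    design: pd.DataFrame,
    responses: pd.DataFrame,
    config: ModelingConfig | None = None,
) -> list[FittedModel]:
    """Fit every (donor, response, algorithm, equation) candidate model.

    Reference runs are excluded (their coded levels are undefined);
    replicates enter as separate observations with run-level CV grouping.
    Model ids follow the ``b{block}.model{n}{e|v}`` convention, numbering
    the algorithm × equation grid 1–9.
    """
    if config is None:
        config = ModelingConfig()
    cols = factor_columns(design)
    dsd = design[design["run_role"] == "dsd_formulation"]
    donors = list(pd.unique(responses["donor_id"]))
    resp_names = list(pd.unique(responses["response"]))
    spec_grid = [
        (alg, eq) for alg in config.algorithms for eq in config.equations
    ]
    ss = np.random.SeedSequence(config.seed)
    fitted: list[FittedModel] = []
    for d_idx, donor in enumerate(donors):
        block_col = "block_id" if "block_id" in dsd.columns else None
        block = dsd[dsd[block_col] == donor] if block_col and donor in set(dsd[block_col]) else dsd
        block = block.drop_duplicates("run_id")
        for response in resp_names:
            sub = responses[
                (responses["donor_id"] == donor) & (responses["response"] == response)
            ]
            merged = sub.merge(block[["run_id", *cols]], on="run_id", how="inner")
            if merged.empty:
                continue
            X = merged[cols].to_numpy(dtype=float)
            y = merged["value"].to_numpy(dtype=float)
            groups = merged["run_id"].to_numpy()
            fold_seed = int(ss.generate_state(1)[0] % (2**31))
            splits = run_folds(groups, config.folds, fold_seed)
            for m_idx, (alg, eq) in enumerate(spec_grid, start=1):
                F = build_features(X, eq)
                est, hp, cv_rmse, cv_r2 = _fit_one(alg, F, y, splits, config, fold_seed)
                scaler = Scaler().fit(F)
                model = FittedModel(
                    model_id=f"b{d_idx + 1}.model{m_idx}{_response_suffix(response)}",
                    donor_id=str(donor),
                    response=response,
                    algorithm=alg,
                    equation=eq,
                    estimator=est,
                    scaler=scaler,
                    factor_ids=cols,
                    hyperparams=hp,
                    cv_rmse=cv_rmse,
                    cv_r2=cv_r2,
                    y_train_min=float(y.min()),
                    y_train_max=float(y.max()),
                )
                train_pred = model.predict(X)
                model.train_rmse = _rmse(y, train_pred)
                model.train_r2 = _r2(y, train_pred)
                fitted.append(model)
    return fitted


def rank_and_select(
    candidates: list[FittedModel],
    eligible_algorithms: tuple[str, ...] = ("elastic_net", "random_forest"),
) -> dict[tuple[str, str], FittedModel]:
    """One winner per (donor, response): lowest CV RMSE, R² breaks ties.

    Only regularized and forest candidates are eligible for the finals;
    ordinary least squares competes for reference but is excluded from
    selection for its weaker robustness against overfitting.
    """
    if not candidates:
        raise ValueError("no candidate models to select from")
    cells: dict[tuple[str, str], list[FittedModel]] = {}
    for m in candidates:
        cells.setdefault((m.donor_id, m.response), []).append(m)
    winners = {}
    for key, group in cells.items():
        eligible = [m for m in group if m.algorithm in eligible_algorithms]
        if not eligible:
            raise ValueError(f"no eligible candidates for {key}")
        winners[key] = min(eligible, key=lambda m: (m.cv_rmse, -m.cv_r2))
    return winners


def metrics_table(models: list[FittedModel] | dict) -> pd.DataFrame:
    """Tabulate model metrics (one row per model, train and CV columns)."""
    if isinstance(models, dict):
        models = list(models.values())
    return pd.DataFrame(
        [
            {
                "donor_id": m.donor_id,
                "response": m.response,
                "model_id": m.model_id,
                "method": m.algorithm,
                "equation": m.equation,
                "train_rmse": m.train_rmse,
                "train_r2": m.train_r2,
                "cv_rmse": m.cv_rmse,
                "cv_r2": m.cv_r2,
            }
            for m in models
        ]
    )
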