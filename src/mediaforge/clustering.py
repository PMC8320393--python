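"""Consensus clustering of pooled in-silico formulations.

The pooled top candidates from all donor models are centered and scaled,
their clustering tendency quantified with the Hopkins statistic, and
k-means applied (elbow curve and silhouette widths as diagnostics).  Each
cluster is collapsed to a component-wise-median "cluster medium"
formulation, characterized by its composition (which response and which
donors its members came from), and back-evaluated by predicting both
responses in every donor's final model.  Cluster media representing all
training donors are ranked by predicted median expansion to pick the
formulations worth confirming experimentally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .models import FittedModel, Scaler
from .search import pool_factor_columns
from .simulate import EXPANSION

__all__ = [
    "hopkins_statistic",
    "ClusterSolution",
    "kmeans_cluster",
    "elbow_curve",
    "silhouette_widths",
    "cluster_composition",
    "cluster_median_formulations",
    "back_evaluate",
    "SelectionResult",
    "select_cluster_media",
    "pca_projection",
]


def hopkins_statistic(
    points: np.ndarray,
    sample_fraction: float = 0.1,
    seed: int | None = None,
) -> float:
    """Clustering tendency H = Σu / (Σu + Σw) on nearest-neighbor distances.

    ``u`` are distances from m uniform pseudo-points (drawn in the data's
    bounding box) to their nearest data point; ``w`` are distances from m
    sampled data points to their nearest *other* data point.  H ≈ 0.5
    indicates spatial uniformity; H → 1 indicates clustered structure.
    """
    X = np.asarray(points, dtype=float)
    n, d = X.shape
    m = int(np.ceil(sample_fraction * n))
    if n < 2 * m or m < 1:
        raise ValueError(f"need at least {2 * m} points for sample_fraction={sample_fraction}")
    # child stream: pseudo-points must never replay the generator sequence
    # that may have produced the data itself under the same seed
    rng = np.random.default_rng(
        None if seed is None else np.random.SeedSequence(seed, spawn_key=(1,))
    )
    lo, hi = X.min(axis=0), X.max(axis=0)
    pseudo = rng.uniform(lo, hi, size=(m, d))
    tree = cKDTree(X)
    u, _ = tree.query(pseudo, k=1)
    idx = rng.choice(n, m, replace=False)
    w, _ = tree.query(X[idx], k=2)
    w = w[:, 1]  # skip self-match
    return float(u.sum() / (u.sum() + w.sum()))


@dataclass
class ClusterSolution:
    """A fitted k-means partition with its quality diagnostics."""

    k_clusters: int
    assignments: np.ndarray          # 1-based cluster labels
    centroids: np.ndarray            # in the scaled space
    wss: float                       # total within-cluster sum of squares
    scaler: Scaler
    silhouette: np.ndarray | None = None
    avg_silhouette: float = np.nan
    hopkins: float = np.nan

    def centroids_unscaled(self) -> np.ndarray:
        return self.scaler.inverse_transform(self.centroids)


def scale_points(X: np.ndarray) -> tuple[np.ndarray, Scaler]:
    scaler = Scaler().fit(X)
    return scaler.transform(X), scaler


def kmeans_cluster(
    points: np.ndarray,
    k: int,
    n_restarts: int = 25,
    max_iter: int = 300,
    seed: int | None = None,
    scale: bool = True,
) -> ClusterSolution:
    """k-means (Lloyd, k-means++ seeding, best of ``n_restarts``)."""
    X = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of points ({len(X)})")
    scaler = Scaler().fit(X)
    Xs = scaler.transform(X) if scale else X.copy()
    if not scale:
        # identity scaler so centroid back-transformation stays exact
        scaler = Scaler()
        scaler.kept_ = np.arange(X.shape[1])
        scaler.mean_ = np.zeros(X.shape[1])
        scaler.scale_ = np.ones(X.shape[1])
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=None if seed is None else int(seed) % (2**31),
    )
    labels = km.fit_predict(Xs)
    solution = ClusterSolution(
        k_clusters=k,
        assignments=labels + 1,
        centroids=km.cluster_centers_,
        wss=float(km.inertia_),
        scaler=scaler,
    )
    if k >= 2 and k < len(X):
        widths, avg = silhouette_widths(Xs, labels)
        solution.silhouette = widths
        solution.avg_silhouette = avg
    return solution


def elbow_curve(
    points: np.ndarray,
    k_range,
    n_restarts: int = 25,
    seed: int | None = None,
    scale: bool = True,
) -> pd.DataFrame:
    """Total within-cluster sum of squares across candidate cluster counts."""
    seeds = np.random.SeedSequence(seed).generate_state(len(list(k_range))) % (2**31)
    rows = [
        {"k": int(k), "wss": kmeans_cluster(points, int(k), n_restarts, seed=int(s), scale=scale).wss}
        for k, s in zip(k_range, seeds)
    ]
    return pd.DataFrame(rows)


def silhouette_widths(points: np.ndarray, assignments: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouette s = (b − a)/max(a, b) and its average.

    Euclidean distances; singleton clusters score 0 by convention.
    """
    labels = np.asarray(assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette widths require at least 2 clusters")
    widths = silhouette_samples(np.asarray(points, dtype=float), labels)
    return widths, float(widths.mean())


def cluster_composition(pool: pd.DataFrame, solution: ClusterSolution) -> pd.DataFrame:
    """Member counts and percentages per cluster by response and donor origin.

    One row per (cluster, response); ``donors`` lists the donors whose
    candidates contributed members for that response.
    """
    if len(pool) != len(solution.assignments):
        raise ValueError("pool and cluster assignments are misaligned")
    df = pool.copy()
    df["cluster"] = solution.assignments
    rows = []
    for cluster, grp in df.groupby("cluster"):
        total = len(grp)
        for response, rgrp in grp.groupby("response"):
            rows.append(
                {
                    "cluster": int(cluster),
                    "response": response,
                    "n": len(rgrp),
                    "percentage": 100.0 * len(rgrp) / total,
                    "donors": tuple(sorted(rgrp["donor_id"].unique())),
                }
            )
    return pd.DataFrame(rows)


def cluster_median_formulations(pool: pd.DataFrame, solution: ClusterSolution) -> pd.DataFrame:
    """Component-wise median formulation of each cluster (coded units)."""
    factor_cols = pool_factor_columns(pool)
    df = pool.copy()
    df["cluster"] = solution.assignments
    media = df.groupby("cluster")[factor_cols].median()
    media.index.name = "cluster"
    return media.reset_index()


def back_evaluate(
    media: pd.DataFrame,
    finals: dict[tuple[str, str], FittedModel],
) -> pd.DataFrame:
    """Predict every cluster medium in every donor's final model.

    Returns one row per (cluster medium, response) with per-donor
    predictions plus their median and IQR — the cross-donor robustness
    summary used to choose formulations.
    """
    responses = sorted({r for _, r in finals})
    donors = sorted({d for d, _ in finals})
    missing = [(d, r) for d in donors for r in responses if (d, r) not in finals]
    if missing:
        raise ValueError(f"missing final models for {missing}")
    factor_cols = [c for c in media.columns if c != "cluster"]
    X = media[factor_cols].to_numpy(dtype=float)
    rows = []
    for response in responses:
        preds = {d: finals[(d, response)].predict(X) for d in donors}
        mat = np.column_stack([preds[d] for d in donors])
        q25, q50, q75 = np.percentile(mat, [25, 50, 75], axis=1)
        for i, cluster in enumerate(media["cluster"]):
            row = {
                "cluster": cluster,
                "response": response,
                "predicted_median": float(q50[i]),
                "iqr": float(q75[i] - q25[i]),
            }
            row.update({f"pred_{d}": float(mat[i, j]) for j, d in enumerate(donors)})
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SelectionResult:
    selected_clusters: list[int]
    eligible_clusters: list[int]
    rationale: list[str] = field(default_factory=list)
    warning: str | None = None


def select_cluster_media(
    composition: pd.DataFrame,
    back_eval: pd.DataFrame,
    n_select: int = 2,
    expansion_response: str = EXPANSION,
    all_donors: tuple[str, ...] | None = None,
) -> SelectionResult:
    """Choose cluster media for confirmation.

    Eligibility: the cluster's expansion-response members must represent
    every training donor (a cluster backed by all donors is the one most
    likely to generalize).  Eligible clusters are ranked by predicted
    median expansion, descending.  If none is eligible, the best-ranked
    cluster overall is returned with a warning flag.
    """
    if all_donors is None:
        all_donors = tuple(
            sorted(set().union(*[set(d) for d in composition["donors"]]))
        )
    exp_rows = composition[composition["response"] == expansion_response]
    eligible = [
        int(r["cluster"])
        for _, r in exp_rows.iterrows()
        if set(all_donors) <= set(r["donors"])
    ]
    medians = (
        back_eval[back_eval["response"] == expansion_response]
        .set_index("cluster")["predicted_median"]
        .to_dict()
    )
    rationale = []
    warning = None
    if eligible:
        ranked = sorted(eligible, key=lambda c: -medians.get(c, -np.inf))
        chosen = ranked[:n_select]
        for c in chosen:
            rationale.append(
                f"cluster {c}: expansion members from all donors; "
                f"predicted median expansion {medians.get(c, float('nan')):.2f}"
            )
        if len(chosen) < n_select:
            rest = sorted(
                (c for c in medians if c not in chosen), key=lambda c: -medians[c]
            )
            fill = rest[: n_select - len(chosen)]
            chosen = chosen + fill
            warning = (
                f"only {len(eligible)} cluster(s) represent all donors; "
                f"filled remaining slot(s) from {fill} by predicted expansion"
            )
            rationale.append(warning)
    else:
        ranked = sorted(medians, key=lambda c: -medians[c])
        chosen = ranked[:n_select]
        warning = "no cluster represents all donors; falling back to rank only"
        rationale.append(warning)
    return SelectionResult(
        selected_clusters=[int(c) for c in chosen],
        eligible_clusters=eligible,
        rationale=rationale,
        warning=warning,
    )


def pca_projection(points: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component coordinates and explained-variance ratios."""
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(np.asarray(points, dtype=float))
    return coords, pca.explained_variance_ratio_
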