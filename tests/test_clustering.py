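"""Clustering-stage tests: Hopkins statistic, k-means, silhouette,
cluster profiles, median formulations, back-evaluation and selection."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from mediaforge import clustering as cl
from mediaforge import models as mz
from mediaforge import search as sr


def _blobs(rng, centers, n_per, sd):
    pts = [rng.normal(c, sd, size=(n_per, len(c))) for c in centers]
    return np.vstack(pts)


class TestHopkins:
    def test_two_tight_blobs_score_high(self):
        rng = np.random.default_rng(0)
        X = _blobs(rng, [(0, 0), (1, 1)], 200, 0.01)
        h = cl.hopkins_statistic(X, seed=1)
        assert h > 0.8

    def test_duplicated_data_keeps_conclusion(self):
        rng = np.random.default_rng(2)
        X = _blobs(rng, [(0, 0), (1, 1)], 150, 0.01)
        h1 = cl.hopkins_statistic(X, seed=3)
        h2 = cl.hopkins_statistic(np.vstack([X, X]), seed=3)
        assert h1 > 0.8 and h2 > 0.8

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            cl.hopkins_statistic(np.zeros((1, 2)))


class TestKMeans:
    def test_single_cluster_wss_is_total_ss(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        sol = cl.kmeans_cluster(X, 1, n_restarts=1, seed=0, scale=False)
        total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
        assert sol.wss == pytest.approx(total_ss, rel=1e-9)

    def test_k_equals_n_gives_zero_wss(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 2))
        sol = cl.kmeans_cluster(X, 8, n_restarts=5, seed=1, scale=False)
        assert sol.wss == pytest.approx(0.0, abs=1e-12)

    def test_k_above_n_errors(self):
        with pytest.raises(ValueError):
            cl.kmeans_cluster(np.zeros((3, 2)), 4)

    def test_matches_exhaustive_partition_optimum_on_toy(self):
        """Best-of-restarts k-means equals the brute-force optimal
        2-partition of a 12-point set (all 2^11 assignments checked)."""
        rng = np.random.default_rng(6)
        X = _blobs(rng, [(0, 0), (2.5, 2.5)], 6, 0.6)
        sol = cl.kmeans_cluster(X, 2, n_restarts=20, seed=7, scale=False)

        best = np.inf
        n = len(X)
        for bits in product([0, 1], repeat=n - 1):
            lab = np.array((0,) + bits)
            if lab.min() == lab.max():
                continue
            wss = 0.0
            for g in (0, 1):
                pts = X[lab == g]
                if len(pts):
                    wss += ((pts - pts.mean(axis=0)) ** 2).sum()
            best = min(best, wss)
        assert sol.wss == pytest.approx(best, rel=1e-9)

    def test_centroid_unscaling_exact(self):
        rng = np.random.default_rng(8)
        X = rng.normal(loc=5.0, scale=3.0, size=(40, 4))
        sol = cl.kmeans_cluster(X, 3, n_restarts=10, seed=9, scale=True)
        back = sol.centroids_unscaled()
        for c in range(1, 4):
            members = X[sol.assignments == c]
            assert np.allclose(back[c - 1], members.mean(axis=0), atol=1e-8)


class TestElbow:
    def test_wss_monotone_non_increasing(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 3))
        curve = cl.elbow_curve(X, range(1, 8), n_restarts=10, seed=11)
        assert (np.diff(curve["wss"]) <= 1e-9).all()

    def test_three_planted_blobs_drop_at_three(self):
        rng = np.random.default_rng(12)
        X = _blobs(rng, [(0, 0), (6, 0), (3, 6)], 30, 0.3)
        curve = cl.elbow_curve(X, range(1, 7), n_restarts=10, seed=13, scale=False)
        wss = curve["wss"].to_numpy()
        rel_drop = (wss[:-1] - wss[1:]) / wss[:-1]
        assert np.argmax(rel_drop) + 2 == 3  # drop from k=2 to k=3 dominates


class TestSilhouette:
    def test_two_far_blobs_near_one(self):
        rng = np.random.default_rng(14)
        X = _blobs(rng, [(0, 0), (10, 10)], 20, 0.1)
        labels = np.repeat([0, 1], 20)
        widths, avg = cl.silhouette_widths(X, labels)
        assert avg > 0.9
        assert ((widths >= -1) & (widths <= 1)).all()

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            cl.silhouette_widths(np.zeros((5, 2)), np.zeros(5))

    def test_matches_pairwise_brute_force_oracle(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(15, 3))
        labels = rng.integers(0, 3, 15)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, 15)
        widths, avg = cl.silhouette_widths(X, labels)

        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        expected = np.empty(15)
        for i in range(15):
            own = labels == labels[i]
            n_own = own.sum()
            if n_own == 1:
                expected[i] = 0.0
                continue
            a = D[i, own].sum() / (n_own - 1)
            b = min(
                D[i, labels == other].mean()
                for other in np.unique(labels)
                if other != labels[i]
            )
            expected[i] = (b - a) / max(a, b)
        assert np.allclose(widths, expected)
        assert avg == pytest.approx(expected.mean())


def _toy_pool():
    rng = np.random.default_rng(16)
    rows = []
    for i in range(20):
        rows.append(
            {
                "c01": rng.uniform(-1, 1), "c02": rng.uniform(-1, 1),
                "donor_id": f"d{i % 3}", "response": "expansion_d6" if i % 2 else "viability_d3",
                "model_id": "m", "predicted": float(i), "rank": i % 5 + 1,
            }
        )
    return pd.DataFrame(rows)


class TestCompositionAndMedia:
    def test_counts_partition_pool(self):
        pool = _toy_pool()
        sol = cl.kmeans_cluster(pool[["c01", "c02"]].to_numpy(), 3, 10, seed=17)
        comp = cl.cluster_composition(pool, sol)
        assert comp["n"].sum() == len(pool)
        for _, grp in comp.groupby("cluster"):
            assert grp["percentage"].sum() == pytest.approx(100.0)

    def test_percentages_match_hand_tally(self):
        pool = _toy_pool()
        sol = cl.kmeans_cluster(pool[["c01", "c02"]].to_numpy(), 2, 10, seed=18)
        comp = cl.cluster_composition(pool, sol)
        df = pool.assign(cluster=sol.assignments)
        for _, row in comp.iterrows():
            sub = df[df["cluster"] == row["cluster"]]
            n = ((sub["response"] == row["response"])).sum()
            assert row["n"] == n
            assert row["percentage"] == pytest.approx(100 * n / len(sub))
            exp_donors = tuple(sorted(sub[sub["response"] == row["response"]]["donor_id"].unique()))
            assert row["donors"] == exp_donors

    def test_single_response_pool_is_100_percent(self):
        pool = _toy_pool()
        pool["response"] = "expansion_d6"
        sol = cl.kmeans_cluster(pool[["c01", "c02"]].to_numpy(), 2, 10, seed=19)
        comp = cl.cluster_composition(pool, sol)
        assert (comp["percentage"] == 100.0).all()

    def test_median_formulation_matches_sort_oracle(self):
        pool = _toy_pool()
        sol = cl.kmeans_cluster(pool[["c01", "c02"]].to_numpy(), 2, 10, seed=20)
        media = cl.cluster_median_formulations(pool, sol)
        df = pool.assign(cluster=sol.assignments)
        for _, m in media.iterrows():
            members = df[df["cluster"] == m["cluster"]]
            for c in ("c01", "c02"):
                vals = np.sort(members[c].to_numpy())
                n = len(vals)
                expected = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
                assert m[c] == pytest.approx(expected)
                assert members[c].min() <= m[c] <= members[c].max()

    def test_three_level_median_is_zero(self):
        assert float(np.median([-1.0, 0.0, 1.0])) == 0.0


def _constant_model(donor, response, value):
    class Const:
        def __init__(self, v): self.v = v
        def predict(self, F): return np.full(len(F), self.v)
    scaler = mz.Scaler()
    scaler.kept_ = np.arange(2)
    scaler.mean_ = np.zeros(2)
    scaler.scale_ = np.ones(2)
    return mz.FittedModel(
        model_id=f"{donor}{response[0]}", donor_id=donor, response=response,
        algorithm="elastic_net", equation="eq1", estimator=Const(value),
        scaler=scaler, factor_ids=["c01", "c02"],
    )


class TestBackEvaluation:
    def test_identical_models_give_zero_iqr(self):
        finals = {
            (d, r): _constant_model(d, r, 25.0)
            for d in ("d1", "d2", "d3", "d4")
            for r in ("expansion_d6", "viability_d3")
        }
        media = pd.DataFrame({"cluster": [1, 2], "c01": [0.0, 0.5], "c02": [0.1, -0.5]})
        be = cl.back_evaluate(media, finals)
        assert len(be) == 4  # 2 media x 2 responses
        assert (be["iqr"] == 0.0).all()
        assert (be["predicted_median"] == 25.0).all()

    def test_median_iqr_match_quantile_oracle(self):
        vals = {"d1": 20.0, "d2": 22.0, "d3": 27.0, "d4": 31.0}
        finals = {
            (d, r): _constant_model(d, r, v)
            for d, v in vals.items()
            for r in ("expansion_d6",)
        }
        media = pd.DataFrame({"cluster": [1], "c01": [0.0], "c02": [0.0]})
        be = cl.back_evaluate(media, finals)
        arr = np.array(sorted(vals.values()))
        q25, q50, q75 = np.percentile(arr, [25, 50, 75])
        assert be["predicted_median"].iloc[0] == pytest.approx(q50)
        assert be["iqr"].iloc[0] == pytest.approx(q75 - q25)

    def test_missing_model_errors(self):
        finals = {("d1", "expansion_d6"): _constant_model("d1", "expansion_d6", 1.0),
                  ("d2", "viability_d3"): _constant_model("d2", "viability_d3", 1.0)}
        media = pd.DataFrame({"cluster": [1], "c01": [0.0], "c02": [0.0]})
        with pytest.raises(ValueError):
            cl.back_evaluate(media, finals)


class TestSelection:
    @staticmethod
    def _composition(donor_sets):
        rows = []
        for cluster, donors in donor_sets.items():
            rows.append({"cluster": cluster, "response": "expansion_d6",
                         "n": 10, "percentage": 60.0, "donors": donors})
            rows.append({"cluster": cluster, "response": "viability_d3",
                         "n": 5, "percentage": 40.0, "donors": donors})
        return pd.DataFrame(rows)

    @staticmethod
    def _back_eval(medians):
        return pd.DataFrame(
            [{"cluster": c, "response": "expansion_d6", "predicted_median": m, "iqr": 1.0}
             for c, m in medians.items()]
        )

    def test_selection_matches_hand_ranking(self):
        comp = self._composition({
            1: ("d1", "d2", "d3", "d4"), 2: ("d1", "d2"),
            3: ("d1", "d2", "d3", "d4"), 4: ("d1", "d2", "d3", "d4"),
        })
        be = self._back_eval({1: 28.0, 2: 35.0, 3: 31.0, 4: 29.5})
        sel = cl.select_cluster_media(comp, be, n_select=2,
                                      all_donors=("d1", "d2", "d3", "d4"))
        # cluster 2 ranks highest but lacks donors; 3 and 4 win among eligible
        assert sel.selected_clusters == [3, 4]
        assert sel.warning is None

    def test_single_eligible_cluster_always_selected(self):
        comp = self._composition({1: ("d1",), 2: ("d1", "d2")})
        be = self._back_eval({1: 40.0, 2: 10.0})
        sel = cl.select_cluster_media(comp, be, n_select=1, all_donors=("d1", "d2"))
        assert sel.selected_clusters == [2]

    def test_no_eligible_falls_back_with_warning(self):
        comp = self._composition({1: ("d1",), 2: ("d2",)})
        be = self._back_eval({1: 20.0, 2: 25.0})
        sel = cl.select_cluster_media(comp, be, n_select=1, all_donors=("d1", "d2", "d3"))
        assert sel.selected_clusters == [2]
        assert sel.warning is not None

    def test_shortfall_filled_from_ranked_rest(self):
        comp = self._composition({1: ("d1", "d2"), 2: ("d1",), 3: ("d2",)})
        be = self._back_eval({1: 20.0, 2: 30.0, 3: 25.0})
        sel = cl.select_cluster_media(comp, be, n_select=2, all_donors=("d1", "d2"))
        assert sel.selected_clusters == [1, 2]
        assert sel.warning is not None


def test_pca_projection_shapes():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(50, 6))
    coords, ratios = cl.pca_projection(X)
    assert coords.shape == (50, 2)
    assert ratios.shape == (2,)
    assert 0 < ratios.sum() <= 1.0
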