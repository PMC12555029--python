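"""Neighbor graphs, interaction statistic, permutation test, aggregation."""

import numpy as np
import pandas as pd
import pytest

from imctme import spatial
from imctme.errors import DataError


def _roi(xy, labels=None, ids=None):
    n = len(xy)
    return pd.DataFrame({
        "cell_id": ids if ids is not None else [f"c{i:03d}" for i in range(n)],
        "roi_id": "R1",
        "x_um": [p[0] for p in xy],
        "y_um": [p[1] for p in xy],
        **({"phenotype": labels} if labels is not None else {}),
    })


class TestBuildGraph:
    def test_expansion_strict_radius(self):
        near = _roi([(0.0, 0.0), (19.9, 0.0)])
        g = spatial.build_graph(near, "expansion", radius_um=20.0)
        assert len(g.edges) == 1
        exact = _roi([(0.0, 0.0), (20.0, 0.0)])
        g = spatial.build_graph(exact, "expansion", radius_um=20.0)
        assert len(g.edges) == 0

    def test_expansion_undirected_no_self_edges(self):
        rng = np.random.default_rng(0)
        df = _roi(rng.uniform(0, 100, (50, 2)))
        g = spatial.build_graph(df, "expansion", radius_um=25.0)
        assert not g.directed
        assert (g.edges[:, 0] != g.edges[:, 1]).all()

    def test_knn_outdegree_and_bruteforce_equality(self):
        rng = np.random.default_rng(1)
        df = _roi(rng.uniform(0, 300, (100, 2)))
        g = spatial.build_graph(df, "knn", k=10)
        assert g.directed
        deg = np.bincount(g.edges[:, 0], minlength=100)
        assert (deg == 10).all()
        # independent O(n^2) oracle
        xy = df[["x_um", "y_um"]].to_numpy()
        expected = set()
        for i in range(100):
            d = [(np.hypot(*(xy[i] - xy[j])), j) for j in range(100) if j != i]
            d.sort()
            for _dist, j in d[:10]:
                expected.add((i, j))
        assert expected == set(map(tuple, g.edges))

    def test_knn_truncates_k(self, caplog):
        df = _roi([(0, 0), (1, 0), (2, 0)])
        with caplog.at_level("WARNING"):
            g = spatial.build_graph(df, "knn", k=10)
        assert g.parameter == 2.0
        assert "truncating" in caplog.text

    def test_knn_distance_tie_lower_cell_id(self):
        # two equidistant candidates: the lower cell id wins
        df = _roi([(0.0, 0.0), (10.0, 0.0), (-10.0, 0.0)],
                  ids=["c2", "c0", "c1"])
        g = spatial.build_graph(df, "knn", k=1)
        out = {tuple(e) for e in g.edges}
        # row 0 ("c2") ties between rows 1 ("c0") and 2 ("c1"): "c0" wins
        assert (0, 1) in out


class TestStatistic:
    def test_arithmetic(self):
        # 2 A cells, each with exactly 3 B neighbors within radius
        xy = [(0, 0), (100, 0)]
        for cx, _ in list(xy):
            for dx in (5, -5, 0):
                xy.append((cx + dx, 6))
        labels = ["A", "A"] + ["B"] * 6
        g = spatial.build_graph(_roi(xy), "expansion", radius_um=15.0)
        assert spatial.interaction_statistic(g, labels, "A", "B") == 3.0

    def test_no_target_cells_zero(self):
        g = spatial.build_graph(_roi([(0, 0), (5, 0)]), "expansion", 20.0)
        assert spatial.interaction_statistic(g, ["A", "A"], "A", "B") == 0.0

    def test_no_source_cells_missing(self):
        g = spatial.build_graph(_roi([(0, 0), (5, 0)]), "expansion", 20.0)
        assert np.isnan(spatial.interaction_statistic(g, ["B", "B"], "A", "B"))

    def test_equals_bruteforce_on_random_geometric(self):
        rng = np.random.default_rng(2)
        n = 300
        xy = rng.uniform(0, 300, (n, 2))
        labels = rng.choice(["A", "B", "C"], size=n)
        df = _roi(xy)
        g = spatial.build_graph(df, "expansion", radius_um=20.0)
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        adj = d2 < 400.0
        for a in "ABC":
            for b in "ABC":
                counts = adj[labels == a][:, labels == b].sum()
                expected = counts / (labels == a).sum()
                got = spatial.interaction_statistic(g, labels, a, b)
                assert got == pytest.approx(expected)


class TestPermutationTest:
    def test_single_type_sigval_zero_p_one(self):
        rng = np.random.default_rng(3)
        df = _roi(rng.uniform(0, 100, (40, 2)))
        g = spatial.build_graph(df, "expansion", 20.0)
        res = spatial.permutation_test(g, ["A"] * 40, n_perm=200, seed=0)
        row = res.iloc[0]
        assert row["p_enrich"] == 1.0 and row["p_avoid"] == 1.0
        assert row["sigval"] == 0

    def test_p_values_never_zero(self):
        rng = np.random.default_rng(4)
        df = _roi(rng.uniform(0, 200, (100, 2)))
        labels = rng.choice(["A", "B"], size=100)
        g = spatial.build_graph(df, "expansion", 20.0)
        res = spatial.permutation_test(g, labels, n_perm=100, seed=1)
        ok = res[~res["missing"]]
        assert (ok["p_enrich"] > 0).all() and (ok["p_avoid"] > 0).all()
        assert (ok["p_enrich"] >= 1 / 101).all()

    def test_absent_type_marked_missing(self):
        rng = np.random.default_rng(5)
        df = _roi(rng.uniform(0, 100, (30, 2)))
        g = spatial.build_graph(df, "expansion", 20.0)
        res = spatial.permutation_test(g, ["A"] * 30, n_perm=50, seed=0,
                                       types=["A", "B"])
        ab = res[(res["from_type"] == "A") & (res["to_type"] == "B")].iloc[0]
        assert bool(ab["missing"]) and np.isnan(ab["sigval"])

    def test_relabeling_permutes_results_consistently(self):
        rng = np.random.default_rng(6)
        df = _roi(rng.uniform(0, 200, (150, 2)))
        labels = rng.choice(["A", "B", "C"], size=150)
        g = spatial.build_graph(df, "expansion", 25.0)
        res1 = spatial.permutation_test(g, labels, n_perm=300, seed=7)
        swap = {"A": "B", "B": "A", "C": "C"}
        res2 = spatial.permutation_test(g, [swap[l] for l in labels],
                                        n_perm=300, seed=7)
        for _, row in res1.iterrows():
            match = res2[(res2["from_type"] == swap[row["from_type"]])
                         & (res2["to_type"] == swap[row["to_type"]])].iloc[0]
            assert match["observed"] == pytest.approx(row["observed"])

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(8)
        df = _roi(rng.uniform(0, 150, (80, 2)))
        labels = rng.choice(["A", "B"], size=80)
        g = spatial.build_graph(df, "expansion", 20.0)
        r1 = spatial.permutation_test(g, labels, n_perm=100, seed=11)
        r2 = spatial.permutation_test(g, labels, n_perm=100, seed=11)
        pd.testing.assert_frame_equal(r1, r2)


class TestAggregateScores:
    def _results(self, entries):
        rows = []
        for roi, fr, to, sig in entries:
            rows.append({"roi_id": roi, "from_type": fr, "to_type": to,
                         "observed": 1.0, "p_enrich": 0.5, "p_avoid": 0.5,
                         "sigval": sig, "n_perm": 100,
                         "missing": np.isnan(sig)})
        return pd.DataFrame(rows)

    def test_roi_to_sample_mean(self):
        res = self._results([("R1", "A", "B", 1.0), ("R2", "A", "B", 1.0),
                             ("R3", "A", "B", 0.0)])
        mats = spatial.aggregate_scores(
            res, {"R1": "S1", "R2": "S1", "R3": "S1"}, {"S1": "g"})
        assert mats["g"].scores.loc["A", "B"] == pytest.approx(2 / 3)

    def test_two_stage_mean(self):
        res = self._results(
            [("R1", "A", "B", 1.0), ("R2", "A", "B", 1.0), ("R3", "A", "B", 0.0),
             ("R4", "A", "B", 0.0)])
        mats = spatial.aggregate_scores(
            res, {"R1": "S1", "R2": "S1", "R3": "S1", "R4": "S2"},
            {"S1": "g", "S2": "g"})
        assert mats["g"].scores.loc["A", "B"] == pytest.approx(1 / 3)

    def test_missing_excluded_from_both_stages(self):
        res = self._results([("R1", "A", "B", np.nan), ("R2", "A", "B", -1.0),
                             ("R3", "A", "B", np.nan)])
        mats = spatial.aggregate_scores(
            res, {"R1": "S1", "R2": "S1", "R3": "S2"},
            {"S1": "g", "S2": "g"})
        assert mats["g"].scores.loc["A", "B"] == pytest.approx(-1.0)
        assert mats["g"].n_samples.loc["A", "B"] == 1

    def test_groups_by_subtype_without_code_change(self, phenotyped_cohort):
        _, labeled, meta, truth, *_ = phenotyped_cohort
        sub = labeled[labeled["roi_id"].isin(labeled["roi_id"].unique()[:4])]
        results = spatial.score_rois(sub, label_col="phenotype",
                                     n_perm=100, seed=0)
        roi_to_sample = dict(sub.drop_duplicates("roi_id")
                             [["roi_id", "sample_id"]].to_numpy())
        groups = dict(truth.per_sample[["sample_id", "true_subtype"]].to_numpy())
        mats = spatial.aggregate_scores(results, roi_to_sample, groups)
        assert set(mats) <= {"AGCT-1", "AGCT-2"}
        for m in mats.values():
            vals = m.scores.to_numpy(float)
            assert np.nanmax(np.abs(vals)) <= 1.0

    def test_unmapped_roi_rejected(self):
        res = self._results([("R1", "A", "B", 1.0)])
        with pytest.raises(DataError, match="R1"):
            spatial.aggregate_scores(res, {}, {})


class TestNullCalibration:
    def test_mean_sigval_near_zero_under_random_labels(self):
        rng = np.random.default_rng(9)
        sig_sum, count = 0.0, 0
        for rep in range(10):
            df = _roi(rng.uniform(0, 400, (400, 2)))
            labels = rng.choice(["A", "B", "C", "D"], size=400)
            g = spatial.build_graph(df, "expansion", 20.0)
            res = spatial.permutation_test(g, labels, n_perm=200,
                                           seed=100 + rep)
            ok = res[~res["missing"]]
            sig_sum += ok["sigval"].sum()
            count += len(ok)
        assert abs(sig_sum / count) <= 0.1


class TestFigureExports:
    def test_heatmap_export_writes_png(self, tmp_path):
        scores = pd.DataFrame([[1.0, -0.5], [0.2, 0.0]],
                              index=["A", "B"], columns=["A", "B"])
        counts = pd.DataFrame([[3, 3], [3, 3]],
                              index=["A", "B"], columns=["A", "B"])
        mat = spatial.InteractionScoreMatrix("g", scores, counts)
        path = tmp_path / "heatmap.png"
        spatial.plot_score_heatmap(mat, path)
        assert path.stat().st_size > 0
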