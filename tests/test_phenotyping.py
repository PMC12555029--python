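"""Positivity fitting, gating, hormone quadrants, subsampling, embedding."""

import numpy as np
import pandas as pd
import pytest

from imctme import phenotyping as ph
from imctme.errors import (ConfigurationError, ContractViolationError,
                           DegenerateDistributionError)
from imctme.panel import default_panel

from conftest import random_cell_table


def _intraclass_variance_minimizer(x: np.ndarray) -> float:
    """Exhaustive-search Otsu oracle: the cut minimizing within-class
    variance over all midpoints between consecutive sorted values."""
    xs = np.sort(x)
    best_t, best_v = xs[0], np.inf
    for i in range(1, len(xs)):
        t = (xs[i - 1] + xs[i]) / 2
        lo, hi = xs[:i], xs[i:]
        v = lo.var() * len(lo) + hi.var() * len(hi)
        if v < best_v:
            best_v, best_t = v, t
    return best_t


class TestFitPositivity:
    def test_threshold_between_component_medians(self, panel):
        rng = np.random.default_rng(0)
        cells = random_cell_table(panel, n=600, seed=0)
        lo = np.exp(rng.normal(0.0, 0.25, 300))
        hi = np.exp(rng.normal(4.0, 0.35, 300))
        cells["FOXL2"] = np.concatenate([lo, hi])
        model = ph.fit_positivity(cells, panel, method="otsu")
        t = model.thresholds["FOXL2"]
        assert np.median(lo) < t < np.median(hi)
        # the exhaustive intraclass-variance minimizer lands in the same gap
        oracle = _intraclass_variance_minimizer(
            np.arcsinh(cells["FOXL2"].to_numpy()))
        assert np.median(np.arcsinh(lo)) < oracle < np.median(np.arcsinh(hi))

    def test_fixed_method_returns_map(self, panel):
        cells = random_cell_table(panel, n=10)
        fixed = {m: 1.5 for m in panel.names}
        model = ph.fit_positivity(cells, panel, method="fixed", fixed=fixed)
        assert model.thresholds == fixed

    def test_all_background_marker_fixed_high_threshold(self, panel):
        cells = random_cell_table(panel, n=200, seed=1)
        cut = float(np.percentile(cells["FOXP3"], 99.9)) + 1.0
        model = ph.fit_positivity(cells, panel, method="fixed",
                                  fixed={"FOXP3": cut})
        assert model.is_positive(cells, "FOXP3").sum() == 0

    def test_constant_marker_raises_degenerate(self, panel):
        cells = random_cell_table(panel, n=50)
        cells["Ki67"] = 1.0
        with pytest.raises(DegenerateDistributionError, match="Ki67"):
            ph.fit_positivity(cells, panel, method="otsu")

    def test_unimodal_marker_all_one_side(self, panel):
        # background-only marker: nothing positive; uniformly-high marker
        # (DNA-like): everything positive
        rng = np.random.default_rng(2)
        cells = random_cell_table(panel, n=500, seed=2)
        cells["CD123"] = np.exp(rng.normal(0.0, 0.25, 500))
        cells["DNA1"] = np.exp(rng.normal(4.0, 0.35, 500))
        model = ph.fit_positivity(cells, panel, method="otsu")
        assert model.is_positive(cells, "CD123").sum() == 0
        assert model.is_positive(cells, "DNA1").all()


class TestAssignLineages:
    def test_foxl2_branch_label(self, panel):
        cells = random_cell_table(panel, n=3, seed=3)
        for m in panel.names:
            cells[m] = 0.5
        cells.loc[:, ["DNA1", "DNA2", "FOXL2"]] = 60.0
        cells.loc[1, "COL1A1"] = 60.0
        thresholds = {m: 5.0 for m in panel.names}
        model = ph.fit_positivity(cells, panel, "fixed", thresholds)
        tree = ph.default_gating_tree(panel)
        labeled, _ = ph.assign_lineages(cells, tree, model)
        assert labeled.loc[0, "phenotype"] == "FOXL2+COL1A1-"
        assert labeled.loc[1, "phenotype"] == "FOXL2+COL1A1+"

    def test_all_negative_cell_unassigned(self, panel):
        cells = random_cell_table(panel, n=1)
        for m in panel.names:
            cells[m] = 0.5
        cells[["DNA1", "DNA2"]] = 60.0
        model = ph.fit_positivity(cells, panel, "fixed",
                                  {m: 5.0 for m in panel.names})
        labeled, _ = ph.assign_lineages(cells, ph.default_gating_tree(panel),
                                        model)
        assert labeled.loc[0, "phenotype"] == "unassigned"

    def test_synthetic_cohort_confusion_matrix_diagonal(self, phenotyped_cohort):
        cfg, labeled, meta, truth, positivity, summary = phenotyped_cohort
        assert (labeled["phenotype"] == labeled["true_phenotype"]).all()
        counts = labeled["phenotype"].value_counts()
        true_counts = labeled["true_phenotype"].value_counts()
        pd.testing.assert_series_equal(counts.sort_index(),
                                       true_counts.sort_index(),
                                       check_names=False)

    def test_partition_every_cell_exactly_one_label(self, phenotyped_cohort):
        _, labeled, *_ = phenotyped_cohort
        assert labeled["phenotype"].notna().all()

    def test_gating_invariant_to_monotone_transform(self, panel):
        # scaling intensities and thresholds jointly by any strictly
        # monotone map preserves every label
        cells = random_cell_table(panel, n=100, seed=4)
        cells[["DNA1", "DNA2"]] = 50.0
        cells.loc[:40, "CD45"] = 80.0
        cells.loc[:20, "CD68"] = 80.0
        thresholds = {m: 5.0 for m in panel.names}
        tree = ph.default_gating_tree(panel)
        base = ph.assign_lineages(
            cells, tree, ph.fit_positivity(cells, panel, "fixed", thresholds)
        )[0]["phenotype"]
        for g in (lambda v: 3 * v + 1, np.sqrt, lambda v: np.log1p(v)):
            warped = cells.copy()
            warped[panel.names] = g(warped[panel.names].to_numpy(float))
            warped_thr = {m: float(g(np.array([t]))[0])
                          for m, t in thresholds.items()}
            out = ph.assign_lineages(
                warped, tree,
                ph.fit_positivity(warped, panel, "fixed", warped_thr)
            )[0]["phenotype"]
            assert (out == base).all()


class TestClassifyHormone:
    def _foxl2_cells(self, panel, n=8):
        cells = random_cell_table(panel, n=n, seed=5)
        for m in panel.names:
            cells[m] = 0.5
        cells[["DNA1", "DNA2", "FOXL2"]] = 60.0
        return cells

    def test_quadrant_definitions(self, panel):
        cells = self._foxl2_cells(panel, 4)
        cells.loc[0, ["PR", "ERa"]] = [60.0, 60.0]
        cells.loc[1, ["PR", "ERa"]] = [60.0, 0.5]
        cells.loc[2, ["PR", "ERa"]] = [0.5, 60.0]
        model = ph.fit_positivity(cells, panel, "fixed",
                                  {m: 5.0 for m in panel.names})
        out, _ = ph.classify_hormone(cells, model)
        assert out["hormone_class"].tolist()[:4] == [
            "PR+ERa+", "PR+ERa-", "PR-ERa+", "PR-ERa-"]

    def test_eight_subpopulations_when_both_col1a1_states(self, panel):
        cells = self._foxl2_cells(panel, 8)
        pr = [60, 60, 0.5, 0.5] * 2
        era = [60, 0.5, 60, 0.5] * 2
        cells["PR"] = pr
        cells["ERa"] = era
        cells.loc[4:, "COL1A1"] = 60.0
        model = ph.fit_positivity(cells, panel, "fixed",
                                  {m: 5.0 for m in panel.names})
        out, counts = ph.classify_hormone(cells, model)
        assert out["foxl2_subpopulation"].nunique() == 8

    def test_foxl2_negative_input_rejected(self, panel):
        cells = self._foxl2_cells(panel, 3)
        cells.loc[1, "FOXL2"] = 0.5
        model = ph.fit_positivity(cells, panel, "fixed",
                                  {m: 5.0 for m in panel.names})
        with pytest.raises(ContractViolationError, match="FOXL2-negative"):
            ph.classify_hormone(cells, model)

    def test_pr_enriched_in_collagen_class(self, phenotyped_cohort, panel):
        # generator plants higher PR positivity among collagen-embedded
        # FOXL2+ cells; the classified intensities reproduce the ordering
        _, labeled, _, _, positivity, _ = phenotyped_cohort
        foxl2 = labeled[labeled["phenotype"].isin(
            ["FOXL2+COL1A1-", "FOXL2+COL1A1+"])]
        out, _ = ph.classify_hormone(foxl2, positivity)
        mean_pr = out.groupby("phenotype")["PR"].mean()
        assert mean_pr["FOXL2+COL1A1+"] > mean_pr["FOXL2+COL1A1-"]


class TestBalancedSubsample:
    def _cells_with_groups(self, panel, sizes):
        frames = []
        for i, (g, n) in enumerate(sizes.items()):
            df = random_cell_table(panel, n=n, seed=10 + i)
            df["cell_id"] = [f"{g}_{j}" for j in range(n)]
            df["major_group"] = g
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def test_six_groups_of_thousand(self, panel):
        cells = self._cells_with_groups(panel, {f"g{i}": 1200 for i in range(6)})
        out = ph.balanced_subsample(cells, "major_group",
                                    [f"g{i}" for i in range(6)], 1000, seed=0,
                                    panel=panel)
        assert len(out) == 6000

    def test_eight_groups_of_thousand(self, panel):
        cells = self._cells_with_groups(panel, {f"g{i}": 1100 for i in range(8)})
        out = ph.balanced_subsample(cells, "major_group",
                                    [f"g{i}" for i in range(8)], 1000, seed=0)
        assert len(out) == 8000

    def test_small_group_taken_whole(self, panel, caplog):
        cells = self._cells_with_groups(panel, {"big": 1500, "small": 300})
        with caplog.at_level("WARNING"):
            out = ph.balanced_subsample(cells, "major_group", ["big", "small"],
                                        1000, seed=0)
        assert (out["major_group"] == "small").sum() == 300
        assert (out["major_group"] == "big").sum() == 1000
        assert "small" in caplog.text

    def test_unknown_group_rejected(self, panel):
        cells = self._cells_with_groups(panel, {"a": 10})
        with pytest.raises(ConfigurationError, match="nope"):
            ph.balanced_subsample(cells, "major_group", ["nope"], 5, seed=0)

    def test_deterministic_and_without_replacement(self, panel):
        cells = self._cells_with_groups(panel, {"a": 50, "b": 50})
        s1 = ph.balanced_subsample(cells, "major_group", ["a", "b"], 30, seed=3)
        s2 = ph.balanced_subsample(cells, "major_group", ["a", "b"], 30, seed=3)
        pd.testing.assert_frame_equal(s1, s2)
        assert s1["cell_id"].is_unique

    def test_panel_restricts_to_phenotypic_markers(self, panel):
        cells = self._cells_with_groups(panel, {"a": 20})
        out = ph.balanced_subsample(cells, "major_group", ["a"], 10, seed=0,
                                    panel=panel)
        assert "Ki67" not in out.columns and "DNA1" not in out.columns
        assert "FOXL2" in out.columns


class TestEmbedTsne:
    def _two_population_table(self, panel, n=120):
        rng = np.random.default_rng(6)
        cells = random_cell_table(panel, n=n, seed=6)
        half = n // 2
        for m in ("FOXL2", "SF1", "Calretinin"):
            cells.loc[:half - 1, m] = np.exp(rng.normal(4, 0.3, half))
        for m in ("CD45", "CD68", "CD163"):
            cells.loc[half:, m] = np.exp(rng.normal(4, 0.3, n - half))
        cells["pop"] = ["t"] * half + ["i"] * (n - half)
        return cells

    def test_shape_and_determinism(self, panel):
        cells = self._two_population_table(panel)
        feats = panel.phenotypic_markers
        c1 = ph.embed_tsne(cells, feature_cols=feats, perplexity=10, seed=4)
        c2 = ph.embed_tsne(cells, feature_cols=feats, perplexity=10, seed=4)
        assert c1.shape == (len(cells), 2)
        np.testing.assert_array_equal(c1.to_numpy(), c2.to_numpy())
        assert c1.attrs["perplexity"] == 10

    def test_disjoint_populations_separate(self, panel):
        cells = self._two_population_table(panel)
        coords = ph.embed_tsne(cells, feature_cols=panel.phenotypic_markers,
                               perplexity=10, seed=4)
        xy = coords.to_numpy()
        pop = (cells["pop"] == "t").to_numpy()
        c_t, c_i = xy[pop].mean(axis=0), xy[~pop].mean(axis=0)
        inter = np.linalg.norm(c_t - c_i)
        intra = np.mean([np.linalg.norm(xy[pop] - c_t, axis=1).mean(),
                         np.linalg.norm(xy[~pop] - c_i, axis=1).mean()])
        assert inter > intra

    def test_too_few_rows_suggests_smaller_perplexity(self, panel):
        cells = self._two_population_table(panel, n=20)
        with pytest.raises(ConfigurationError, match="perplexity"):
            ph.embed_tsne(cells, feature_cols=panel.phenotypic_markers,
                          perplexity=30, seed=0)
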