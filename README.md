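# imctme

Spatially resolved tumor-microenvironment analysis for imaging mass
cytometry (IMC), built around adult-type ovarian granulosa cell tumors
(AGCT) — a rare sex cord–stromal cancer defined by the FOXL2 c.C402G
mutation. IMC images 30–40 metal-tagged antibodies at ~1 μm resolution
over 1 × 1 mm regions of interest (ROIs); after cell segmentation each
ROI becomes a table of cells with per-marker mean intensities. `imctme`
takes it from there:

* **Phenotyping** — supervised gating hierarchy (first-match-wins marker
  conjunctions) with robust automatic positivity thresholds on
  arcsinh-transformed intensities; hormone-receptor quadrants
  (PR±ERα±) within FOXL2+ cells; balanced subsampling and t-SNE.
* **Compartments** — segmentation of ROI images into pure tumor
  (FOXL2+COL1A1−), collagen-rich (COL1A1+ of any FOXL2 status), vessel
  (CD31+) and excluded (DNA-void/hemorrhage) regions; per-compartment
  areas, densities, intensities; cell morphology features.
* **Subtyping** — the per-sample statistic
  f = #(FOXL2+COL1A1+) / #(FOXL2+), bimodal across samples; the
  classification cut is the valley of its kernel density (AGCT-2 iff
  f ≥ threshold, cut ≈ 0.37 on cohorts of this structure).
* **Spatial interactions** — neighbor graphs (20 μm expansion or 10-NN)
  and a label-permutation test (n = 1,000): each ordered cell-type pair
  gets a sigval of +1 (enrichment), −1 (avoidance) or 0 at p < 0.01,
  averaged ROIs → sample → group.
* **Cohort statistics** — sample-level means, two-sided Wilcoxon
  rank-sum (exact for small tie-free samples), Benjamini–Hochberg.
* **Synthetic cohorts** — a ground-truthed generator (bimodal subtype
  mixture, cold macrophage-dominated immune contexture, collagen/tumor
  geometry, planted attraction/avoidance, renderable multichannel
  images) used to validate every stage.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from imctme import CohortConfig, simulate_cohort, default_panel
from imctme import phenotyping as ph
from imctme.subtyping import foxl2_col1a1_fraction, valley_threshold, classify_subtypes
from imctme import spatial

cfg = CohortConfig(n_samples=12, n_primary=4, rois_per_sample=(2, 2),
                   cells_per_roi=(1000, 1000), roi_side_um=500.0, seed=42)
cells, meta, truth = simulate_cohort(cfg)
panel = default_panel()

positivity = ph.fit_positivity(cells, panel, method="otsu")
tree = ph.default_gating_tree(panel)
labeled, summary = ph.assign_lineages(cells, tree, positivity)
print(f"assigned {summary.attrs['assigned_fraction']:.1%} of {len(labeled):,} cells")

fractions, _ = foxl2_col1a1_fraction(labeled)
valley = valley_threshold(fractions)
table = classify_subtypes(fractions, valley.threshold, meta)
s = table.attrs["summary"]
print(f"valley threshold: {valley.threshold:.3f}")
print(f"AGCT-1: {s['n_agct1']} samples ({s['agct1_share_pct']:.0f}%), "
      f"AGCT-2: {s['n_agct2']} samples ({s['agct2_share_pct']:.0f}%)")

roi = labeled[labeled["roi_id"] == "S01_R1"]
graph = spatial.build_graph(roi, "expansion", radius_um=20.0)
res = spatial.permutation_test(graph, roi["phenotype"].to_numpy(),
                               n_perm=1000, alpha=0.01, seed=0)
self_int = res[(res.from_type == "FOXL2+COL1A1-")
               & (res.to_type == "FOXL2+COL1A1-")].iloc[0]
print(f"FOXL2+COL1A1- self-interaction: observed {self_int['observed']:.2f} "
      f"neighbors/cell, p_enrich = {self_int['p_enrich']:.4f}, "
      f"sigval = {self_int['sigval']:+.0f}")
```

prints

```
assigned 98.0% of 24,000 cells
valley threshold: 0.378
AGCT-1: 7 samples (58%), AGCT-2: 5 samples (42%)
FOXL2+COL1A1- self-interaction: observed 12.70 neighbors/cell, p_enrich = 0.0010, sigval = +1
```

The gating assigns 98% of cells to a lineage (the remaining 2% match no
gate); the per-sample FOXL2+COL1A1+ fractions split bimodally and the
density valley lands near 0.38, separating 7 collagen-depleted (AGCT-1)
from 5 collagen-intermixed (AGCT-2) samples; and tumor cells colocalize
with themselves — a 20 μm-neighborhood self-interaction far above the
permutation null (sigval +1), as expected for cells growing in nests.

The same flow runs from the shell:

```sh
imctme run-all --outdir run --seed 42 --threshold 0.37
imctme report --rundir run
```

Each run writes a `manifest.json` recording the config, seed and content
hash of every output; reruns with the same config and seed reproduce the
manifest bit for bit and skip unchanged stages.

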