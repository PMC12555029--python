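# Methods

`imctme` implements a spatially resolved tumor-microenvironment (TME)
analysis for imaging mass cytometry (IMC) of adult-type granulosa cell
tumors (AGCT) and comparable tissues. The pipeline consumes per-cell
tables (one row per segmented cell: ROI, coordinates in μm, mean intensity
per marker of a 34-channel panel) and, optionally, multichannel ROI
rasters. This note documents the models, the parameters that matter, the
synthetic-data generator used for validation, and the numerical choices.

## Cell phenotyping

Lineages are assigned by a supervised gating hierarchy: an ordered tree of
marker-positivity conjunctions evaluated first-match-wins, so every cell
reaches exactly one leaf. The default tree requires DNA positivity, then
branches endothelium (CD31+), the CD45+ immune subtree (M2 macrophage
CD68+CD163+, M0 macrophage CD68+, Treg CD4+FOXP3+, CD8 T, CD4 T,
neutrophil CD66b+CD11b+, memory B CD20+CD11b+, B cell, plasmacytoid DC
CD123+, NK CD56+, CD33+ myeloid, undefined CD45+), the FOXL2+ branch split
by COL1A1 status, and the stromal branch (COL1A1+αSMA+, COL1A1+, αSMA+,
other stromal by vimentin). The shipped tree is a reconstruction of a
typical AGCT lineage strategy and is fully overridable via YAML.

**Positivity thresholds.** Per marker, intensities are arcsinh-transformed
(cofactor 1, conventional for this modality) and clipped at the 99.5th
percentile. The automatic threshold is chosen as follows:

1. If the smoothed intensity histogram has two modes separated by at least
   `min_separation` = 2 arcsinh units (the background and positive
   populations), the threshold is the center of the minimal-density
   plateau between the two highest such modes. This is robust both to
   class imbalance (rare positive populations, where plain Otsu splits the
   background) and to stray points in the gap.
2. Otherwise Otsu's criterion is used if its two classes are separated by
   `min_separation`.
3. Otherwise the marker is unimodal: every cell is called positive when
   the median arcsinh level exceeds `high_level` = 2.5 (≈ raw intensity 6;
   markers expressed by essentially all cells, such as the DNA
   intercalators), else negative (markers absent from the tissue).

Ties at the threshold count as negative, making gating deterministic and
invariant under monotone transforms applied jointly to intensities and
thresholds. Fixed user-supplied thresholds bypass all of this.

Hormone-receptor quadrants (PR±ERα±) are assigned per FOXL2+ cell from the
PR and ERα thresholds; crossed with COL1A1 status this yields eight
FOXL2+ subpopulations. Balanced subsampling (default 1,000 cells per
group, without replacement, seeded) feeds the t-SNE embedding (Barnes–Hut,
perplexity 30, θ = 0.5, 2-D), which is delegated to scikit-learn and used
for visualization only.

## Tissue compartments

ROI rasters are partitioned with precedence
**excluded > collagen_rich > tumor > vessel > background**:

* antigen channels (COL1A1, FOXL2, CD31): Gaussian smoothing (σ = 2 px) →
  Otsu (or fixed) threshold → morphological closing (disc radius 5 px,
  edge-padded so borders are not eroded) → removal of regions < 500 μm²;
* tumor is the FOXL2 mask **minus** collagen, so FOXL2+COL1A1+ fibromatous
  tissue falls in the collagen-rich category (a single histologic
  category, matching how such tissue behaves);
* excluded regions are DNA voids: connected components ≥ 2,000 μm² where
  the lightly smoothed (σ = 1 px) summed DNA signal falls below an
  absolute floor of 0.5 intensity units. An absolute floor is used rather
  than Otsu because hemorrhage is signal-free by definition, whereas Otsu
  on a DNA channel separates nuclei from tissue baseline, not tissue from
  void.

Cells take the compartment of the pixel containing their centroid (floor
convention, half-open pixels); cells on excluded pixels are flagged and
dropped from downstream statistics. When no images are available, a
table-only fallback assigns compartments from per-cell COL1A1/FOXL2/CD31
positivity with the same precedence; results are approximate near true
compartment boundaries and are flagged as such.

Per-compartment summaries report areas (pixel counts × pixel area),
cell densities (cells/mm², missing — not zero — for empty compartments),
and mean marker intensities per compartment. Morphology features for a
connected pixel region (≥ 4 px): form factor 4πA/P², solidity A/A_hull,
convexity P_hull/P, eccentricity and major/minor axes from the
moment-equivalent ellipse, largest/lesser diameter as max/min Feret
diameter over the pixel-corner convex hull, and ellipticalness
A/(π·(a/2)·(b/2)) — the last is a documented substitute for a proprietary
definition. Discretization keeps the form factor of a digital square
within 5% of π/4 and the solidity of convex regions within ~2% of 1 for
radii ≳ 30 px.

## Microenvironment subtyping

The subtype statistic is f = (# FOXL2+COL1A1+ cells)/(# FOXL2+ cells) per
sample, pooled over the sample's ROIs (cell-weighted rather than
ROI-averaged, because the statistic is defined on cells; per-ROI fractions
are returned as diagnostics). Across a cohort f is bimodal; the
classification threshold is found by the **valley method**: a Gaussian KDE
(Silverman bandwidth, boundary reflection at 0 and 1, 512-point grid) is
evaluated and the threshold is the density argmin strictly between the two
highest modes. A local maximum counts as a mode only if it reaches 20% of
the highest mode's density (`min_mode_ratio`); this prevents spurious side
bumps of undersmoothed unimodal samples from producing a false valley,
and a genuinely unimodal density raises an error instructing a manual
threshold. Exactly tied maxima resolve to the most separated pair
(logged). Samples with f ≥ threshold are AGCT-2 (collagen-intermixed),
otherwise AGCT-1; the boundary f = t counts as AGCT-2 for determinism.
On the default cohort mixture the recovered threshold is ≈ 0.35–0.37.

## Spatial interaction scoring

Per ROI a neighbor graph is built on centroids: **expansion** (undirected
edge iff distance strictly < 20 μm) or **knn** (directed out-edges to the
k = 10 nearest cells; distance ties broken toward the lower cell id; knn
graphs are kept directed, with symmetrization deliberately not applied).
The "classic" statistic for an ordered pair (from, to) is the mean number
of to-type neighbors per from-type cell.

Significance uses a label permutation null: all labels in the ROI are
shuffled uniformly with the graph fixed (default n = 1,000 permutations).
With the plus-one convention, p_enrich = (1 + #{perm ≥ obs})/(n+1), and
symmetrically for depletion, so p values are never zero. A pair scores
sigval +1 when p_enrich < α (default 0.01), −1 when p_avoid < α, else 0;
if both fall below α the smaller p wins and an exact tie scores 0 with a
warning. Pairs whose from- or to-type is absent from an ROI are *missing*,
not zero. The implementation permutes label vectors in chunks and counts
all T×T pair contingencies per permutation with a single bincount, making
1,000 permutations on a 2,000-cell ROI run in ~0.1 s. Scores are averaged
in two stages — ROIs to sample, then samples to group (condition or
subtype) — with missing entries excluded at both stages.

Under uniformly random labels (10 types, 2,000 cells, α = 0.01) the
fraction of non-zero sigvals is ~1–2%, consistent with two one-sided tests
at α each; planted attraction/avoidance at full strength is recovered with
the correct sign in ≥ 90% (empirically 100%) of replicate ROIs.

## Cohort statistics

The sample is the unit of inference: per-ROI measurements (e.g., a
phenotype's fraction of total or per-compartment cells) are averaged to
one value per sample before testing; ROIs with empty denominators are
missing and excluded (logged), never imputed. Group comparisons use the
two-sided Wilcoxon rank-sum test: exact via a dynamic program over the
rank-sum distribution when n_A + n_B ≤ 12 and the data are tie-free,
otherwise the tie- and continuity-corrected normal approximation. All
values identical across both groups degenerates to p = 1 with a warning.
Benjamini–Hochberg step-up adjustment (with monotonicity enforcement,
input order preserved) is available per comparison family but comparisons
default to unadjusted p values at α = 0.05, matching how composition
comparisons are conventionally reported for cohorts of this size.

## Synthetic cohort generator

The generator is first-class, tested code and the pipeline's validation
oracle. Its defaults emulate a two-dozen-sample AGCT cohort:

* 23 evaluable samples (8 primary, 15 recurrent; recurrent sites drawn
  from abdomen/pelvis, spleen, liver, large bowel, ovary), 2–6 ROIs per
  sample, 3,000–9,000 cells per 1 × 1 mm ROI at 1 μm pixels — all
  downscalable via config for fast tests;
* per-sample FOXL2+COL1A1+ fraction drawn from a two-component Gaussian
  mixture (means 0.15/0.55, SDs 0.05, low-component weight 15/23) — the
  generative definition of AGCT-1/AGCT-2, with an analytic density valley
  at ≈ 0.35;
* a cold immune contexture: 60% FOXL2+ cells, 25% stromal, 10% immune
  (macrophage-dominated, sparse lymphocytes), 3% endothelial, 2%
  unassignable — so the assigned fraction is 98% by design;
* spatial structure as disc unions: collagen blobs (default 30% area
  fraction), small CD31+ vessel discs placed clear of collagen and
  hemorrhage, optional DNA-void hemorrhage discs; FOXL2+COL1A1− tumor
  cells placed as Thomas-process clusters (nests) in the tumor region,
  collagen-resident phenotypes inside collagen, endothelium in vessels,
  immune cells anywhere viable. Cells keep a 6 μm margin from compartment
  boundaries so centroid-based compartment assignment is unambiguous;
  ground-truth compartments are evaluated analytically at the final cell
  positions;
* interaction planting: attraction re-places affected cells as Gaussian
  offspring (SD = radius/2) of a random partner-type parent; avoidance
  re-scatters them with hard-core rejection within the exclusion radius;
  `strength` is the affected fraction;
* intensities: log-normal positive population (median e⁴ ≈ 55, σ = 0.35
  log-units) vs log-normal background (median 1, σ = 0.25), a ≥ 4
  log-unit separation chosen so automatic gating has effectively zero
  error at cohort scale — validation failures then indicate logic errors,
  not marginal thresholds. PR positivity is planted at 0.45 among
  FOXL2+COL1A1+ vs 0.25 among FOXL2+COL1A1− cells (ERα 0.10/0.08),
  reproducing the collagen-associated PR enrichment pattern
  qualitatively;
* rendering: per-channel rasters with log-normal background noise;
  COL1A1/FOXL2/CD31 as continuous textures over their true regions; DNA
  as a baseline (2.0) over viable tissue plus a disc per cell, exactly
  zero in hemorrhage; each cell's positive markers painted as 4 μm discs
  carrying the cell's tabulated intensity;
* randomness: one master seed; every sample and ROI uses the substream
  `default_rng([seed, stream, sample_idx, roi_idx])`, so outputs are
  byte-identical across runs and independent of generation order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: raw ion-count noise, channel spillover and
ablation artifacts; touching/overlapping cells and segmentation errors;
marker populations with genuinely overlapping intensity distributions
(real gating needs curated thresholds); irregular (non-disc) compartment
geometry, collagen fiber texture; spatial covariation between phenotype
frequencies and position beyond the planted structure. Results on real
IMC exports therefore depend on the quality of the upstream segmentation
and on reviewing the fitted thresholds.

## Problem sizes used in validation

The test-suite and acceptance-script runs use deliberately scaled
problems chosen to keep the full validation loop interactive while
leaving every statistical check well-powered: permutation-null
calibration on 20–100 ROIs of 2,000 cells (n_perm = 1,000), planted
recovery on 20–50 ROIs of 1,000 cells, segmentation on 400 × 400 μm ROIs,
threshold recovery on 100 replicates of 40-sample cohorts (40 rather than
the study-scale 23, where ~3% of random cohorts draw too few
high-fraction samples for any method to see a second mode), and gating
fidelity on a 48,000-cell cohort. All sizes are configurable.

## Known limitations

* The gating tree and positivity defaults are a reconstruction; real
  panels require reviewing both.
* The valley method needs a genuinely bimodal cohort; small cohorts can
  be unimodal by chance, in which case a manual threshold must be
  supplied (the error says so).
* Compartment segmentation is threshold-based; it assumes compartment
  markers with clear foreground/background contrast.
* The table-only compartment fallback cannot represent excluded regions
  or area-based quantities.
* Wilcoxon exact mode requires tie-free data; with ties the normal
  approximation is used regardless of sample size.
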