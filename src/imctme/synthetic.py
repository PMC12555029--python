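"""Synthetic cohort generator with known ground truth.

Generates cohorts of segmented-cell tables, sample metadata, and (on
demand) multichannel ROI rasters that emulate the statistical structure the
downstream analysis assumes:

* ~2-6 ROIs per sample, configurable cells per ROI, square ROIs
  (default side 1000 um — 1-mm^2 regions at ~1 um pixels);
* a bimodal across-sample distribution of the per-sample fraction of
  FOXL2+COL1A1+ cells among all FOXL2+ cells (two-component Gaussian
  mixture, the generative definition of the AGCT-1/AGCT-2 subtypes);
* a "cold", macrophage-dominated immune contexture with sparse lymphocytes;
* collagen-rich versus pure-tumor spatial regions (random disc blobs),
  small CD31+ vessel regions and optional DNA-void hemorrhage regions;
* planted cell-cell colocalization (Thomas-type parent/offspring
  displacement) and avoidance (hard-core thinning) patterns;
* a log-normal positive/background intensity model per marker, separated by
  ~4 log-units by default so that default gating is unambiguous.

Randomness: one master seed; each sample and ROI draws from an independent
substream ``default_rng([master_seed, stream, index...])`` so generation is
reproducible regardless of ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import compartments as comp
from .errors import ConfigurationError
from .io import RoiImage, write_cell_table, write_sample_meta
from .panel import MarkerPanel, default_panel

log = logging.getLogger(__name__)

FOXL2_COMBINED = "FOXL2+"          # split per sample into the two classes below
FOXL2_TUMOR = "FOXL2+COL1A1-"
FOXL2_COLLAGEN = "FOXL2+COL1A1+"

IMMUNE_PHENOTYPES = (
    "M0_macrophage", "M2_macrophage", "CD8_T", "CD4_T", "Treg", "neutrophil",
    "B_cell", "memory_B", "DC", "NK", "myeloid", "undefined_CD45",
)

#: cold, macrophage-dominated immune contexture; FOXL2+ cells dominant
DEFAULT_PHENOTYPE_FREQUENCIES: dict[str, float] = {
    FOXL2_COMBINED: 0.60,
    "COL1A1+aSMA+": 0.08,
    "COL1A1+": 0.10,
    "aSMA+": 0.05,
    "other_stromal": 0.02,
    "M0_macrophage": 0.045,
    "M2_macrophage": 0.025,
    "CD8_T": 0.010,
    "CD4_T": 0.008,
    "neutrophil": 0.005,
    "B_cell": 0.002,
    "undefined_CD45": 0.005,
    "endothelial": 0.030,
    "unassigned": 0.020,
}

#: markers each phenotype expresses (besides the DNA channels all cells get)
PHENOTYPE_SIGNATURES: dict[str, tuple[str, ...]] = {
    FOXL2_TUMOR: ("FOXL2", "SF1", "Calretinin", "InhibinA", "CD56"),
    FOXL2_COLLAGEN: ("FOXL2", "SF1", "Calretinin", "InhibinA", "CD56",
                     "COL1A1", "FAP"),
    "COL1A1+aSMA+": ("COL1A1", "aSMA", "Vimentin"),
    "COL1A1+": ("COL1A1", "Vimentin"),
    "aSMA+": ("aSMA",),
    "other_stromal": ("Vimentin", "S100A4", "PDGFRa", "PDGFRb"),
    "endothelial": ("CD31",),
    "M0_macrophage": ("CD45", "CD68", "CD11b"),
    "M2_macrophage": ("CD45", "CD68", "CD163", "CD11b"),
    "CD8_T": ("CD45", "CD8a", "CD45RO"),
    "CD4_T": ("CD45", "CD4"),
    "Treg": ("CD45", "CD4", "FOXP3", "CD25"),
    "neutrophil": ("CD45", "CD66b", "CD11b"),
    "B_cell": ("CD45", "CD20"),
    "memory_B": ("CD45", "CD20", "CD11b"),
    "DC": ("CD45", "CD123"),
    "NK": ("CD45", "CD56"),
    "myeloid": ("CD45", "CD33"),
    "undefined_CD45": ("CD45",),
    "unassigned": (),
}

RECURRENT_SITES = ("abdomen_pelvis", "spleen", "liver", "large_bowel", "ovary")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MarkerIntensity:
    """Log-normal positive population vs log-normal background (log-scale
    location/scale); the default 4-log-unit separation makes marker gating
    unambiguous so tests exercise logic, not marginal thresholds."""

    pos_mean_log: float = 4.0
    pos_sd_log: float = 0.35
    bg_mean_log: float = 0.0
    bg_sd_log: float = 0.25


@dataclass
class SubtypeMix:
    """Two-component Gaussian mixture for the per-sample FOXL2+COL1A1+
    fraction (truncated to (0, 1)).  ``weight_low`` is the probability of
    the low-fraction component (the AGCT-1-like mode)."""

    mean_low: float = 0.15
    mean_high: float = 0.55
    sd_low: float = 0.05
    sd_high: float = 0.05
    weight_low: float = 15 / 23

    def validate(self) -> None:
        for name in ("mean_low", "mean_high", "weight_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"subtype_mix.{name} must be in [0, 1]")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ConfigurationError("subtype_mix spreads must be > 0")


@dataclass
class InteractionRule:
    """One planted spatial pattern between two phenotypes."""

    type_a: str
    type_b: str
    mode: str = "attract"          # attract | avoid | neutral
    strength: float = 1.0          # fraction of type_b cells affected
    radius_um: float = 15.0        # cluster / exclusion radius

    def validate(self) -> None:
        if self.mode not in ("attract", "avoid", "neutral"):
            raise ConfigurationError(
                f"interaction rule ({self.type_a}, {self.type_b}): unknown "
                f"mode {self.mode!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ConfigurationError(
                f"interaction rule ({self.type_a}, {self.type_b}): strength "
                f"{self.strength} outside [0, 1]")
        if self.radius_um <= 0:
            raise ConfigurationError(
                f"interaction rule ({self.type_a}, {self.type_b}): radius "
                "must be > 0")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Defaults emulate the cohort structure of a two-dozen-sample granulosa
    cell tumor study: 23 evaluable samples (8 primary, 15 recurrent), up to
    six 1 x 1 mm ROIs per sample, and a bimodal subtype-fraction mixture.
    """

    n_samples: int = 23
    n_primary: int = 8
    rois_per_sample: tuple[int, int] = (2, 6)
    cells_per_roi: tuple[int, int] = (3000, 9000)
    roi_side_um: float = 1000.0
    pixel_size_um: float = 1.0
    subtype_mix: SubtypeMix = field(default_factory=SubtypeMix)
    phenotype_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_FREQUENCIES))
    immune_fraction: float | None = None
    interaction_plan: list[InteractionRule] = field(default_factory=list)
    intensity_model: dict[str, MarkerIntensity] = field(default_factory=dict)
    default_intensity: MarkerIntensity = field(default_factory=MarkerIntensity)
    # spatial structure
    collagen_area_fraction: float = 0.30
    collagen_blob_radius_um: float = 120.0
    n_vessels: int = 3
    vessel_radius_um: float = 20.0
    hemorrhage_per_roi: int = 0
    hemorrhage_radius_um: float = 80.0
    cell_radius_um: float = 4.0
    boundary_margin_um: float = 6.0
    tumor_cluster_sigma_um: float = 30.0
    tumor_cells_per_cluster: float = 80.0
    # hormone-receptor model: per FOXL2 class, (P(PR+), P(ERa+)); PR
    # enriched in the collagen-embedded class
    hormone_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {FOXL2_TUMOR: (0.25, 0.08),
                                 FOXL2_COLLAGEN: (0.45, 0.10)})
    ki67_fraction: float = 0.10
    seed: int = 0

    # ------------------------------------------------------------------
    def normalized_frequencies(self) -> dict[str, float]:
        freqs = dict(self.phenotype_frequencies)
        if self.immune_fraction is not None:
            immune = {k: v for k, v in freqs.items() if k in IMMUNE_PHENOTYPES}
            current = sum(immune.values())
            other = 1.0 - current
            if current <= 0 or other <= 0:
                raise ConfigurationError(
                    "immune_fraction override needs immune and non-immune mass")
            for k in immune:
                freqs[k] *= self.immune_fraction / current
            scale = (1.0 - self.immune_fraction) / other
            for k in freqs:
                if k not in IMMUNE_PHENOTYPES:
                    freqs[k] *= scale
        return freqs

    def phenotype_labels(self) -> list[str]:
        labels = []
        for k in self.normalized_frequencies():
            if k == FOXL2_COMBINED:
                labels += [FOXL2_TUMOR, FOXL2_COLLAGEN]
            else:
                labels.append(k)
        return labels

    def validate(self) -> None:
        freqs = self.normalized_frequencies()
        if any(not 0 <= v <= 1 for v in freqs.values()):
            raise ConfigurationError("phenotype frequencies must be in [0, 1]")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype_frequencies must sum to 1 (got {total!r})")
        unknown = [k for k in freqs
                   if k != FOXL2_COMBINED and k not in PHENOTYPE_SIGNATURES]
        if unknown:
            raise ConfigurationError(
                f"phenotype_frequencies names unknown phenotype(s): {unknown}")
        if not 0 <= self.n_primary <= self.n_samples:
            raise ConfigurationError("need 0 <= n_primary <= n_samples")
        if self.roi_side_um <= 0:
            raise ConfigurationError("roi_side_um must be > 0")
        if self.rois_per_sample[0] < 1 or self.rois_per_sample[0] > self.rois_per_sample[1]:
            raise ConfigurationError("invalid rois_per_sample range")
        if self.cells_per_roi[0] < 1 or self.cells_per_roi[0] > self.cells_per_roi[1]:
            raise ConfigurationError("invalid cells_per_roi range")
        if not 0 <= self.collagen_area_fraction < 1:
            raise ConfigurationError("collagen_area_fraction must be in [0, 1)")
        self.subtype_mix.validate()
        known = set(self.phenotype_labels())
        for rule in self.interaction_plan:
            rule.validate()
            for t in (rule.type_a, rule.type_b):
                if t not in known:
                    raise ConfigurationError(
                        f"interaction_plan entry ({rule.type_a!r}, "
                        f"{rule.type_b!r}, {rule.mode!r}) references unknown "
                        f"phenotype {t!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["rois_per_sample"] = list(self.rois_per_sample)
        d["cells_per_roi"] = list(self.cells_per_roi)
        d["hormone_model"] = {k: list(v) for k, v in self.hormone_model.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "subtype_mix" in d and isinstance(d["subtype_mix"], dict):
            d["subtype_mix"] = SubtypeMix(**d["subtype_mix"])
        if "default_intensity" in d and isinstance(d["default_intensity"], dict):
            d["default_intensity"] = MarkerIntensity(**d["default_intensity"])
        if "intensity_model" in d:
            d["intensity_model"] = {
                k: MarkerIntensity(**v) if isinstance(v, dict) else v
                for k, v in d["intensity_model"].items()}
        if "interaction_plan" in d:
            d["interaction_plan"] = [
                InteractionRule(**r) if isinstance(r, dict) else r
                for r in d["interaction_plan"]]
        for key in ("rois_per_sample", "cells_per_roi"):
            if key in d:
                d[key] = tuple(d[key])
        if "hormone_model" in d:
            d["hormone_model"] = {k: tuple(v) for k, v in d["hormone_model"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# ROI geometry and ground truth
# ---------------------------------------------------------------------------

@dataclass
class RoiGeometry:
    """Analytic compartment geometry of one ROI (disc unions)."""

    side_um: float
    collagen_disks: np.ndarray      # (K, 3): x, y, r
    vessel_disks: np.ndarray
    hemorrhage_disks: np.ndarray

    @staticmethod
    def _in_disks(pts: np.ndarray, disks: np.ndarray, grow: float = 0.0) -> np.ndarray:
        inside = np.zeros(len(pts), dtype=bool)
        for x, y, r in disks:
            rr = r + grow
            if rr <= 0:
                continue
            inside |= ((pts[:, 0] - x) ** 2 + (pts[:, 1] - y) ** 2) <= rr * rr
        return inside

    def label_at(self, pts: np.ndarray) -> np.ndarray:
        """Compartment codes with precedence excluded > collagen > tumor
        (non-vessel remainder) > vessel."""
        pts = np.asarray(pts, dtype=float)
        labels = np.full(len(pts), comp.TUMOR, dtype=np.uint8)
        labels[self._in_disks(pts, self.vessel_disks)] = comp.VESSEL
        labels[self._in_disks(pts, self.collagen_disks)] = comp.COLLAGEN_RICH
        labels[self._in_disks(pts, self.hemorrhage_disks)] = comp.EXCLUDED
        return labels

    def rasterize(self, pixel_size_um: float) -> np.ndarray:
        n = int(round(self.side_um / pixel_size_um))
        jj, ii = np.meshgrid(np.arange(n), np.arange(n))
        pts = np.stack([(jj.ravel() + 0.5) * pixel_size_um,
                        (ii.ravel() + 0.5) * pixel_size_um], axis=1)
        return self.label_at(pts).reshape(n, n)


@dataclass
class GroundTruth:
    """Generator bookkeeping used as the acceptance oracle."""

    per_sample: pd.DataFrame        # sample_id, mix_component, drawn/true fraction...
    per_roi: pd.DataFrame           # roi_id, sample_id, n_cells
    roi_geometry: dict[str, RoiGeometry]
    interaction_plan: list[InteractionRule]


# ---------------------------------------------------------------------------
# spatial sampling helpers
# ---------------------------------------------------------------------------

def _sample_in_region(rng: np.random.Generator, n: int, side: float,
                      predicate: Callable[[np.ndarray], np.ndarray],
                      max_rounds: int = 400) -> np.ndarray:
    """Uniform points in {p in [0, side)^2 : predicate(p)} by rejection."""
    if n == 0:
        return np.empty((0, 2))
    out = []
    got = 0
    for _ in range(max_rounds):
        m = min(max(1024, 50 * (n - got)), 200_000)
        cand = rng.uniform(0, side, size=(m, 2))
        keep = cand[predicate(cand)]
        if len(keep):
            out.append(keep[: n - got])
            got += len(out[-1])
        if got >= n:
            return np.concatenate(out)
    log.warning("region sampling fell back to uniform for %d points", n - got)
    out.append(rng.uniform(0, side, size=(n - got, 2)))
    return np.concatenate(out)


def _thomas_in_region(rng: np.random.Generator, n: int, side: float,
                      predicate, sigma: float, per_cluster: float) -> np.ndarray:
    """Thomas-process-style clustered points inside a region: uniform
    parents, Gaussian offspring, rejected outside the region."""
    if n == 0:
        return np.empty((0, 2))
    n_parents = max(1, int(round(n / per_cluster)))
    parents = _sample_in_region(rng, n_parents, side, predicate)
    pts = np.empty((0, 2))
    for _ in range(200):
        need = n - len(pts)
        if need <= 0:
            break
        idx = rng.integers(0, n_parents, size=2 * need)
        cand = parents[idx] + rng.normal(0.0, sigma, size=(2 * need, 2))
        ok = (cand >= 0).all(axis=1) & (cand < side).all(axis=1)
        cand = cand[ok]
        cand = cand[predicate(cand)]
        pts = np.vstack([pts, cand[:need]])
    if len(pts) < n:
        pts = np.vstack([pts, _sample_in_region(rng, n - len(pts), side, predicate)])
    return pts[:n]


# ---------------------------------------------------------------------------
# interaction planting
# ---------------------------------------------------------------------------

def plant_interactions(cells: pd.DataFrame, plan: Sequence[InteractionRule],
                       side_um: float, rng: np.random.Generator | int,
                       phenotype_col: str = "true_phenotype") -> pd.DataFrame:
    """Impose planted attraction/avoidance patterns on positioned cells.

    ``attract``: an affected type_b cell is re-placed as Gaussian offspring
    (sd = radius/2) of a random type_a parent.  ``avoid``: affected type_b
    cells are re-scattered uniformly, rejecting positions within the
    exclusion radius of any type_a cell.  ``neutral``: untouched.  All
    points stay inside the ROI.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = cells.copy()
    xy = out[["x_um", "y_um"]].to_numpy(dtype=float)
    labels = out[phenotype_col].to_numpy()
    for rule in plan:
        rule.validate()
        if rule.mode == "neutral":
            continue
        a_idx = np.flatnonzero(labels == rule.type_a)
        b_idx = np.flatnonzero(labels == rule.type_b)
        if len(a_idx) == 0 or len(b_idx) == 0:
            log.warning("plant_interactions: no %s/%s cells in ROI; rule skipped",
                        rule.type_a, rule.type_b)
            continue
        affected = b_idx[rng.random(len(b_idx)) < rule.strength]
        if len(affected) == 0:
            continue
        a_xy = xy[a_idx]
        if rule.mode == "attract":
            parents = a_xy[rng.integers(0, len(a_xy), size=len(affected))]
            new = parents + rng.normal(0.0, rule.radius_um / 2.0,
                                       size=(len(affected), 2))
            eps = 1e-6
            new = np.clip(new, 0.0, side_um - eps)
            xy[affected] = new
        else:  # avoid — hard-core rejection against type_a positions
            from scipy.spatial import cKDTree

            tree = cKDTree(a_xy)
            placed = np.zeros(len(affected), dtype=bool)
            pos = np.empty((len(affected), 2))
            for _ in range(200):
                todo = np.flatnonzero(~placed)
                if len(todo) == 0:
                    break
                cand = rng.uniform(0, side_um, size=(len(todo), 2))
                d, _i = tree.query(cand, k=1)
                ok = d >= rule.radius_um
                pos[todo[ok]] = cand[ok]
                placed[todo[ok]] = True
            if not placed.all():
                log.warning("avoid rule (%s, %s): %d cells could not honour the "
                            "exclusion radius", rule.type_a, rule.type_b,
                            int((~placed).sum()))
                pos[~placed] = rng.uniform(0, side_um, size=((~placed).sum(), 2))
            xy[affected] = pos
    out["x_um"] = xy[:, 0]
    out["y_um"] = xy[:, 1]
    return out


# ---------------------------------------------------------------------------
# intensity synthesis
# ---------------------------------------------------------------------------

def _marker_params(config: CohortConfig, marker: str) -> MarkerIntensity:
    return config.intensity_model.get(marker, config.default_intensity)


def _draw_intensities(rng: np.random.Generator, config: CohortConfig,
                      panel: MarkerPanel, phenotypes: np.ndarray,
                      pr_pos: np.ndarray, era_pos: np.ndarray) -> np.ndarray:
    n = len(phenotypes)
    markers = panel.names
    X = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        p = _marker_params(config, m)
        X[:, j] = np.exp(rng.normal(p.bg_mean_log, p.bg_sd_log, size=n))
    mcol = {m: j for j, m in enumerate(markers)}

    def set_positive(row_mask: np.ndarray, marker: str) -> None:
        j = mcol[marker]
        k = int(row_mask.sum())
        if k == 0:
            return
        p = _marker_params(config, marker)
        X[row_mask, j] = np.exp(rng.normal(p.pos_mean_log, p.pos_sd_log, size=k))

    all_rows = np.ones(n, dtype=bool)
    for dna in panel.dna_markers:
        set_positive(all_rows, dna)
    for pheno, sig in PHENOTYPE_SIGNATURES.items():
        rows = phenotypes == pheno
        if not rows.any():
            continue
        for marker in sig:
            set_positive(rows, marker)
    foxl2_rows = (phenotypes == FOXL2_TUMOR) | (phenotypes == FOXL2_COLLAGEN)
    set_positive(foxl2_rows & pr_pos, "PR")
    set_positive(foxl2_rows & era_pos, "ERa")
    if config.ki67_fraction > 0:
        prolif = foxl2_rows & (rng.random(n) < config.ki67_fraction)
        set_positive(prolif, "Ki67")
    return X


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _make_geometry(rng: np.random.Generator, config: CohortConfig) -> RoiGeometry:
    side = config.roi_side_um
    r_blob = min(config.collagen_blob_radius_um, side / 4)
    target = config.collagen_area_fraction
    k = max(1, int(round(target * side * side / (np.pi * r_blob ** 2)))) if target > 0 else 0
    collagen = np.empty((k, 3))
    for i in range(k):
        collagen[i] = (*rng.uniform(0.05 * side, 0.95 * side, size=2), r_blob)

    hem = np.empty((config.hemorrhage_per_roi, 3))
    for i in range(config.hemorrhage_per_roi):
        hem[i] = (*rng.uniform(0.2 * side, 0.8 * side, size=2),
                  config.hemorrhage_radius_um)

    def clear_for_vessel(pts):
        grow = config.vessel_radius_um
        return (~RoiGeometry._in_disks(pts, collagen, grow=grow)
                & ~RoiGeometry._in_disks(pts, hem, grow=grow))

    vessels = np.empty((config.n_vessels, 3))
    for i in range(config.n_vessels):
        for _ in range(100):
            c = rng.uniform(0.05 * side, 0.95 * side, size=2)
            if clear_for_vessel(c[None, :])[0]:
                break
        vessels[i] = (*c, config.vessel_radius_um)
    return RoiGeometry(side_um=side, collagen_disks=collagen,
                       vessel_disks=vessels, hemorrhage_disks=hem)


def _place_cells(rng: np.random.Generator, config: CohortConfig,
                 geom: RoiGeometry, phenotypes: np.ndarray) -> np.ndarray:
    """Place each cell inside the region its phenotype occupies, keeping a
    margin from compartment boundaries so that centroid-based compartment
    assignment is unambiguous."""
    side = geom.side_um
    m = config.boundary_margin_um

    def in_bounds(pts):
        return ((pts >= m) & (pts <= side - m)).all(axis=1)

    def no_hem(pts):
        return ~RoiGeometry._in_disks(pts, geom.hemorrhage_disks, grow=m)

    def collagen_interior(pts):
        return (in_bounds(pts) & no_hem(pts)
                & RoiGeometry._in_disks(pts, geom.collagen_disks, grow=-m)
                & ~RoiGeometry._in_disks(pts, geom.vessel_disks, grow=m))

    def tumor_interior(pts):
        return (in_bounds(pts) & no_hem(pts)
                & ~RoiGeometry._in_disks(pts, geom.collagen_disks, grow=m)
                & ~RoiGeometry._in_disks(pts, geom.vessel_disks, grow=m))

    def vessel_interior(pts):
        return (in_bounds(pts) & no_hem(pts)
                & RoiGeometry._in_disks(pts, geom.vessel_disks, grow=-2.0))

    def anywhere(pts):
        return in_bounds(pts) & no_hem(pts)

    region_of = {
        FOXL2_TUMOR: "tumor", FOXL2_COLLAGEN: "collagen",
        "COL1A1+aSMA+": "collagen", "COL1A1+": "collagen",
        "other_stromal": "collagen", "aSMA+": "anywhere",
        "endothelial": "vessel", "unassigned": "anywhere",
    }
    predicates = {"tumor": tumor_interior, "collagen": collagen_interior,
                  "vessel": vessel_interior, "anywhere": anywhere}

    xy = np.empty((len(phenotypes), 2))
    for pheno in np.unique(phenotypes):
        rows = np.flatnonzero(phenotypes == pheno)
        region = region_of.get(pheno, "anywhere")
        if pheno == FOXL2_TUMOR:
            xy[rows] = _thomas_in_region(
                rng, len(rows), side, predicates["tumor"],
                sigma=config.tumor_cluster_sigma_um,
                per_cluster=config.tumor_cells_per_cluster)
        else:
            xy[rows] = _sample_in_region(rng, len(rows), side,
                                         predicates[region])
    return xy


def simulate_cohort(config: CohortConfig,
                    panel: MarkerPanel | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (cell table, sample metadata, ground truth).

    Deterministic for a fixed config+seed; per-cell rows carry
    ``true_phenotype``, ``true_compartment`` and ``true_hormone_class``
    sidecar columns in addition to the standard cell-table schema.
    """
    config.validate()
    panel = panel or default_panel()
    freqs = config.normalized_frequencies()
    foxl2_mass = freqs.get(FOXL2_COMBINED, 0.0)
    other = [(k, v) for k, v in freqs.items() if k != FOXL2_COMBINED]

    meta_rows = []
    sample_rows = []
    roi_rows = []
    cell_frames = []
    geometries: dict[str, RoiGeometry] = {}

    for s in range(config.n_samples):
        srng = np.random.default_rng([config.seed, 1, s])
        sample_id = f"S{s + 1:02d}"
        primary = s < config.n_primary
        meta_rows.append({
            "sample_id": sample_id,
            "condition": "primary" if primary else "recurrent",
            "site": "ovary" if primary else str(srng.choice(RECURRENT_SITES)),
        })
        component = "low" if srng.random() < config.subtype_mix.weight_low else "high"
        mu = (config.subtype_mix.mean_low if component == "low"
              else config.subtype_mix.mean_high)
        sd = (config.subtype_mix.sd_low if component == "low"
              else config.subtype_mix.sd_high)
        f = float(np.clip(srng.normal(mu, sd), 1e-3, 1 - 1e-3))
        n_rois = int(srng.integers(config.rois_per_sample[0],
                                   config.rois_per_sample[1] + 1))
        probs = [foxl2_mass * (1 - f), foxl2_mass * f] + [v for _, v in other]
        names = [FOXL2_TUMOR, FOXL2_COLLAGEN] + [k for k, _ in other]
        probs_arr = np.asarray(probs) / np.sum(probs)

        for r in range(n_rois):
            rng = np.random.default_rng([config.seed, 2, s, r])
            roi_id = f"{sample_id}_R{r + 1}"
            n_cells = int(rng.integers(config.cells_per_roi[0],
                                       config.cells_per_roi[1] + 1))
            geom = _make_geometry(rng, config)
            geometries[roi_id] = geom
            counts = rng.multinomial(n_cells, probs_arr)
            phenotypes = np.repeat(names, counts)
            rng.shuffle(phenotypes)
            xy = _place_cells(rng, config, geom, phenotypes)
            df = pd.DataFrame({
                "cell_id": [f"{roi_id}_C{i:05d}" for i in range(n_cells)],
                "sample_id": sample_id,
                "roi_id": roi_id,
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "true_phenotype": phenotypes,
            })
            if config.interaction_plan:
                df = plant_interactions(df, config.interaction_plan,
                                        geom.side_um, rng)
            pts = df[["x_um", "y_um"]].to_numpy()
            df["true_compartment"] = [comp.LABEL_NAMES[c]
                                      for c in geom.label_at(pts)]
            foxl2_rows = df["true_phenotype"].isin(
                [FOXL2_TUMOR, FOXL2_COLLAGEN]).to_numpy()
            pr_pos = np.zeros(n_cells, dtype=bool)
            era_pos = np.zeros(n_cells, dtype=bool)
            for cls, (p_pr, p_era) in config.hormone_model.items():
                rows = (df["true_phenotype"] == cls).to_numpy()
                pr_pos[rows] = rng.random(rows.sum()) < p_pr
                era_pos[rows] = rng.random(rows.sum()) < p_era
            hormone = np.where(
                pr_pos & era_pos, "PR+ERa+",
                np.where(pr_pos, "PR+ERa-",
                         np.where(era_pos, "PR-ERa+", "PR-ERa-")))
            df["true_hormone_class"] = np.where(foxl2_rows, hormone, "")
            X = _draw_intensities(rng, config, panel,
                                  df["true_phenotype"].to_numpy(),
                                  pr_pos, era_pos)
            for j, mname in enumerate(panel.names):
                df[mname] = X[:, j]
            cell_frames.append(df)
            roi_rows.append({"roi_id": roi_id, "sample_id": sample_id,
                             "n_cells": n_cells})

        sample_rows.append({
            "sample_id": sample_id,
            "mix_component": component,
            "true_subtype": "AGCT-1" if component == "low" else "AGCT-2",
            "drawn_fraction": f,
            "n_rois": n_rois,
        })

    cells = pd.concat(cell_frames, ignore_index=True)
    # reorder: schema columns first, truth sidecars last
    marker_cols = panel.names
    ordered = (["cell_id", "sample_id", "roi_id", "x_um", "y_um"] + marker_cols
               + ["true_phenotype", "true_compartment", "true_hormone_class"])
    cells = cells[ordered]
    meta = pd.DataFrame(meta_rows)
    per_sample = pd.DataFrame(sample_rows)
    # realized fraction bookkeeping (exact, by construction)
    grp = cells.groupby("sample_id")["true_phenotype"]
    n_fc = grp.apply(lambda s: int((s == FOXL2_COLLAGEN).sum()))
    n_fox = grp.apply(lambda s: int(s.isin([FOXL2_TUMOR, FOXL2_COLLAGEN]).sum()))
    per_sample = per_sample.merge(
        pd.DataFrame({"sample_id": n_fc.index,
                      "n_foxl2_col1a1": n_fc.to_numpy(),
                      "n_foxl2": n_fox.to_numpy()}),
        on="sample_id")
    per_sample["true_fraction"] = (per_sample["n_foxl2_col1a1"]
                                   / per_sample["n_foxl2"])
    truth = GroundTruth(per_sample=per_sample,
                        per_roi=pd.DataFrame(roi_rows),
                        roi_geometry=geometries,
                        interaction_plan=list(config.interaction_plan))
    return cells, meta, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_roi_image(cells: pd.DataFrame, geometry: RoiGeometry,
                     panel: MarkerPanel | None = None,
                     channels: Sequence[str] | None = None,
                     pixel_size_um: float = 1.0,
                     config: CohortConfig | None = None,
                     seed: int = 0,
                     dna_baseline: float = 2.0,
                     min_paint_intensity: float = 5.0) -> RoiImage:
    """Render a multichannel raster for one ROI.

    Cell-borne markers are painted as discs at centroids using the cell's
    tabulated intensity; COL1A1 / FOXL2 / CD31 additionally get continuous
    textures over the true collagen / tumor / vessel regions; DNA channels
    get a baseline over viable tissue plus a disc per cell, and are zero in
    hemorrhage regions.
    """
    panel = panel or default_panel()
    config = config or CohortConfig()
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    channels = list(channels) if channels is not None else panel.names
    for c in channels:
        if c not in panel:
            raise ConfigurationError(f"requested channel {c!r} not in panel")
    rng = np.random.default_rng([seed, 3])
    n = int(round(geometry.side_um / pixel_size_um))
    label_raster = geometry.rasterize(pixel_size_um)
    collagen_px = label_raster == comp.COLLAGEN_RICH
    tumor_px = label_raster == comp.TUMOR
    vessel_px = label_raster == comp.VESSEL
    hem_px = label_raster == comp.EXCLUDED

    r_px = max(1, int(round(config.cell_radius_um / pixel_size_um)))
    dy, dx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
    disk = (dy ** 2 + dx ** 2) <= r_px ** 2
    dy, dx = dy[disk], dx[disk]
    rows = np.floor(cells["y_um"].to_numpy(float) / pixel_size_um).astype(int) \
        if len(cells) else np.empty(0, dtype=int)
    cols = np.floor(cells["x_um"].to_numpy(float) / pixel_size_um).astype(int) \
        if len(cells) else np.empty(0, dtype=int)

    def texture(mask: np.ndarray, marker: str) -> np.ndarray:
        p = _marker_params(config, marker)
        k = int(mask.sum())
        vals = np.zeros((n, n), dtype=np.float32)
        vals[mask] = np.exp(rng.normal(p.pos_mean_log, p.pos_sd_log, size=k))
        return vals

    stack = np.empty((len(channels), n, n), dtype=np.float32)
    for ci, marker in enumerate(channels):
        p = _marker_params(config, marker)
        plane = np.exp(rng.normal(p.bg_mean_log, p.bg_sd_log,
                                  size=(n, n))).astype(np.float32)
        if marker == "COL1A1":
            plane = np.maximum(plane, texture(collagen_px, marker))
        elif marker == "FOXL2":
            plane = np.maximum(plane, texture(tumor_px, marker))
        elif marker == "CD31":
            plane = np.maximum(plane, texture(vessel_px, marker))
        elif panel.category_of(marker) == "DNA":
            base = np.full((n, n), dna_baseline, dtype=np.float32)
            base *= rng.uniform(0.8, 1.2, size=(n, n)).astype(np.float32)
            plane = np.maximum(plane, base)
        if len(cells):
            values = cells[marker].to_numpy(float)
            paint = np.flatnonzero(values > min_paint_intensity)
            for i in paint:
                rr = rows[i] + dy
                cc = cols[i] + dx
                ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
                np.maximum.at(plane, (rr[ok], cc[ok]), np.float32(values[i]))
        if panel.category_of(marker) == "DNA":
            plane[hem_px] = 0.0
        stack[ci] = plane
    roi_id = str(cells["roi_id"].iloc[0]) if len(cells) else ""
    sample_id = str(cells["sample_id"].iloc[0]) if len(cells) else ""
    return RoiImage(channels=stack, channel_names=channels,
                    pixel_size_um=pixel_size_um, roi_id=roi_id,
                    sample_id=sample_id)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_cohort(outdir, cells: pd.DataFrame, meta: pd.DataFrame,
                 truth: GroundTruth, config: CohortConfig,
                 panel: MarkerPanel | None = None) -> dict[str, str]:
    """Write cells/metadata/ground-truth CSVs and the config YAML."""
    import os

    panel = panel or default_panel()
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "cells": os.path.join(outdir, "cells.csv"),
        "metadata": os.path.join(outdir, "metadata.csv"),
        "truth_samples": os.path.join(outdir, "truth_samples.csv"),
        "truth_rois": os.path.join(outdir, "truth_rois.csv"),
        "config": os.path.join(outdir, "config.yaml"),
        "panel": os.path.join(outdir, "panel.yaml"),
    }
    write_cell_table(cells, paths["cells"], panel)
    write_sample_meta(meta, paths["metadata"])
    truth.per_sample.to_csv(paths["truth_samples"], index=False)
    truth.per_roi.to_csv(paths["truth_rois"], index=False)
    config.to_yaml(paths["config"])
    panel.to_yaml(paths["panel"])
    return paths
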