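"""Tissue compartment segmentation and cell morphology.

ROIs are partitioned into **tumor** (FOXL2+ staining minus collagen),
**collagen_rich** (COL1A1+ regions of any FOXL2 status, including
fibromatous tumor), **vessel** (CD31+ remainder), **excluded**
(DNA-void regions — hemorrhage / acellular tissue) and **background**.
Precedence when channel masks overlap: excluded > collagen_rich > tumor >
vessel > background.

Per-channel segmentation pipeline: Gaussian smoothing, threshold (Otsu by
default), morphological closing, small-object removal.  Cells are assigned
the compartment of the pixel containing their centroid (floor convention).

Morphology features follow the common definitions used by commercial
histology software: form factor 4*pi*A/P^2, solidity A/A_hull, convexity
P_hull/P, moment-equivalent-ellipse eccentricity and axes, min/max Feret
diameters, and ellipticalness A/(pi*a*b) (area relative to the
moment-equivalent ellipse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure, morphology
from skimage.filters import gaussian, threshold_otsu

from .errors import DataError, DegenerateShapeError, SchemaError
from .io import RoiImage

log = logging.getLogger(__name__)

# compartment label codes (raster values)
BACKGROUND, TUMOR, COLLAGEN_RICH, VESSEL, EXCLUDED = 0, 1, 2, 3, 4
LABEL_NAMES = {
    BACKGROUND: "background",
    TUMOR: "tumor",
    COLLAGEN_RICH: "collagen_rich",
    VESSEL: "vessel",
    EXCLUDED: "excluded",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class SegmentationParams:
    """Tunable parameters of the compartment segmentation pipeline."""

    smooth_sigma_px: float = 2.0
    closing_radius_px: int = 5
    min_area_um2: float = 500.0
    #: fixed per-channel thresholds; channels not listed use Otsu
    fixed_thresholds: Mapping[str, float] = field(default_factory=dict)
    #: DNA-void detection: absolute intensity floor on the smoothed DNA
    #: channel; connected void regions above the minimum area are excluded
    dna_smooth_sigma_px: float = 1.0
    dna_void_threshold: float = 0.5
    min_excluded_area_um2: float = 2000.0
    tumor_marker: str = "FOXL2"
    collagen_marker: str = "COL1A1"
    vessel_marker: str = "CD31"
    dna_markers: Sequence[str] = ("DNA1", "DNA2")


@dataclass
class CompartmentMask:
    """Label raster over ROI pixels; a partition (one label per pixel)."""

    labels: np.ndarray
    pixel_size_um: float
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise DataError("compartment mask must be 2-D")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2

    def area_um2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.pixel_area_um2


@dataclass
class MorphologyFeatures:
    convexity: float
    eccentricity: float
    ellipticalness: float
    form_factor: float
    largest_diameter_um: float
    lesser_diameter_um: float
    major_axis_um: float
    minor_axis_um: float
    perimeter_um: float
    solidity: float


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _channel_mask(channel: np.ndarray, params: SegmentationParams,
                  fixed: float | None) -> np.ndarray:
    sm = gaussian(channel.astype(float), sigma=params.smooth_sigma_px,
                  preserve_range=True)
    if fixed is not None:
        thr = float(fixed)
    else:
        if np.ptp(sm) == 0:
            return np.zeros_like(sm, dtype=bool)
        thr = threshold_otsu(sm)
    mask = sm > thr
    r = params.closing_radius_px
    if r > 0:
        padded = np.pad(mask, r, mode="edge")
        padded = ndimage.binary_closing(padded, structure=morphology.disk(r))
        mask = padded[r:-r, r:-r]
    return mask


def _remove_small(mask: np.ndarray, min_area_um2: float,
                  pixel_area: float) -> np.ndarray:
    min_px = int(np.ceil(min_area_um2 / pixel_area))
    if min_px <= 1:
        return mask
    lab, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def segment_compartments(image: RoiImage,
                         params: SegmentationParams | None = None) -> CompartmentMask:
    """Segment an ROI image into the compartment partition.

    Requires the COL1A1, FOXL2 and CD31 channels plus at least one DNA
    channel; raises :class:`SchemaError` if any is missing.
    """
    params = params or SegmentationParams()
    for name in (params.collagen_marker, params.tumor_marker, params.vessel_marker):
        if not image.has_channel(name):
            raise SchemaError(f"segmentation requires channel {name!r}")
    dna_present = [m for m in params.dna_markers if image.has_channel(m)]
    if not dna_present:
        raise SchemaError(
            f"segmentation requires a DNA channel (one of {list(params.dna_markers)})")
    px_area = image.pixel_size_um ** 2

    # DNA-void (hemorrhage / acellular) regions
    dna = sum(image.channel(m).astype(float) for m in dna_present)
    dna_sm = gaussian(dna, sigma=params.dna_smooth_sigma_px, preserve_range=True)
    void = dna_sm < params.dna_void_threshold
    void = _remove_small(void, params.min_excluded_area_um2, px_area)

    fixed = params.fixed_thresholds
    collagen = _channel_mask(image.channel(params.collagen_marker), params,
                             fixed.get(params.collagen_marker))
    collagen = _remove_small(collagen, params.min_area_um2, px_area)
    foxl2 = _channel_mask(image.channel(params.tumor_marker), params,
                          fixed.get(params.tumor_marker))
    foxl2 = _remove_small(foxl2, params.min_area_um2, px_area)
    vessel = _channel_mask(image.channel(params.vessel_marker), params,
                           fixed.get(params.vessel_marker))
    vessel = _remove_small(vessel, params.min_area_um2, px_area)

    labels = np.full(image.shape, BACKGROUND, dtype=np.uint8)
    labels[vessel] = VESSEL
    labels[foxl2] = TUMOR          # tumor = FOXL2 mask minus collagen (below)
    labels[collagen] = COLLAGEN_RICH
    labels[void] = EXCLUDED
    return CompartmentMask(labels=labels, pixel_size_um=image.pixel_size_um,
                           roi_id=image.roi_id)


def assign_cells_to_compartments(cells: pd.DataFrame,
                                 mask: CompartmentMask) -> pd.DataFrame:
    """Label each cell with the compartment of its centroid pixel.

    Centroid (x, y) in micrometres maps to pixel (floor(y/px), floor(x/px)).
    Cells on excluded pixels are flagged (``excluded`` column) so that
    downstream statistics can drop them.
    """
    h, w = mask.labels.shape
    col = np.floor(cells["x_um"].to_numpy(float) / mask.pixel_size_um).astype(int)
    row = np.floor(cells["y_um"].to_numpy(float) / mask.pixel_size_um).astype(int)
    oob = (row < 0) | (row >= h) | (col < 0) | (col >= w)
    if oob.any():
        bad_id = cells["cell_id"].to_numpy()[oob][0]
        raise DataError(
            f"cell {bad_id!r} centroid outside the {h}x{w} compartment raster")
    codes = mask.labels[row, col]
    out = cells.copy()
    out["compartment"] = [LABEL_NAMES[c] for c in codes]
    out["excluded"] = codes == EXCLUDED
    return out


def assign_compartments_from_markers(cells: pd.DataFrame, positivity) -> pd.DataFrame:
    """Table-only fallback when no images are available.

    Approximates compartments from per-cell positivity with the same
    precedence: collagen_rich (COL1A1+) > tumor (FOXL2+COL1A1-) > vessel
    (CD31+) > background.  Results are approximate relative to pixel masks.
    """
    col = positivity.is_positive(cells, "COL1A1")
    fox = positivity.is_positive(cells, "FOXL2")
    cd31 = positivity.is_positive(cells, "CD31")
    labels = np.where(col, "collagen_rich",
                      np.where(fox, "tumor",
                               np.where(cd31, "vessel", "background")))
    out = cells.copy()
    out["compartment"] = labels
    out["excluded"] = False
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_compartments(cells: pd.DataFrame, mask: CompartmentMask,
                           markers: Sequence[str] = ("COL1A1", "PR", "ERa"),
                           image: RoiImage | None = None) -> dict:
    """Per-ROI areas, densities and mean intensities by compartment.

    * areas: pixel counts x pixel area (um^2)
    * tissue = tumor + collagen_rich + vessel (viable, non-excluded)
    * collagen_fraction = collagen area / tissue area
    * densities in cells/mm^2 over non-excluded cells; empty compartments
      report NaN (missing), not zero
    * mean marker intensities over cells per compartment; collagen pixel
      intensity additionally over collagen-rich pixels when *image* given
    """
    areas = {name: mask.area_um2(code) for code, name in LABEL_NAMES.items()}
    tissue_area = areas["tumor"] + areas["collagen_rich"] + areas["vessel"]
    collagen_fraction = (areas["collagen_rich"] / tissue_area
                         if tissue_area > 0 else float("nan"))

    viable = cells[~cells.get("excluded", pd.Series(False, index=cells.index))]

    def density(n: int, area_um2: float) -> float:
        if area_um2 <= 0:
            return float("nan")
        return n / (area_um2 / 1e6)

    densities = {
        "total_tissue": density(len(viable), tissue_area),
        "tumor": density(int((viable["compartment"] == "tumor").sum()),
                         areas["tumor"]),
        "collagen_rich": density(
            int((viable["compartment"] == "collagen_rich").sum()),
            areas["collagen_rich"]),
    }
    mean_intensity: dict[str, dict[str, float]] = {}
    for marker in markers:
        if marker not in viable.columns:
            continue
        per_comp = {}
        for comp in ("tumor", "collagen_rich"):
            sub = viable.loc[viable["compartment"] == comp, marker]
            per_comp[comp] = float(sub.mean()) if len(sub) else float("nan")
        mean_intensity[marker] = per_comp
    out = {
        "roi_id": mask.roi_id,
        "areas_um2": areas,
        "tissue_area_um2": tissue_area,
        "collagen_fraction": collagen_fraction,
        "density_cells_per_mm2": densities,
        "mean_intensity": mean_intensity,
    }
    if image is not None:
        collagen_px = image.channel("COL1A1")[mask.labels == COLLAGEN_RICH]
        out["collagen_pixel_intensity"] = (
            float(collagen_px.mean()) if collagen_px.size else float("nan"))
    return out


def summaries_to_frame(summaries: Sequence[dict]) -> pd.DataFrame:
    """Flatten per-ROI summaries to one row per ROI x compartment."""
    rows = []
    for s in summaries:
        for comp, area in s["areas_um2"].items():
            rows.append({
                "roi_id": s["roi_id"],
                "compartment": comp,
                "area_um2": area,
                "collagen_fraction": s["collagen_fraction"],
                "density_cells_per_mm2": s["density_cells_per_mm2"].get(comp,
                                                                        np.nan),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------

def write_compartment_mask(mask: CompartmentMask, path) -> None:
    """Write a label mask as a single-page TIFF plus a JSON legend
    (``<path>.json``) mapping label codes to compartment names."""
    import json

    import tifffile

    tifffile.imwrite(path, mask.labels, photometric="minisblack",
                     description=json.dumps({
                         "legend": {str(k): v for k, v in LABEL_NAMES.items()},
                         "pixel_size_um": mask.pixel_size_um,
                         "roi_id": mask.roi_id,
                     }))
    with open(f"{path}.json", "w") as fh:
        json.dump({str(k): v for k, v in LABEL_NAMES.items()}, fh, indent=2)


def read_compartment_mask(path) -> CompartmentMask:
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return CompartmentMask(labels=labels,
                           pixel_size_um=float(meta["pixel_size_um"]),
                           roi_id=str(meta.get("roi_id", "")))


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def _hull_geometry(region_mask: np.ndarray) -> tuple[float, float, float]:
    """(hull perimeter, max Feret, min Feret) from pixel-corner hull, px."""
    rows, cols = np.nonzero(region_mask)
    corners = np.concatenate([
        np.stack([rows - 0.5, cols - 0.5], axis=1),
        np.stack([rows - 0.5, cols + 0.5], axis=1),
        np.stack([rows + 0.5, cols - 0.5], axis=1),
        np.stack([rows + 0.5, cols + 0.5], axis=1),
    ])
    hull = ConvexHull(corners)
    pts = corners[hull.vertices]
    diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    hull_perim = float(np.sqrt((diffs ** 2).sum(axis=1)).sum())
    # max Feret: maximum pairwise distance between hull vertices
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    feret_max = float(np.sqrt(d2.max()))
    # min Feret: rotating calipers — minimal width over hull edge normals
    edges = diffs / np.sqrt((diffs ** 2).sum(axis=1, keepdims=True))
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1)
    proj = pts @ normals.T                     # (n_pts, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    feret_min = float(widths.min())
    return hull_perim, feret_max, feret_min


def compute_morphology(region_mask: np.ndarray,
                       pixel_size_um: float = 1.0) -> MorphologyFeatures:
    """Morphology features of one connected pixel region (>= 4 pixels)."""
    region_mask = np.asarray(region_mask, dtype=bool)
    n_px = int(region_mask.sum())
    if n_px < 4:
        raise DegenerateShapeError(
            f"region has {n_px} pixels; morphology needs >= 4")
    lab, n_comp = ndimage.label(region_mask)
    if n_comp != 1:
        raise DataError(f"region mask has {n_comp} connected components; expected 1")
    props = measure.regionprops(lab)[0]
    area = props.area                      # px^2
    perim = props.perimeter                # px
    if perim == 0:
        raise DegenerateShapeError("region perimeter is zero")
    hull_perim, feret_max, feret_min = _hull_geometry(region_mask)
    major = props.axis_major_length
    minor = props.axis_minor_length
    ellipse_area = np.pi * (major / 2) * (minor / 2)
    px = pixel_size_um
    return MorphologyFeatures(
        convexity=float(hull_perim / perim),
        eccentricity=float(props.eccentricity),
        ellipticalness=float(area / ellipse_area) if ellipse_area > 0 else float("nan"),
        form_factor=float(4 * np.pi * area / perim ** 2),
        largest_diameter_um=feret_max * px,
        lesser_diameter_um=feret_min * px,
        major_axis_um=major * px,
        minor_axis_um=minor * px,
        perimeter_um=perim * px,
        solidity=float(props.solidity),
    )
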