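"""Supervised cell phenotyping.

Cells are assigned lineage labels by walking an ordered gating hierarchy of
marker-positivity predicates (first matching sibling wins, depth first).
Positivity is decided per marker by comparing the raw intensity against a
threshold fitted on arcsinh-transformed, percentile-clipped intensities —
either Otsu's criterion per marker or user-fixed values.  Ties at the
threshold count as negative, so gating is deterministic and invariant under
any strictly monotone transform applied jointly to intensities and
thresholds.

The default tree shipped with the package is a reconstruction of a typical
granulosa-cell-tumor lineage assignment strategy (DNA+ required, then
endothelium, the CD45+ immune subtree, the FOXL2+ branch split by COL1A1,
then stromal classes) and is fully overridable via YAML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    ContractViolationError,
    DegenerateDistributionError,
)
from .io import HORMONE_LABELS
from .panel import MarkerPanel

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# gating tree
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    """One gate: a conjunction of marker signs, leading to a leaf label or
    to an ordered list of child gates."""

    terms: list[tuple[str, bool]] = field(default_factory=list)  # (marker, positive)
    label: str | None = None
    children: list["GateNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return self.label is not None


@dataclass
class GatingTree:
    """Ordered hierarchy of marker-positivity gates.

    Every cell reaches exactly one leaf: gates are tried in order, the
    first whose conjunction holds is descended into, and cells matching no
    gate at the root fall through to ``default_label``.
    """

    root_children: list[GateNode]
    default_label: str = UNASSIGNED

    # -- validation ------------------------------------------------------
    def validate(self, panel: MarkerPanel) -> None:
        labels: list[str] = []

        def walk(node: GateNode, depth: int) -> None:
            if depth > 32:
                raise ConfigurationError("gating tree deeper than 32 levels (cycle?)")
            for marker, _ in node.terms:
                if marker not in panel:
                    raise ConfigurationError(
                        f"gating tree references unknown marker {marker!r}"
                    )
            if node.is_leaf() and node.children:
                raise ConfigurationError(
                    f"gate with label {node.label!r} also has children"
                )
            if node.is_leaf():
                labels.append(node.label)  # type: ignore[arg-type]
            elif node.children:
                for child in node.children:
                    walk(child, depth + 1)
            else:
                raise ConfigurationError("gate has neither label nor children")

        for child in self.root_children:
            walk(child, 0)
        labels.append(self.default_label)
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise ConfigurationError(f"duplicate leaf label(s) in gating tree: {dupes}")

    @property
    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: GateNode) -> None:
            if node.is_leaf():
                out.append(node.label)  # type: ignore[arg-type]
            for child in node.children:
                walk(child)

        for child in self.root_children:
            walk(child)
        out.append(self.default_label)
        return out

    @property
    def markers_used(self) -> list[str]:
        out: set[str] = set()

        def walk(node: GateNode) -> None:
            out.update(m for m, _ in node.terms)
            for child in node.children:
                walk(child)

        for child in self.root_children:
            walk(child)
        return sorted(out)

    # -- (de)serialization ----------------------------------------------
    @classmethod
    def from_dict(cls, payload: Mapping, panel: MarkerPanel) -> "GatingTree":
        if not isinstance(payload, Mapping) or "nodes" not in payload:
            raise ConfigurationError("gating YAML must contain a 'nodes' list")

        def parse(node: Mapping) -> GateNode:
            terms = []
            for marker, sign in (node.get("when") or {}).items():
                if sign not in ("+", "-"):
                    raise ConfigurationError(
                        f"gate sign for {marker!r} must be '+' or '-', got {sign!r}"
                    )
                terms.append((str(marker), sign == "+"))
            label = node.get("label")
            children = [parse(c) for c in node.get("children", [])]
            return GateNode(terms=terms, label=label, children=children)

        tree = cls(
            root_children=[parse(n) for n in payload["nodes"]],
            default_label=str(payload.get("default_label", UNASSIGNED)),
        )
        tree.validate(panel)
        return tree

    def to_dict(self) -> dict:
        def dump(node: GateNode) -> dict:
            out: dict = {"when": {m: ("+" if pos else "-") for m, pos in node.terms}}
            if node.is_leaf():
                out["label"] = node.label
            else:
                out["children"] = [dump(c) for c in node.children]
            return out

        return {
            "default_label": self.default_label,
            "nodes": [dump(n) for n in self.root_children],
        }


#: Default lineage assignment hierarchy (first-match-wins).  A
#: reconstruction from canonical marker combinations; override via YAML for
#: other panels.
DEFAULT_GATING = {
    "default_label": UNASSIGNED,
    "nodes": [
        {"when": {"DNA1": "-", "DNA2": "-"}, "label": "non_cell"},
        {"when": {"CD31": "+"}, "label": "endothelial"},
        {
            "when": {"CD45": "+"},
            "children": [
                {"when": {"CD68": "+", "CD163": "+"}, "label": "M2_macrophage"},
                {"when": {"CD68": "+"}, "label": "M0_macrophage"},
                {"when": {"CD4": "+", "FOXP3": "+"}, "label": "Treg"},
                {"when": {"CD8a": "+"}, "label": "CD8_T"},
                {"when": {"CD4": "+"}, "label": "CD4_T"},
                {"when": {"CD66b": "+", "CD11b": "+"}, "label": "neutrophil"},
                {"when": {"CD20": "+", "CD11b": "+"}, "label": "memory_B"},
                {"when": {"CD20": "+"}, "label": "B_cell"},
                {"when": {"CD123": "+"}, "label": "DC"},
                {"when": {"CD56": "+"}, "label": "NK"},
                {"when": {"CD33": "+"}, "label": "myeloid"},
                {"when": {}, "label": "undefined_CD45"},
            ],
        },
        {
            "when": {"FOXL2": "+"},
            "children": [
                {"when": {"COL1A1": "+"}, "label": "FOXL2+COL1A1+"},
                {"when": {}, "label": "FOXL2+COL1A1-"},
            ],
        },
        {"when": {"COL1A1": "+", "aSMA": "+"}, "label": "COL1A1+aSMA+"},
        {"when": {"COL1A1": "+"}, "label": "COL1A1+"},
        {"when": {"aSMA": "+"}, "label": "aSMA+"},
        {"when": {"Vimentin": "+"}, "label": "other_stromal"},
    ],
}


#: major cell groups used for composition plots and balanced embeddings
IMMUNE_LEAVES = frozenset({
    "M0_macrophage", "M2_macrophage", "Treg", "CD8_T", "CD4_T", "neutrophil",
    "memory_B", "B_cell", "DC", "NK", "myeloid", "undefined_CD45",
})
STROMAL_LEAVES = frozenset({"COL1A1+aSMA+", "COL1A1+", "aSMA+", "other_stromal"})


def major_group(phenotype: str) -> str:
    """Collapse a lineage label to its major cell group."""
    if phenotype in ("FOXL2+COL1A1-", "FOXL2+COL1A1+", "endothelial"):
        return phenotype
    if phenotype in IMMUNE_LEAVES:
        return "immune"
    if phenotype in STROMAL_LEAVES:
        return "stromal"
    return UNASSIGNED


def default_gating_tree(panel: MarkerPanel) -> GatingTree:
    return GatingTree.from_dict(DEFAULT_GATING, panel)


def load_packaged_gating(panel: MarkerPanel) -> GatingTree:
    ref = resources.files("imctme") / "data" / "gating_default.yaml"
    with resources.as_file(ref) as path:
        with open(path) as fh:
            return GatingTree.from_dict(yaml.safe_load(fh), panel)


# ---------------------------------------------------------------------------
# positivity model
# ---------------------------------------------------------------------------

@dataclass
class PositivityModel:
    """Per-marker positivity thresholds.

    Thresholds are stored on the raw intensity scale (back-transformed from
    the arcsinh scale they were fitted on); a cell is positive iff its raw
    intensity is strictly greater than the threshold.
    """

    thresholds: dict[str, float]
    cofactor: float = 1.0
    clip_percentile: float = 99.5
    method: str = "otsu"

    def __post_init__(self) -> None:
        if self.cofactor <= 0:
            raise ConfigurationError("arcsinh cofactor must be > 0")
        for marker, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ConfigurationError(f"non-finite threshold for {marker!r}")

    def transform(self, values: np.ndarray) -> np.ndarray:
        return np.arcsinh(np.asarray(values, dtype=float) / self.cofactor)

    def is_positive(self, cells: pd.DataFrame, marker: str) -> np.ndarray:
        if marker not in self.thresholds:
            raise ConfigurationError(f"no positivity threshold for marker {marker!r}")
        return cells[marker].to_numpy(dtype=float) > self.thresholds[marker]


def _otsu_threshold(values: np.ndarray) -> float:
    """Otsu's criterion on a 1-D sample (256-bin exhaustive search)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(values, nbins=256))


def _smoothed_histogram(x: np.ndarray, n_bins: int = 512
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Binned Gaussian-smoothed density (Silverman bandwidth)."""
    from scipy.ndimage import gaussian_filter1d

    lo, hi = float(x.min()), float(x.max())
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    sd = float(np.std(x, ddof=1))
    bw = 0.9 * sd * len(x) ** (-1 / 5)
    bin_width = (hi - lo) / n_bins
    dens = gaussian_filter1d(counts.astype(float),
                             sigma=max(bw / bin_width, 1.0), mode="constant")
    return centers, dens


def _arcsinh_threshold(x: np.ndarray, min_separation: float,
                       high_level: float, marker: str) -> float:
    """Threshold on the arcsinh scale.

    Otsu when it cleanly bisects two populations (class means separated by
    at least *min_separation*); otherwise the density valley between the
    outermost pair of sufficiently separated modes (rescues markers whose
    positive population is rare, where Otsu splits the background);
    otherwise the marker is unimodal and every cell is called positive or
    negative depending on whether the typical level exceeds *high_level*.
    """
    centers, dens = _smoothed_histogram(x)
    peaks = [i for i in range(len(dens))
             if dens[i] > 0
             and (i == 0 or dens[i] >= dens[i - 1])
             and (i == len(dens) - 1 or dens[i] > dens[i + 1])]
    if len(peaks) >= 2:
        # the two highest modes at least min_separation apart: the
        # background and positive populations
        by_height = sorted(peaks, key=lambda i: dens[i], reverse=True)
        main = by_height[0]
        partner = next((i for i in by_height[1:]
                        if abs(centers[i] - centers[main]) >= min_separation),
                       None)
        if partner is not None:
            lo_i, hi_i = sorted((main, partner))
            interior = dens[lo_i + 1:hi_i]
            at_min = np.flatnonzero(interior == interior.min())
            valley = lo_i + 1 + int(at_min[len(at_min) // 2])  # plateau center
            return float(centers[valley])
    t = _otsu_threshold(x)
    lower, upper = x[x <= t], x[x > t]
    if len(lower) and len(upper) and upper.mean() - lower.mean() >= min_separation:
        return t
    log.info("marker %r: unimodal intensity distribution; calling all cells "
             "%s", marker,
             "positive" if np.median(x) > high_level else "negative")
    if np.median(x) > high_level:
        return float(x.min() - 1.0)
    return float(x.max() + 1.0)


def fit_positivity(
    cells: pd.DataFrame,
    panel: MarkerPanel,
    method: str = "otsu",
    fixed: Mapping[str, float] | None = None,
    cofactor: float = 1.0,
    clip_percentile: float = 99.5,
    min_separation: float = 2.0,
    high_level: float = 2.5,
) -> PositivityModel:
    """Fit per-marker positivity thresholds.

    ``method='otsu'`` thresholds arcsinh-transformed, percentile-clipped
    intensities per marker by Otsu's criterion, guarded against unimodal
    distributions: markers whose two Otsu classes are separated by less
    than *min_separation* arcsinh units fall back to a density-valley cut
    (rare-positive markers) or, failing that, to an all-positive /
    all-negative call by comparing the median level to *high_level*
    (markers expressed by essentially every cell, such as DNA
    intercalators, versus markers absent from the tissue).
    ``method='fixed'`` takes thresholds (raw intensity scale) from *fixed*.
    """
    if method == "fixed":
        if fixed is None:
            raise ConfigurationError("method='fixed' requires a threshold map")
        return PositivityModel(
            thresholds={m: float(t) for m, t in fixed.items()},
            cofactor=cofactor,
            clip_percentile=clip_percentile,
            method="fixed",
        )
    if method != "otsu":
        raise ConfigurationError(f"unknown positivity method {method!r}")
    thresholds: dict[str, float] = {}
    for marker in panel.names:
        raw = cells[marker].to_numpy(dtype=float)
        x = np.arcsinh(raw / cofactor)
        x = np.minimum(x, np.percentile(x, clip_percentile))
        if np.ptp(x) == 0:
            raise DegenerateDistributionError(
                f"marker {marker!r} has constant intensity; cannot fit Otsu "
                "threshold (use method='fixed')"
            )
        t_arcsinh = _arcsinh_threshold(x, min_separation, high_level, marker)
        thresholds[marker] = float(np.sinh(t_arcsinh) * cofactor)
    return PositivityModel(
        thresholds=thresholds,
        cofactor=cofactor,
        clip_percentile=clip_percentile,
        method="otsu",
    )


# ---------------------------------------------------------------------------
# lineage assignment
# ---------------------------------------------------------------------------

def assign_lineages(
    cells: pd.DataFrame,
    tree: GatingTree,
    positivity: PositivityModel,
    unassigned_labels: Iterable[str] = (UNASSIGNED, "non_cell"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each cell exactly one leaf label of *tree*.

    Returns ``(cells_with_phenotype, summary)`` where *summary* has one row
    per label (count, fraction) plus an ``assigned_fraction`` attribute in
    ``summary.attrs`` (labels in *unassigned_labels* count as unassigned).
    """
    for marker in tree.markers_used:
        if marker not in positivity.thresholds:
            raise ConfigurationError(
                f"positivity model lacks a threshold for gated marker {marker!r}"
            )
    n = len(cells)
    pos_cache = {m: positivity.is_positive(cells, m) for m in tree.markers_used}
    labels = np.full(n, tree.default_label, dtype=object)
    assigned = np.zeros(n, dtype=bool)

    def walk(node: GateNode, mask: np.ndarray) -> None:
        here = mask.copy()
        for marker, want_pos in node.terms:
            here &= pos_cache[marker] if want_pos else ~pos_cache[marker]
            if not here.any():
                return
        if node.is_leaf():
            labels[here] = node.label
            assigned[here] = True
        else:
            remaining = here
            for child in node.children:
                walk(child, remaining & ~assigned)

    for child in tree.root_children:
        walk(child, ~assigned)

    out = cells.copy()
    out["phenotype"] = labels
    counts = out["phenotype"].value_counts()
    summary = pd.DataFrame(
        {"phenotype": counts.index, "count": counts.to_numpy()}
    )
    summary["fraction"] = summary["count"] / max(n, 1)
    unas = set(unassigned_labels)
    assigned_fraction = float(
        summary.loc[~summary["phenotype"].isin(unas), "count"].sum() / max(n, 1)
    )
    summary.attrs["assigned_fraction"] = assigned_fraction
    return out, summary


# ---------------------------------------------------------------------------
# hormone-receptor quadrants
# ---------------------------------------------------------------------------

def classify_hormone(
    foxl2_cells: pd.DataFrame,
    positivity: PositivityModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify FOXL2+ cells into the four PR/ERa quadrants.

    Input must be restricted to FOXL2+ cells (checked against *positivity*);
    combined with COL1A1 status this yields up to eight subpopulation
    labels.  Returns ``(cells, counts_per_roi)``.
    """
    if len(foxl2_cells) == 0:
        raise ContractViolationError("classify_hormone: empty input")
    foxl2_pos = positivity.is_positive(foxl2_cells, "FOXL2")
    if not foxl2_pos.all():
        n_bad = int((~foxl2_pos).sum())
        raise ContractViolationError(
            f"classify_hormone: input contains {n_bad} FOXL2-negative cell(s)"
        )
    pr = positivity.is_positive(foxl2_cells, "PR")
    era = positivity.is_positive(foxl2_cells, "ERa")
    col = positivity.is_positive(foxl2_cells, "COL1A1")

    quadrant = np.where(
        pr & era, HORMONE_LABELS[0],
        np.where(pr, HORMONE_LABELS[1], np.where(era, HORMONE_LABELS[2],
                 HORMONE_LABELS[3])),
    )
    out = foxl2_cells.copy()
    out["hormone_class"] = quadrant
    col_label = np.where(col, "FOXL2+COL1A1+", "FOXL2+COL1A1-")
    out["foxl2_subpopulation"] = pd.Series(col_label, index=out.index).str.cat(
        out["hormone_class"], sep=" "
    )
    counts = (
        out.groupby(["roi_id", "foxl2_subpopulation"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out, counts


# ---------------------------------------------------------------------------
# balanced subsampling and embedding
# ---------------------------------------------------------------------------

def balanced_subsample(
    cells: pd.DataFrame,
    group_col: str,
    groups: Iterable[str],
    n_per_group: int,
    seed: int,
    panel: MarkerPanel | None = None,
) -> pd.DataFrame:
    """Sample up to *n_per_group* cells per group, without replacement.

    When *panel* is given, only phenotypic marker columns are retained
    (functional and DNA channels dropped), as appropriate for identity-
    focused embeddings.  Deterministic per *seed*.
    """
    groups = list(groups)
    available = set(cells[group_col].unique())
    unknown = [g for g in groups if g not in available]
    if unknown:
        raise ConfigurationError(f"unknown group name(s): {unknown}")
    rng = np.random.default_rng(seed)
    parts = []
    for g in groups:
        sub = cells[cells[group_col] == g]
        if len(sub) < n_per_group:
            log.warning(
                "group %r has only %d cells (< %d requested); taking all",
                g, len(sub), n_per_group,
            )
            take = len(sub)
        else:
            take = n_per_group
        idx = rng.choice(len(sub), size=take, replace=False)
        parts.append(sub.iloc[np.sort(idx)])
    out = pd.concat(parts, ignore_index=True)
    if panel is not None:
        keep = ["cell_id", "sample_id", "roi_id", group_col] + [
            m for m in panel.phenotypic_markers if m in out.columns
        ]
        out = out[[c for c in dict.fromkeys(keep)]]
    return out


def embed_tsne(
    subsample: pd.DataFrame,
    feature_cols: list[str] | None = None,
    perplexity: float = 30.0,
    theta: float = 0.5,
    dims: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """t-SNE embedding of a (balanced) subsample.

    Delegates the optimization to scikit-learn's Barnes-Hut t-SNE
    (``angle`` = *theta*).  Returns one coordinate row per input row, with
    parameters and seed recorded in ``result.attrs``.
    """
    from sklearn.manifold import TSNE

    if feature_cols is None:
        feature_cols = [
            c for c in subsample.columns
            if subsample[c].dtype.kind in "fiu" and not c.endswith("_um")
            and c != "cell_id"
        ]
    X = subsample[feature_cols].to_numpy(dtype=float)
    X = np.arcsinh(X)
    if len(X) < 3 * perplexity:
        raise ConfigurationError(
            f"t-SNE needs >= 3*perplexity rows ({3 * perplexity:.0f}); got "
            f"{len(X)}. Reduce perplexity."
        )
    tsne = TSNE(
        n_components=dims,
        perplexity=perplexity,
        angle=theta,
        method="barnes_hut" if dims <= 3 else "exact",
        init="pca",
        random_state=seed,
    )
    coords = tsne.fit_transform(X)
    out = pd.DataFrame(coords, columns=[f"tsne{i + 1}" for i in range(dims)])
    out.attrs.update(
        {"perplexity": perplexity, "theta": theta, "dims": dims, "seed": seed,
         "features": feature_cols}
    )
    return out
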